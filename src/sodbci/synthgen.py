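"""Synthetic EEG sessions for the wireless stimulus-on-device paradigm.

Emulates a four-node setup in which each appliance carries its own visual
stimulus and receives its triggers over a wireless link.  The link imposes a
per-node transmission delay: the 16 Hz flicker used for registration is
phase-shifted by that delay, and the P300 elicited by the 8 Hz oddball
flashes is latency-shifted by the same delay (plus per-flash and neural
jitter).  Event markers record the time the coordinator *sent* each trigger;
all delay lives in the signal — that desynchronization is exactly what the
downstream calibration has to learn.

Ground truth (true flash onsets, true P300 latencies, true phase lags) is
carried alongside every generated session so estimators can be scored
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EEGRecording, PHASE_CONDITIONS_DEG

__all__ = [
    "SubjectProfile",
    "NodeTimingModel",
    "ParadigmConfig",
    "GeneratedSession",
    "generate_background_noise",
    "generate_ssvep_block",
    "generate_p300_epoch",
    "simulate_registration_session",
    "simulate_operation_session",
    "default_nodes",
]

PARIETAL = ("P3", "Pz", "P4")
OCCIPITAL = ("O1", "O2")


@dataclass
class SubjectProfile:
    """Subject-dependent response parameters.

    Defaults are typical magnitudes for visual ERP work: a P300 of a few
    microvolts riding on ~10 uV background EEG, with single-trial latency
    jitter of several milliseconds.
    """

    p300_base_latency: float = 310.0  # ms, nominal peak after the flash
    p300_amplitude: float = 4.0  # uV
    p300_width: float = 22.0  # ms, Gaussian template SD
    p300_latency_jitter_sd: float = 8.0  # ms, neural trial-to-trial jitter
    ssvep_gain: float = 2.0  # uV, fundamental amplitude
    noise_sd: float = 12.0  # uV, total background SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p300_amplitude < 0:
            raise ValueError("p300_amplitude must be >= 0")
        if self.p300_width <= 0:
            raise ValueError("p300_width must be > 0")
        if self.p300_latency_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class NodeTimingModel:
    """Wireless timing of one stimulation node."""

    node_id: int
    transmission_delay: float = 0.0  # ms, constant per node
    flash_jitter_sd: float = 2.0  # ms, per-flash random extra delay

    def __post_init__(self) -> None:
        if self.transmission_delay < 0:
            raise ValueError("transmission_delay must be >= 0")
        if self.flash_jitter_sd < 0:
            raise ValueError("flash_jitter_sd must be >= 0")


@dataclass
class ParadigmConfig:
    """Stimulation and acquisition parameters of the paradigm."""

    n_nodes: int = 4
    flicker_freq: float = 16.0  # Hz
    flash_freq: float = 8.0  # Hz -> 125 ms SOA
    flicker_duration: float = 5.0  # s per phase condition
    inter_phase_gap: float = 2.0  # s between flicker blocks
    flashes_per_stimulus: int = 30  # registration oddball block
    repetitions: int = 5  # flashes per node per online trial
    sampling_rate: float = 500.0  # Hz
    channel_labels: tuple[str, ...] = ("P3", "Pz", "P4", "O1", "O2")
    phase_conditions: tuple[float, ...] = PHASE_CONDITIONS_DEG  # degrees
    inter_trial_gap: float = 1.0  # s after the last flash of a trial
    block_gap: float = 2.0  # s between paradigm sections

    def __post_init__(self) -> None:
        if self.flicker_freq % self.flash_freq != 0:
            raise ValueError("flash_freq must divide flicker_freq in this design")
        if self.sampling_rate <= 2 * self.flicker_freq:
            raise ValueError("sampling rate must exceed twice the flicker rate")

    @property
    def flicker_period_ms(self) -> float:
        return 1000.0 / self.flicker_freq

    @property
    def t_ref_ms(self) -> float:
        """Latency of the first positive peak of the zero-phase reference
        flicker response: a quarter period (15.625 ms at 16 Hz)."""
        return 0.25 * self.flicker_period_ms

    @property
    def soa_ms(self) -> float:
        return 1000.0 / self.flash_freq


@dataclass
class GeneratedSession:
    """A synthetic recording with its event markers and ground truth.

    ``truth`` maps table names to DataFrames:

    - ``flashes``: one row per flash (onset_s, node_id, is_target,
      true_flash_onset_s, true_latency_ms, trial, repetition, block)
    - ``flicker``: one row per flicker block (onset_s, node_id,
      phase_condition_deg, true_lag_deg, block)
    - ``nodes``: the timing model actually used (node_id,
      transmission_delay_ms, flash_jitter_sd_ms)
    """

    recording: EEGRecording
    events: pd.DataFrame
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)


def default_nodes(
    delays_ms: tuple[float, ...] = (0.0, 15.625, 31.25, 46.875),
    flash_jitter_sd: float = 2.0,
) -> list[NodeTimingModel]:
    """Four nodes with quarter-period-spaced transmission delays, the
    delay grid used throughout the evaluation of this method."""
    return [
        NodeTimingModel(node_id=i, transmission_delay=d, flash_jitter_sd=flash_jitter_sd)
        for i, d in enumerate(delays_ms)
    ]


def generate_background_noise(
    n_samples: int,
    n_channels: int,
    profile: SubjectProfile,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Background EEG: an equal-power mix of 1/f-shaped and white noise,
    normalized to ``profile.noise_sd`` total standard deviation.

    The 1/f component is produced by amplitude-shaping white noise in the
    frequency domain with a 1/sqrt(f) envelope (flat below 1 Hz so the DC
    region stays finite).
    """
    if n_samples <= 0 or n_channels <= 0:
        raise ValueError("n_samples and n_channels must be positive")
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    if profile.noise_sd == 0:
        # draw the same variates to keep the stream position deterministic
        rng.standard_normal((n_channels, n_samples))
        rng.standard_normal((n_channels, n_samples))
        return np.zeros((n_channels, n_samples))

    white = rng.standard_normal((n_channels, n_samples))
    pink_seed = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0)  # unit grid; only the shape matters
    envelope = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if n_samples > 1 else 1.0))
    envelope[0] = envelope[1] if envelope.size > 1 else 1.0
    pink = np.fft.irfft(np.fft.rfft(pink_seed, axis=1) * envelope, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    pink /= sd
    mix = (pink + white) / np.sqrt(2.0)
    return profile.noise_sd * mix


def _ssvep_true_peak_ms(
    condition_phase_deg: float, node: NodeTimingModel, cfg: ParadigmConfig
) -> float:
    """First-positive-peak latency of the evoked flicker response relative
    to the coordinator trigger: t_ref + phase offset + transmission delay."""
    T = cfg.flicker_period_ms
    return cfg.t_ref_ms + condition_phase_deg / 360.0 * T + node.transmission_delay


def _ssvep_waveform(
    n_samples: int,
    sfreq: float,
    peak_ms: float,
    flicker_freq: float,
    gain: float,
    harmonic_ratio: float = 0.2,
) -> np.ndarray:
    t = np.arange(n_samples) / sfreq  # seconds from block onset
    tp = peak_ms / 1000.0
    wave = gain * np.cos(2 * np.pi * flicker_freq * (t - tp))
    if harmonic_ratio:
        wave += gain * harmonic_ratio * np.cos(2 * np.pi * 2 * flicker_freq * (t - tp))
    return wave


def generate_ssvep_block(
    condition_phase: float,
    node: NodeTimingModel,
    cfg: ParadigmConfig,
    profile: SubjectProfile,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """One flicker block: 5 s of steady-state response embedded in noise.

    ``condition_phase`` is the stimulation phase in degrees, one of
    {0, 90, 180, 270}.  Returns ``(segment, true_lag_deg)`` where the
    segment is ``(n_channels, n_samples)`` and the true lag already folds
    in the node's transmission delay (wrapped to [0, 360)).
    """
    if condition_phase not in cfg.phase_conditions:
        raise ValueError(
            f"unsupported phase condition {condition_phase}; "
            f"expected one of {cfg.phase_conditions}"
        )
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    n = round(cfg.flicker_duration * cfg.sampling_rate)
    seg = generate_background_noise(n, len(cfg.channel_labels), profile, rng)
    peak_ms = _ssvep_true_peak_ms(condition_phase, node, cfg)
    wave = _ssvep_waveform(n, cfg.sampling_rate, peak_ms, cfg.flicker_freq, profile.ssvep_gain)
    occ = [cfg.channel_labels.index(ch) for ch in OCCIPITAL]
    seg[occ, :] += wave
    true_lag = (condition_phase + node.transmission_delay / cfg.flicker_period_ms * 360.0) % 360.0
    return seg, true_lag


def _p300_bump(
    n_samples: int, sfreq: float, latency_ms: float, amplitude: float, width_ms: float
) -> np.ndarray:
    t_ms = np.arange(n_samples) / sfreq * 1000.0
    return amplitude * np.exp(-0.5 * ((t_ms - latency_ms) / width_ms) ** 2)


def _p300_channel_weights(ch_names: tuple[str, ...]) -> np.ndarray:
    """Parietal-dominant topography: full amplitude on P3/Pz/P4, half on
    O1/O2, zero elsewhere."""
    w = np.zeros(len(ch_names))
    for i, ch in enumerate(ch_names):
        if ch in PARIETAL:
            w[i] = 1.0
        elif ch in OCCIPITAL:
            w[i] = 0.5
    return w


def generate_p300_epoch(
    is_target: bool,
    node: NodeTimingModel,
    profile: SubjectProfile,
    cfg: ParadigmConfig,
    rng: np.random.Generator | None = None,
    epoch_length_ms: float = 800.0,
) -> tuple[np.ndarray, float]:
    """One single-flash segment, trigger at t=0.

    Target flashes add a positive Gaussian deflection at
    ``base latency + transmission delay + jitter`` (truncated at zero so the
    template never precedes the flash); nontargets are background only.
    Returns ``(segment, true_latency_ms)`` with NaN latency for nontargets.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    n = round(epoch_length_ms / 1000.0 * cfg.sampling_rate)
    seg = generate_background_noise(n, len(cfg.channel_labels), profile, rng)
    if not is_target:
        return seg, float("nan")
    flash_jitter = max(0.0, rng.normal(0.0, node.flash_jitter_sd)) if node.flash_jitter_sd else 0.0
    neural = rng.normal(0.0, profile.p300_latency_jitter_sd) if profile.p300_latency_jitter_sd else 0.0
    latency = max(0.0, profile.p300_base_latency + node.transmission_delay + flash_jitter + neural)
    bump = _p300_bump(n, cfg.sampling_rate, latency, profile.p300_amplitude, profile.p300_width)
    seg += np.outer(_p300_channel_weights(tuple(cfg.channel_labels)), bump)
    return seg, latency


def _flash_schedule(
    rng: np.random.Generator, n_nodes: int, n_rounds: int
) -> np.ndarray:
    """Randomized block order: each round is a fresh permutation of the
    nodes, so every node flashes exactly once per round."""
    return np.concatenate([rng.permutation(n_nodes) for _ in range(n_rounds)])


def _add_flash_block(
    sig: np.ndarray,
    start_s: float,
    target_node: int,
    order: np.ndarray,
    nodes: list[NodeTimingModel],
    cfg: ParadigmConfig,
    profile: SubjectProfile,
    rng: np.random.Generator,
    events: list[dict],
    flash_truth: list[dict],
    *,
    block: int | None = None,
    trial: int | None = None,
) -> float:
    """Append one oddball flash block to the signal; returns its end time."""
    sfreq = cfg.sampling_rate
    weights = _p300_channel_weights(tuple(cfg.channel_labels))
    n_total = sig.shape[1]
    seen: dict[int, int] = {}
    for k, node_id in enumerate(order):
        node_id = int(node_id)
        node = nodes[node_id]
        onset = start_s + k * cfg.soa_ms / 1000.0
        is_target = node_id == target_node
        rep = seen.get(node_id, 0)
        seen[node_id] = rep + 1
        flash_jitter = (
            max(0.0, rng.normal(0.0, node.flash_jitter_sd)) if node.flash_jitter_sd else 0.0
        )
        true_onset = onset + (node.transmission_delay + flash_jitter) / 1000.0
        latency = float("nan")
        if is_target and profile.p300_amplitude > 0:
            neural = (
                rng.normal(0.0, profile.p300_latency_jitter_sd)
                if profile.p300_latency_jitter_sd
                else 0.0
            )
            latency = max(
                0.0,
                profile.p300_base_latency + node.transmission_delay + flash_jitter + neural,
            )
            center = onset + latency / 1000.0
            lo = max(0, int(math.floor((center - 0.25) * sfreq)))
            hi = min(n_total, int(math.ceil((center + 0.25) * sfreq)))
            t_ms = (np.arange(lo, hi) / sfreq - onset) * 1000.0
            bump = profile.p300_amplitude * np.exp(
                -0.5 * ((t_ms - latency) / profile.p300_width) ** 2
            )
            sig[:, lo:hi] += np.outer(weights, bump)
        elif is_target:
            # amplitude 0: latency still drawn so truth stays comparable
            neural = (
                rng.normal(0.0, profile.p300_latency_jitter_sd)
                if profile.p300_latency_jitter_sd
                else 0.0
            )
            latency = max(
                0.0,
                profile.p300_base_latency + node.transmission_delay + flash_jitter + neural,
            )
        events.append(
            {
                "onset_s": onset,
                "node_id": node_id,
                "kind": "flash",
                "phase_condition_deg": float("nan"),
                "is_target": bool(is_target),
                "trial": trial,
                "repetition": rep,
                "block": block,
            }
        )
        flash_truth.append(
            {
                "onset_s": onset,
                "node_id": node_id,
                "is_target": bool(is_target),
                "true_flash_onset_s": true_onset,
                "true_latency_ms": latency,
                "trial": trial,
                "repetition": rep,
                "block": block,
            }
        )
    return start_s + len(order) * cfg.soa_ms / 1000.0


def _nodes_frame(nodes: list[NodeTimingModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_id": [n.node_id for n in nodes],
            "transmission_delay_ms": [n.transmission_delay for n in nodes],
            "flash_jitter_sd_ms": [n.flash_jitter_sd for n in nodes],
        }
    )


def simulate_registration_session(
    nodes: list[NodeTimingModel],
    cfg: ParadigmConfig | None = None,
    profile: SubjectProfile | None = None,
    seed: int | None = None,
) -> GeneratedSession:
    """Simulate the registration scheme: node by node, a flicker sweep over
    the four phase conditions followed by an oddball training block with the
    registered node as target.

    Per registered node this yields 4 flicker blocks (5 s each, 2 s gaps)
    and ``flashes_per_stimulus`` flashes of every node
    (4 x 30 = 120 flash events: 30 target, 90 nontarget at defaults).
    """
    cfg = cfg or ParadigmConfig()
    profile = profile or SubjectProfile()
    if len(nodes) != cfg.n_nodes:
        raise ValueError("need one timing model per node")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    sfreq = cfg.sampling_rate
    n_ch = len(cfg.channel_labels)

    # ---- lay out the timeline first so the signal buffer can be allocated
    flick_len = cfg.flicker_duration + cfg.inter_phase_gap
    flash_block_len = cfg.n_nodes * cfg.flashes_per_stimulus * cfg.soa_ms / 1000.0
    per_node = len(cfg.phase_conditions) * flick_len + flash_block_len + cfg.block_gap
    total_s = len(nodes) * per_node + 1.0  # tail so late windows stay in bounds
    n_total = int(round(total_s * sfreq))
    sig = generate_background_noise(n_total, n_ch, profile, rng)

    events: list[dict] = []
    flash_truth: list[dict] = []
    flick_truth: list[dict] = []
    occ = [cfg.channel_labels.index(ch) for ch in OCCIPITAL]

    t = 0.0
    for node in nodes:
        for phi in cfg.phase_conditions:
            onset = t
            n_seg = round(cfg.flicker_duration * sfreq)
            lo = int(round(onset * sfreq))
            peak_ms = _ssvep_true_peak_ms(phi, node, cfg)
            wave = _ssvep_waveform(
                n_seg, sfreq, peak_ms, cfg.flicker_freq, profile.ssvep_gain
            )
            sig[np.ix_(occ, range(lo, lo + n_seg))] += wave
            true_lag = (
                phi + node.transmission_delay / cfg.flicker_period_ms * 360.0
            ) % 360.0
            events.append(
                {
                    "onset_s": onset,
                    "node_id": node.node_id,
                    "kind": "flicker_onset",
                    "phase_condition_deg": phi,
                    "is_target": None,
                    "trial": None,
                    "repetition": None,
                    "block": node.node_id,
                }
            )
            flick_truth.append(
                {
                    "onset_s": onset,
                    "node_id": node.node_id,
                    "phase_condition_deg": phi,
                    "true_lag_deg": true_lag,
                    "block": node.node_id,
                }
            )
            t += flick_len
        order = _flash_schedule(rng, cfg.n_nodes, cfg.flashes_per_stimulus)
        t = _add_flash_block(
            sig, t, node.node_id, order, nodes, cfg, profile, rng,
            events, flash_truth, block=node.node_id,
        )
        t += cfg.block_gap

    recording = EEGRecording(data=sig, sfreq=sfreq, ch_names=list(cfg.channel_labels))
    truth = {
        "flashes": pd.DataFrame(flash_truth),
        "flicker": pd.DataFrame(flick_truth),
        "nodes": _nodes_frame(nodes),
    }
    return GeneratedSession(recording=recording, events=pd.DataFrame(events), truth=truth)


def simulate_operation_session(
    nodes: list[NodeTimingModel],
    cfg: ParadigmConfig | None = None,
    profile: SubjectProfile | None = None,
    n_trials: int = 100,
    cued: list[int] | None = None,
    seed: int | None = None,
) -> GeneratedSession:
    """Simulate an online operation session.

    Each trial cues one node; all nodes flash ``repetitions`` times in
    randomized block order (4 x 5 = 20 flashes per trial at defaults).
    100 trials therefore yield 100 target and 300 nontarget averaged
    epoch groups.  Cues default to a balanced shuffled assignment.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = cfg or ParadigmConfig()
    profile = profile or SubjectProfile()
    if len(nodes) != cfg.n_nodes:
        raise ValueError("need one timing model per node")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    sfreq = cfg.sampling_rate
    n_ch = len(cfg.channel_labels)

    if cued is None:
        base = np.tile(np.arange(cfg.n_nodes), n_trials // cfg.n_nodes + 1)[:n_trials]
        cued_arr = rng.permutation(base)
    else:
        if len(cued) != n_trials:
            raise ValueError("cued list must have one entry per trial")
        cued_arr = np.asarray(cued)

    trial_len = cfg.repetitions * cfg.n_nodes * cfg.soa_ms / 1000.0 + cfg.inter_trial_gap
    total_s = n_trials * trial_len + 1.0
    n_total = int(round(total_s * sfreq))
    sig = generate_background_noise(n_total, n_ch, profile, rng)

    events: list[dict] = []
    flash_truth: list[dict] = []
    t = 0.0
    for trial in range(n_trials):
        order = _flash_schedule(rng, cfg.n_nodes, cfg.repetitions)
        t = _add_flash_block(
            sig, t, int(cued_arr[trial]), order, nodes, cfg, profile, rng,
            events, flash_truth, trial=trial,
        )
        t += cfg.inter_trial_gap

    recording = EEGRecording(data=sig, sfreq=sfreq, ch_names=list(cfg.channel_labels))
    trials = pd.DataFrame({"trial": np.arange(n_trials), "cued_node": cued_arr})
    truth = {
        "flashes": pd.DataFrame(flash_truth),
        "trials": trials,
        "nodes": _nodes_frame(nodes),
    }
    return GeneratedSession(recording=recording, events=pd.DataFrame(events), truth=truth)
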