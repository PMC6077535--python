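"""SSVEP peak-latency and phase-lag estimation.

The evoked flicker response is phase-locked to the (delayed) stimulus, so
its peak latency relative to the coordinator trigger carries the wireless
transmission delay.  The latency is read off the Fourier component at the
stimulation frequency: over an exact number of cycles (5 s x 16 Hz = 80)
that bin is leakage-free, which sidesteps the fact that at 500 Hz a 16 Hz
cycle is not an integer number of samples (31.25) and time-domain peak
picking would need interpolation.

The phase lag theta of a block stimulated with phase condition phi at a node
with delay d satisfies theta = phi + d/T * 360 (mod 360), with T the flicker
period — the linear relationship the downstream calibration exploits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    EEGRecording,
    NoSSVEPError,
    PHASE_CONDITIONS_DEG,
    PhaseLagVector,
)

__all__ = [
    "estimate_response_peak",
    "compute_phase_lag",
    "build_phase_lag_vector",
    "T_REF_MS",
    "FLICKER_PERIOD_MS",
]

#: First-positive-peak latency of the zero-phase 16 Hz reference, ms (T/4).
T_REF_MS = 15.625
#: Period of the 16 Hz flicker, ms.
FLICKER_PERIOD_MS = 62.5

SSVEP_CHANNELS = ("O1", "O2")


def estimate_response_peak(
    segment: np.ndarray,
    sfreq: float,
    flicker_freq: float = 16.0,
    amplitude_floor: float = 0.1,
) -> float:
    """Latency (ms) of the first positive peak of the response at
    ``flicker_freq`` within one stimulation period.

    ``segment`` is 1-D (already channel-averaged) or 2-D
    ``(channels, samples)``, in which case rows are averaged.  The segment
    should span an integer number of flicker cycles so the Fourier bin is
    exact.  Raises :class:`NoSSVEPError` if the component amplitude falls
    below ``amplitude_floor`` (uV).
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=0)
    n = x.size
    if n < sfreq / flicker_freq:
        raise ValueError("segment shorter than one flicker cycle")
    x = x - x.mean()
    t = np.arange(n) / sfreq
    c = np.sum(x * np.exp(-2j * np.pi * flicker_freq * t))
    amplitude = 2.0 * np.abs(c) / n
    if amplitude < amplitude_floor:
        raise NoSSVEPError(
            f"response at {flicker_freq} Hz is {amplitude:.3g} uV, below the "
            f"{amplitude_floor} uV floor"
        )
    # x(t) ~ A cos(2 pi f t + phase); the first positive peak after t=0 is
    # where the argument is a multiple of 2 pi.
    phase = np.angle(c)
    period_ms = 1000.0 / flicker_freq
    t_res = (-phase / (2 * np.pi * flicker_freq)) * 1000.0
    return float(t_res % period_ms)


def compute_phase_lag(t_res: float, t_ref: float = T_REF_MS, T: float = FLICKER_PERIOD_MS) -> float:
    """Phase lag in degrees: ``(t_res - t_ref) / T * 360``, wrapped to
    [0, 360)."""
    if T <= 0:
        raise ValueError("flicker period must be positive")
    return float(((t_res - t_ref) / T * 360.0) % 360.0)


def build_phase_lag_vector(
    recording: EEGRecording,
    events: pd.DataFrame,
    node_id: int,
    flicker_freq: float = 16.0,
    flicker_duration: float = 5.0,
    channels: tuple[str, ...] = SSVEP_CHANNELS,
) -> PhaseLagVector:
    """Measure the four-condition phase-lag vector of one node from its
    registration flicker blocks.

    ``events`` must contain ``flicker_onset`` rows with ``node_id`` and
    ``phase_condition_deg``; every condition in {0, 90, 180, 270} must be
    present for the node.
    """
    flick = events[(events["kind"] == "flicker_onset") & (events["node_id"] == node_id)]
    lags: dict[float, float] = {}
    ch_idx = recording.channel_index([c for c in channels if c in recording.ch_names])
    n_seg = round(flicker_duration * recording.sfreq)
    for cond in PHASE_CONDITIONS_DEG:
        rows = flick[np.isclose(flick["phase_condition_deg"].astype(float), cond)]
        if len(rows) == 0:
            raise ValueError(
                f"node {node_id}: missing flicker block for phase condition "
                f"{cond} deg"
            )
        onset = float(rows.iloc[0]["onset_s"])
        start = int(np.floor(onset * recording.sfreq))
        seg = recording.data[np.ix_(ch_idx, range(start, start + n_seg))]
        t_res = estimate_response_peak(seg, recording.sfreq, flicker_freq)
        lags[cond] = compute_phase_lag(t_res, T_REF_MS, 1000.0 / flicker_freq)
    return PhaseLagVector(lags=lags, node_id=node_id)
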