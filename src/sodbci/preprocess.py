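"""Band-pass filtering, epoch extraction, downsampling, averaging, and
P300 latency-centroid estimation.

Conventions used throughout (and relied on by the window-placement logic in
:mod:`sodbci.decode`): 0-based sample indexing, half-open windows
``[start, start + n)``, and ``sample = floor(time * rate)``.  The band-pass
is a zero-phase (forward-backward) 4th-order Butterworth: latency is the
measurand here, so the filter must not shift it.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .types import EEGRecording, Epoch, EpochSet, LatencyCentroid, NoP300Error

__all__ = [
    "bandpass_filter",
    "extract_epochs",
    "downsample",
    "average_epochs",
    "estimate_p300_centroid",
    "CENTROID_CHANNELS",
]

#: Channels averaged before latency-centroid estimation (parietal dominant).
CENTROID_CHANNELS = ("P3", "Pz", "P4")


def bandpass_filter(
    recording: EEGRecording, low: float = 4.0, high: float = 20.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass; removes DC, preserves latency."""
    nyq = recording.sfreq / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.sfreq, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(filtered)


def extract_epochs(
    recording: EEGRecording,
    events,
    start_offset: float = 0.0,
    length: float = 600.0,
) -> EpochSet:
    """Cut one epoch per event row.

    Parameters
    ----------
    events:
        DataFrame with at least ``onset_s``; any of ``node_id``,
        ``is_target``, ``trial``, ``repetition``, ``block`` are carried into
        each epoch's ``meta``.
    start_offset, length:
        Window ``[onset + start_offset, onset + start_offset + length)``
        in ms relative to the trigger.
    """
    n = round(length * recording.sfreq / 1000.0)
    meta_cols = [
        c for c in ("node_id", "is_target", "trial", "repetition", "block")
        if c in events.columns
    ]
    epochs = []
    for idx, row in events.iterrows():
        start = int(np.floor((row["onset_s"] + start_offset / 1000.0) * recording.sfreq))
        if start < 0 or start + n > recording.n_samples:
            raise ValueError(
                f"epoch window [{start}, {start + n}) for event at "
                f"{row['onset_s']:.3f} s (row {idx}) is outside the recording"
            )
        meta = {c: row[c] for c in meta_cols}
        epochs.append(
            Epoch(
                samples=recording.data[:, start : start + n],
                t0_ms=start_offset,
                sfreq=recording.sfreq,
                ch_names=recording.ch_names,
                meta=meta,
            )
        )
    return EpochSet(epochs)


def downsample(epochs: EpochSet, target_rate: float = 62.5) -> EpochSet:
    """Decimate each epoch by the integer factor ``sfreq / target_rate``,
    keeping phase-0 samples.  The band-pass has already limited the signal
    below the target Nyquist, so plain sample picking is alias-free."""
    if len(epochs) == 0:
        return epochs
    factor = epochs.sfreq / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_rate} Hz does not divide {epochs.sfreq} Hz"
        )
    factor = int(round(factor))
    out = [
        ep.copy_with(ep.samples[:, ::factor], sfreq=target_rate)
        for ep in epochs
    ]
    return EpochSet(out)


def average_epochs(epochs: EpochSet, group_keys: Sequence[str]) -> EpochSet:
    """Sample-wise mean per group of ``meta`` keys.

    The returned epochs carry the grouping keys (plus ``n_averaged``) in
    their ``meta``; groups are emitted in order of first appearance.
    """
    if len(epochs) == 0:
        raise ValueError("cannot average an empty epoch set")
    groups: dict[tuple, list[Epoch]] = defaultdict(list)
    order: list[tuple] = []
    for ep in epochs:
        key = tuple(ep.meta.get(k) for k in group_keys)
        if key not in groups:
            order.append(key)
        groups[key].append(ep)
    out = []
    for key in order:
        members = groups[key]
        mean = np.mean([ep.samples for ep in members], axis=0)
        meta = dict(zip(group_keys, key))
        # carry constant metadata through (e.g. is_target within a node group)
        for extra in ("is_target", "node_id", "trial", "block"):
            if extra not in meta:
                vals = {m.meta.get(extra) for m in members}
                if len(vals) == 1:
                    meta[extra] = vals.pop()
        meta["n_averaged"] = len(members)
        out.append(members[0].copy_with(mean, meta=meta))
    return EpochSet(out)


def estimate_p300_centroid(
    avg_epoch: Epoch,
    search_window: tuple[float, float] = (200.0, 500.0),
    channels: Sequence[str] = CENTROID_CHANNELS,
) -> LatencyCentroid:
    """Half-peak amplitude-weighted latency centroid of the averaged P300.

    The parietal channels are averaged, the maximum within the search
    window located, and the amplitude-weighted mean time taken over a
    contiguous run of samples at or above 50% of that peak.  When several
    runs clear the threshold (noisy multimodal averages), the run with the
    largest area is used: a broad evoked deflection beats a narrow noise
    spike of comparable height.  For a clean symmetric deflection the
    centroid equals the peak latency; under noise it degrades gracefully
    instead of jumping between samples.
    """
    times = avg_epoch.times_ms
    lo, hi = search_window
    if lo < times[0] or hi > times[-1] + 1000.0 / avg_epoch.sfreq:
        raise ValueError(
            f"search window {search_window} outside epoch span "
            f"[{times[0]}, {times[-1]}] ms"
        )
    chans = [c for c in channels if c in avg_epoch.ch_names]
    if not chans:
        raise ValueError("none of the centroid channels present in epoch")
    wave = avg_epoch.samples[avg_epoch.channel_index(chans)].mean(axis=0)
    mask = (times >= lo) & (times < hi)
    idx = np.flatnonzero(mask)
    win = wave[idx]
    peak_pos = int(np.argmax(win))
    peak = win[peak_pos]
    if peak <= 0 or np.allclose(win, win[0]):
        raise NoP300Error("no positive deflection in the search window")
    half = 0.5 * peak
    above = win >= half
    # contiguous runs above the half-max threshold; keep the one with the
    # largest area
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(win))
    a, b = max(zip(starts, ends), key=lambda r: win[r[0] : r[1]].sum())
    sel = idx[a:b]
    weights = wave[sel]
    value = float(np.sum(times[sel] * weights) / np.sum(weights))
    return LatencyCentroid(value=value, source="measured")
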