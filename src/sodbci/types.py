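"""Shared containers for continuous EEG, epochs, and decoding artifacts.

The containers are deliberately light: plain dataclasses wrapping numpy
arrays and pandas frames, with the invariants a decoding pipeline relies on
(channel/sample geometry, explicit epoch time origin ``t0_ms``) enforced at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "Epoch",
    "EpochSet",
    "PhaseLagVector",
    "LatencyCentroid",
    "SessionMetrics",
    "NoP300Error",
    "NoSSVEPError",
    "NoRuleFiredError",
    "PHASE_CONDITIONS_DEG",
]

#: Flicker stimulation phase conditions, degrees. Order is canonical.
PHASE_CONDITIONS_DEG = (0.0, 90.0, 180.0, 270.0)


class NoP300Error(ValueError):
    """Raised when an averaged epoch contains no positive deflection."""


class NoSSVEPError(ValueError):
    """Raised when a flicker segment has no measurable response at the
    stimulation frequency."""


class NoRuleFiredError(ValueError):
    """Raised when a fuzzy inference input fires no rule (all upper firing
    strengths are zero)."""


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` array, microvolts.
    sfreq:
        Sampling rate in Hz.
    ch_names:
        Channel labels, one per row of ``data``.
    """

    data: np.ndarray
    sfreq: float
    ch_names: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.ch_names = list(self.ch_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.ch_names.index(n) for n in names])
        except ValueError as exc:
            raise KeyError(f"channel not present: {exc}") from None

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data=data, sfreq=self.sfreq, ch_names=list(self.ch_names))


@dataclass
class Epoch:
    """A stimulus-locked EEG segment.

    ``t0_ms`` is the latency of the first sample relative to the event
    trigger (the coordinator send time), so windows expressed in
    trigger-relative milliseconds can always be located on the sample grid.
    """

    samples: np.ndarray  # (n_channels, n_times)
    t0_ms: float
    sfreq: float
    ch_names: Sequence[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be 2-D")
        if len(self.ch_names) != self.samples.shape[0]:
            raise ValueError("channel names do not match sample rows")
        self.ch_names = list(self.ch_names)

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Trigger-relative time of each sample, ms."""
        return self.t0_ms + np.arange(self.n_times) * 1000.0 / self.sfreq

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.ch_names.index(n) for n in names])

    def copy_with(self, samples: np.ndarray, **changes: Any) -> "Epoch":
        kwargs = {
            "samples": samples,
            "t0_ms": self.t0_ms,
            "sfreq": self.sfreq,
            "ch_names": list(self.ch_names),
            "meta": dict(self.meta),
        }
        kwargs.update(changes)
        return Epoch(**kwargs)


class EpochSet:
    """A homogeneous collection of :class:`Epoch`.

    All member epochs share channel labels, sampling rate, ``t0_ms`` and
    length; grouping keys live in each epoch's ``meta`` dict
    (``node_id``, ``trial``, ``repetition``, ``is_target``, ``block`` ...).
    """

    def __init__(self, epochs: Sequence[Epoch]):
        epochs = list(epochs)
        if epochs:
            ref = epochs[0]
            for ep in epochs[1:]:
                if (
                    ep.samples.shape != ref.samples.shape
                    or ep.sfreq != ref.sfreq
                    or ep.t0_ms != ref.t0_ms
                    or ep.ch_names != ref.ch_names
                ):
                    raise ValueError("epochs in a set must share geometry")
        self.epochs = epochs

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    @property
    def sfreq(self) -> float:
        return self.epochs[0].sfreq

    @property
    def t0_ms(self) -> float:
        return self.epochs[0].t0_ms

    @property
    def ch_names(self) -> list[str]:
        return self.epochs[0].ch_names

    def stack(self) -> np.ndarray:
        """``(n_epochs, n_channels, n_times)`` array."""
        return np.stack([ep.samples for ep in self.epochs])

    def select(self, **criteria: Any) -> "EpochSet":
        """Subset by exact match on ``meta`` entries."""
        keep = [
            ep
            for ep in self.epochs
            if all(ep.meta.get(k) == v for k, v in criteria.items())
        ]
        return EpochSet(keep)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame([ep.meta for ep in self.epochs])


@dataclass
class PhaseLagVector:
    """Four SSVEP phase lags (degrees in [0, 360)), one per stimulation
    phase condition {0, pi/2, pi, 3pi/2}, for one stimulation node."""

    lags: dict[float, float]  # condition degrees -> lag degrees
    node_id: int

    def __post_init__(self) -> None:
        missing = [c for c in PHASE_CONDITIONS_DEG if c not in self.lags]
        if missing:
            raise ValueError(f"missing phase condition(s): {missing}")
        for c, lag in self.lags.items():
            if not (0.0 <= lag < 360.0):
                raise ValueError(f"lag {lag} for condition {c} outside [0, 360)")

    def as_array(self) -> np.ndarray:
        """Lags ordered by the canonical condition order."""
        return np.array([self.lags[c] for c in PHASE_CONDITIONS_DEG])


@dataclass
class LatencyCentroid:
    """Temporal center of a P300 deflection, ms from the flash trigger."""

    value: float
    source: str  # "measured" | "predicted"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("latency centroid must be non-negative")
        if self.source not in ("measured", "predicted"):
            raise ValueError("source must be 'measured' or 'predicted'")


@dataclass
class SessionMetrics:
    """Per-condition selection performance of an operation session."""

    accuracy: float  # percent of trials with correct node selection
    itr: float  # bits/min
    epoch_length: float  # ms
    calibrated: bool
    n_trials: int = 0
    selection_time: float = 3.0  # seconds per selection

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy is a percentage in [0, 100]")
        if self.itr < 0:
            raise ValueError("ITR cannot be negative")
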