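"""Interval type-2 fuzzy regressor: four phase-lag inputs, one latency output.

The system uses Gaussian membership functions with an uncertain mean
(``[m_low, m_high]``, fixed sigma): the footprint of uncertainty is the band
between the lower membership function (minimum of the two shifted
Gaussians) and the upper one (1 inside the mean interval, nearest shifted
Gaussian outside).  The rule base is diagonal — rule ``j`` pairs the ``j``-th
membership function of every input under a product t-norm — so three rules
cover the three membership functions and the full parameter vector stays at
D = 4 inputs x 3 MFs x 3 parameters + 3 rules x 2 consequent endpoints = 42,
a size a bee-colony search can handle.

Inference: fuzzify -> product-t-norm firing intervals -> Karnik-Mendel
center-of-sets type reduction to [y_l, y_r] -> midpoint defuzzification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import LatencyCentroid, NoRuleFiredError, PhaseLagVector

__all__ = [
    "IT2MembershipFunction",
    "IT2FParams",
    "N_INPUTS",
    "N_MFS",
    "N_RULES",
    "N_PARAMS",
    "fuzzify",
    "compute_firing_intervals",
    "type_reduce_cos",
    "defuzzify",
    "predict",
    "predict_batch",
]

N_INPUTS = 4  # one phase lag per stimulation phase condition
N_MFS = 3  # membership functions per input
N_RULES = 3  # diagonal rule base: one rule per MF index
N_PARAMS = N_INPUTS * N_MFS * 3 + N_RULES * 2  # = 42


@dataclass
class IT2MembershipFunction:
    """Gaussian MF with uncertain mean ``[m_low, m_high]`` and fixed sigma."""

    m_low: float
    m_high: float
    sigma: float

    def __post_init__(self) -> None:
        if self.m_low > self.m_high:
            raise ValueError("m_low must not exceed m_high")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def grades(self, x: float) -> tuple[float, float]:
        """(lower, upper) membership grades at ``x``."""
        lo, up = _grades_arrays(
            np.asarray([x], dtype=float),
            np.asarray([self.m_low]),
            np.asarray([self.m_high]),
            np.asarray([self.sigma]),
        )
        return float(lo[0]), float(up[0])


def _grades_arrays(
    x: np.ndarray, m_low: np.ndarray, m_high: np.ndarray, sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized lower/upper Gaussian grades; broadcasts ``x`` against the
    MF parameter arrays."""
    g_lo = np.exp(-0.5 * ((x - m_low) / sigma) ** 2)
    g_hi = np.exp(-0.5 * ((x - m_high) / sigma) ** 2)
    lower = np.minimum(g_lo, g_hi)
    upper = np.where(
        (x >= m_low) & (x <= m_high), 1.0, np.maximum(g_lo, g_hi)
    )
    return lower, upper


@dataclass
class IT2FParams:
    """Full parameter set of the regressor.

    ``m_low``, ``m_high``, ``sigma`` have shape ``(N_INPUTS, N_MFS)``;
    ``c_l``, ``c_r`` have shape ``(N_RULES,)`` (interval consequents, ms).
    """

    m_low: np.ndarray
    m_high: np.ndarray
    sigma: np.ndarray
    c_l: np.ndarray
    c_r: np.ndarray

    def __post_init__(self) -> None:
        self.m_low = np.asarray(self.m_low, dtype=float)
        self.m_high = np.asarray(self.m_high, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.c_l = np.asarray(self.c_l, dtype=float)
        self.c_r = np.asarray(self.c_r, dtype=float)
        if self.m_low.shape != (N_INPUTS, N_MFS):
            raise ValueError(f"m_low must be {(N_INPUTS, N_MFS)}")
        for name, arr in (("m_high", self.m_high), ("sigma", self.sigma)):
            if arr.shape != (N_INPUTS, N_MFS):
                raise ValueError(f"{name} must be {(N_INPUTS, N_MFS)}")
        if self.c_l.shape != (N_RULES,) or self.c_r.shape != (N_RULES,):
            raise ValueError(f"consequents must be {(N_RULES,)}")
        if np.any(self.m_low > self.m_high):
            raise ValueError("m_low must not exceed m_high")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.c_l > self.c_r):
            raise ValueError("c_l must not exceed c_r")

    # ---- flat-vector codec (the bee-colony search operates on this) ----

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.m_low.ravel(),
                self.m_high.ravel(),
                self.sigma.ravel(),
                self.c_l,
                self.c_r,
            ]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, repair: bool = False) -> "IT2FParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_PARAMS,):
            raise ValueError(f"parameter vector must have length {N_PARAMS}")
        k = N_INPUTS * N_MFS
        m_low = vec[:k].reshape(N_INPUTS, N_MFS).copy()
        m_high = vec[k : 2 * k].reshape(N_INPUTS, N_MFS).copy()
        sigma = vec[2 * k : 3 * k].reshape(N_INPUTS, N_MFS).copy()
        c_l = vec[3 * k : 3 * k + N_RULES].copy()
        c_r = vec[3 * k + N_RULES :].copy()
        if repair:
            m_lo = np.minimum(m_low, m_high)
            m_hi = np.maximum(m_low, m_high)
            m_low, m_high = m_lo, m_hi
            sigma = np.abs(sigma)
            sigma[sigma == 0] = 1e-6
            cl = np.minimum(c_l, c_r)
            cr = np.maximum(c_l, c_r)
            c_l, c_r = cl, cr
        return cls(m_low=m_low, m_high=m_high, sigma=sigma, c_l=c_l, c_r=c_r)

    # ---- JSON round trip (exact: floats serialized via repr) ----

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "m_low": self.m_low.tolist(),
            "m_high": self.m_high.tolist(),
            "sigma": self.sigma.tolist(),
            "c_l": self.c_l.tolist(),
            "c_r": self.c_r.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "IT2FParams":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        d = json.loads(text)
        return cls(**{k: np.asarray(v) for k, v in d.items()})


def fuzzify(x: PhaseLagVector | np.ndarray, params: IT2FParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-input, per-MF membership intervals.

    Returns ``(lower, upper)``, each ``(N_INPUTS, N_MFS)``.
    """
    xv = x.as_array() if isinstance(x, PhaseLagVector) else np.asarray(x, dtype=float)
    if xv.shape != (N_INPUTS,):
        raise ValueError(f"input must have {N_INPUTS} phase lags")
    return _grades_arrays(xv[:, None], params.m_low, params.m_high, params.sigma)


def compute_firing_intervals(
    grades: tuple[np.ndarray, np.ndarray], params: IT2FParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Product t-norm across inputs, diagonal rule base.

    Rule ``j`` combines MF ``j`` of every input; returns
    ``(f_low, f_high)``, each ``(N_RULES,)``.
    """
    lower, upper = grades
    return lower.prod(axis=0), upper.prod(axis=0)


def _km_bound(c: np.ndarray, f_low: np.ndarray, f_high: np.ndarray, side: str) -> float:
    """Karnik-Mendel iteration for one bound of the type-reduced interval.

    Consequent endpoints ``c`` are sorted ascending; for ``side='left'`` the
    admissible weight pattern is f_high below the switch point and f_low
    above (minimizing the weighted mean), mirrored for ``side='right'``.
    The switch point is integer-valued, so iteration terminates exactly.
    """
    order = np.argsort(c, kind="stable")
    c = c[order]
    f_low = f_low[order]
    f_high = f_high[order]
    n = c.size
    w = (f_low + f_high) / 2.0
    if w.sum() == 0:
        w = f_high.copy()
    y = float(np.dot(w, c) / w.sum())
    prev_k = -2
    for _ in range(n + 2):
        # switch point: number of consequents at or below y
        k = int(np.searchsorted(c, y, side="right"))
        k = min(max(k, 1), n - 1) if n > 1 else 0
        if side == "left":
            w = np.concatenate([f_high[:k], f_low[k:]])
        else:
            w = np.concatenate([f_low[:k], f_high[k:]])
        s = w.sum()
        if s == 0:
            w = f_high.copy()
            s = w.sum()
        y_new = float(np.dot(w, c) / s)
        if k == prev_k:
            return y_new
        prev_k = k
        y = y_new
    return y


def _km_bound_batch(
    c: np.ndarray, f_low: np.ndarray, f_high: np.ndarray, side: str
) -> np.ndarray:
    """Karnik-Mendel bound for a batch: same iteration as :func:`_km_bound`
    vectorized over rows of ``f_low``/``f_high`` (``(K, n)``).  The update
    is idempotent once the integer switch point stabilizes, so a fixed
    ``n + 2`` sweeps suffice for exact convergence."""
    order = np.argsort(c, kind="stable")
    c = c[order]
    f_low = f_low[:, order]
    f_high = f_high[:, order]
    K, n = f_low.shape
    w = (f_low + f_high) / 2.0
    s = w.sum(axis=1)
    bad = s == 0
    if np.any(bad):
        w[bad] = f_high[bad]
        s = w.sum(axis=1)
    y = (w @ c) / s
    pos = np.arange(n)[None, :]
    for _ in range(n + 2):
        k = np.sum(c[None, :] <= y[:, None], axis=1)
        if n > 1:
            k = np.clip(k, 1, n - 1)
        else:
            k = np.zeros(K, dtype=int)
        mask = pos < k[:, None]
        if side == "left":
            w = np.where(mask, f_high, f_low)
        else:
            w = np.where(mask, f_low, f_high)
        s = w.sum(axis=1)
        bad = s == 0
        if np.any(bad):
            w[bad] = f_high[bad]
            s = w.sum(axis=1)
        y = (w @ c) / s
    return y


def type_reduce_cos(
    firing: tuple[np.ndarray, np.ndarray], consequents: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float]:
    """Center-of-sets type reduction via the Karnik-Mendel procedure.

    ``firing`` is ``(f_low, f_high)`` per rule; ``consequents`` is
    ``(c_l, c_r)``.  Returns the type-reduced interval ``(y_l, y_r)`` with
    ``y_l <= y_r``.  Raises :class:`NoRuleFiredError` when every upper
    firing strength is zero.
    """
    f_low, f_high = (np.asarray(a, dtype=float) for a in firing)
    c_l, c_r = (np.asarray(a, dtype=float) for a in consequents)
    if np.all(f_high <= 0):
        raise NoRuleFiredError("all upper firing strengths are zero")
    y_l = _km_bound(c_l, f_low, f_high, side="left")
    y_r = _km_bound(c_r, f_low, f_high, side="right")
    return y_l, y_r


def defuzzify(y_l: float, y_r: float) -> float:
    """Crisp output: interval midpoint."""
    if y_l > y_r + 1e-12:
        raise ValueError("y_l must not exceed y_r")
    return 0.5 * (y_l + y_r)


def predict(x: PhaseLagVector | np.ndarray, params: IT2FParams) -> LatencyCentroid:
    """Full inference chain on one phase-lag vector."""
    grades = fuzzify(x, params)
    firing = compute_firing_intervals(grades, params)
    y_l, y_r = type_reduce_cos(firing, (params.c_l, params.c_r))
    return LatencyCentroid(value=max(0.0, defuzzify(y_l, y_r)), source="predicted")


def predict_batch(X: np.ndarray, params: IT2FParams) -> np.ndarray:
    """Predict latencies for ``(K, N_INPUTS)`` inputs.

    Fuzzification and firing are vectorized over the batch; the
    Karnik-Mendel reduction runs per row (three rules, a handful of
    iterations).  Raises :class:`NoRuleFiredError` if any row fires no rule.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_INPUTS:
        raise ValueError(f"X must be (K, {N_INPUTS})")
    lower, upper = _grades_arrays(
        X[:, :, None], params.m_low[None], params.m_high[None], params.sigma[None]
    )
    f_low = lower.prod(axis=1)  # (K, N_RULES)
    f_high = upper.prod(axis=1)
    silent = np.all(f_high <= 0, axis=1)
    if np.any(silent):
        raise NoRuleFiredError(
            f"input row(s) {np.flatnonzero(silent).tolist()} fire no rule"
        )
    y_l = _km_bound_batch(params.c_l, f_low, f_high, side="left")
    y_r = _km_bound_batch(params.c_r, f_low, f_high, side="right")
    return 0.5 * (y_l + y_r)
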