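"""CCA-based spatial filter for event-related potentials.

The filter is learned by canonically correlating the concatenated
single-trial target epochs (``M``) with the grand-average ERP tiled at each
epoch position (``N``): the leading canonical components are the channel
weightings under which single trials best resemble the average ERP, i.e.
the directions in sensor space with the highest ERP signal-to-noise ratio.
``W_M^T`` is then applied as a spatial filter to any epoch.

The transformations are obtained from the generalized eigenproblems

    C_MM^-1 C_MN C_NN^-1 C_NM  W_M = rho^2 W_M
    C_NN^-1 C_NM C_MM^-1 C_MN  W_N = rho^2 W_N

with a small ridge added to near-singular covariances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .types import Epoch, EpochSet

__all__ = ["PairedDataset", "SpatialFilter", "build_target_signal", "fit_cca", "apply_filter"]

logger = logging.getLogger(__name__)


@dataclass
class PairedDataset:
    """Observation matrix ``M`` and target-signal matrix ``N``
    (channels x concatenated samples, equal shapes)."""

    M: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.M.shape != self.N.shape:
            raise ValueError("M and N must have identical shapes")
        if self.M.ndim != 2:
            raise ValueError("M and N must be 2-D (channels x samples)")


@dataclass
class SpatialFilter:
    """Fitted CCA transformations and canonical correlations."""

    W_M: np.ndarray  # (q, q), columns sorted by descending rho
    W_N: np.ndarray
    rho: np.ndarray  # canonical correlations, descending, in [0, 1]
    n_keep: int = 1

    def __post_init__(self) -> None:
        self.W_M = np.asarray(self.W_M, dtype=float)
        self.W_N = np.asarray(self.W_N, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(np.diff(self.rho) > 1e-9):
            raise ValueError("rho must be sorted descending")
        if np.any((self.rho < -1e-9) | (self.rho > 1 + 1e-9)):
            raise ValueError("canonical correlations must lie in [0, 1]")
        if not (1 <= self.n_keep <= self.W_M.shape[1]):
            raise ValueError("n_keep must be in [1, q]")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "W_M": self.W_M.tolist(),
            "W_N": self.W_N.tolist(),
            "rho": self.rho.tolist(),
            "n_keep": self.n_keep,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpatialFilter":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        d = json.loads(text)
        return cls(
            W_M=np.asarray(d["W_M"]),
            W_N=np.asarray(d["W_N"]),
            rho=np.asarray(d["rho"]),
            n_keep=int(d["n_keep"]),
        )


def build_target_signal(target_epochs: EpochSet) -> PairedDataset:
    """Assemble ``M`` (concatenated single-trial target epochs) and ``N``
    (the grand-average epoch repeated at each trial position)."""
    if len(target_epochs) < 2:
        raise ValueError(
            "need at least two target epochs; with a single epoch the "
            "average equals the trial and the CCA is degenerate"
        )
    stacked = target_epochs.stack()  # (n_ep, q, t)
    avg = stacked.mean(axis=0)
    M = np.concatenate(list(stacked), axis=1)
    N = np.tile(avg, (1, stacked.shape[0]))
    return PairedDataset(M=M, N=N)


def _regularized_inv(C: np.ndarray, ridge_rel: float = 1e-6) -> np.ndarray:
    q = C.shape[0]
    try:
        cond = np.linalg.cond(C)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        ridge = ridge_rel * np.trace(C) / q
        if ridge <= 0:
            ridge = ridge_rel
        logger.info("near-singular covariance: adding ridge %.3g", ridge)
        C = C + ridge * np.eye(q)
    return np.linalg.inv(C)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude weight of each component is
    positive."""
    W = W.copy()
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_cca(data: PairedDataset) -> SpatialFilter:
    """Fit the canonical transformations from the paired dataset."""
    M = data.M - data.M.mean(axis=1, keepdims=True)
    N = data.N - data.N.mean(axis=1, keepdims=True)
    n = M.shape[1]
    C_MM = M @ M.T / n
    C_NN = N @ N.T / n
    C_MN = M @ N.T / n
    C_NM = C_MN.T
    iMM = _regularized_inv(C_MM)
    iNN = _regularized_inv(C_NN)

    A = iMM @ C_MN @ iNN @ C_NM
    B = iNN @ C_NM @ iMM @ C_MN
    eval_M, evec_M = linalg.eig(A)
    eval_N, evec_N = linalg.eig(B)
    order_M = np.argsort(-eval_M.real)
    order_N = np.argsort(-eval_N.real)
    rho = np.sqrt(np.clip(eval_M.real[order_M], 0.0, 1.0))
    W_M = evec_M.real[:, order_M]
    W_N = evec_N.real[:, order_N]
    W_M /= np.linalg.norm(W_M, axis=0, keepdims=True)
    W_N /= np.linalg.norm(W_N, axis=0, keepdims=True)
    return SpatialFilter(W_M=_fix_signs(W_M), W_N=_fix_signs(W_N), rho=rho)


def apply_filter(filt: SpatialFilter, epoch: Epoch, n_keep: int | None = None) -> Epoch:
    """Project an epoch through the first ``n_keep`` spatial components.

    Virtual channels are named ``CC1 .. CCk``.
    """
    n_keep = filt.n_keep if n_keep is None else n_keep
    if epoch.samples.shape[0] != filt.W_M.shape[0]:
        raise ValueError(
            f"epoch has {epoch.samples.shape[0]} channels, filter expects "
            f"{filt.W_M.shape[0]}"
        )
    proj = filt.W_M[:, :n_keep].T @ epoch.samples
    return epoch.copy_with(proj, ch_names=[f"CC{i + 1}" for i in range(n_keep)])
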