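"""Feature extraction, target/nontarget classification, and evaluation.

Epoch windows come in two flavors.  A *calibrated* window is centered on
the node's predicted latency centroid ``t_c`` (half the window length on
each side), so the feature interval tracks the wireless transmission delay
of that node.  A *fixed* window starts 300 ms after the coordinator trigger
regardless of node — the conventional choice, which drifts off the response
as the delay grows.

Classification is a soft-margin RBF SVM (target = +1, nontarget = -1) with
``(C, gamma)`` chosen by stratified 5-fold cross-validation; four-way node
selection takes the argmax of the SVM decision value over the four
candidate feature vectors of a trial.  Performance is summarized as
selection accuracy and the Wolpaw information transfer rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cca_spatial import SpatialFilter, apply_filter
from .preprocess import downsample
from .types import Epoch, EpochSet

__all__ = [
    "EPOCH_LENGTH_SWEEP_MS",
    "FIXED_WINDOW_START_MS",
    "FeatureVector",
    "DecodeModel",
    "extract_features",
    "train_svm",
    "select_target",
    "compute_accuracy",
    "compute_itr",
    "compute_correlation",
]

#: Window lengths evaluated in the epoch-length sweep, ms.
EPOCH_LENGTH_SWEEP_MS = (160.0, 140.0, 120.0, 100.0, 80.0, 60.0)
#: Start of the uncalibrated window relative to the flash trigger, ms.
FIXED_WINDOW_START_MS = 300.0

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


@dataclass
class FeatureVector:
    """One averaged, filtered, windowed, downsampled epoch as a feature
    row, with its trial bookkeeping."""

    values: np.ndarray
    label: int  # +1 target, -1 nontarget (0 if unknown)
    node_id: int
    trial: int | None = None


@dataclass
class DecodeModel:
    """A fitted classifier plus the hyperparameters the grid search chose."""

    estimator: Pipeline
    C: float
    gamma: float
    cv_score: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(np.atleast_2d(X))


def window_bounds(
    length_ms: float,
    calibrated: bool,
    t_c_ms: float | None = None,
    fixed_start_ms: float = FIXED_WINDOW_START_MS,
) -> tuple[float, float]:
    """Trigger-relative window ``[start, stop)`` in ms."""
    if length_ms <= 0:
        raise ValueError("window length must be positive")
    if calibrated:
        if t_c_ms is None:
            raise ValueError("calibrated windows need a predicted centroid")
        return t_c_ms - length_ms / 2.0, t_c_ms + length_ms / 2.0
    return fixed_start_ms, fixed_start_ms + length_ms


def _slice_window(epoch: Epoch, start_ms: float, length_ms: float) -> Epoch:
    n = round(length_ms * epoch.sfreq / 1000.0)
    start = int(math.floor((start_ms - epoch.t0_ms) * epoch.sfreq / 1000.0))
    if start < 0 or start + n > epoch.n_times:
        raise ValueError(
            f"window [{start_ms}, {start_ms + length_ms}) ms escapes epoch "
            f"span [{epoch.t0_ms}, {epoch.t0_ms + epoch.n_times * 1000.0 / epoch.sfreq}) ms"
        )
    return epoch.copy_with(
        epoch.samples[:, start : start + n], t0_ms=epoch.t0_ms + start * 1000.0 / epoch.sfreq
    )


def extract_features(
    avg_epochs: EpochSet,
    length_ms: float,
    calibrated: bool,
    predicted_tc: dict[int, float] | None = None,
    spatial_filter: SpatialFilter | None = None,
    target_rate: float = 62.5,
) -> list[FeatureVector]:
    """Turn repetition-averaged per-node epochs into feature vectors.

    ``avg_epochs`` must carry ``node_id`` (and optionally ``trial`` /
    ``is_target``) in their ``meta``.  For calibrated windows
    ``predicted_tc`` maps node id -> predicted centroid (ms).
    """
    out = []
    for ep in avg_epochs:
        node = int(ep.meta["node_id"])
        t_c = None if predicted_tc is None else predicted_tc.get(node)
        if calibrated and t_c is None:
            raise ValueError(f"no predicted centroid for node {node}")
        start, stop = window_bounds(length_ms, calibrated, t_c)
        win = _slice_window(ep, start, stop - start)
        if spatial_filter is not None:
            win = apply_filter(spatial_filter, win)
        win_set = downsample(EpochSet([win]), target_rate)
        values = win_set[0].samples.ravel()
        is_target = ep.meta.get("is_target")
        label = 0 if is_target is None else (1 if is_target else -1)
        trial = ep.meta.get("trial")
        out.append(
            FeatureVector(
                values=values,
                label=label,
                node_id=node,
                trial=None if trial is None else int(trial),
            )
        )
    return out


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([f.values for f in features])
    y = np.array([f.label for f in features])
    return X, y


def train_svm(
    features: list[FeatureVector],
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> DecodeModel:
    """Fit the RBF SVM with stratified cross-validated grid search."""
    X, y = feature_matrix(features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))]
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    grid = GridSearchCV(
        pipe,
        {"svm__C": list(c_grid), "svm__gamma": list(gamma_grid)},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    grid.fit(X, y)
    return DecodeModel(
        estimator=grid.best_estimator_,
        C=float(grid.best_params_["svm__C"]),
        gamma=float(grid.best_params_["svm__gamma"]),
        cv_score=float(grid.best_score_),
    )


def select_target(trial_features: list[FeatureVector], model: DecodeModel) -> int:
    """Four-way selection: the node whose feature vector gets the highest
    SVM decision value; exact ties go to the lowest node id."""
    nodes = [f.node_id for f in trial_features]
    if len(set(nodes)) != len(nodes):
        raise ValueError("one candidate feature vector per node expected")
    X = np.stack([f.values for f in trial_features])
    d = model.decision_values(X)
    best = max(range(len(nodes)), key=lambda i: (d[i], -nodes[i]))
    return nodes[best]


def compute_accuracy(selections, truth) -> float:
    """Percent of trials whose selected node matches the cued node."""
    selections = np.asarray(selections)
    truth = np.asarray(truth)
    if selections.size == 0:
        raise ValueError("no selections to score")
    if selections.shape != truth.shape:
        raise ValueError("selections and truth must have equal length")
    return 100.0 * float(np.mean(selections == truth))


def compute_itr(accuracy: float, n_choices: int = 4, selection_time: float = 3.0) -> float:
    """Wolpaw information transfer rate in bits/min.

    ``accuracy`` is a fraction in [0, 1]; bits per selection are
    ``log2 N + P log2 P + (1-P) log2((1-P)/(N-1))`` with the P in {0, 1}
    terms taken as continuity limits, scaled by selections per minute.
    """
    P = float(accuracy)
    if not (0.0 <= P <= 1.0):
        raise ValueError("accuracy must be a fraction in [0, 1]")
    if n_choices < 2:
        raise ValueError("need at least two choices")
    if selection_time <= 0:
        raise ValueError("selection time must be positive")
    bits = math.log2(n_choices)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (n_choices - 1))
    bits = max(0.0, bits)
    return bits * 60.0 / selection_time


def compute_correlation(p300_latencies, ssvep_phases) -> float:
    """Pearson correlation between elicited-P300 latencies and evoked-SSVEP
    phases."""
    x = np.asarray(p300_latencies, dtype=float)
    y = np.asarray(ssvep_phases, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])
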