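"""Per-neuron odor information and elapsed-time decoding.

Odor information: activity is discretized into 20 levels per neuron
(uniform partition of [0, neuron max]); for each time bin, the mutual
information between bin identity (baseline vs target) and activity level
is computed with the plug-in estimator and averaged across neurons.

Time decoding: population vectors within the short-delay window
(1.1-3.4 s, 1/3-s class bins, 7 classes) are classified with a linear
max-margin one-vs-one multiclass decoder under trial-grouped k-fold
cross-validation; the score is the Pearson correlation between actual
and predicted class indices on held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .core_io import AlignedActivity, ValidationError

__all__ = [
    "InfoParams",
    "DecodeParams",
    "discretize_activity",
    "odor_information",
    "binary_mutual_information",
    "class_labels",
    "decode_time",
]

_EPS = 1e-9


@dataclass(frozen=True)
class InfoParams:
    n_activity_levels: int = 20
    baseline_time: float = -1.5
    bin_range: tuple[float, float] = (-1.0, 11.0)

    def __post_init__(self) -> None:
        if self.n_activity_levels < 2:
            raise ValidationError("need >= 2 activity levels")
        if self.baseline_time >= 0:
            raise ValidationError("baseline_time must precede 1st-odor onset")


@dataclass(frozen=True)
class DecodeParams:
    window: tuple[float, float] = (1.1, 3.4)
    class_bin: float = 1.0 / 3.0
    cv_folds: int = 5
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        span = self.window[1] - self.window[0]
        n = round(span / self.class_bin)
        if n < 1 or abs(n * self.class_bin - span) > self.class_bin / 2:
            raise ValidationError("window length must divide into class bins")


def discretize_activity(tensor: np.ndarray,
                        params: InfoParams = InfoParams()) -> np.ndarray:
    """Map each neuron's activity to integer levels 0..L-1.

    Level = min(floor(value / max * L), L - 1) with the per-neuron max over
    the whole tensor; an all-zero neuron maps to level 0 everywhere.
    """
    x = np.asarray(tensor, dtype=float)
    levels = params.n_activity_levels
    mx = x.reshape(x.shape[0], -1).max(axis=1)
    safe = np.where(mx > 0, mx, 1.0).reshape((-1,) + (1,) * (x.ndim - 1))
    out = np.floor(x / safe * levels).astype(int)
    return np.minimum(out, levels - 1)


def binary_mutual_information(counts_base: np.ndarray,
                              counts_t: np.ndarray) -> float:
    """Plug-in MI (bits) between bin identity and activity level.

    ``counts_base``/``counts_t`` are level histograms over trials for the
    baseline and target bins. 0*log(0) terms contribute zero.
    """
    cb = np.asarray(counts_base, dtype=float)
    ct = np.asarray(counts_t, dtype=float)
    n = cb.sum() + ct.sum()
    if n == 0:
        return 0.0
    joint = np.stack([cb, ct]) / n  # 2 x levels
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (px * py))
    return float(np.nansum(term))


def odor_information(aligned: AlignedActivity,
                     trial_positions: list[int] | None = None,
                     params: InfoParams = InfoParams(),
                     discretized: np.ndarray | None = None) -> pd.DataFrame:
    """Mean MI (bits/cell) between the baseline bin and every target bin.

    Discretization uses the per-neuron max over the *full* aligned tensor
    so compared conditions share a level scale; ``trial_positions``
    (tensor positions) then selects the trials of one condition —
    balance reverse comparisons upstream via nearest-neighbor matching.
    """
    if discretized is None:
        discretized = discretize_activity(aligned.tensor, params)
    if trial_positions is not None:
        disc = discretized[:, np.asarray(trial_positions, dtype=int), :]
    else:
        disc = discretized
    n_neurons, n_trials, _ = disc.shape
    if n_trials < 2:
        raise ValidationError("need >= 2 trials")

    time_axis = aligned.time_axis
    base_bin = int(np.argmin(np.abs(time_axis - params.baseline_time)))
    targets = np.nonzero((time_axis >= params.bin_range[0] - _EPS)
                         & (time_axis <= params.bin_range[1] + _EPS))[0]
    levels = params.n_activity_levels

    mi = np.zeros((n_neurons, targets.size))
    for i in range(n_neurons):
        counts_base = np.bincount(disc[i, :, base_bin], minlength=levels)
        for k, t in enumerate(targets):
            counts_t = np.bincount(disc[i, :, t], minlength=levels)
            mi[i, k] = binary_mutual_information(counts_base, counts_t)
    return pd.DataFrame({
        "bin_time_s": time_axis[targets],
        "mi_bits": mi.mean(axis=0),
    })


def class_labels(params: DecodeParams = DecodeParams()) -> tuple[np.ndarray, np.ndarray]:
    """Partition the decoding window into class bins; (edges, centers)."""
    span = params.window[1] - params.window[0]
    n = int(round(span / params.class_bin))
    edges = params.window[0] + np.arange(n + 1) * params.class_bin
    centers = (edges[:-1] + edges[1:]) / 2
    return edges, centers


def _class_features(aligned: AlignedActivity, params: DecodeParams,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges, _ = class_labels(params)
    n_classes = len(edges) - 1
    cols = []
    for c in range(n_classes):
        sel = (aligned.time_axis >= edges[c] - _EPS) \
            & (aligned.time_axis < edges[c + 1] - _EPS)
        if not sel.any():
            raise ValidationError(f"no aligned bins inside class {c}")
        cols.append(aligned.tensor[:, :, sel].mean(axis=2))  # neurons x trials
    # samples ordered trial-major: (trial0, class0), (trial0, class1), ...
    X = np.stack(cols, axis=2)  # neurons x trials x classes
    n_trials = X.shape[1]
    Xs = X.transpose(1, 2, 0).reshape(n_trials * n_classes, -1)
    y = np.tile(np.arange(n_classes), n_trials)
    groups = np.repeat(np.arange(n_trials), n_classes)
    return Xs, y, groups


def decode_time(aligned: AlignedActivity,
                params: DecodeParams = DecodeParams(),
                seed: int = 0,
                permute_labels: bool = False,
                ) -> tuple[float, np.ndarray]:
    """Cross-validated multiclass time-bin decoding of one condition.

    All class bins of a trial stay in one fold (trial-grouped k-fold), so
    no within-trial leakage inflates the score. Returns the Pearson
    correlation of actual vs predicted class indices over held-out
    samples (0 if predictions are degenerate) and the confusion matrix.
    """
    n_trials = aligned.n_trials
    if n_trials < params.cv_folds:
        raise ValidationError(
            f"{n_trials} trials < {params.cv_folds} cross-validation folds")
    X, y, groups = _class_features(aligned, params)
    rng = np.random.default_rng(seed)
    if permute_labels:
        # permute within each trial: keeps every fold class-balanced, so the
        # chance-level score is unbiased (a global permutation gives k-fold
        # CV its well-known slight below-chance bias)
        y = y.copy()
        for t in range(n_trials):
            m = groups == t
            y[m] = rng.permutation(y[m])

    n_classes = int(y.max()) + 1 if y.size else 0
    trial_order = rng.permutation(n_trials)
    kf = KFold(n_splits=params.cv_folds)
    actual, predicted = [], []
    for train_trials, test_trials in kf.split(trial_order):
        tr = np.isin(groups, trial_order[train_trials])
        te = np.isin(groups, trial_order[test_trials])
        clf = SVC(kernel="linear", C=params.C,
                  decision_function_shape="ovo")
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        actual.append(y[te])
        predicted.append(pred)
    actual = np.concatenate(actual)
    predicted = np.concatenate(predicted)

    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (actual, predicted), 1)
    if np.std(actual) == 0 or np.std(predicted) == 0:
        score = 0.0
    else:
        score = float(np.corrcoef(actual, predicted)[0, 1])
    return score, conf
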