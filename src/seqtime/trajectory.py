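"""Population-trajectory geometry: baseline distance, speed, PCA views.

All metrics are computed in full dimensional space and divided by the
square root of the number of cells entering the trace, so k-fold
duplication of the cell set leaves them unchanged. PCA is provided for
visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .core_io import AlignedActivity, TaskConfig, ValidationError
from .preprocessing import match_standard_trials
from .sequence import SequenceCellStats

__all__ = [
    "TrajectoryMetrics",
    "baseline_point",
    "distance_from_baseline",
    "trajectory_speed",
    "pca_projection",
    "per_bin_condition_test",
    "condition_mean",
    "cells_for_condition",
    "trajectory_metrics",
]

_EPS = 1e-9


@dataclass
class TrajectoryMetrics:
    condition: str
    distance: np.ndarray  # per bin, a.u.
    speed: np.ndarray  # per consecutive bin pair, a.u.
    n_cells: int
    baseline: np.ndarray
    bin_size: float
    time_axis: np.ndarray


def baseline_point(traj: np.ndarray, time_axis: np.ndarray,
                   window: tuple[float, float] = (-2.0, 0.0)) -> np.ndarray:
    """Per-neuron mean over the pre-odor baseline bins.

    ``traj`` is neurons x bins (a condition-averaged trajectory).
    """
    sel = (time_axis >= window[0] - _EPS) & (time_axis < window[1] - _EPS)
    if not sel.any():
        raise ValidationError("no bins inside the baseline window")
    return np.asarray(traj, dtype=float)[:, sel].mean(axis=1)


def distance_from_baseline(traj: np.ndarray, baseline: np.ndarray,
                           n_cells: int) -> np.ndarray:
    """Euclidean distance of each bin's population vector from baseline, /sqrt(n)."""
    diff = np.asarray(traj, dtype=float) - np.asarray(baseline, dtype=float)[:, None]
    return np.linalg.norm(diff, axis=0) / np.sqrt(n_cells)


def trajectory_speed(traj: np.ndarray, n_cells: int) -> np.ndarray:
    """Euclidean distance between neighboring bins, /sqrt(n); length bins-1."""
    step = np.diff(np.asarray(traj, dtype=float), axis=1)
    return np.linalg.norm(step, axis=0) / np.sqrt(n_cells)


def pca_projection(condition_means: dict[str, np.ndarray],
                   n_components: int = 2) -> dict[str, np.ndarray]:
    """Fit PCA on the concatenated condition means, project each condition.

    Inputs are neurons x bins per condition; outputs bins x components.
    Visualization only — metrics never use the projection.
    """
    keys = list(condition_means)
    stacked = np.concatenate([condition_means[k].T for k in keys], axis=0)
    pca = PCA(n_components=n_components)
    pca.fit(stacked)
    return {k: pca.transform(condition_means[k].T) for k in keys}


def cells_for_condition(stats: list[SequenceCellStats], condition: str) -> list[int]:
    """Significant cells entering a condition's trace.

    Cued-short conditions (standard_short, reverse_long — both follow the
    short-cue odor) use significant short-trial cells; cued-long
    conditions use long-trial cells.
    """
    cue = "short" if condition in ("standard_short", "reverse_long") else "long"
    return [s.neuron for s in stats if s.significant and s.preferred == cue]


def condition_mean(aligned: AlignedActivity, condition: str,
                   neurons: list[int] | None = None,
                   balance_against: str | None = None) -> np.ndarray:
    """Neurons x bins mean trajectory of one condition.

    When a standard condition is compared against a reverse one, pass the
    reverse condition via ``balance_against`` to restrict the standard
    trials to the nearest-neighbor matches of the reverse trials.
    """
    if balance_against is not None and condition.startswith("standard"):
        rev_positions = [int(aligned.trial_index_map[j])
                         for j in range(aligned.n_trials)
                         if aligned.trials.condition_of(
                             aligned.trials[aligned.trial_index_map[j]])
                         == balance_against]
        matched = set(match_standard_trials(aligned.trials, rev_positions))
        keep = [j for j in range(aligned.n_trials)
                if int(aligned.trial_index_map[j]) in matched]
        sl = aligned.subset(keep)
    else:
        sl = aligned.condition_slice(condition)
    if sl.n_trials == 0:
        raise ValidationError(f"no trials in condition {condition}")
    mean = sl.tensor.mean(axis=1)
    if neurons is not None:
        mean = mean[np.asarray(neurons, dtype=int)]
    return mean


def trajectory_metrics(aligned: AlignedActivity, stats: list[SequenceCellStats],
                       condition: str, cfg: TaskConfig,
                       balance_against: str | None = None,
                       use_union: bool = False,
                       baseline_window: tuple[float, float] = (-2.0, 0.0),
                       ) -> TrajectoryMetrics:
    """Distance-from-baseline and speed series for one condition."""
    if use_union:
        neurons = sorted({s.neuron for s in stats if s.significant})
    else:
        neurons = cells_for_condition(stats, condition)
    if not neurons:
        raise ValidationError("no significant cells for this condition")
    traj = condition_mean(aligned, condition, neurons, balance_against)
    base = baseline_point(traj, aligned.time_axis, baseline_window)
    n = len(neurons)
    return TrajectoryMetrics(
        condition=condition,
        distance=distance_from_baseline(traj, base, n),
        speed=trajectory_speed(traj, n),
        n_cells=n,
        baseline=base,
        bin_size=aligned.bin_size,
        time_axis=aligned.time_axis,
    )


def per_bin_condition_test(values_a: np.ndarray, values_b: np.ndarray,
                           animal: list[str], day: list[str],
                           alpha: float = 0.01) -> pd.DataFrame:
    """Per-bin condition comparison across sessions with animal/day factors.

    ``values_a``/``values_b`` are sessions x bins for the two conditions.
    Per bin, the session-wise difference is modeled as
    ``d ~ C(animal, Sum) + C(day, Sum)`` and the intercept (the
    factor-adjusted mean difference) is t-tested; p-values are BH-adjusted
    across bins and masked at adjusted p < alpha.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("condition arrays must have identical shapes")
    n_sessions, n_bins = a.shape
    if n_sessions < 2:
        raise ValidationError("need >= 2 sessions")
    terms = []
    if len(set(animal)) > 1:
        terms.append("C(animal, Sum)")
    if len(set(day)) > 1:
        terms.append("C(day, Sum)")
    formula = "d ~ " + (" + ".join(terms) if terms else "1")

    pvals, means = [], []
    for bin_i in range(n_bins):
        d = a[:, bin_i] - b[:, bin_i]
        means.append(float(d.mean()))
        df = pd.DataFrame({"d": d, "animal": animal, "day": day})
        fit = smf.ols(formula, data=df).fit()
        p = fit.pvalues.get("Intercept", np.nan)
        pvals.append(1.0 if np.isnan(p) else float(p))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "mean_diff": means,
        "p": pvals,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
    })
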