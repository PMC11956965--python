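"""Task performance, lick latency, and locomotion analysis.

Scoring: responses count only inside the response window, the 3-s period
starting at 2nd-odor onset (half-open [onset, onset + 3)). Non-match
trials are correct with a lick in the window; match trials are correct
without one. Session latency is the median first-lick latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core_io import (AlignedActivity, TaskConfig, Trial, TrialTable,
                      ValidationError)

__all__ = [
    "BehaviorSummary",
    "LocomotionParams",
    "score_trial",
    "first_lick_latency",
    "summarize_behavior",
    "paired_category_test",
    "locomotion_zbin",
    "running_bouts",
    "trial_running_flags",
    "exclude_running",
]

_EPS = 1e-9

CATEGORIES = ("standard_short", "standard_long", "reverse_short",
              "reverse_long", "standard", "reverse")


@dataclass
class BehaviorSummary:
    accuracy_pct: dict = field(default_factory=dict)  # category -> %
    median_latency_ms: dict = field(default_factory=dict)
    n_trials: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LocomotionParams:
    bin_frames: int = 5
    z_floor: float = 1.0
    bout_min_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_frames < 1 or self.z_floor <= 0 or self.bout_min_duration <= 0:
            raise ValidationError("locomotion parameters must be positive")


def _window_licks(trial: Trial, cfg: TaskConfig) -> list[float]:
    lo = trial.odor2_onset
    hi = trial.odor2_onset + cfg.response_window
    return [t for t in trial.licks if lo <= t < hi]


def score_trial(trial: Trial, cfg: TaskConfig) -> bool:
    """Correct iff licked on a non-match, or withheld on a match."""
    licked = bool(_window_licks(trial, cfg))
    return licked if not trial.is_match else not licked


def first_lick_latency(trial: Trial, cfg: TaskConfig) -> float | None:
    """Seconds from 2nd-odor onset to the first in-window lick, or None."""
    licks = _window_licks(trial, cfg)
    return licks[0] - trial.odor2_onset if licks else None


def summarize_behavior(trials: TrialTable,
                       correct_only_latency: bool = False) -> BehaviorSummary:
    """Accuracy % and median first-lick latency (ms) per category.

    Empty categories are omitted rather than reported as 0.
    """
    cfg = trials.cfg
    summary = BehaviorSummary()
    for cat in CATEGORIES:
        if cat in ("standard", "reverse"):
            members = [t for t in trials
                       if trials.condition_of(t).startswith(cat)]
        else:
            members = [t for t in trials if trials.condition_of(t) == cat]
        if not members:
            continue
        correct = [score_trial(t, cfg) for t in members]
        summary.accuracy_pct[cat] = 100.0 * sum(correct) / len(members)
        summary.n_trials[cat] = len(members)
        lats = []
        for t, ok in zip(members, correct):
            if correct_only_latency and not ok:
                continue
            lat = first_lick_latency(t, cfg)
            if lat is not None:
                lats.append(lat)
        if lats:
            summary.median_latency_ms[cat] = 1000.0 * float(np.median(lats))
    return summary


def paired_category_test(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Paired t-test p-value across sessions; identical pairs give p = 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need >= 2 paired sessions")
    d = a - b
    if np.allclose(d, d[0]):
        return 1.0 if abs(d[0]) < _EPS else 0.0
    return float(sps.ttest_rel(a, b).pvalue)


def locomotion_zbin(trace: np.ndarray,
                    params: LocomotionParams = LocomotionParams()) -> np.ndarray:
    """Bin to 5-frame means, z-score the whole series, floor below 1 to 0.

    A constant trace (zero variance) comes out all zero. A partial
    trailing bin is dropped, matching the activity binning.
    """
    x = np.asarray(trace, dtype=float)
    n_bins = x.shape[0] // params.bin_frames
    binned = x[:n_bins * params.bin_frames].reshape(n_bins, params.bin_frames).mean(axis=1)
    sd = binned.std()
    if sd == 0:
        return np.zeros(n_bins)
    z = (binned - binned.mean()) / sd
    z[z < params.z_floor] = 0.0
    return z


def running_bouts(zbinned: np.ndarray, frame_rate: float,
                  params: LocomotionParams = LocomotionParams(),
                  ) -> list[tuple[float, float]]:
    """Maximal runs of above-floor bins lasting >= the minimum duration.

    Returns (start_s, end_s) intervals in session time; the duration
    threshold is closed (an exactly 1-s run counts).
    """
    bin_size = params.bin_frames / frame_rate
    above = np.asarray(zbinned) > 0  # floored series: surviving bins are above z_floor
    bouts = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            duration = (j - i) * bin_size
            if duration >= params.bout_min_duration - _EPS:
                bouts.append((i * bin_size, j * bin_size))
            i = j
        else:
            i += 1
    return bouts


def trial_running_flags(trials: TrialTable, bouts: list[tuple[float, float]],
                        ) -> np.ndarray:
    """Trial is 'running' iff any bout intersects its delay period."""
    cfg = trials.cfg
    flags = np.zeros(len(trials), dtype=bool)
    for i, t in enumerate(trials):
        d0 = t.odor1_onset + cfg.odor_duration
        d1 = t.odor2_onset
        flags[i] = any(b0 < d1 and b1 > d0 for b0, b1 in bouts)
    return flags


def exclude_running(aligned: AlignedActivity, flags: np.ndarray,
                    ) -> AlignedActivity:
    """Restrict the tensor to trials whose running flag is False.

    ``flags`` is indexed by TrialTable position.
    """
    flags = np.asarray(flags, dtype=bool)
    keep = [j for j in range(aligned.n_trials)
            if not flags[aligned.trial_index_map[j]]]
    return aligned.subset(keep)
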