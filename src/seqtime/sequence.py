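"""Sequence-cell detection and peak-distribution analyses.

A neuron is assigned the standard trial type (cued-short vs cued-long)
with the larger trial-averaged peak inside that type's analysis window
(1st odor + delay: 3.5 s or 6 s). The peak is significant if it exceeds
the 95th percentile of 2000 circular shuffles (each shuffle rotates each
trial's within-window trace independently) AND at least 20% of preferred
trials show a >= 2 STD event within 0.5 s of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import AlignedActivity, TaskConfig, ValidationError

__all__ = [
    "DetectionParams",
    "SequenceCellStats",
    "preferred_trial_type",
    "circular_shuffle_test",
    "reliability",
    "detect_sequence_cells",
    "sequence_heatmap",
    "compare_peak_distributions",
    "binned_peak_fractions",
    "stats_to_frame",
]

_EPS = 1e-9


@dataclass(frozen=True)
class DetectionParams:
    n_shuffles: int = 2000
    percentile: float = 95.0
    min_reliability: float = 0.20
    peak_window_halfwidth: float = 0.5
    z_event_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValidationError("percentile must lie in (0, 100)")
        if not 0 <= self.min_reliability <= 1:
            raise ValidationError("min_reliability must lie in [0, 1]")


@dataclass(frozen=True)
class SequenceCellStats:
    neuron: int
    preferred: str  # "short" or "long"
    peak_bin: int  # index into the aligned time axis
    peak_time: float  # seconds from 1st-odor onset
    observed_peak: float
    shuffle_threshold: float
    reliability: float
    significant: bool


def _window_bins(time_axis: np.ndarray, length_s: float) -> np.ndarray:
    """Bins whose centers lie in [0, length_s) — 1st odor plus delay."""
    return np.nonzero((time_axis >= -_EPS) & (time_axis < length_s - _EPS))[0]


def _cue_condition(kind: str, cfg: TaskConfig) -> str:
    # cued-short standard trials have the short realized delay and vice versa
    return f"standard_{kind}"


def preferred_trial_type(aligned: AlignedActivity, neuron: int,
                         cfg: TaskConfig) -> str:
    """Standard trial type with the larger average peak; tie -> short."""
    peaks = {}
    for kind, length in (("short", cfg.odor_duration + cfg.short_delay),
                         ("long", cfg.odor_duration + cfg.long_delay)):
        sl = aligned.condition_slice(_cue_condition(kind, cfg))
        win = _window_bins(aligned.time_axis, length)
        if sl.n_trials == 0 or win.size == 0:
            peaks[kind] = 0.0
            continue
        peaks[kind] = float(sl.tensor[neuron][:, win].mean(axis=0).max())
    return "short" if peaks["short"] >= peaks["long"] else "long"


def circular_shuffle_test(trial_traces: np.ndarray, params: DetectionParams,
                          rng: np.random.Generator,
                          ) -> tuple[float, float, bool]:
    """Peak-of-average significance against per-trial circular rotations.

    ``trial_traces`` is trials x window-bins. Each of ``n_shuffles``
    surrogates rotates every trial independently by a uniform offset,
    re-averages, and records the window max; the threshold is the
    percentile (linear interpolation) of those maxima. Pass requires a
    strictly greater observed peak, so flat or all-zero input fails.
    """
    traces = np.asarray(trial_traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValidationError("need >= 2 preferred trials")
    n_trials, n_bins = traces.shape
    observed = float(traces.mean(axis=0).max())
    offsets = rng.integers(0, n_bins, size=(params.n_shuffles, n_trials))
    idx = (np.arange(n_bins)[None, None, :] - offsets[:, :, None]) % n_bins
    shuffled = traces[np.arange(n_trials)[None, :, None], idx]
    maxima = shuffled.mean(axis=1).max(axis=1)
    threshold = float(np.percentile(maxima, params.percentile))
    return observed, threshold, observed > threshold


def reliability(trial_traces: np.ndarray, time_axis: np.ndarray,
                peak_time: float, params: DetectionParams) -> float:
    """Fraction of trials with an above-threshold event near the peak.

    The window is peak_time +/- 0.5 s, boundary included, clipped at the
    trial edges.
    """
    traces = np.asarray(trial_traces, dtype=float)
    hw = params.peak_window_halfwidth
    near = np.abs(time_axis - peak_time) <= hw + _EPS
    if not near.any() or traces.shape[0] == 0:
        return 0.0
    hit = (traces[:, near] >= params.z_event_threshold).any(axis=1)
    return float(hit.mean())


def detect_sequence_cells(aligned: AlignedActivity, cfg: TaskConfig,
                          params: DetectionParams = DetectionParams(),
                          seed: int = 0) -> list[SequenceCellStats]:
    """Run the full per-neuron detection over an aligned session.

    Uses standard trials only. One seeded generator serves all neurons in
    order, so results are bit-reproducible for a given (aligned, seed).
    """
    rng = np.random.default_rng(seed)
    lengths = {"short": cfg.odor_duration + cfg.short_delay,
               "long": cfg.odor_duration + cfg.long_delay}
    slices = {k: aligned.condition_slice(_cue_condition(k, cfg)) for k in lengths}
    wins = {k: _window_bins(aligned.time_axis, v) for k, v in lengths.items()}

    out = []
    for neuron in range(aligned.n_neurons):
        pref = preferred_trial_type(aligned, neuron, cfg)
        sl = slices[pref]
        win = wins[pref]
        traces = sl.tensor[neuron][:, win]
        observed, threshold, passed = circular_shuffle_test(traces, params, rng)
        mean_trace = traces.mean(axis=0)
        peak_local = int(np.argmax(mean_trace))  # ties -> earliest
        peak_bin = int(win[peak_local])
        peak_time = float(aligned.time_axis[peak_bin])
        rel = reliability(sl.tensor[neuron], aligned.time_axis, peak_time, params)
        out.append(SequenceCellStats(
            neuron=neuron, preferred=pref, peak_bin=peak_bin,
            peak_time=peak_time, observed_peak=observed,
            shuffle_threshold=threshold, reliability=rel,
            significant=bool(passed and rel >= params.min_reliability),
        ))
    return out


def stats_to_frame(stats: list[SequenceCellStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def sequence_heatmap(stats: list[SequenceCellStats], aligned: AlignedActivity,
                     cfg: TaskConfig, preferred: str,
                     render_condition: str | None = None,
                     ) -> tuple[np.ndarray, list[int]]:
    """Peak-normalized average traces of significant cells, peak-sorted.

    Sort order comes from the preferred standard trials; pass
    ``render_condition`` to display another trial type in that same order.
    Returns (matrix, neuron order).
    """
    cells = sorted(
        (s for s in stats if s.significant and s.preferred == preferred),
        key=lambda s: s.peak_bin,
    )
    order = [s.neuron for s in cells]
    cond = render_condition or _cue_condition(preferred, cfg)
    sl = aligned.condition_slice(cond)
    rows = []
    for n in order:
        trace = sl.tensor[n].mean(axis=0)
        peak = trace.max()
        rows.append(trace / peak if peak > 0 else trace)
    mat = np.vstack(rows) if rows else np.empty((0, aligned.n_bins))
    return mat, order


def compare_peak_distributions(short_peaks: np.ndarray, long_peaks: np.ndarray,
                               window: tuple[float, float] = (0.0, 3.5),
                               ) -> tuple[float, float]:
    """Two-sample KS test on peak times restricted to a common window."""
    s = np.asarray(short_peaks, dtype=float)
    l = np.asarray(long_peaks, dtype=float)
    s = s[(s >= window[0]) & (s <= window[1])]
    l = l[(l >= window[0]) & (l <= window[1])]
    if s.size == 0 or l.size == 0:
        raise ValidationError("no peaks in window for one of the sequences")
    res = sps.ks_2samp(s, l)
    return float(res.statistic), float(res.pvalue)


def binned_peak_fractions(per_session_stats: list[list[SequenceCellStats]],
                          bin_s: float = 0.5,
                          window: tuple[float, float] = (0.0, 3.5),
                          ) -> pd.DataFrame:
    """Per-session peak-location fractions in 0.5-s bins, with paired tests.

    For each session, the fraction of each sequence's significant cells
    whose peak falls in each bin of the window (denominator: cells with a
    peak inside the window). Bins are compared short vs long with paired
    t-tests, BH-adjusted across bins.
    """
    if len(per_session_stats) < 2:
        raise ValidationError("need >= 2 sessions for paired tests")
    edges = np.arange(window[0], window[1] + _EPS, bin_s)
    n_bins = len(edges) - 1
    fracs = {"short": [], "long": []}
    for stats in per_session_stats:
        for kind in ("short", "long"):
            peaks = np.array([s.peak_time for s in stats
                              if s.significant and s.preferred == kind])
            peaks = peaks[(peaks >= window[0]) & (peaks < window[1])]
            if peaks.size == 0:
                fracs[kind].append(np.full(n_bins, np.nan))
                continue
            counts, _ = np.histogram(peaks, bins=edges)
            fracs[kind].append(counts / peaks.size)
    short = np.vstack(fracs["short"])
    long_ = np.vstack(fracs["long"])

    pvals = []
    for b in range(n_bins):
        ok = ~np.isnan(short[:, b]) & ~np.isnan(long_[:, b])
        if ok.sum() < 2:
            pvals.append(1.0)
            continue
        d = short[ok, b] - long_[ok, b]
        if np.allclose(d, 0):
            pvals.append(1.0)
            continue
        p = sps.ttest_rel(short[ok, b], long_[ok, b]).pvalue
        pvals.append(1.0 if np.isnan(p) else float(p))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({
        "bin_start_s": edges[:-1],
        "bin_end_s": edges[1:],
        "frac_short": np.nanmean(short, axis=0),
        "frac_long": np.nanmean(long_, axis=0),
        "p": pvals,
        "p_adj": p_adj,
    })
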