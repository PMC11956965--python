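"""Signal conditioning and trial alignment.

Conditioning: per neuron, a centered 10-frame rolling mean (edge windows
shrink to the available frames), whole-session z-scoring, then a hard
floor — values below 2 set to zero. The output stays on the z-score
scale ("firing rate (STD)").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AlignedActivity, SessionRecording, TrialTable, ValidationError

__all__ = [
    "ConditioningParams",
    "condition_signal",
    "align",
    "match_standard_trials",
    "condition_and_align",
]


@dataclass(frozen=True)
class ConditioningParams:
    smooth_window: int = 10
    floor_z: float = 2.0
    bin_frames: int = 5

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.bin_frames < 1 or self.floor_z <= 0:
            raise ValidationError("conditioning parameters must be positive")


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean along the last axis with edge shrinkage.

    Frame i averages frames [i - window//2, i - window//2 + window)
    clipped to the valid range; edge windows use the available frames.
    """
    n = x.shape[-1]
    csum = np.cumsum(x, axis=-1, dtype=float)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    lo = np.clip(np.arange(n) - window // 2, 0, n)
    hi = np.clip(np.arange(n) - window // 2 + window, 0, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def condition_signal(raw: np.ndarray,
                     params: ConditioningParams = ConditioningParams(),
                     ) -> np.ndarray:
    """Smooth, z-score per neuron over the session, floor below threshold.

    Zero-variance neurons come out all zero rather than raising.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size and raw.min() < 0:
        raise ValidationError("raw activity must be nonnegative")
    smoothed = _rolling_mean(raw, params.smooth_window)
    mu = smoothed.mean(axis=-1, keepdims=True)
    sd = smoothed.std(axis=-1, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = np.where(sd > 0, (smoothed - mu) / safe, 0.0)
    z[z < params.floor_z] = 0.0
    return z


def align(rec: SessionRecording, window: tuple[float, float] = (-2.0, 11.0),
          bin_frames: int = 5, activity: np.ndarray | None = None,
          ) -> AlignedActivity:
    """Cut the activity matrix into a neurons x trials x bins tensor.

    Each trial's frames from ``odor1_onset + window[0]`` onward are
    averaged in consecutive ``bin_frames`` groups; a partial trailing bin
    is dropped. ``activity`` overrides the recording's matrix (e.g. a
    conditioned copy); it must share the frame clock.
    """
    if activity is None:
        activity = rec.activity
    fr = rec.frame_rate
    span = window[1] - window[0]
    if span <= 0:
        raise ValidationError("window must have positive length")
    n_win_frames = int(np.floor(span * fr + 1e-9))
    n_bins = n_win_frames // bin_frames
    if n_bins == 0:
        raise ValidationError("window shorter than one bin")

    starts, bad = [], []
    for t in rec.trials:
        s = int(np.floor((t.odor1_onset + window[0]) * fr + 1e-9))
        if s < 0 or s + n_bins * bin_frames > rec.n_frames:
            bad.append(t.index)
        starts.append(s)
    if bad:
        raise ValidationError(f"trial windows outside recording: {bad}")

    n_neurons = activity.shape[0]
    tensor = np.empty((n_neurons, len(starts), n_bins), dtype=float)
    for j, s in enumerate(starts):
        seg = activity[:, s:s + n_bins * bin_frames]
        tensor[:, j, :] = seg.reshape(n_neurons, n_bins, bin_frames).mean(axis=2)

    bin_size = bin_frames / fr
    time_axis = window[0] + (np.arange(n_bins) + 0.5) * bin_size
    return AlignedActivity(
        tensor=tensor, bin_frames=bin_frames, bin_size=bin_size,
        time_axis=time_axis, trial_index_map=np.arange(len(starts)),
        trials=rec.trials,
    )


def condition_and_align(rec: SessionRecording,
                        cparams: ConditioningParams = ConditioningParams(),
                        window: tuple[float, float] = (-2.0, 11.0),
                        ) -> AlignedActivity:
    """Convenience: condition the raw matrix, then align."""
    conditioned = condition_signal(rec.activity, cparams)
    return align(rec, window=window, bin_frames=cparams.bin_frames,
                 activity=conditioned)


def match_standard_trials(trials: TrialTable,
                          reverse_positions: list[int]) -> list[int]:
    """One nearest standard trial per reverse trial, without replacement.

    Candidates are standard trials of the same realized delay length.
    Reverse trials are processed in ascending index order; each takes the
    unused standard trial with minimal |index difference|, ties going to
    the earlier standard trial. Returns standard table positions parallel
    to ``reverse_positions`` (sorted ascending).
    """
    reverse_positions = sorted(reverse_positions, key=lambda p: trials[p].index)
    used: set[int] = set()
    out = []
    for p in reverse_positions:
        rt = trials[p]
        if not rt.is_reverse:
            raise ValidationError(f"trial {rt.index} is not a reverse trial")
        length = "short" if rt.delay == trials.cfg.short_delay else "long"
        best = None
        for q, st in enumerate(trials):
            if st.is_reverse or q in used:
                continue
            if trials.condition_of(st) != f"standard_{length}":
                continue
            d = abs(st.index - rt.index)
            if best is None or d < best[0] or (d == best[0] and st.index < trials[best[1]].index):
                best = (d, q)
        if best is None:
            raise ValidationError(
                f"no unused standard trial available for reverse trial {rt.index}")
        used.add(best[1])
        out.append(best[1])
    return out
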