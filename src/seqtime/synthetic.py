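"""Synthetic session generator.

Emits sessions with the statistical structure the analysis stages assume:
a blocked trial schedule with an exact reverse-trial count, planted
Gaussian-field sequence cells with tunable reliability and an optional
over-representation of fields just before the expected 2nd odor, lick
behavior with plantable accuracy/latency effects, and sparse locomotion.

Activity is emitted directly as nonnegative "deconvolved-like" transients;
no indicator biophysics is simulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import SessionRecording, TaskConfig, Trial, TrialTable, ValidationError

__all__ = [
    "PlantedCell",
    "GeneratorParams",
    "GenerationError",
    "generate_trials",
    "generate_neurons",
    "generate_behavior",
    "generate_locomotion",
    "generate_session",
    "sample_field_centers",
]

ODOR_PAIRS = ("AA", "AB", "BA", "BB")


class GenerationError(Exception):
    pass


@dataclass(frozen=True)
class PlantedCell:
    """Ground truth for one generated neuron with a temporal field."""

    neuron: int
    preferred_odor: str
    field_center: float  # seconds from the alignment event
    field_width: float  # Gaussian SD, seconds
    amplitude: float
    trial_reliability: float
    background_rate: float  # spurious events per second
    is_odor_cell: bool
    align_event: str = "odor1"  # "odor1" or "odor2"

    def __post_init__(self) -> None:
        if not 0 <= self.trial_reliability <= 1:
            raise ValidationError("trial_reliability must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorParams:
    n_cells_per_odor: int = 40
    n_noise_cells: int = 60
    n_odor2_cells: int = 10
    anticipation_weight: float = 0.0  # extra field mass in last 0.5 s of short delay
    field_width: float = 0.15
    amplitude: float = 8.0
    trial_reliability: float = 0.8
    background_rate: float = 0.0  # per planted cell
    noise_background_rate: float = 0.05  # per noise cell
    noise_sd: float = 0.05  # half-normal additive noise, activity units
    accuracy: dict = field(default_factory=lambda: {
        "standard_short": 0.875,
        "standard_long": 0.865,
        "reverse_short": 0.868,
        "reverse_long": 0.81,
    })
    latency_mean: float = 0.563
    latency_sd: float = 0.12
    reverse_latency_shift: float = 0.021
    bout_probability: float = 0.15
    bout_duration_mean: float = 1.5
    bout_duration_sd: float = 0.3
    bout_amplitude: float = 6.0
    twitch_amplitude: float = 1.0
    locomotion_noise_sd: float = 0.1
    iti: float = 6.0
    pre_roll: float = 5.0
    tail: float = 8.5

    def __post_init__(self) -> None:
        probs = [self.trial_reliability, self.bout_probability,
                 *self.accuracy.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        counts = [self.n_cells_per_odor, self.n_noise_cells, self.n_odor2_cells]
        if any(c < 0 for c in counts):
            raise ValidationError("cell counts must be >= 0")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------


def generate_trials(cfg: TaskConfig, seed: int | np.random.Generator,
                    iti: float = 6.0, pre_roll: float = 5.0) -> TrialTable:
    """Blocked pseudorandom schedule with an exact reverse-trial count.

    Each block contains the four odor pairs equally often; exactly
    ``round(reverse_fraction * total)`` trials are flagged reverse,
    placed uniformly at random across the whole session. Reverse trials
    realize the delay cued by the *other* odor.
    """
    if cfg.trials_per_block % 4:
        raise ValidationError("trials_per_block must be divisible by 4")
    rng = _rng(seed)
    a, b = cfg.odor_labels
    pair_of = {"AA": (a, a), "AB": (a, b), "BA": (b, a), "BB": (b, b)}
    pairs: list[tuple[str, str]] = []
    per_pair = cfg.trials_per_block // 4
    for _ in range(cfg.n_blocks):
        block = [pair_of[p] for p in ODOR_PAIRS for _ in range(per_pair)]
        rng.shuffle(block)
        pairs.extend(block)
    total = len(pairs)
    n_reverse = round(cfg.reverse_fraction * total)
    reverse_idx = set(rng.choice(total, size=n_reverse, replace=False).tolist())

    other = {a: b, b: a}
    trials = []
    t = pre_roll
    for i, (o1, o2) in enumerate(pairs):
        is_rev = i in reverse_idx
        delay = cfg.cued_delay(other[o1] if is_rev else o1)
        onset2 = t + cfg.odor_duration + delay
        trials.append(Trial(
            index=i, odor1=o1, odor2=o2, delay=delay, is_reverse=is_rev,
            odor1_onset=t, odor2_onset=onset2,
        ))
        t = onset2 + cfg.odor_duration + cfg.response_window + iti
    return TrialTable(trials, cfg)


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------


def sample_field_centers(cfg: TaskConfig, n: int, weight: float,
                         preferred_odor: str,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw field centers tiling odor + cued delay.

    With probability ``weight / (1 + weight)`` a center is drawn from the
    last 0.5 s of the short delay (anticipatory over-representation,
    applied only to short-cue cells); otherwise uniform over
    [0, odor_duration + cued delay]. ``weight=0`` is pure uniform tiling.
    """
    span = cfg.odor_duration + cfg.cued_delay(preferred_odor)
    centers = rng.uniform(0.0, span, size=n)
    if weight > 0 and cfg.cued_delay(preferred_odor) == cfg.short_delay:
        hot_end = cfg.odor_duration + cfg.short_delay
        take = rng.random(n) < weight / (1.0 + weight)
        centers[take] = rng.uniform(hot_end - 0.5, hot_end, size=int(take.sum()))
    return centers


def _n_frames_for(trials: TrialTable, frame_rate: float, tail: float) -> int:
    end = max(t.odor2_onset for t in trials) + tail
    return int(math.ceil(end * frame_rate))


def _add_transient(row: np.ndarray, frame_rate: float, center_s: float,
                   width_s: float, amplitude: float,
                   clip_end_s: float | None = None) -> None:
    lo = max(0, int((center_s - 4 * width_s) * frame_rate))
    hi_s = center_s + 4 * width_s
    if clip_end_s is not None:
        hi_s = min(hi_s, clip_end_s)
    hi = min(row.shape[0], int(math.ceil(hi_s * frame_rate)))
    if hi <= lo:
        return
    t = (np.arange(lo, hi) + 0.5) / frame_rate
    row[lo:hi] += amplitude * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def generate_neurons(cfg: TaskConfig, trials: TrialTable,
                     params: GeneratorParams,
                     seed: int | np.random.Generator,
                     ) -> tuple[np.ndarray, list[PlantedCell]]:
    """Emit the activity matrix and the planted ground truth.

    Each planted cell fires, on each preferred-1st-odor trial with
    probability ``trial_reliability``, a Gaussian transient at its field
    center; the transient is clipped at 2nd-odor onset when the realized
    delay is shorter than the field (reverse-short truncation). Noise
    cells emit only background events. Half-normal noise is added
    everywhere.
    """
    rng = _rng(seed)
    frame_rate = cfg.frame_rate
    n_frames = _n_frames_for(trials, frame_rate, params.tail)
    max_span = cfg.odor_duration + cfg.long_delay

    cells: list[PlantedCell] = []
    neuron = 0
    for odor in cfg.odor_labels:
        centers = sample_field_centers(
            cfg, params.n_cells_per_odor, params.anticipation_weight, odor, rng)
        for c in centers:
            if not 0 <= c <= max_span:
                raise GenerationError(f"field center {c} outside [0, {max_span}]")
            cells.append(PlantedCell(
                neuron=neuron, preferred_odor=odor, field_center=float(c),
                field_width=params.field_width, amplitude=params.amplitude,
                trial_reliability=params.trial_reliability,
                background_rate=params.background_rate,
                is_odor_cell=bool(c < cfg.odor_duration), align_event="odor1",
            ))
            neuron += 1
    for k in range(params.n_odor2_cells):
        odor = cfg.odor_labels[k % 2]
        cells.append(PlantedCell(
            neuron=neuron, preferred_odor=odor,
            field_center=float(rng.uniform(0.1, cfg.odor_duration)),
            field_width=params.field_width, amplitude=params.amplitude,
            trial_reliability=params.trial_reliability,
            background_rate=params.background_rate,
            is_odor_cell=True, align_event="odor2",
        ))
        neuron += 1

    n_total = neuron + params.n_noise_cells
    activity = np.zeros((n_total, n_frames), dtype=float)
    duration = n_frames / frame_rate

    for cell in cells:
        row = activity[cell.neuron]
        for trial in trials:
            if cell.align_event == "odor1":
                if trial.odor1 != cell.preferred_odor:
                    continue
                if rng.random() >= cell.trial_reliability:
                    continue
                _add_transient(row, frame_rate,
                               trial.odor1_onset + cell.field_center,
                               cell.field_width, cell.amplitude,
                               clip_end_s=trial.odor2_onset)
            else:
                if trial.odor2 != cell.preferred_odor:
                    continue
                if rng.random() >= cell.trial_reliability:
                    continue
                _add_transient(row, frame_rate,
                               trial.odor2_onset + cell.field_center,
                               cell.field_width, cell.amplitude)
        _add_background(row, frame_rate, duration, cell.background_rate,
                        params, rng)

    for i in range(neuron, n_total):
        _add_background(activity[i], frame_rate, duration,
                        params.noise_background_rate, params, rng)

    if params.noise_sd > 0:
        activity += np.abs(rng.normal(0.0, params.noise_sd, size=activity.shape))
    return activity, cells


def _add_background(row: np.ndarray, frame_rate: float, duration: float,
                    rate: float, params: GeneratorParams,
                    rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    n_events = rng.poisson(rate * duration)
    for t in rng.uniform(0.0, duration, size=n_events):
        _add_transient(row, frame_rate, t, params.field_width, params.amplitude)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def generate_behavior(trials: TrialTable, params: GeneratorParams,
                      seed: int | np.random.Generator) -> TrialTable:
    """Draw per-trial outcomes and lick times from the planted statistics.

    Correctness is Bernoulli with the category's accuracy; a responding
    trial gets a first lick at a Gaussian latency (shifted on reverse
    trials) truncated into the response window.
    """
    rng = _rng(seed)
    cfg = trials.cfg
    out = []
    clipped = 0
    for trial in trials:
        category = trials.condition_of(trial)
        acc = params.accuracy.get(category, 1.0)
        correct = rng.random() < acc
        licks_now = correct != trial.is_match  # lick iff (non-match & correct) or (match & wrong)
        licks: tuple[float, ...] = ()
        rewarded = False
        if licks_now:
            mean = params.latency_mean + (
                params.reverse_latency_shift if trial.is_reverse else 0.0)
            lat = rng.normal(mean, params.latency_sd) if params.latency_sd > 0 else mean
            lo, hi = 0.01, cfg.response_window - 0.01
            if not lo <= lat <= hi:
                clipped += 1
                lat = min(max(lat, lo), hi)
            first = trial.odor2_onset + lat
            licks = (first, first + 0.2)
            rewarded = not trial.is_match
        out.append(Trial(
            index=trial.index, odor1=trial.odor1, odor2=trial.odor2,
            delay=trial.delay, is_reverse=trial.is_reverse,
            odor1_onset=trial.odor1_onset, odor2_onset=trial.odor2_onset,
            licks=licks, rewarded=rewarded,
        ))
    if clipped:
        warnings.warn(
            f"{clipped} latency draws fell outside the response window "
            "and were truncated", stacklevel=2)
    return trials.with_trials(out)


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------


def generate_locomotion(trials: TrialTable, params: GeneratorParams,
                        seed: int | np.random.Generator,
                        n_frames: int | None = None) -> np.ndarray:
    """Low noise + odor-onset twitches + occasional >=1-s delay bouts."""
    rng = _rng(seed)
    cfg = trials.cfg
    fr = cfg.frame_rate
    if n_frames is None:
        n_frames = _n_frames_for(trials, fr, params.tail)
    trace = np.abs(rng.normal(0.0, params.locomotion_noise_sd, size=n_frames))

    def bump(start_s: float, dur_s: float, amp: float) -> None:
        lo = max(0, int(start_s * fr))
        hi = min(n_frames, int((start_s + dur_s) * fr))
        trace[lo:hi] += amp

    for trial in trials:
        bump(trial.odor1_onset, 0.2, params.twitch_amplitude)
        bump(trial.odor2_onset, 0.2, params.twitch_amplitude)
        if params.bout_probability > 0 and rng.random() < params.bout_probability:
            dur = max(1.0, rng.normal(params.bout_duration_mean,
                                      params.bout_duration_sd))
            delay_start = trial.odor1_onset + cfg.odor_duration
            start = rng.uniform(delay_start,
                                max(delay_start, trial.odor2_onset - dur))
            bump(start, dur, params.bout_amplitude)
    return trace


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------


def generate_session(cfg: TaskConfig, params: GeneratorParams, seed: int,
                     animal: str = "synthetic", day: str = "day1",
                     ) -> tuple[SessionRecording, list[PlantedCell]]:
    """Build a full session deterministically from (cfg, params, seed)."""
    rng = np.random.default_rng(seed)
    trials = generate_trials(cfg, rng, iti=params.iti, pre_roll=params.pre_roll)
    trials = generate_behavior(trials, params, rng)
    activity, cells = generate_neurons(cfg, trials, params, rng)
    locomotion = generate_locomotion(trials, params, rng,
                                     n_frames=activity.shape[1])
    rec = SessionRecording(
        activity=activity, frame_rate=cfg.frame_rate, trials=trials,
        locomotion=locomotion, animal=animal, day=day,
        condition="with-reverse" if cfg.reverse_fraction > 0 else "standard-only",
    )
    return rec, cells


def truth_frame(cells: list[PlantedCell]):
    """Planted ground truth as a table (neuron, preferred_odor, center...)."""
    import pandas as pd

    return pd.DataFrame([{
        "neuron": c.neuron,
        "preferred_odor": c.preferred_odor,
        "center_s": c.field_center,
        "width_s": c.field_width,
        "amplitude": c.amplitude,
        "reliability": c.trial_reliability,
        "align_event": c.align_event,
    } for c in cells])
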