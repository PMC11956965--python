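"""Data model and on-disk session container.

Time convention: all event times are seconds from session start; frame ``i``
covers ``[i / frame_rate, (i + 1) / frame_rate)`` with 0-based frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "Trial",
    "TrialTable",
    "SessionRecording",
    "AlignedActivity",
    "SessionFormatError",
    "ValidationError",
    "read_session",
    "write_session",
    "read_aligned",
    "write_aligned",
    "load_task_config",
]


class SessionFormatError(Exception):
    """A session container is missing a required dataset or attribute."""


class ValidationError(Exception):
    """A data structure violates one of its declared invariants."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskConfig:
    """Task timing and schedule parameters.

    Defaults follow the task as run: 1-s odors, 2.5-s delay cued by odor A
    and 5.0-s delay cued by odor B, 20% reverse trials, 7 blocks of 20
    trials, a 3-s response window from 2nd-odor onset, and 30.9 Hz imaging.
    ``counterbalance=True`` swaps which odor cues the short delay.
    """

    odor_labels: tuple[str, str] = ("A", "B")
    odor_duration: float = 1.0
    delay_map: Mapping[str, float] = field(
        default_factory=lambda: {"A": 2.5, "B": 5.0}
    )
    reverse_fraction: float = 0.2
    n_blocks: int = 7
    trials_per_block: int = 20
    response_window: float = 3.0
    frame_rate: float = 30.9
    counterbalance: bool = False

    def __post_init__(self) -> None:
        if self.odor_duration <= 0:
            raise ValidationError("odor_duration must be > 0")
        delays = [self.delay_map[o] for o in self.odor_labels]
        if any(d <= 0 for d in delays) or delays[0] == delays[1]:
            raise ValidationError("delays must be strictly positive and distinct")
        if not 0 <= self.reverse_fraction < 1:
            raise ValidationError("reverse_fraction must lie in [0, 1)")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        if self.counterbalance:
            a, b = self.odor_labels
            swapped = {a: self.delay_map[b], b: self.delay_map[a]}
            object.__setattr__(self, "delay_map", swapped)
            object.__setattr__(self, "counterbalance", False)

    @property
    def short_delay(self) -> float:
        return min(self.delay_map.values())

    @property
    def long_delay(self) -> float:
        return max(self.delay_map.values())

    def cued_delay(self, odor1: str) -> float:
        return self.delay_map[odor1]


def load_task_config(path: str | os.PathLike) -> TaskConfig:
    """Load a TaskConfig from a YAML key/value file, validating invariants."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "odor_labels" in raw:
        raw["odor_labels"] = tuple(raw["odor_labels"])
    if "delay_map" in raw:
        raw["delay_map"] = {str(k): float(v) for k, v in raw["delay_map"].items()}
    return TaskConfig(**raw)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    """One trial's events, all times in seconds from session start."""

    index: int
    odor1: str
    odor2: str
    delay: float
    is_reverse: bool
    odor1_onset: float
    odor2_onset: float
    licks: tuple[float, ...] = ()
    rewarded: bool = False
    correct: bool | None = None
    first_lick_latency: float | None = None

    def __post_init__(self) -> None:
        if list(self.licks) != sorted(self.licks):
            raise ValidationError(f"trial {self.index}: licks not sorted")

    @property
    def is_match(self) -> bool:
        return self.odor1 == self.odor2


class TrialTable:
    """Ordered collection of trials with condition helpers."""

    def __init__(self, trials: Sequence[Trial], cfg: TaskConfig):
        self.trials = list(trials)
        self.cfg = cfg
        for t in self.trials:
            expected = t.odor1_onset + cfg.odor_duration + t.delay
            if abs(t.odor2_onset - expected) > 1e-9:
                raise ValidationError(
                    f"trial {t.index}: odor2_onset {t.odor2_onset} != "
                    f"odor1_onset + odor_duration + delay ({expected})"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrialTable) and self.trials == other.trials

    def condition_of(self, trial: Trial) -> str:
        """Label among standard/reverse x short/long by realized delay."""
        length = "short" if trial.delay == self.cfg.short_delay else "long"
        kind = "reverse" if trial.is_reverse else "standard"
        return f"{kind}_{length}"

    def select(self, condition: str) -> list[int]:
        """Indices (table positions) of trials in a named condition."""
        return [i for i, t in enumerate(self.trials) if self.condition_of(t) == condition]

    def with_trials(self, trials: Sequence[Trial]) -> "TrialTable":
        return TrialTable(trials, self.cfg)

    # -- tabular round trip --------------------------------------------------

    _COLUMNS = [
        "index", "odor1", "odor2", "delay_s", "is_reverse",
        "odor1_onset_s", "licks", "rewarded",
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "index": t.index,
                "odor1": t.odor1,
                "odor2": t.odor2,
                "delay_s": t.delay,
                "is_reverse": int(t.is_reverse),
                "odor1_onset_s": t.odor1_onset,
                "licks": ";".join(repr(x) for x in t.licks),
                "rewarded": int(t.rewarded),
            })
        return pd.DataFrame(rows, columns=self._COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cfg: TaskConfig) -> "TrialTable":
        trials = []
        for _, row in df.iterrows():
            licks = tuple(
                float(x) for x in str(row["licks"]).split(";") if x not in ("", "nan")
            )
            delay = float(row["delay_s"])
            onset = float(row["odor1_onset_s"])
            trials.append(Trial(
                index=int(row["index"]),
                odor1=str(row["odor1"]),
                odor2=str(row["odor2"]),
                delay=delay,
                is_reverse=bool(int(row["is_reverse"])),
                odor1_onset=onset,
                odor2_onset=onset + cfg.odor_duration + delay,
                licks=licks,
                rewarded=bool(int(row["rewarded"])),
            ))
        return cls(trials, cfg)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


@dataclass
class SessionRecording:
    """One session: activity matrix, frame clock, trials, locomotion."""

    activity: np.ndarray  # neurons x frames, nonnegative
    frame_rate: float
    trials: TrialTable
    locomotion: np.ndarray  # frames
    animal: str = "synthetic"
    day: str = "day1"
    condition: str = "with-reverse"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.locomotion = np.asarray(self.locomotion, dtype=float)
        self.validate()

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> None:
        if self.activity.ndim != 2:
            raise ValidationError("activity must be neurons x frames")
        if self.activity.size and np.min(self.activity) < 0:
            raise ValidationError("activity has negative entries")
        if self.locomotion.ndim != 1 or self.locomotion.shape[0] != self.n_frames:
            raise ValidationError("locomotion length must equal frame count")
        rw = self.trials.cfg.response_window
        for t in self.trials:
            if t.odor1_onset < 0 or t.odor2_onset + rw > self.duration + 1e-9:
                raise ValidationError(
                    f"trial {t.index} window [{t.odor1_onset}, "
                    f"{t.odor2_onset + rw}] outside recording of "
                    f"{self.duration:.2f} s"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionRecording):
            return NotImplemented
        return (
            np.array_equal(self.activity, other.activity)
            and self.frame_rate == other.frame_rate
            and self.trials == other.trials
            and np.array_equal(self.locomotion, other.locomotion)
            and (self.animal, self.day, self.condition)
            == (other.animal, other.day, other.condition)
        )


@dataclass
class AlignedActivity:
    """Neurons x trials x time-bins tensor aligned to 1st-odor onset."""

    tensor: np.ndarray
    bin_frames: int
    bin_size: float  # seconds
    time_axis: np.ndarray  # bin-center times relative to 1st-odor onset
    trial_index_map: np.ndarray  # tensor trial -> TrialTable position
    trials: TrialTable

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.trial_index_map = np.asarray(self.trial_index_map, dtype=int)
        if self.tensor.ndim != 3:
            raise ValidationError("tensor must be neurons x trials x bins")
        if self.tensor.shape[1] != self.trial_index_map.shape[0]:
            raise ValidationError("trial_index_map inconsistent with tensor")
        if self.tensor.shape[2] != self.time_axis.shape[0]:
            raise ValidationError("time_axis inconsistent with tensor")
        if len(self.time_axis) > 1:
            d = np.diff(self.time_axis)
            if np.any(d <= 0) or not np.allclose(d, d[0]):
                raise ValidationError("time_axis must increase uniformly")

    @property
    def n_neurons(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_trials(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_bins(self) -> int:
        return self.tensor.shape[2]

    def trial_objects(self) -> list[Trial]:
        return [self.trials[i] for i in self.trial_index_map]

    def condition_slice(self, condition: str) -> "AlignedActivity":
        """Restrict to trials of one condition label."""
        keep = [
            j for j, i in enumerate(self.trial_index_map)
            if self.trials.condition_of(self.trials[i]) == condition
        ]
        return self.subset(keep)

    def subset(self, tensor_positions: Sequence[int]) -> "AlignedActivity":
        idx = np.asarray(tensor_positions, dtype=int)
        return AlignedActivity(
            tensor=self.tensor[:, idx, :],
            bin_frames=self.bin_frames,
            bin_size=self.bin_size,
            time_axis=self.time_axis,
            trial_index_map=self.trial_index_map[idx],
            trials=self.trials,
        )


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_CFG_ATTRS = (
    "odor_duration", "reverse_fraction", "n_blocks", "trials_per_block",
    "response_window", "frame_rate",
)


def write_session(rec: SessionRecording, path: str | os.PathLike) -> None:
    """Write a session container (HDF5 + sidecar trials CSV).

    Numeric arrays round-trip bit-exactly through :func:`read_session`.
    """
    path = os.fspath(path)
    cfg = rec.trials.cfg
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=rec.activity.astype(np.float64))
        f.create_dataset("locomotion", data=rec.locomotion.astype(np.float64))
        f.attrs["frame_rate"] = rec.frame_rate
        f.attrs["animal"] = rec.animal
        f.attrs["day"] = rec.day
        f.attrs["condition"] = rec.condition
        f.attrs["odor_labels"] = list(cfg.odor_labels)
        f.attrs["delays"] = [cfg.delay_map[o] for o in cfg.odor_labels]
        for name in _CFG_ATTRS:
            f.attrs[name] = getattr(cfg, name)
        grp = f.create_group("trials")
        df = rec.trials.to_frame()
        for col in df.columns:
            vals = df[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype(h5py.string_dtype())
            grp.create_dataset(col, data=vals)
    rec.trials.to_frame().to_csv(_sidecar_path(path), index=False)


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".trials.csv"


def write_aligned(aligned: AlignedActivity, path: str | os.PathLike) -> None:
    """Persist an aligned tensor plus its trial table and task config."""
    path = os.fspath(path)
    cfg = aligned.trials.cfg
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=aligned.tensor.astype(np.float64))
        f.create_dataset("time_axis", data=aligned.time_axis)
        f.create_dataset("trial_index_map", data=aligned.trial_index_map)
        f.attrs["bin_frames"] = aligned.bin_frames
        f.attrs["bin_size"] = aligned.bin_size
        f.attrs["odor_labels"] = list(cfg.odor_labels)
        f.attrs["delays"] = [cfg.delay_map[o] for o in cfg.odor_labels]
        for name in _CFG_ATTRS:
            f.attrs[name] = getattr(cfg, name)
        grp = f.create_group("trials")
        df = aligned.trials.to_frame()
        for col in df.columns:
            vals = df[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype(h5py.string_dtype())
            grp.create_dataset(col, data=vals)


def _read_cfg_and_trials(f: h5py.File) -> TrialTable:
    labels = tuple(
        x.decode() if isinstance(x, bytes) else str(x)
        for x in f.attrs["odor_labels"]
    )
    delays = [float(x) for x in f.attrs["delays"]]
    cfg = TaskConfig(
        odor_labels=labels,
        odor_duration=float(f.attrs["odor_duration"]),
        delay_map=dict(zip(labels, delays)),
        reverse_fraction=float(f.attrs["reverse_fraction"]),
        n_blocks=int(f.attrs["n_blocks"]),
        trials_per_block=int(f.attrs["trials_per_block"]),
        response_window=float(f.attrs["response_window"]),
        frame_rate=float(f.attrs["frame_rate"]),
    )
    grp = f["trials"]
    cols = {}
    for col in TrialTable._COLUMNS:
        if col not in grp:
            raise SessionFormatError(f"missing dataset: /trials/{col}")
        vals = grp[col][()]
        if vals.dtype.kind in ("S", "O"):
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
        cols[col] = vals
    return TrialTable.from_frame(pd.DataFrame(cols), cfg)


def read_aligned(path: str | os.PathLike) -> AlignedActivity:
    with h5py.File(os.fspath(path), "r") as f:
        for name in ("tensor", "time_axis", "trial_index_map", "trials"):
            if name not in f:
                raise SessionFormatError(f"missing dataset: /{name}")
        trials = _read_cfg_and_trials(f)
        return AlignedActivity(
            tensor=f["tensor"][()],
            bin_frames=int(f.attrs["bin_frames"]),
            bin_size=float(f.attrs["bin_size"]),
            time_axis=f["time_axis"][()],
            trial_index_map=f["trial_index_map"][()],
            trials=trials,
        )


def read_session(path: str | os.PathLike) -> SessionRecording:
    """Read and fully validate a session container written by write_session."""
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        for name in ("activity", "locomotion", "trials"):
            if name not in f:
                raise SessionFormatError(f"missing dataset: /{name}")
        for name in _CFG_ATTRS + ("animal", "day", "condition", "odor_labels", "delays"):
            if name not in f.attrs:
                raise SessionFormatError(f"missing attribute: {name}")
        trials = _read_cfg_and_trials(f)
        return SessionRecording(
            activity=f["activity"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            trials=trials,
            locomotion=f["locomotion"][()],
            animal=str(f.attrs["animal"]),
            day=str(f.attrs["day"]),
            condition=str(f.attrs["condition"]),
        )
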