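"""Core containers shared across the pipeline.

A :class:`Recording` is one channel of surface EMG with its trial identity;
an :class:`EventTable` marks the repetition phases of an exercise set. Both
are deliberately light wrappers around numpy / pandas objects so the rest
of the package can stay functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Exercise labels used throughout: barbell military press (BMP) and machine
#: shoulder press (MSP), each with the load path in front of or behind the head.
EXERCISES = ("front_BMP", "back_BMP", "front_MSP", "back_MSP")

MUSCLES = (
    "anterior_deltoid",
    "medial_deltoid",
    "posterior_deltoid",
    "upper_trapezius",
    "pectoralis_major",
    "triceps_brachii",
)

PHASES = ("ascending", "isometric", "descending")
#: Phases that enter the activation table (the isometric pause is computed
#: upstream but not analysed).
ANALYZED_PHASES = ("ascending", "descending")


def exercise_factors(exercise: str) -> tuple[str, str]:
    """Map an exercise label to its (load, position) factor levels.

    ``front_BMP`` -> ("barbell", "front"), ``back_MSP`` -> ("machine", "back"), etc.
    """
    try:
        position, kind = exercise.split("_")
    except ValueError:
        raise ValueError(f"unrecognized exercise label: {exercise!r}") from None
    if position not in ("front", "back") or kind not in ("BMP", "MSP"):
        raise ValueError(f"unrecognized exercise label: {exercise!r}")
    load = "barbell" if kind == "BMP" else "machine"
    return load, position


@dataclass(frozen=True)
class Recording:
    """One channel of sEMG, in microvolts, with its trial identity."""

    samples: np.ndarray  # µV
    fs: float  # Hz
    participant: str = ""
    muscle: str = ""
    trial_kind: str = "exercise"  # "mvic" | "exercise"
    exercise: Optional[str] = None
    attempt: Optional[int] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=float))

    def label(self) -> str:
        if self.trial_kind == "mvic":
            return f"{self.participant}_{self.muscle}_mvic{self.attempt}"
        return f"{self.participant}_{self.muscle}_{self.exercise}"


@dataclass(frozen=True)
class EventTable:
    """Phase markers for one exercise set.

    Stored as a sorted DataFrame with columns ``onset`` (s), ``duration``
    (s), ``phase`` and ``rep`` (1-based repetition index). Intervals are
    half-open ``[onset, onset + duration)`` and must not overlap.
    """

    events: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ev = self.events
        required = {"onset", "duration", "phase", "rep"}
        missing = required - set(ev.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        ev = ev.sort_values("onset", kind="mergesort").reset_index(drop=True)
        if (ev["duration"] <= 0).any():
            raise ValueError("event durations must be positive")
        ends = ev["onset"].to_numpy() + ev["duration"].to_numpy()
        # small tolerance so quantized boundaries that abut exactly don't trip
        if np.any(ev["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
            raise ValueError("event table contains overlapping phases")
        object.__setattr__(self, "events", ev)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_duration(self) -> float:
        return float(self.events["duration"].sum())

    @property
    def end(self) -> float:
        last = self.events.iloc[-1]
        return float(last["onset"] + last["duration"])

    def to_frame(self) -> pd.DataFrame:
        """Long TSV form: onset, duration, trial_type = 'phase:rep'."""
        out = pd.DataFrame(
            {
                "onset": self.events["onset"],
                "duration": self.events["duration"],
                "trial_type": self.events["phase"].astype(str)
                + ":"
                + self.events["rep"].astype(int).astype(str),
            }
        )
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventTable":
        required = {"onset", "duration", "trial_type"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"events file missing columns: {sorted(missing)}")
        phases, reps = [], []
        for t in frame["trial_type"]:
            phase, _, rep = str(t).partition(":")
            phases.append(phase)
            reps.append(int(rep) if rep else 1)
        ev = pd.DataFrame(
            {
                "onset": frame["onset"].astype(float),
                "duration": frame["duration"].astype(float),
                "phase": phases,
                "rep": reps,
            }
        )
        return cls(ev)


@dataclass
class Dataset:
    """A complete study in memory: traces, events, manifest, ground truth.

    Produced by the generator or re-read from disk; ``config`` is the
    generator configuration when known.
    """

    recordings: list[Recording]
    events: dict[str, EventTable]
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    mvic_truth: pd.DataFrame
    config: Optional[object] = None
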