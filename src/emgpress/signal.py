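"""Signal conditioning: band-pass filtering, moving-RMS envelopes, MVIC
references, phase segmentation and the normalized activation table.

The reduction chain mirrors standard surface-EMG practice: a 4th-order
Butterworth band-pass (nominally 10-500 Hz), a 25-ms moving RMS window, a
maximal-contraction (MVIC) reference taken as the central-2-s envelope mean
per attempt, phase means over the event-marked ascending / isometric /
descending segments, aggregation that drops the first and last repetition
of each set, and normalization to percent of MVIC (nRMS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import (
    ANALYZED_PHASES,
    EventTable,
    Recording,
    exercise_factors,
)

logger = logging.getLogger(__name__)

_clamp_warned: set[tuple[float, float]] = set()

__all__ = [
    "FilterSpec",
    "Envelope",
    "MvicReference",
    "design_sos",
    "bandpass_filter",
    "moving_rms",
    "mvic_reference",
    "segment_phases",
    "aggregate_repetitions",
    "normalize",
    "build_activation_table",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``order`` is the scipy design order (4, the acquisition chain's
    "IV-order" filter). With ``mode='zero_phase'`` the filter is applied
    forward-backward, which squares the magnitude response (-6 dB at the
    band edges instead of -3 dB) but leaves envelopes lag-free.
    """

    order: int = 4
    low_cut: float = 10.0  # Hz
    high_cut: float = 500.0  # Hz
    mode: Literal["zero_phase", "causal"] = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def effective_high_cut(self, fs: float) -> float:
        """Upper edge actually used at sampling rate ``fs``.

        A 10-500 Hz band at fs = 1000 Hz puts the upper edge exactly at
        Nyquist, which is not designable; the edge is clamped to
        0.99 * fs / 2 with a warning.
        """
        nyq = fs / 2.0
        if self.low_cut >= nyq:
            raise ValueError(
                f"low_cut {self.low_cut} Hz is at or above Nyquist ({nyq} Hz); "
                "lower the cutoff or raise the sampling rate"
            )
        if self.high_cut < nyq:
            return self.high_cut
        clamped = 0.99 * nyq
        key = (self.high_cut, fs)
        if key not in _clamp_warned:  # warn once per (cutoff, fs) pair
            _clamp_warned.add(key)
            msg = (
                f"high_cut {self.high_cut} Hz is at or above Nyquist ({nyq} Hz); "
                f"clamping to {clamped:.1f} Hz"
            )
            warnings.warn(msg, UserWarning, stacklevel=3)
            logger.warning(msg)
        return clamped


@dataclass(frozen=True)
class Envelope:
    """Moving-RMS envelope with window-center timestamps."""

    values: np.ndarray  # µV, all >= 0
    times: np.ndarray  # s, window centers
    fs: float
    window_s: float
    hop: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must align")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


@dataclass(frozen=True)
class MvicReference:
    """Per-participant, per-muscle normalization reference in µV."""

    participant: str
    muscle: str
    value: float
    per_attempt_values: tuple[float, ...]
    rule: Literal["max_of_attempts", "mean_of_attempts"] = "max_of_attempts"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("MVIC reference must be positive")


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-section design for ``spec`` at sampling rate ``fs``."""
    high = spec.effective_high_cut(fs)
    return sps.butter(spec.order, [spec.low_cut, high], btype="bandpass", fs=fs, output="sos")


def frequency_response(spec: FilterSpec, fs: float, freqs: Sequence[float]) -> np.ndarray:
    """Single-pass magnitude response of the designed filter at ``freqs`` (Hz)."""
    sos = design_sos(spec, fs)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)


def bandpass_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-pass filter a recording, preserving its length and timebase."""
    sos = design_sos(spec, rec.fs)
    if spec.mode == "zero_phase":
        filtered = sps.sosfiltfilt(sos, rec.samples)
    else:
        filtered = sps.sosfilt(sos, rec.samples)
    return rec.with_samples(filtered)


def moving_rms(rec: Recording, window_s: float = 0.025, hop: int = 1) -> Envelope:
    """Moving-window RMS envelope.

    Windows lie fully inside the signal (no padding); value k is the RMS of
    samples ``[k*hop, k*hop + W)`` and is stamped at the window center.
    """
    window = int(round(window_s * rec.fs))
    if window < 2:
        raise ValueError(f"window of {window_s} s is under 2 samples at fs={rec.fs}")
    if hop < 1:
        raise ValueError("hop must be >= 1 sample")
    x = rec.samples
    if x.size < window:
        raise ValueError(
            f"signal of {x.size} samples is shorter than the {window}-sample window"
        )
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    sums = csum[window:] - csum[:-window]
    means = sums[::hop] / window
    # cumulative round-off can leave tiny negatives on silent stretches
    values = np.sqrt(np.maximum(means, 0.0))
    starts = np.arange(0, x.size - window + 1, hop)
    times = (starts + (window - 1) / 2.0) / rec.fs
    return Envelope(values=values, times=times, fs=rec.fs, window_s=window_s, hop=hop)


def _central_mean(env: Envelope, central_s: float) -> float:
    t0, t1 = env.times[0], env.times[-1]
    if t1 - t0 < central_s - 1e-9:
        raise ValueError(
            f"attempt envelope spans {t1 - t0:.3f} s, shorter than the "
            f"central window of {central_s} s"
        )
    mid = 0.5 * (t0 + t1)
    mask = (env.times >= mid - central_s / 2) & (env.times <= mid + central_s / 2)
    return float(env.values[mask].mean())


def mvic_reference(
    envelopes: Sequence[Envelope],
    rule: Literal["max_of_attempts", "mean_of_attempts"] = "max_of_attempts",
    central_s: float = 2.0,
    participant: str = "",
    muscle: str = "",
) -> MvicReference:
    """MVIC reference: central-``central_s`` envelope mean per attempt,
    combined across attempts by ``rule`` (default: the peak attempt)."""
    if not envelopes:
        raise ValueError("need at least one MVIC attempt")
    per_attempt = []
    for i, env in enumerate(envelopes, start=1):
        try:
            per_attempt.append(_central_mean(env, central_s))
        except ValueError as exc:
            raise ValueError(f"MVIC attempt {i}: {exc}") from None
    if rule == "max_of_attempts":
        value = max(per_attempt)
    elif rule == "mean_of_attempts":
        value = float(np.mean(per_attempt))
    else:
        raise ValueError(f"unknown MVIC rule {rule!r}")
    return MvicReference(
        participant=participant,
        muscle=muscle,
        value=value,
        per_attempt_values=tuple(per_attempt),
        rule=rule,
    )


def segment_phases(env: Envelope, events: EventTable) -> pd.DataFrame:
    """Mean envelope RMS per (repetition, phase).

    A window contributes to a phase iff its center timestamp lies in
    ``[onset, onset + duration)``.
    """
    # recover the signal's end from the last window center (half-open samples)
    signal_end = env.times[-1] + env.window_s / 2.0 + 1.0 / env.fs
    rows = []
    for _, ev in events.events.iterrows():
        onset, duration = float(ev["onset"]), float(ev["duration"])
        if onset < -1e-9 or onset + duration > signal_end + 1e-6:
            raise ValueError(
                f"event {ev['phase']}:{int(ev['rep'])} at [{onset:.3f}, "
                f"{onset + duration:.3f}) s lies outside the recording"
            )
        mask = (env.times >= onset) & (env.times < onset + duration)
        if not mask.any():
            raise ValueError(
                f"phase {ev['phase']}:{int(ev['rep'])} contains no envelope windows"
            )
        rows.append(
            {
                "rep": int(ev["rep"]),
                "phase": str(ev["phase"]),
                "mean_rms": float(env.values[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def aggregate_repetitions(per_rep: pd.DataFrame, n_reps: int) -> pd.DataFrame:
    """Phase means over the interior repetitions (2 .. n_reps-1).

    The first and last repetition of each set are dropped for technique
    consistency, so at least three repetitions are required.
    """
    if n_reps < 3:
        raise ValueError("need at least 3 repetitions: first and last are excluded")
    kept = per_rep[(per_rep["rep"] > 1) & (per_rep["rep"] < n_reps)]
    if kept.empty:
        raise ValueError("no interior repetitions left after exclusion")
    out = (
        kept.groupby("phase", sort=False)["mean_rms"]
        .mean()
        .rename("mean_rms")
        .reset_index()
    )
    out["reps_used"] = [tuple(sorted(kept.loc[kept["phase"] == p, "rep"])) for p in out["phase"]]
    return out


def normalize(phase_mean: float, mvic: MvicReference | float) -> float:
    """Normalized RMS in percent of the MVIC reference (may exceed 100)."""
    value = mvic.value if isinstance(mvic, MvicReference) else float(mvic)
    if value <= 0:
        raise ValueError("MVIC reference must be positive")
    return 100.0 * phase_mean / value


@dataclass
class _TrialSet:
    mvic: dict[int, Recording] = field(default_factory=dict)
    exercise: dict[str, tuple[Recording, EventTable]] = field(default_factory=dict)


def build_activation_table(dataset, config=None) -> pd.DataFrame:
    """Run the full reduction on a dataset and return the activation table.

    ``dataset`` is a :class:`~emgpress.datatypes.Dataset` (from the
    generator or loaded from disk). Returns one row per participant x
    muscle x exercise x analyzed phase with columns participant, muscle,
    exercise, load, position, phase, nrms_percent, reps_used.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    cfg = config or PipelineConfig()
    groups: dict[tuple[str, str], _TrialSet] = {}
    for rec in dataset.recordings:
        key = (rec.participant, rec.muscle)
        ts = groups.setdefault(key, _TrialSet())
        if rec.trial_kind == "mvic":
            ts.mvic[int(rec.attempt)] = rec
        else:
            ts.exercise[rec.exercise] = (rec, dataset.events[rec.label()])

    exercises = sorted({rec.exercise for rec in dataset.recordings if rec.trial_kind == "exercise"})
    missing: list[tuple[str, str, str]] = []
    rows = []
    for (participant, muscle), ts in sorted(groups.items()):
        if not ts.mvic:
            missing.extend((participant, muscle, "mvic") for _ in (1,))
            continue
        envs = [
            moving_rms(bandpass_filter(ts.mvic[a], cfg.filter), cfg.window_s, cfg.hop)
            for a in sorted(ts.mvic)
        ]
        mvic = mvic_reference(
            envs, rule=cfg.mvic_rule, central_s=cfg.mvic_central_s,
            participant=participant, muscle=muscle,
        )
        for exercise in exercises:
            if exercise not in ts.exercise:
                missing.append((participant, muscle, exercise))
                continue
            rec, events = ts.exercise[exercise]
            env = moving_rms(bandpass_filter(rec, cfg.filter), cfg.window_s, cfg.hop)
            per_rep = segment_phases(env, events)
            n_reps = int(per_rep["rep"].max())
            per_phase = aggregate_repetitions(per_rep, n_reps)
            load, position = exercise_factors(exercise)
            for _, ph in per_phase.iterrows():
                if ph["phase"] not in ANALYZED_PHASES:
                    continue  # isometric pause: computed, not emitted
                rows.append(
                    {
                        "participant": participant,
                        "muscle": muscle,
                        "exercise": exercise,
                        "load": load,
                        "position": position,
                        "phase": ph["phase"],
                        "nrms_percent": normalize(ph["mean_rms"], mvic),
                        "reps_used": ";".join(str(r) for r in ph["reps_used"]),
                    }
                )
    if missing:
        raise ValueError(f"incomplete dataset; missing trials: {missing[:10]}")
    return pd.DataFrame(rows)
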