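"""Synthetic sEMG cohorts with known ground truth.

The generator emulates the study design the analysis expects: eight
participants, six shoulder-girdle muscles, four overhead-press variations
(barbell / machine crossed with front / back), six repetitions per set with
2-s ascending, ~0.5-s isometric and 2-s descending phases, plus three 5-s
maximal-contraction (MVIC) trials per muscle.

Signal model
------------
Each trace is an amplitude-modulated stochastic carrier: white Gaussian
noise shaped by a Butterworth band-pass (default 20-150 Hz), which yields
the unimodal "belly-shaped" power spectrum of clean surface EMG. Within
each repetition phase the carrier segment is rescaled so its realized RMS
equals the programmed level exactly, so ground-truth activation tables are
exact by construction; phase-to-phase transitions are 100-ms linear ramps.
Participant MVIC amplitudes are log-normal. Between-participant scatter of
the activation levels (``within_cell_sd``) controls the realized effect
sizes, so standardized differences between conditions can be programmed
directly.

Seeding: one master seed; every trial draws from a substream derived from
(participant, muscle, trial, attempt), so adding trials never perturbs
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import (
    ANALYZED_PHASES,
    EXERCISES,
    MUSCLES,
    PHASES,
    Dataset,
    EventTable,
    Recording,
)

__all__ = [
    "SynthConfig",
    "ArtifactSpec",
    "Dataset",
    "default_activation_table",
    "make_carrier",
    "make_mvic_trial",
    "make_exercise_trial",
    "inject_artifact",
    "sample_activation_matrix",
    "make_cohort",
]


def default_activation_table() -> dict[tuple[str, str, str], float]:
    """Mean nRMS fraction per (muscle, exercise, phase).

    The numbers are user-set fixtures with a qualitative ordering that
    matches the study's findings (posterior deltoid: back > front and
    barbell > machine; pectoralis major: front > back; ascending >
    descending everywhere; upper trapezius flat across exercises) — they
    are not measured values.
    """
    base = {
        # muscle: {exercise: ascending level}
        "anterior_deltoid": {
            "front_BMP": 0.62, "back_BMP": 0.72, "front_MSP": 0.58, "back_MSP": 0.66,
        },
        "medial_deltoid": {
            "front_BMP": 0.55, "back_BMP": 0.78, "front_MSP": 0.48, "back_MSP": 0.64,
        },
        "posterior_deltoid": {
            "front_BMP": 0.35, "back_BMP": 0.70, "front_MSP": 0.25, "back_MSP": 0.52,
        },
        "upper_trapezius": {
            "front_BMP": 0.60, "back_BMP": 0.60, "front_MSP": 0.60, "back_MSP": 0.60,
        },
        "pectoralis_major": {
            "front_BMP": 0.55, "back_BMP": 0.35, "front_MSP": 0.50, "back_MSP": 0.28,
        },
        "triceps_brachii": {
            "front_BMP": 0.80, "back_BMP": 0.74, "front_MSP": 0.76, "back_MSP": 0.72,
        },
    }
    table: dict[tuple[str, str, str], float] = {}
    for muscle, per_ex in base.items():
        for exercise, asc in per_ex.items():
            table[(muscle, exercise, "ascending")] = asc
            table[(muscle, exercise, "isometric")] = round(asc * 0.85, 4)
            table[(muscle, exercise, "descending")] = round(asc * 0.65, 4)
    return table


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact to inject: mains interference, motion drift, or the
    amplitude loss + spectral edge shift of an innervation-zone placement.

    ``amplitude`` is the artifact RMS as a fraction of the trace RMS;
    ``target`` selects trials by substring of their label ('' = all).
    """

    kind: str  # "powerline" | "motion" | "innervation_zone"
    amplitude: float = 1.0
    frequency: float = 50.0  # Hz, powerline only
    target: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("powerline", "motion", "innervation_zone"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("artifact amplitude must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the generator (defaults = the protocol)."""

    n_participants: int = 8
    fs: float = 1000.0
    muscles: tuple[str, ...] = MUSCLES
    exercises: tuple[str, ...] = EXERCISES
    n_reps: int = 6
    phase_durations: tuple[float, float, float] = (2.0, 0.5, 2.0)  # asc, iso, desc
    mvic_attempts: int = 3
    mvic_duration: float = 5.0
    mvic_base_uv: float = 400.0
    between_subject_cv: float = 0.15
    within_cell_sd: float = 0.05  # between-participant scatter of cell nRMS
    carrier_band: tuple[float, float] = (20.0, 150.0)
    activation_table: dict = field(default_factory=default_activation_table)
    artifact_specs: tuple[ArtifactSpec, ...] = ()
    event_quantization: Optional[float] = None  # e.g. 1/30 s camera frames
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ValueError("carrier band must satisfy 0 < low < high")
        if self.fs <= 2 * hi:
            raise ValueError(
                f"fs={self.fs} must exceed twice the upper carrier edge ({hi} Hz)"
            )
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        if any(v <= 0 for v in self.activation_table.values()):
            raise ValueError("activation_table entries must be positive")
        if self.n_reps < 3:
            raise ValueError("need n_reps >= 3 (first and last are excluded downstream)")

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_participants))

    def activation(self, muscle: str, exercise: str, phase: str) -> float:
        key = (muscle, exercise, phase)
        if key not in self.activation_table:
            raise ValueError(f"activation_table has no entry for {key}")
        return float(self.activation_table[key])


# --- seeding -----------------------------------------------------------

_KIND_CODES = {"mvic": 1, "exercise": 2, "amplitude": 3, "cells": 4, "artifact": 5}


def _rng(seed: int, kind: str, *key: int) -> np.random.Generator:
    """Deterministic substream for one trial (or one model layer)."""
    ss = np.random.SeedSequence(seed, spawn_key=(_KIND_CODES[kind], *key))
    return np.random.Generator(np.random.PCG64(ss))


# --- carriers ----------------------------------------------------------

def make_carrier(
    duration: float,
    fs: float,
    band: tuple[float, float] = (20.0, 150.0),
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Zero-mean, unit-RMS band-limited Gaussian carrier.

    White noise shaped by a 4th-order Butterworth band-pass; the power
    spectrum is unimodal with its bulk inside ``band``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(
            f"carrier band {band} must lie strictly inside (0, {fs / 2}) Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    # generate with padding so filter transients never touch the output
    pad = int(round(0.5 * fs))
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)[pad : pad + n]
    shaped = shaped / np.sqrt(np.mean(shaped**2))
    return Recording(samples=shaped, fs=fs)


def _segment_normalize(x: np.ndarray, bounds: Sequence[int]) -> np.ndarray:
    """Rescale each [bounds[i], bounds[i+1]) slice of x to unit RMS."""
    out = x.copy()
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = out[a:b]
        rms = np.sqrt(np.mean(seg**2))
        if rms > 0:
            out[a:b] = seg / rms
    return out


def _ramped_levels(levels: np.ndarray, bounds: Sequence[int], fs: float,
                   ramp_s: float = 0.1) -> np.ndarray:
    """Piecewise-constant level profile with linear ramps centered on the
    interior boundaries (moving-average smoothing of the step function)."""
    n = bounds[-1]
    prof = np.empty(n)
    for lev, a, b in zip(levels, bounds[:-1], bounds[1:]):
        prof[a:b] = lev
    w = max(int(round(ramp_s * fs)), 1)
    padded = np.concatenate([np.full(w, prof[0]), prof, np.full(w, prof[-1])])
    kernel = np.ones(w) / w
    smoothed = np.convolve(padded, kernel, mode="same")[w : w + n]
    return smoothed


# --- trials ------------------------------------------------------------

def mvic_amplitude(participant_idx: int, muscle_idx: int, config: SynthConfig) -> float:
    """Participant-muscle MVIC plateau amplitude (µV), log-normal across
    participants with the configured coefficient of variation."""
    cv = config.between_subject_cv
    sigma = np.sqrt(np.log1p(cv**2))
    rng = _rng(config.seed, "amplitude", participant_idx, muscle_idx)
    return float(config.mvic_base_uv * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def make_mvic_trial(
    participant: str, muscle: str, attempt: int, config: SynthConfig
) -> tuple[Recording, float]:
    """One 5-s MVIC attempt: carrier under a plateau envelope (0.5-s edge
    ramps, >=3-s flat middle), scaled so the central-2-s RMS equals the
    participant-muscle amplitude. Returns (recording, plateau RMS in µV)."""
    if not 1 <= attempt <= config.mvic_attempts:
        raise ValueError(f"attempt must be in 1..{config.mvic_attempts}")
    p = config.participants.index(participant)
    m = config.muscles.index(muscle)
    amp = mvic_amplitude(p, m, config)
    fs = config.fs
    rng = _rng(config.seed, "mvic", p, m, attempt)
    carrier = make_carrier(config.mvic_duration, fs, config.carrier_band, rng)
    n = carrier.samples.size
    ramp = int(round(0.5 * fs))
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp :] = np.linspace(0.0, 1.0, ramp, endpoint=False)[::-1]
    x = carrier.samples * env
    if amp > 0:
        c0 = int(round((config.mvic_duration / 2 - 1.0) * fs))
        c1 = int(round((config.mvic_duration / 2 + 1.0) * fs))
        central_rms = np.sqrt(np.mean(x[c0:c1] ** 2))
        x = x * (amp / central_rms)
    else:
        x = np.zeros(n)
    rec = Recording(
        samples=x, fs=fs, participant=participant, muscle=muscle,
        trial_kind="mvic", attempt=attempt,
    )
    return rec, amp


def sample_activation_matrix(config: SynthConfig) -> pd.DataFrame:
    """Participant-level true activation levels (nRMS fraction).

    One row per (participant, muscle, exercise, phase): the mean from the
    activation table plus an independent N(0, within_cell_sd) participant
    deviation, floored just above zero. This is the statistical layer the
    waveform synthesis realizes exactly, so cohort-level effect sizes are
    governed by these draws.
    """
    rows = []
    for p, participant in enumerate(config.participants):
        for m, muscle in enumerate(config.muscles):
            rng = _rng(config.seed, "cells", p, m)
            for exercise in config.exercises:
                for phase in PHASES:
                    mean = config.activation(muscle, exercise, phase)
                    val = mean + rng.normal(0.0, config.within_cell_sd)
                    rows.append(
                        {
                            "participant": participant,
                            "muscle": muscle,
                            "exercise": exercise,
                            "phase": phase,
                            "true_nrms": max(val, 1e-4),
                        }
                    )
    return pd.DataFrame(rows)


def _event_table(config: SynthConfig) -> EventTable:
    asc, iso, desc = config.phase_durations
    rows = []
    t = 0.0
    for rep in range(1, config.n_reps + 1):
        for phase, dur in zip(PHASES, (asc, iso, desc)):
            rows.append({"onset": t, "duration": dur, "phase": phase, "rep": rep})
            t += dur
    ev = pd.DataFrame(rows)
    q = config.event_quantization
    if q:
        bounds = np.concatenate([ev["onset"].to_numpy(), [t]])
        qb = np.round(bounds / q) * q
        ev["onset"] = qb[:-1]
        ev["duration"] = np.diff(qb)
    return EventTable(ev)


def make_exercise_trial(
    participant: str,
    muscle: str,
    exercise: str,
    config: SynthConfig,
    activations: Optional[pd.DataFrame] = None,
) -> tuple[Recording, EventTable, dict[str, float]]:
    """One six-repetition exercise set.

    The carrier is segment-normalized per (repetition, phase) and modulated
    so each phase's realized RMS equals MVIC_amplitude x the participant's
    true activation for that cell; 100-ms linear ramps join phase levels.
    Returns (recording, events, true nRMS fraction per analyzed phase).
    """
    if exercise not in config.exercises:
        raise ValueError(f"unknown exercise {exercise!r}")
    p = config.participants.index(participant)
    m = config.muscles.index(muscle)
    e = config.exercises.index(exercise)
    amp = mvic_amplitude(p, m, config)
    if activations is None:
        activations = sample_activation_matrix(config)
    sel = activations[
        (activations["participant"] == participant)
        & (activations["muscle"] == muscle)
        & (activations["exercise"] == exercise)
    ].set_index("phase")["true_nrms"]
    for phase in PHASES:
        if phase not in sel.index:
            raise ValueError(
                f"no activation level for ({muscle!r}, {exercise!r}, {phase!r})"
            )

    events = _event_table(config)
    fs = config.fs
    total = events.end
    rng = _rng(config.seed, "exercise", p, m, e)
    carrier = make_carrier(total, fs, config.carrier_band, rng)

    bounds = [int(round(o * fs)) for o in events.events["onset"]]
    bounds.append(carrier.samples.size)
    levels = np.array([sel[ph] for ph in events.events["phase"]]) * amp
    normalized = _segment_normalize(carrier.samples, bounds)
    profile = _ramped_levels(levels, bounds, fs)
    x = normalized * profile
    rec = Recording(
        samples=x, fs=fs, participant=participant, muscle=muscle,
        trial_kind="exercise", exercise=exercise,
    )
    truth = {ph: float(sel[ph]) for ph in ANALYZED_PHASES}
    return rec, events, truth


def inject_artifact(
    rec: Recording, spec: ArtifactSpec, seed: int | np.random.Generator = 0
) -> Recording:
    """Superimpose one artifact on a recording.

    powerline: sinusoid at ``spec.frequency`` with RMS = amplitude x trace
    RMS. motion: band-limited (<10 Hz) drift at the same relative RMS.
    innervation_zone: the carrier is attenuated to 40% and narrow-band
    content is piled onto the low edge of the physiological band, which
    shifts the spectral mode to the band edge.
    """
    if spec.amplitude == 0:
        return rec
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rec.samples
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        rms = 1.0
    n = x.size
    if spec.kind == "powerline":
        t = np.arange(n) / rec.fs
        phase = rng.uniform(0, 2 * np.pi)
        art = np.sqrt(2.0) * spec.amplitude * rms * np.sin(2 * np.pi * spec.frequency * t + phase)
        return rec.with_samples(x + art)
    if spec.kind == "motion":
        pad = int(round(0.5 * rec.fs))
        white = rng.standard_normal(n + 2 * pad)
        sos = sps.butter(4, 8.0, btype="lowpass", fs=rec.fs, output="sos")
        drift = sps.sosfiltfilt(sos, white)[pad : pad + n]
        drift = drift / np.sqrt(np.mean(drift**2)) * spec.amplitude * rms
        return rec.with_samples(x + drift)
    # innervation_zone
    pad = int(round(0.5 * rec.fs))
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, [17.0, 23.0], btype="bandpass", fs=rec.fs, output="sos")
    edge = sps.sosfiltfilt(sos, white)[pad : pad + n]
    edge = edge / np.sqrt(np.mean(edge**2)) * spec.amplitude * rms
    return rec.with_samples(0.4 * x + edge)


def make_cohort(config: SynthConfig = SynthConfig()) -> Dataset:
    """Simulate the full study.

    Returns every MVIC and exercise recording, per-trial event tables, a
    manifest, the ground-truth nRMS table (participant x muscle x exercise
    x analyzed phase) and the true MVIC amplitudes.
    """
    activations = sample_activation_matrix(config)
    recordings: list[Recording] = []
    events: dict[str, EventTable] = {}
    manifest_rows = []
    mvic_rows = []
    for p, participant in enumerate(config.participants):
        for m, muscle in enumerate(config.muscles):
            amp = mvic_amplitude(p, m, config)
            mvic_rows.append(
                {"participant": participant, "muscle": muscle, "true_amplitude_uv": amp}
            )
            for attempt in range(1, config.mvic_attempts + 1):
                rec, _ = make_mvic_trial(participant, muscle, attempt, config)
                rec = _maybe_inject(rec, config)
                recordings.append(rec)
                manifest_rows.append(_manifest_row(rec))
            for exercise in config.exercises:
                rec, ev, _ = make_exercise_trial(
                    participant, muscle, exercise, config, activations
                )
                rec = _maybe_inject(rec, config)
                recordings.append(rec)
                events[rec.label()] = ev
                manifest_rows.append(_manifest_row(rec))

    truth = activations[activations["phase"].isin(ANALYZED_PHASES)].copy()
    truth["true_nrms_percent"] = 100.0 * truth.pop("true_nrms")
    manifest = pd.DataFrame(manifest_rows)
    return Dataset(
        recordings=recordings,
        events=events,
        manifest=manifest,
        ground_truth=truth.reset_index(drop=True),
        mvic_truth=pd.DataFrame(mvic_rows),
        config=config,
    )


def _manifest_row(rec: Recording) -> dict:
    return {
        "label": rec.label(),
        "participant": rec.participant,
        "muscle": rec.muscle,
        "trial_kind": rec.trial_kind,
        "exercise": rec.exercise if rec.exercise else "",
        "attempt": rec.attempt if rec.attempt else "",
    }


def _maybe_inject(rec: Recording, config: SynthConfig) -> Recording:
    for i, spec in enumerate(config.artifact_specs):
        if spec.target in rec.label():
            rng = _rng(config.seed, "artifact", i, hash(rec.label()) % (2**31))
            rec = inject_artifact(rec, spec, rng)
    return rec
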