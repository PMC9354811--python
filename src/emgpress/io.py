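"""Reading and writing the on-disk dataset layout.

Signals travel as long-format CSV (columns ``time_s``, ``value_uV``); EDF
files are read through ``mne`` when it is installed (there is no EDF
writer in this package's dependency set, so CSV is the round-trip format).
Events are TSV with columns ``onset``, ``duration``, ``trial_type``
('phase:rep'); the manifest maps files to their trial identity.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import Dataset, EventTable, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_manifest",
    "write_dataset",
    "load_dataset",
]


def write_recording(rec: Recording, path: str | Path, precision: int = 6) -> None:
    """Write a recording as long CSV (time_s, value_uV) at fixed precision."""
    path = Path(path)
    data = np.column_stack([rec.times, rec.samples])
    header = "time_s,value_uV"
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt=f"%.{precision}f")


def read_recording(
    path: str | Path,
    participant: str = "",
    muscle: str = "",
    trial_kind: str = "exercise",
    exercise: Optional[str] = None,
    attempt: Optional[int] = None,
    expected_fs: Optional[float] = None,
) -> Recording:
    """Read a signal file (``.csv`` long format, or ``.edf`` via mne)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        frame = pd.read_csv(path)
        for col in ("time_s", "value_uV"):
            if col not in frame.columns:
                raise ValueError(f"{path.name}: missing required column {col!r}")
        t = frame["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError(f"{path.name}: need at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path.name}: time axis is not strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-4):
            raise ValueError(f"{path.name}: time axis is not uniformly sampled")
        fs = 1.0 / dt[0]
        samples = frame["value_uV"].to_numpy(dtype=float)
    elif suffix == ".edf":
        try:
            import mne
        except ImportError:
            raise ImportError(
                "reading EDF requires the optional 'mne' dependency "
                "(pip install emgpress[edf])"
            ) from None
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        if muscle and muscle in raw.ch_names:
            data = raw.get_data(picks=[muscle])[0]
        else:
            data = raw.get_data()[0]
            if not muscle and raw.ch_names:
                muscle = raw.ch_names[0]
        samples = data * 1e6  # mne holds volts
    else:
        raise ValueError(f"unknown signal format {suffix!r} (expected .csv or .edf)")
    if expected_fs is not None and not np.isclose(fs, expected_fs, rtol=1e-3):
        logger.warning(
            "%s: sampling rate %.1f Hz differs from configured %.1f Hz",
            path.name, fs, expected_fs,
        )
    fs = round(fs, 6)
    return Recording(
        samples=samples, fs=fs, participant=participant, muscle=muscle,
        trial_kind=trial_kind, exercise=exercise, attempt=attempt,
    )


def write_events(events: EventTable, path: str | Path, precision: int = 6) -> None:
    frame = events.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}f")


def read_events(path: str | Path) -> EventTable:
    frame = pd.read_csv(path, sep="\t")
    return EventTable.from_frame(frame)


_MANIFEST_COLUMNS = [
    "path", "events_path", "participant", "muscle", "trial_kind", "exercise", "attempt",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial manifest CSV.

    Required columns: path, participant, muscle, trial_kind, and exercise /
    attempt / events_path as applicable. Paths are resolved relative to the
    manifest's directory and must exist.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"path", "participant", "muscle", "trial_kind"} - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    resolved = []
    for _, row in frame.iterrows():
        p = base / row["path"]
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
        resolved.append(str(p))
    frame["path"] = resolved
    if "events_path" in frame.columns:
        frame["events_path"] = [
            str(base / p) if p else "" for p in frame["events_path"]
        ]
        for p in frame["events_path"]:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing events file: {p}")
    key = frame[["participant", "muscle", "trial_kind"]].astype(str).agg("|".join, axis=1)
    key = key + "|" + frame.get("exercise", "").astype(str) + "|" + frame.get("attempt", "").astype(str)
    if key.duplicated().any():
        dupes = frame.loc[key.duplicated(), "path"].tolist()
        raise ValueError(f"manifest contains duplicate trial identities: {dupes}")
    return frame


def write_dataset(dataset: Dataset, outdir: str | Path, precision: int = 6) -> Path:
    """Write a generated cohort to the standard layout.

    ``<out>/signals/*.csv``, ``<out>/events/*.tsv``, ``<out>/manifest.csv``,
    ``<out>/ground_truth.csv`` and ``<out>/config.yaml``.
    """
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    (outdir / "events").mkdir(exist_ok=True)
    manifest_rows = []
    for rec in dataset.recordings:
        label = rec.label()
        sig_rel = f"signals/{label}.csv"
        write_recording(rec, outdir / sig_rel, precision=precision)
        ev_rel = ""
        if label in dataset.events:
            ev_rel = f"events/{label}.tsv"
            write_events(dataset.events[label], outdir / ev_rel, precision=precision)
        manifest_rows.append(
            {
                "path": sig_rel,
                "events_path": ev_rel,
                "participant": rec.participant,
                "muscle": rec.muscle,
                "trial_kind": rec.trial_kind,
                "exercise": rec.exercise or "",
                "attempt": rec.attempt if rec.attempt is not None else "",
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    dataset.ground_truth.to_csv(
        outdir / "ground_truth.csv", index=False, float_format=f"%.{precision}f"
    )
    dataset.mvic_truth.to_csv(
        outdir / "mvic_truth.csv", index=False, float_format=f"%.{precision}f"
    )
    if dataset.config is not None:
        cfg = dataclasses.asdict(dataset.config)
        cfg["activation_table"] = {
            "|".join(k): float(v) for k, v in cfg["activation_table"].items()
        }
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return outdir


def load_dataset(outdir: str | Path) -> Dataset:
    """Re-read a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    manifest = read_manifest(outdir / "manifest.csv")
    recordings, events = [], {}
    for _, row in manifest.iterrows():
        rec = read_recording(
            row["path"],
            participant=row["participant"],
            muscle=row["muscle"],
            trial_kind=row["trial_kind"],
            exercise=row["exercise"] or None,
            attempt=int(row["attempt"]) if row["attempt"] else None,
        )
        recordings.append(rec)
        if row.get("events_path"):
            events[rec.label()] = read_events(row["events_path"])
    gt_path = outdir / "ground_truth.csv"
    ground_truth = pd.read_csv(gt_path) if gt_path.exists() else pd.DataFrame()
    mv_path = outdir / "mvic_truth.csv"
    mvic_truth = pd.read_csv(mv_path) if mv_path.exists() else pd.DataFrame()
    return Dataset(
        recordings=recordings,
        events=events,
        manifest=manifest,
        ground_truth=ground_truth,
        mvic_truth=mvic_truth,
        config=None,
    )
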