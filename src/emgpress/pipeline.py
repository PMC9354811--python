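"""End-to-end orchestration: process -> qc -> stats, with provenance.

`run_pipeline` ties the stages together on an on-disk dataset and writes
activations.csv, qc.json, anova.csv, pairwise.csv, shapiro.csv, run.log
and a copy of the configuration into the output directory.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import io as eio
from .config import PipelineConfig
from .datatypes import Dataset
from .qc import qc_trial
from .signal import build_activation_table
from .stats import analyze_activations

logger = logging.getLogger(__name__)

__all__ = ["load_manifest_dataset", "qc_dataset", "run_pipeline"]


def _package_version() -> str:
    try:
        return version("emgpress")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def load_manifest_dataset(manifest_path: str | Path) -> Dataset:
    """Build an in-memory dataset from a trial manifest."""
    manifest = eio.read_manifest(manifest_path)
    recordings, events = [], {}
    for _, row in manifest.iterrows():
        rec = eio.read_recording(
            row["path"],
            participant=row["participant"],
            muscle=row["muscle"],
            trial_kind=row["trial_kind"],
            exercise=(row.get("exercise") or None),
            attempt=int(row["attempt"]) if row.get("attempt") else None,
        )
        recordings.append(rec)
        if row.get("events_path"):
            events[rec.label()] = eio.read_events(row["events_path"])
    return Dataset(
        recordings=recordings, events=events, manifest=manifest,
        ground_truth=pd.DataFrame(), mvic_truth=pd.DataFrame(),
    )


def qc_dataset(dataset: Dataset, config: PipelineConfig) -> list[dict]:
    """Run the placement check on every exercise trial (raw traces)."""
    reports = []
    for rec in dataset.recordings:
        if rec.trial_kind != "exercise":
            continue
        for report in qc_trial(rec, dataset.events.get(rec.label()), config.qc):
            reports.append(report.to_dict())
    return reports


def run_pipeline(
    manifest_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Execute process -> qc -> stats on a manifest and write all outputs.

    Deterministic: identical inputs produce byte-identical CSV outputs.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("emgpress")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("emgpress %s", _package_version())
        logger.info("manifest: %s", manifest_path)
        try:
            dataset = load_manifest_dataset(manifest_path)
        except Exception as exc:
            logger.error("stage=load: %s", exc)
            raise RuntimeError(f"stage=load: {exc}") from exc

        try:
            qc_reports = qc_dataset(dataset, cfg)
            (outdir / "qc.json").write_text(json.dumps(qc_reports, indent=1))
            n_fail = sum(not r["pass"] for r in qc_reports)
            logger.info("qc: %d segment reports, %d failing", len(qc_reports), n_fail)
        except Exception as exc:
            logger.error("stage=qc: %s", exc)
            raise RuntimeError(f"stage=qc: {exc}") from exc

        try:
            activations = build_activation_table(dataset, cfg)
            activations.to_csv(
                outdir / "activations.csv", index=False, float_format="%.6f"
            )
            logger.info("activations: %d records", len(activations))
        except Exception as exc:
            logger.error("stage=process: %s", exc)
            raise RuntimeError(f"stage=process: {exc}") from exc

        try:
            anova, pairwise, shapiro = analyze_activations(
                activations, family_mode=cfg.family_mode
            )
            anova.to_csv(outdir / "anova.csv", index=False, float_format="%.6f")
            pairwise.to_csv(outdir / "pairwise.csv", index=False, float_format="%.6f")
            shapiro.to_csv(outdir / "shapiro.csv", index=False, float_format="%.6f")
            logger.info(
                "stats: %d ANOVA rows, %d pairwise contrasts", len(anova), len(pairwise)
            )
        except Exception as exc:
            logger.error("stage=stats: %s", exc)
            raise RuntimeError(f"stage=stats: {exc}") from exc

        cfg.save(outdir / "config.yaml")
    finally:
        handler.close()
        root.removeHandler(handler)
    return outdir
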