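"""File formats, configuration, and end-to-end pipeline orchestration.

Tables are RFC-4180 CSV (UTF-8), reports and manifests JSON, configuration
YAML or JSON, event images multi-page 16-bit TIFF (one page per channel:
brightfield, CD42b, CD62P).  ``run_pipeline`` executes
simulate → gate/train/classify → score → qc → stats, writing every stage's
output before the next begins and finishing with a manifest of config hash,
seed and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import cohortstats, qc as qc_mod
from .classifier import ClassifierConfig, ClassifierModel, classify, train
from .gating import GatingConfig, focus_score, gate_events
from .synthcyto import (CohortConfig, ConfigurationError, EventImage,
                        RenderParams, render_event, render_event_for_row,
                        simulate_cohort, substream)
from .wpa import summarize_cohort

logger = logging.getLogger("wpaflow")

__all__ = ["EVENT_TABLE_REQUIRED", "RunConfig", "PipelineError",
           "read_event_table", "write_event_table",
           "read_event_image", "write_event_image", "run_pipeline"]

EVENT_TABLE_REQUIRED = [
    "donor_id", "age", "sex", "condition", "replicate", "acquisition_date",
    "event_id", "cd42b_mfi", "cd62p_mfi", "focus",
]
_VALID_CONDITIONS = {"baseline", "ADP"}
_VALID_SEX = {"M", "F"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# --------------------------------------------------------------------------
# event tables

def read_event_table(path: str | Path, strict: bool = False
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Read a per-event CSV table, validating the schema row by row.

    Returns the typed table plus a list of row-level problems ("line N:
    ...").  Malformed rows are dropped (or raised with ``strict=True``);
    unknown extra columns are preserved.  A missing required column is a
    schema error regardless of strictness.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} is missing required column(s): {missing}")

    problems: list[str] = []
    bad = np.zeros(len(df), dtype=bool)

    def _flag(mask: np.ndarray, why: str) -> None:
        for i in np.flatnonzero(mask & ~bad):
            problems.append(f"line {i + 2}: {why}")  # +2: header and 1-based lines
        bad[mask] = True

    _flag(~df["condition"].isin(_VALID_CONDITIONS).to_numpy(), "invalid condition")
    _flag(~df["sex"].isin(_VALID_SEX).to_numpy(), "invalid sex")
    for col in ("cd42b_mfi", "cd62p_mfi", "focus", "age"):
        _flag(pd.to_numeric(df[col], errors="coerce").isna().to_numpy(), f"unparseable {col}")
    dates = pd.to_datetime(df["acquisition_date"], errors="coerce", format="ISO8601")
    _flag(dates.isna().to_numpy(), "unparseable acquisition_date")

    if strict and problems:
        raise ValueError("; ".join(problems))
    out = df[~bad].copy()
    dupes = out.duplicated(subset=["donor_id", "condition", "replicate", "event_id"])
    if dupes.any():
        raise ValueError(f"{int(dupes.sum())} duplicate (donor_id, condition, replicate, "
                         "event_id) keys in event table")
    return out, problems


def write_event_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# event images

def write_event_image(image: EventImage, path: str | Path) -> None:
    """One event as a multi-page 16-bit TIFF (brightfield, CD42b, CD62P)."""
    stack = np.stack([image.brightfield, image.cd42b, image.cd62p])
    stack = np.clip(stack, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"pixel_size_um": image.pixel_size_um})


def read_event_image(path: str | Path, pixel_size_um: float = 0.33) -> EventImage:
    stack = tifffile.imread(path).astype(float)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page TIFF (brightfield, cd42b, cd62p)")
    return EventImage(brightfield=stack[0], cd42b=stack[1], cd62p=stack[2],
                      pixel_size_um=pixel_size_um)


# --------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gating: GatingConfig = field(default_factory=lambda: GatingConfig(cd42b_threshold=300.0))
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    qc: qc_mod.QCConfig = field(default_factory=qc_mod.QCConfig)
    render: RenderParams = field(default_factory=RenderParams)
    n_training_images: int = 2000
    outdir: str = "wpaflow_out"
    log_level: str = "info"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        errors = []
        parts = {}
        for key, typ in (("cohort", CohortConfig), ("gating", GatingConfig),
                         ("classifier", ClassifierConfig), ("qc", qc_mod.QCConfig),
                         ("render", RenderParams)):
            section = data.pop(key, {}) or {}
            fields = {f.name for f in dataclasses.fields(typ)}
            unknown = set(section) - fields
            if unknown:
                errors.append(f"{key}: unknown field(s) {sorted(unknown)}")
                section = {k: v for k, v in section.items() if k in fields}
            for name in ("baseline_class_means", "adp_multipliers", "multiplet_sizes",
                         "conv_filters", "platelet_diameter_um", "erythrocyte_diameter_um"):
                if name in section and isinstance(section[name], list):
                    section[name] = tuple(section[name])
            try:
                parts[key] = typ(**section)
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
        top_fields = {f.name for f in dataclasses.fields(cls)} - set(parts)
        unknown_top = set(data) - top_fields
        if unknown_top:
            errors.append(f"unknown top-level field(s) {sorted(unknown_top)}")
        if errors:
            raise ConfigurationError("; ".join(errors))
        kwargs = {k: v for k, v in data.items() if k in top_fields}
        return cls(**parts, **kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# --------------------------------------------------------------------------
# orchestration

def _train_stage(config: RunConfig) -> ClassifierModel:
    from .synthcyto import render_training_set

    rng = substream(config.seed, 101)
    images, labels = render_training_set(config.n_training_images, config.render,
                                         config.cohort, rng)
    return train(config.classifier, images, labels,
                 rng=np.random.default_rng(config.classifier.seed))


def _classify_stage(events: pd.DataFrame, model: ClassifierModel,
                    config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Render, focus-score, gate and classify each measurement in turn."""
    out_rows = []
    totals = {"n_input": 0, "n_outside_cd42b_gate": 0, "n_out_of_focus": 0,
              "n_coincidence_excluded": 0, "n_retained": 0}
    group_cols = ["donor_id", "condition", "replicate"]
    for mi, (_, grp) in enumerate(events.groupby(group_cols, sort=True)):
        rng = substream(config.seed, 201, mi)
        images = [render_event_for_row(row, config.render, rng)
                  for _, row in grp.iterrows()]
        grp = grp.copy()
        grp["focus"] = [focus_score(img) for img in images]
        retained, report = gate_events(grp, config.gating)
        for key in totals:
            totals[key] += getattr(report, key)
        kept = [images[i] for i in np.flatnonzero(grp.index.isin(retained.index))]
        labels, probs = classify(model, kept)
        retained["class"] = labels
        for j in range(4):
            retained[f"p{j + 1}"] = probs[:, j]
        out_rows.append(retained)
    classified = pd.concat(out_rows, ignore_index=True)
    totals["fraction_excluded"] = (1.0 - totals["n_retained"] / totals["n_input"]
                                   if totals["n_input"] else 0.0)
    return classified, totals


def _stats_stage(summaries: pd.DataFrame) -> dict:
    kept = summaries[summaries["qc_pass"]] if "qc_pass" in summaries.columns else summaries
    response = cohortstats.condition_response(kept)
    per_donor = (kept[kept["condition"] == "baseline"]
                 .groupby("donor_id", sort=True)
                 .agg(wpa=("wpa", "mean"), age=("age", "first"), sex=("sex", "first"))
                 .reset_index())
    results = {"condition_response": {
        "means": response["means"],
        "fold_change": response["fold_change"],
        "paired_wpa": response["paired_wpa"].as_dict() if response["paired_wpa"] else None,
        "paired_cd62p": response["paired_cd62p"].as_dict() if response["paired_cd62p"] else None,
    }}
    regressions = {}
    for stratum in ("all", "male", "female"):
        sub = per_donor
        if stratum == "male":
            sub = per_donor[per_donor["sex"] == "M"]
        elif stratum == "female":
            sub = per_donor[per_donor["sex"] == "F"]
        if len(sub) >= 3 and np.ptp(sub["age"].to_numpy()) > 0:
            regressions[stratum] = cohortstats.age_regression(
                sub["age"], sub["wpa"], stratum=stratum).as_dict()
    results["age_regression_baseline_wpa"] = regressions
    males = per_donor.loc[per_donor["sex"] == "M", "wpa"]
    females = per_donor.loc[per_donor["sex"] == "F", "wpa"]
    if len(males) >= 3 and len(females) >= 3:
        results["sex_contrast_baseline_wpa"] = cohortstats.contrast(
            males, females, labels=("male", "female")).as_dict()
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-cohort pipeline and write all artifacts.

    Stages: simulate → train → classify (render/gate/classify per
    measurement) → score → qc → stats → manifest.  Any failure raises
    :class:`PipelineError` naming the stage, with earlier outputs intact on
    disk.  Returns a result bundle with the key tables and reports.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    bundle: dict = {}
    stage = "setup"
    t_start = time.time()
    try:
        stage = "simulate"
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        events, truth, donors = simulate_cohort(cohort_cfg)
        write_event_table(events, outdir / "events.csv")
        write_event_table(truth, outdir / "ground_truth.csv")
        logger.info("simulate: %d events, %d donors (%.1fs)",
                    len(events), len(donors), time.time() - t_start)

        stage = "train"
        t0 = time.time()
        model = _train_stage(config)
        model.save(outdir / "model.npz")
        logger.info("train: holdout accuracy %.3f (%.1fs)",
                    model.holdout_accuracy, time.time() - t0)

        stage = "classify"
        t0 = time.time()
        classified, gating_totals = _classify_stage(events, model, config)
        write_event_table(classified, outdir / "events_classified.csv")
        (outdir / "gating_report.json").write_text(json.dumps(gating_totals, indent=2))
        logger.info("classify: %d retained of %d (%.1fs)", gating_totals["n_retained"],
                    gating_totals["n_input"], time.time() - t0)

        stage = "score"
        summaries = summarize_cohort(classified)
        truth_key = truth.set_index(["donor_id", "condition", "replicate"])
        summaries["acquisition_date"] = [
            truth_key.loc[(r.donor_id, r.condition, r.replicate), "acquisition_date"]
            for r in summaries.itertuples()]
        write_event_table(summaries, outdir / "summaries.csv")

        stage = "qc"
        filtered, qc_report = qc_mod.apply_qc(summaries, config.qc)
        write_event_table(filtered, outdir / "summaries_qc.csv")
        (outdir / "qc_report.json").write_text(json.dumps(qc_report.as_dict(), indent=2))

        stage = "stats"
        stats_results = _stats_stage(filtered)
        (outdir / "stats.json").write_text(json.dumps(stats_results, indent=2, default=str))

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "files": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                      if p.name != "manifest.json" and p.is_file()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc

    bundle.update(events=events, truth=truth, model=model, classified=classified,
                  summaries=filtered, gating=gating_totals,
                  qc_report=qc_report, stats=stats_results, manifest=manifest)
    logger.info("pipeline complete in %.1fs", time.time() - t_start)
    return bundle
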