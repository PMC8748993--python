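"""End-to-end orchestration: structures -> bonds -> features -> model.

A :class:`RunConfig` (usually loaded from a YAML file) fixes every knob of
a run -- inputs, hydrogen handling, boosting profile, thresholds, seed --
and :func:`run_train` / :func:`run_predict` execute the stages, writing
TSV data outputs plus a JSON :class:`RunReport` with per-stage counts and
provenance, so that a run is reproducible and diffable from its artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import hbond, model as model_mod, structure_io
from .features import FEATURE_COLUMNS, LabeledDataset, build_dataset, extract_features
from .model import (
    DEFAULT_THRESHOLD,
    THRESHOLD_GRID,
    BoostingParams,
    SHBEnsembleModel,
    load_model,
)

logger = logging.getLogger(__name__)


class UsageError(ValueError):
    """Bad configuration or empty inputs (exit code 1 territory)."""


class DataError(ValueError):
    """Inputs parsed but unusable (exit code 2 territory)."""


@dataclass
class RunConfig:
    structures: list[str] = field(default_factory=list)
    feature_tables: list[str] = field(default_factory=list)
    model_file: Optional[str] = None
    out_dir: str = "mapshb_out"
    hydrogen_mode: str = "require"          # or "place"
    profile: str = "fast"                   # or "paper"
    n_members: int = 10
    threshold: float = DEFAULT_THRESHOLD
    threshold_grid: tuple[float, ...] = THRESHOLD_GRID
    seed: int = 0
    max_resolution: float = 1.1
    max_r_factor: float = 0.20
    max_r_gap: float = 0.07
    permissive_quality: bool = False
    apply_quality_filter: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.hydrogen_mode not in ("require", "place"):
            raise UsageError("hydrogen_mode must be 'require' or 'place'")
        if self.profile not in ("fast", "paper"):
            raise UsageError("profile must be 'fast' or 'paper'")
        if not 0.0 <= self.threshold <= 1.0:
            raise UsageError("threshold must be in [0, 1]")

    def boosting_params(self) -> BoostingParams:
        if self.profile == "paper":
            return BoostingParams.paper_profile(seed=self.seed)
        return BoostingParams.fast_profile(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config key(s): {sorted(unknown)}")
        if "threshold_grid" in raw:
            raw["threshold_grid"] = tuple(raw["threshold_grid"])
        return cls(**raw)


@dataclass
class RunReport:
    stage_counts: dict = field(default_factory=dict)
    thresholds: list = field(default_factory=list)
    importance: list = field(default_factory=list)
    member_depths: list = field(default_factory=list)
    member_seeds: list = field(default_factory=list)
    seed: int = 0
    notes: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _load_structure(path: str, config: RunConfig) -> structure_io.ProteinStructure:
    s = structure_io.read_structure(path)
    if config.apply_quality_filter:
        report = structure_io.validate_quality(
            s.quality,
            max_resolution=config.max_resolution,
            max_r_factor=config.max_r_factor,
            max_r_gap=config.max_r_gap,
            permissive=config.permissive_quality,
        )
        if not report.passed:
            raise DataError(f"{path}: fails quality filters: {'; '.join(report.reasons)}")
    if config.hydrogen_mode == "place":
        s = structure_io.place_polar_hydrogens(s)
    return structure_io.assign_secondary_structure(s)


def run_train(config: RunConfig) -> tuple[Path, RunReport]:
    """Train the undersampling ensemble and persist model + report.

    Feature tables and/or structure files may be given; structures are
    detected and featurized first. Returns (model path, report).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    datasets: list[LabeledDataset] = []
    n_structures = 0
    for path in config.feature_tables:
        datasets.append(LabeledDataset.read_tsv(path))
    if config.structures:
        structures = [_load_structure(p, config) for p in config.structures]
        n_structures = len(structures)
        datasets.append(build_dataset(structures))
    if not datasets:
        raise UsageError("run_train needs feature_tables and/or structures")

    table = pd.concat([d.table for d in datasets], ignore_index=True)
    provenance = [p for d in datasets for p in d.provenance]
    dataset = LabeledDataset(table, provenance)
    n_shb, n_nhb = dataset.class_counts()
    if n_shb == 0 or n_nhb == 0:
        raise DataError(
            f"training table has a single class: {n_shb} SHB / {n_nhb} NHB"
        )
    report.stage_counts.update(
        structures_read=n_structures,
        rows_trained=len(dataset),
        n_shb=n_shb,
        n_nhb=n_nhb,
    )

    params = config.boosting_params()
    ensemble = model_mod.train_ensemble(dataset, params, n_members=config.n_members)
    model_path = out_dir / "model.json"
    ensemble.save(model_path)

    report.member_depths = ensemble.depths
    report.member_seeds = ensemble.member_seeds
    report.importance = model_mod.feature_importance(ensemble).to_dict(orient="records")
    report.write(out_dir / "train_report.json")
    return model_path, report


def run_predict(
    config: RunConfig, model: Optional[SHBEnsembleModel] = None
) -> tuple[pd.DataFrame, RunReport]:
    """Detect, featurize and score hydrogen bonds in the input structures.

    Per-structure failures are isolated and logged; the run fails only when
    every structure fails. Writes predictions.tsv and predict_report.json
    to the output directory and returns (predictions, report).
    """
    if not config.structures:
        raise UsageError("run_predict needs at least one structure file")
    if model is None:
        if not config.model_file:
            raise UsageError("run_predict needs a model file")
        model = load_model(config.model_file)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    frames: list[pd.DataFrame] = []
    n_read = n_failed = n_detected = 0
    for path in config.structures:
        try:
            s = _load_structure(path, config)
            records = hbond.detect_hydrogen_bonds(s)
            n_read += 1
            n_detected += len(records)
            if not records:
                continue
            base = hbond.records_to_table(records)
            feats = pd.DataFrame(
                [extract_features(r, s).as_row() for r in records]
            )
            probs = model.predict(feats)
            base["probability"] = [round(float(p), 3) for p in probs]
            base["predicted"] = model_mod.classify(probs, config.threshold)
            frames.append(pd.concat([base, feats], axis=1))
        except (structure_io.StructureError, ValueError) as exc:
            n_failed += 1
            logger.error("structure %s failed: %s", path, exc)
            report.notes.append(f"{path}: {exc}")
    if n_read == 0:
        raise DataError("all input structures failed")

    predictions = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=hbond.TABLE_COLUMNS + ["probability", "predicted"] + FEATURE_COLUMNS)
    )
    report.stage_counts.update(
        structures_read=n_read,
        structures_failed=n_failed,
        records_detected=n_detected,
        records_scored=len(predictions),
        predicted_shb=int((predictions.get("predicted") == "SHB").sum()) if len(predictions) else 0,
    )
    predictions.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
    report.write(out_dir / "predict_report.json")
    return predictions, report
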