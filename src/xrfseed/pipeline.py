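"""One-command orchestration of the full workflow.

``run_pipeline`` chains accession segmentation, numbering, pixel
classification, adherent splitting and trait extraction, and writes
``traits.csv``, ``layout.json``, ``seedlabels.tif`` and ``report.json`` to
the output directory. All randomness flows from one recorded seed, so a
given config reproduces its outputs byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from .accession import SegmentationParams, segment_accessions
from .classifier import evaluate_and_select, predict_seed_mask, split_dataset, train_models
from .containers import ELEMENTS, PixelSampleTable
from .errors import ConfigError
from .io import (
    load_element_stack,
    load_rgb,
    read_polylines,
    write_labels,
    write_traits_csv,
)
from .numbering import assign_roster, number_accessions
from .splitter import SplitParams, split_seeds
from .traits import assemble_records

logger = logging.getLogger(__name__)


class SegmentationConfig(BaseModel):
    close_radius: int = Field(3, ge=0)
    open_radius: int = Field(2, ge=0)
    fill_holes: bool = True

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(self.close_radius, self.open_radius, self.fill_holes)


class SplitConfig(BaseModel):
    split_footprint: int = Field(25, ge=1)
    under_factor: float = Field(0.75, gt=0, lt=1)
    over_factor: float = Field(1.25, gt=1)
    harris_k: float = 0.04
    harris_quantile: float = 0.99
    min_defect_area: int = Field(3, ge=1)
    max_iterations: int = Field(10, ge=1)

    def to_params(self) -> SplitParams:
        return SplitParams(
            self.split_footprint, self.under_factor, self.over_factor,
            self.harris_k, self.harris_quantile, self.min_defect_area,
            self.max_iterations,
        )


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (paths resolve against the config file)."""

    rgb: Path
    elements_dir: Path | None = None
    element_manifest: dict[str, str] | None = None
    pixel_table: Path | None = None
    splits: Path | None = None
    row_lines: Path | None = None
    roster: Path | None = None
    n_rows: int | None = Field(None, ge=1)
    pixel_size: float | None = Field(None, gt=0)
    rng_seed: int = 0
    segmentation: SegmentationConfig = SegmentationConfig()
    split: SplitConfig = SplitConfig()

    @field_validator("element_manifest")
    @classmethod
    def _known_elements(cls, v):
        if v:
            unknown = [el for el in v if el not in ELEMENTS]
            if unknown:
                raise ValueError(
                    f"unknown element(s) {unknown}; allowed: {list(ELEMENTS)}"
                )
        return v


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; every violation is enumerated."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        cfg = PipelineConfig.model_validate(data)
    except ValidationError as exc:
        lines = [f"  - {'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise ConfigError(
            f"{len(lines)} problem(s) in {path}:\n" + "\n".join(lines)
        ) from exc
    # resolve relative paths against the config file location
    base = path.parent
    for name in ("rgb", "elements_dir", "pixel_table", "splits", "row_lines", "roster"):
        value = getattr(cfg, name)
        if value is not None and not Path(value).is_absolute():
            setattr(cfg, name, base / value)
    missing = [str(getattr(cfg, n)) for n in ("rgb", "pixel_table")
               if getattr(cfg, n) is not None and not Path(getattr(cfg, n)).exists()]
    if missing:
        raise ConfigError("missing input file(s): " + ", ".join(missing))
    return cfg


def _load_roster(path: Path) -> dict[int, str]:
    roster: dict[int, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            roster[int(row["index"])] = row["accession_id"]
    return roster


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the workflow; returns the JSON-serialisable run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    caught: list[str] = []

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc[0] is not None:
                    logger.error("pipeline stage '%s' failed", name)
        return _T()

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with stage("load"):
            rgb = load_rgb(config.rgb)
            stack = None
            if config.element_manifest and config.elements_dir:
                stack = load_element_stack(
                    config.elements_dir, config.element_manifest, rgb
                )
            else:
                warnings.warn("no element manifest: writing morphology-only traits")
            split_lines = (read_polylines(config.splits, rgb.shape[:2])
                           if config.splits else [])
            row_lines = (read_polylines(config.row_lines, rgb.shape[:2])
                         if config.row_lines else None)

        with stage("segment_accessions"):
            acc_mask = segment_accessions(
                rgb, config.segmentation.to_params(), split_lines
            )

        with stage("number_accessions"):
            layout = number_accessions(acc_mask, n_rows=config.n_rows,
                                       row_lines=row_lines)
            if config.roster:
                layout = assign_roster(layout, _load_roster(config.roster))

        with stage("train_classifier"):
            if config.pixel_table is None:
                raise ConfigError("pixel_table (labeled training CSV) is required")
            import pandas as pd

            table = PixelSampleTable.from_frame(pd.read_csv(config.pixel_table))
            train, test = split_dataset(table, 0.8, config.rng_seed)
            models = train_models(train, config.rng_seed)
            report = evaluate_and_select(models, test, n_train=len(train),
                                         rng_seed=config.rng_seed)

        with stage("predict_seed_mask"):
            seed_mask = predict_seed_mask(models[report.selected_model], rgb,
                                          restrict_to=acc_mask)

        with stage("split_seeds"):
            seed_labels, unresolved = split_seeds(
                seed_mask, config.split.to_params(), return_info=True
            )

        with stage("extract_traits"):
            records = assemble_records(seed_labels, layout, stack,
                                       pixel_size=config.pixel_size)

        with stage("write_outputs"):
            write_traits_csv(records, out_dir / "traits.csv")
            write_labels(out_dir / "seedlabels.tif", seed_labels)
            (out_dir / "layout.json").write_text(
                json.dumps(layout.to_json_dict(), indent=2, sort_keys=True)
            )

        caught = [str(w.message) for w in wrec]

    run_report = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": json.loads(config.model_dump_json()),
        "n_accessions": len(layout),
        "n_seeds": len(records),
        "unresolved_labels": unresolved,
        "classifier": report.to_json_dict(),
        "timings_s": timings,
        "warnings": caught,
    }
    (out_dir / "report.json").write_text(
        json.dumps(run_report, indent=2, sort_keys=True)
    )
    return run_report
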