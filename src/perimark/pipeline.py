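"""End-to-end analysis pipeline.

Runs simulate (optional) -> screen -> fit single markers -> evolutionary
panel search -> evaluation/reporting from one :class:`RunConfig`, writing
every artifact into a run directory:

* ``manifest.json`` — the fully resolved configuration and library
  versions; every table below is re-derivable from it.
* ``abundance.csv`` / ``labels.csv`` / ``planted_truth.json`` — the cohort
  (written only when simulated).
* ``screening.csv`` — per-taxon Mann-Whitney results.
* ``single_markers.csv`` — cutoff classifiers for the significant taxa,
  ranked by rank score.
* ``combo_results.csv`` / ``combo_models.json`` — the evolved panel
  classifiers (held-out and whole-cohort metrics) and their serialized
  models.
* ``biomarker_counts.csv`` — how often each taxon appears across the
  evolved panels.
* ``performance_classes.csv`` — poor/reasonable/good/excellent counts per
  model family.

Reruns with the same configuration and seed are byte-identical: the run
seed overrides the synthetic-cohort and search seeds, and nothing
time-dependent is written outside the log file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import perimark

from .errors import PerimarkError, ValidationError
from .evolve import EvoConfig, SearchResult, evolve_combinations
from .io import (
    AbundanceTable,
    CohortLabels,
    read_abundance_csv,
    read_labels_csv,
    write_abundance_csv,
    write_labels_csv,
)
from .metrics import PerformanceReport, classify_performance, evaluate_scores, rank_models
from .screening import results_frame, screen_taxa
from .single_marker import fit_single_marker, marker_scores, predict_single_marker
from .synthetic import SyntheticSpec, generate_cohort, spec_from_dict, spec_to_dict

logger = logging.getLogger("perimark")


@dataclass
class RunConfig:
    """One pipeline run: either a pair of input CSVs or a synthetic spec."""

    table_csv: Optional[str] = None
    labels_csv: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    alpha: float = 0.05
    evo: EvoConfig = field(default_factory=EvoConfig)
    roc_interval: float = 5.0
    outdir: str = "perimark_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_csvs = self.table_csv is not None or self.labels_csv is not None
        if has_csvs and (self.table_csv is None or self.labels_csv is None):
            raise ValidationError("table_csv and labels_csv must be given together")
        if has_csvs and self.synthetic is not None:
            raise ValidationError(
                "provide either input CSVs or a synthetic spec, not both"
            )
        if not has_csvs and self.synthetic is None:
            raise ValidationError("provide input CSVs or a synthetic spec")
        if isinstance(self.synthetic, dict):
            self.synthetic = spec_from_dict(self.synthetic)
        if isinstance(self.evo, dict):
            self.evo = EvoConfig(**self.evo)
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = None if self.synthetic is None else spec_to_dict(self.synthetic)
        d["evo"] = dataclasses.asdict(self.evo)
        return d


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) document."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig(**doc)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: failed (%s)", name, exc)
                if isinstance(exc, PerimarkError) and not str(exc).startswith("stage"):
                    raise PerimarkError(f"stage {name}: {exc}") from exc
                return False
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _report_row(report: PerformanceReport) -> dict:
    return {
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
        "rank_score": report.rank_score,
        "performance_class": report.performance_class,
    }


def single_marker_table(
    table: AbundanceTable,
    labels: CohortLabels,
    taxa,
    roc_interval: float = 5.0,
) -> pd.DataFrame:
    """Fit and evaluate a cutoff classifier per taxon; ranked DataFrame."""
    rows, reports = [], []
    for taxon in taxa:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_single_marker(table, labels, taxon)
        report = evaluate_scores(
            marker_scores(model, table),
            predict_single_marker(model, table),
            labels,
            interval=roc_interval,
            model_id=str(taxon),
        )
        reports.append(report)
        rows.append(
            {
                "taxon_id": taxon,
                "direction": model.direction,
                "cutoff": model.cutoff,
                **_report_row(report),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        order = [r.model_id for r in rank_models(reports)]
        frame["taxon_id"] = frame["taxon_id"].astype(str)
        frame = frame.set_index("taxon_id").loc[order].reset_index()
        frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def combo_results_table(search: SearchResult) -> pd.DataFrame:
    """Evolved-panel results ranked by whole-cohort rank score."""
    full_reports = [r.full_report for r in search.models]
    by_id = {r.full_report.model_id: r for r in search.models}
    rows = []
    for rank, report in enumerate(rank_models(full_reports), start=1):
        run = by_id[report.model_id]
        rows.append(
            {
                "rank": rank,
                "run_index": run.run_index,
                "taxa": ";".join(map(str, run.model.taxa)),
                "n_taxa": run.model.n_taxa,
                "threshold": run.model.threshold,
                "test_sensitivity": run.test_report.sensitivity,
                "test_specificity": run.test_report.specificity,
                "test_auc": run.test_report.auc,
                **{f"full_{k}": v for k, v in _report_row(run.full_report).items()},
            }
        )
    return pd.DataFrame(rows)


def performance_class_table(
    single_frame: pd.DataFrame, search: SearchResult
) -> pd.DataFrame:
    """Counts of poor/reasonable/good/excellent models per family."""
    rows = []
    families = {
        "single_marker": list(single_frame.get("performance_class", [])),
        "combo_scoring": [
            classify_performance(r.full_report) for r in search.models
        ],
    }
    for family, classes in families.items():
        for cls in ("poor", "reasonable", "good", "excellent"):
            rows.append(
                {
                    "family": family,
                    "performance_class": cls,
                    "count": int(sum(c == cls for c in classes)),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> Path:
    manifest = {
        "config": config.to_dict(),
        "versions": {
            "perimark": perimark.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    with _stage("load"):
        if config.synthetic is not None:
            spec = dataclasses.replace(config.synthetic, seed=config.seed)
            table, labels = generate_cohort(spec)
            write_abundance_csv(table, outdir / "abundance.csv")
            write_labels_csv(labels, outdir / "labels.csv")
            spec.write_truth_json(outdir / "planted_truth.json")
        else:
            table = read_abundance_csv(config.table_csv)
            labels = read_labels_csv(config.labels_csv)
        labels.require_both_groups()

    with _stage("screen"):
        screening = screen_taxa(table, labels, alpha=config.alpha)
        frame = results_frame(screening)
        frame.to_csv(outdir / "screening.csv", index=False)
        significant = [r.taxon_id for r in screening if r.significant]
        logger.info("screening: %d/%d taxa significant", len(significant), len(screening))

    with _stage("fit-single"):
        singles = single_marker_table(
            table, labels, significant, roc_interval=config.roc_interval
        )
        singles.to_csv(outdir / "single_markers.csv", index=False)

    with _stage("evolve"):
        evo = dataclasses.replace(config.evo, seed=config.seed + 1)
        search = evolve_combinations(table, labels, evo)
        combos = combo_results_table(search)
        combos.to_csv(outdir / "combo_results.csv", index=False)
        models_doc = [
            json.loads(r.model.to_json()) for r in search.models
        ]
        with open(outdir / "combo_models.json", "w") as fh:
            json.dump(models_doc, fh, indent=2)
        counts = pd.DataFrame(
            sorted(search.biomarker_counts.items(), key=lambda kv: (-kv[1], str(kv[0]))),
            columns=["taxon_id", "n_models"],
        )
        counts.to_csv(outdir / "biomarker_counts.csv", index=False)

    with _stage("report"):
        classes = performance_class_table(singles, search)
        classes.to_csv(outdir / "performance_classes.csv", index=False)

    return outdir
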