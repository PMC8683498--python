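"""End-to-end workflows with configuration, logging and artifact output.

Every output table carries the run's configuration hash in a leading comment
line, so a result file can always be traced to the exact thresholds and seed
that produced it.  Identical config + seed reproduces an identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .ccf import DEFAULT_MIN_DEPTH, ccf_matrix
from .clonal_model import ClonalStructureModel, ClonalStructureResults
from .cohort import days_to_months, km_estimate, km_median
from .deconvolution import (
    DEFAULT_ABSENT_THRESHOLD,
    DEFAULT_CLONAL_THRESHOLD,
    DEFAULT_MERGE_TOL,
    DEFAULT_MIN_CLUSTER_SIZE,
)
from .errors import ClonedynError, InputError
from .io import read_mutation_tsv, read_purity_tsv, read_seg, read_survival_tsv
from .pharmacology import DoseResponseMatrix, zip_delta, zip_delta_3d
from .phylogeny import DEFAULT_SUM_RULE_TOL

logger = logging.getLogger("clonedyn")


class RunConfig(BaseModel):
    """Input paths, thresholds and seed for one pipeline run."""

    mutations: Optional[str] = None
    segments: Optional[str] = None
    purities: Optional[str] = None
    survival: Optional[str] = None
    plates: list[str] = Field(default_factory=list)
    plates_are_stack: bool = False

    min_depth: int = Field(DEFAULT_MIN_DEPTH, ge=1, le=1000)
    min_cluster_size: int = Field(DEFAULT_MIN_CLUSTER_SIZE, ge=1, le=1000)
    merge_tol: float = Field(DEFAULT_MERGE_TOL, gt=0.0, le=0.5)
    clonal_threshold: float = Field(DEFAULT_CLONAL_THRESHOLD, gt=0.5, le=1.0)
    absent_threshold: float = Field(DEFAULT_ABSENT_THRESHOLD, ge=0.0, lt=0.5)
    sum_rule_tol: float = Field(DEFAULT_SUM_RULE_TOL, gt=0.0, le=0.5)

    seed: int = 0
    outdir: str = "clonedyn_out"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded,
        so re-running the same analysis elsewhere yields identical files)."""
        payload = json.dumps(
            self.model_dump(exclude={"outdir"}), sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _setup_outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_run_log(config: RunConfig, out: Path, stage: str, extra: dict) -> None:
    log = {
        "tool": "clonedyn",
        "version": __version__,
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "min_depth", "min_cluster_size", "merge_tol",
                "clonal_threshold", "absent_threshold", "sum_rule_tol",
            )
        },
        **extra,
    }
    with open(out / f"run_log_{stage}.json", "w") as fh:
        json.dump(log, fh, indent=2)


def _stage(stage: str):
    """Decorator tagging errors with the failing pipeline stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ClonedynError as exc:
                raise type(exc)(f"[{stage}] {exc}") from exc

        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner

    return wrap


@_stage("clonal")
def run_clonal(config: RunConfig) -> ClonalStructureResults:
    """Mutations + segments + purities -> CCFs -> clusters -> tree ->
    compositions -> distances, all written to the output directory."""
    if not config.mutations or not config.purities:
        raise InputError("clonal stage needs mutation and purity tables")
    out = _setup_outdir(config)
    tag = f"clonedyn config_hash={config.config_hash()}"

    calls = read_mutation_tsv(config.mutations)
    purities = read_purity_tsv(config.purities)
    segments = read_seg(config.segments) if config.segments else None

    matrix = ccf_matrix(calls, purities, segments, min_depth=config.min_depth)
    model = ClonalStructureModel(
        matrix,
        min_cluster_size=config.min_cluster_size,
        merge_tol=config.merge_tol,
        clonal_threshold=config.clonal_threshold,
        absent_threshold=config.absent_threshold,
        sum_rule_tol=config.sum_rule_tol,
    )
    results = model.fit()

    matrix.to_tsv(out / "ccf.tsv", header_comment=tag)
    for name, table in (
        ("clusters.tsv", results.cluster_table()),
        ("assignments.tsv", results.assignment_table()),
        ("composition.tsv", results.composition_table()),
    ):
        with open(out / name, "w") as fh:
            fh.write(f"# {tag}\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(out / "distances.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        results.distances.to_csv(fh, sep="\t", float_format="%.6g")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(results.newick() + "\n")
    _write_run_log(
        config, out, "clonal",
        {"n_mutations": matrix.n_mutations, "n_clusters": results.n_clusters},
    )
    logger.info("clonal stage complete: %d clusters", results.n_clusters)
    return results


@_stage("survival")
def run_survival(config: RunConfig) -> dict:
    """Survival table -> KM curve TSV + summary JSON (CIs reported, not
    validated against any external value)."""
    if not config.survival:
        raise InputError("survival stage needs a survival table")
    out = _setup_outdir(config)
    records = read_survival_tsv(config.survival)
    curve = km_estimate(records)
    median_days = km_median(curve)
    tag = f"clonedyn config_hash={config.config_hash()}"
    with open(out / "km_curve.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        curve.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")
    summary = {
        "n": len(records),
        "events": int(sum(r.event for r in records)),
        "median_days": median_days,
        "median_months": None if median_days is None else round(days_to_months(median_days), 2),
    }
    with open(out / "km_summary.json", "w") as fh:
        json.dump({"config_hash": config.config_hash(), **summary}, fh, indent=2)
    _write_run_log(config, out, "survival", summary)
    return summary


@_stage("synergy")
def run_synergy(config: RunConfig) -> dict:
    """Plate CSVs -> ZIP synergy summaries (mean +- SD across replicates),
    or per-layer results for a third-drug stack."""
    if not config.plates:
        raise InputError("synergy stage needs at least one plate CSV")
    out = _setup_outdir(config)
    tag = f"clonedyn config_hash={config.config_hash()}"
    matrices = [DoseResponseMatrix.from_csv(p).normalized() for p in config.plates]

    report: dict = {"config_hash": config.config_hash()}
    if config.plates_are_stack:
        result3d = zip_delta_3d(matrices)
        report["layers"] = [
            {"conc_c": None if r.conc_c is None else float(r.conc_c),
             "summary": round(float(r.summary), 6), "flags": r.flags}
            for r in result3d.layers
        ]
        # deviation cube as flat TSV (text-only artifacts)
        cube_rows = []
        for li, layer in enumerate(result3d.layers):
            frame = layer.delta.stack().reset_index()
            frame.columns = ["conc_b", "conc_a", "delta"]
            frame.insert(0, "conc_c", result3d.conc_c[li])
            cube_rows.append(frame)
        with open(out / "deviation_cube.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            pd.concat(cube_rows, ignore_index=True).to_csv(
                fh, sep="\t", index=False, float_format="%.6g"
            )
    else:
        summaries = []
        for i, mat in enumerate(matrices):
            res = zip_delta(mat)
            summaries.append(float(res.summary))
            with open(out / f"zip_delta_{i}.tsv", "w") as fh:
                fh.write(f"# {tag}\n")
                res.delta.to_csv(fh, sep="\t", float_format="%.6g")
        report["replicate_summaries"] = [round(s, 6) for s in summaries]
        report["summary_mean"] = round(float(np.mean(summaries)), 6)
        report["summary_sd"] = round(float(np.std(summaries, ddof=1)), 6) if len(summaries) > 1 else None
    with open(out / "synergy_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_run_log(config, out, "synergy", {"n_plates": len(matrices)})
    return report


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
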