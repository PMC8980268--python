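"""End-to-end study orchestration.

Runs the full replica of the hemispheric-network study from one config:
generate the synthetic cohort, temporally preprocess every analyzed
hemisphere, compute patient CVR, build sparsity-thresholded networks and
their graph metrics at each sparsity level, score patients against
hemisphere-matched control norms, and relate node metrics to CVR with the
mixed-effects model (plus the automatic outlier-exclusion sensitivity
rerun). All stages are deterministic under the configured seed; outputs
are plain CSV plus a JSON reproducibility manifest with per-file
checksums.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    assemble_long_table,
    association_report,
    fit_mixed_model,
    sensitivity_rerun,
)
from .config import PipelineConfig
from .cvr import CvrTable, cvr_from_timeseries
from .metrics import NODE_METRICS, MetricSet, compute_metric_set
from .network import apply_sparsity, pearson_matrix
from .norms import ZScoreTable, build_norms, summarize_global, summarize_nodes, zscore_patients
from .preprocess import preprocess_timeseries
from .synthetic import SubjectRecord, file_sha256, generate_cohort

__all__ = ["PipelineResult", "run_pipeline", "preprocess_cohort", "cohort_metric_sets"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Bundle of every stage's tabular outputs."""

    config: PipelineConfig
    manifest: pd.DataFrame
    global_summary: pd.DataFrame  # metric x sparsity table of mean z, SD, p, q
    node_summary: pd.DataFrame
    ztables: dict[float, ZScoreTable]
    cvr_tables: dict[str, CvrTable]
    association: pd.DataFrame
    association_results: dict[str, AssociationResult]
    sensitivity: pd.DataFrame
    checksums: dict[str, str] = field(default_factory=dict)


def preprocess_cohort(
    records: list[SubjectRecord], config: PipelineConfig
) -> list[tuple[str, str, str, "object"]]:
    """Temporal preprocessing of every analyzed subject-hemisphere.

    Controls contribute both hemispheres (bilateral WM/CSF nuisance);
    patients contribute only the hemisphere contralateral to disease
    (contralateral WM/CSF nuisance). Returns tuples of
    ``(subject_id, group, hemisphere, preprocessed RoiTimeSeries)``.
    """
    out = []
    for rec in records:
        if rec.group == "control":
            for hemi in ("left", "right"):
                other = "right" if hemi == "left" else "left"
                ts = preprocess_timeseries(
                    rec.hemispheres[hemi],
                    config.preprocess,
                    nuisance_source="bilateral",
                    other_hemisphere=rec.hemispheres[other],
                )
                out.append((rec.subject_id, "control", hemi, ts))
        else:
            hemi = rec.analyzed_hemisphere
            ts = preprocess_timeseries(
                rec.hemispheres[hemi], config.preprocess, nuisance_source="contralateral"
            )
            out.append((rec.subject_id, "patient", hemi, ts))
    logger.info("preprocessed %d subject-hemispheres", len(out))
    return out


def cohort_metric_sets(
    preprocessed: list[tuple[str, str, str, "object"]],
    sparsity: float,
    modularity_runs: int,
    seed: int,
) -> list[tuple[str, str, str, MetricSet]]:
    """Networks and metric sets for every preprocessed hemisphere."""
    out = []
    for idx, (sid, group, hemi, ts) in enumerate(preprocessed):
        cm = pearson_matrix(ts)
        net = apply_sparsity(cm, sparsity)
        rng = np.random.default_rng([seed, idx, int(round(sparsity * 1000))])
        ms = compute_metric_set(net, n_modularity_runs=modularity_runs, rng=rng)
        out.append((sid, group, hemi, ms))
    return out


def _zscore_stage(
    metric_sets: list[tuple[str, str, str, MetricSet]], sparsity: float
) -> ZScoreTable:
    controls_by_hemi: dict[str, list[MetricSet]] = {"left": [], "right": []}
    patients: list[tuple[str, str, MetricSet]] = []
    for sid, group, hemi, ms in metric_sets:
        if group == "control":
            controls_by_hemi[hemi].append(ms)
        else:
            patients.append((sid, hemi, ms))
    if not patients:
        raise ValueError("cohort has no patients; nothing to z-score")
    norms = {
        hemi: build_norms(sets, hemi, sparsity)
        for hemi, sets in controls_by_hemi.items()
        if sets
    }
    return zscore_patients(patients, norms)


def global_zscore_summary(config: PipelineConfig, sparsity: float) -> pd.DataFrame:
    """Generate one cohort and return its global z-score summary table.

    Light-weight path for simulation studies: runs generation,
    preprocessing, network/metric computation at a single sparsity, and
    normative scoring, skipping CVR and the association stage.
    """
    config.validate()
    records, _ = generate_cohort(config.cohort)
    preprocessed = preprocess_cohort(records, config)
    metric_sets = cohort_metric_sets(
        preprocessed, sparsity, config.modularity_runs, config.seed
    )
    return summarize_global(_zscore_stage(metric_sets, sparsity))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage for every sparsity level; optionally write files."""
    config.validate()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records, manifest = generate_cohort(
        config.cohort,
        output_dir=(out_dir / "cohort") if out_dir else None,
        overwrite=True,
    )
    patients = [r for r in records if r.group == "patient"]
    if not patients:
        raise ValueError("pipeline requires at least one patient (n_patients > 0)")

    preprocessed = preprocess_cohort(records, config)

    cvr_tables: dict[str, CvrTable] = {}
    for rec in patients:
        ts = rec.hemispheres[rec.analyzed_hemisphere]
        cvr_tables[rec.subject_id] = cvr_from_timeseries(
            ts,
            n_discard_volumes=config.preprocess.n_discard_volumes,
            window_volumes=config.cvr_window_volumes,
        )
    logger.info("computed CVR for %d patients", len(cvr_tables))

    ztables: dict[float, ZScoreTable] = {}
    global_frames, node_frames = [], []
    assoc_metric_sets: list[tuple[str, MetricSet]] | None = None
    for sparsity in config.sparsity_levels:
        metric_sets = cohort_metric_sets(
            preprocessed, sparsity, config.modularity_runs, config.seed
        )
        ztable = _zscore_stage(metric_sets, sparsity)
        ztables[sparsity] = ztable
        global_frames.append(summarize_global(ztable))
        node_frames.append(summarize_nodes(ztable))
        if np.isclose(sparsity, config.association_sparsity):
            assoc_metric_sets = [
                (sid, ms) for sid, group, _, ms in metric_sets if group == "patient"
            ]
    if assoc_metric_sets is None:
        metric_sets = cohort_metric_sets(
            preprocessed, config.association_sparsity, config.modularity_runs, config.seed
        )
        assoc_metric_sets = [
            (sid, ms) for sid, group, _, ms in metric_sets if group == "patient"
        ]

    global_summary = pd.concat(global_frames, ignore_index=True)
    node_summary = pd.concat(node_frames, ignore_index=True)

    long_table = assemble_long_table(assoc_metric_sets, cvr_tables)
    results = {m: fit_mixed_model(long_table, m) for m in NODE_METRICS}
    association = association_report(results)
    sens_results = {
        m: sensitivity_rerun(long_table, results[m], exclusion="auto") for m in NODE_METRICS
    }
    sensitivity = association_report(sens_results)

    checksums: dict[str, str] = {}
    if out_dir is not None:
        files = {
            "global_summary.csv": global_summary,
            "node_summary.csv": node_summary,
            "association.csv": association,
            "association_sensitivity.csv": sensitivity,
            "long_table.csv": long_table,
        }
        for sparsity, ztable in ztables.items():
            files[f"global_z_s{int(round(sparsity * 100))}.csv"] = ztable.global_z
            files[f"node_z_s{int(round(sparsity * 100))}.csv"] = ztable.node_z
        for name, frame in files.items():
            frame.to_csv(out_dir / name, index=False, float_format="%.10g")
            checksums[name] = file_sha256(out_dir / name)
        cvr_dir = out_dir / "cvr"
        cvr_dir.mkdir(exist_ok=True)
        for sid, table in cvr_tables.items():
            table.write(cvr_dir / f"{sid}_cvr.csv")
            checksums[f"cvr/{sid}_cvr.csv"] = file_sha256(cvr_dir / f"{sid}_cvr.csv")
        for p in sorted((out_dir / "cohort").glob("*")):
            checksums[f"cohort/{p.name}"] = file_sha256(p)
        run_manifest = {
            "seed": config.seed,
            "config": config.to_dict(),
            "checksums": checksums,
        }
        with open(out_dir / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("wrote pipeline outputs to %s", out_dir)

    return PipelineResult(
        config=config,
        manifest=manifest,
        global_summary=global_summary,
        node_summary=node_summary,
        ztables=ztables,
        cvr_tables=cvr_tables,
        association=association,
        association_results=results,
        sensitivity=sensitivity,
        checksums=checksums,
    )
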