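"""Hemisphere-matched control norms and patient z-scoring.

Control networks define, per hemisphere and sparsity level, a normative
mean and SD for every metric (hemispheric scalar summaries and per-node
values). Each patient's analyzed hemisphere — always the one contralateral
to disease — is scored as z = (x - mean_control) / SD_control against the
matching hemisphere's norms: a patient with right-sided disease is scored
against left-hemisphere control norms, and vice versa. A one-sample t-test
then asks whether patient z-scores have mean zero, with Benjamini-Hochberg
FDR correction applied within each reporting family (the six global
metrics per sparsity; the nodes of one metric for node-level maps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import GLOBAL_METRICS, NODE_METRICS, MetricSet

__all__ = [
    "ControlNorms",
    "ZScoreTable",
    "build_norms",
    "zscore_patients",
    "one_sample_test",
    "fdr_adjust",
    "summarize_global",
    "summarize_nodes",
]

logger = logging.getLogger(__name__)


@dataclass
class ControlNorms:
    """Control mean/SD per metric, keyed by hemisphere and sparsity."""

    hemisphere: str
    sparsity: float
    n_controls: int
    global_stats: pd.DataFrame  # index metric, columns mean/sd
    node_stats: pd.DataFrame  # index (metric, roi), columns mean/sd

    def write(self, path) -> None:
        g = self.global_stats.reset_index()
        g.insert(0, "scope", "global")
        g.insert(1, "roi", "")
        n = self.node_stats.reset_index()
        n.insert(0, "scope", "node")
        out = pd.concat([g, n], ignore_index=True)
        out.insert(0, "hemisphere", self.hemisphere)
        out.insert(1, "sparsity", self.sparsity)
        out.to_csv(path, index=False, float_format="%.10g")


@dataclass
class ZScoreTable:
    """Patient z-scores relative to hemisphere-matched control norms."""

    sparsity: float
    global_z: pd.DataFrame  # columns subject_id, hemisphere, metric, z
    node_z: pd.DataFrame  # columns subject_id, hemisphere, metric, roi, z
    n_excluded: dict[str, int] = field(default_factory=dict)


def _sample_stats(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(np.mean(v)), float(np.std(v, ddof=1))


def build_norms(
    control_metric_sets: list[MetricSet], hemisphere: str, sparsity: float
) -> ControlNorms:
    """Sample mean and SD (n-1 denominator) over control networks.

    Metrics with zero SD across controls, or undefined (NaN) in any
    control, are excluded from the norms with a logged warning.
    """
    if len(control_metric_sets) < 2:
        raise ValueError(
            f"need at least 2 controls to build norms, got {len(control_metric_sets)}"
        )
    for ms in control_metric_sets:
        if not np.isclose(ms.sparsity, sparsity):
            raise ValueError(f"metric set at sparsity {ms.sparsity} != requested {sparsity}")

    g_rows = {}
    for metric in GLOBAL_METRICS:
        vals = np.array([ms.global_summary()[metric] for ms in control_metric_sets])
        if np.isnan(vals).any():
            logger.warning(
                "global metric %r undefined in %d control(s); excluded from norms",
                metric, int(np.isnan(vals).sum()),
            )
            continue
        mean, sd = _sample_stats(vals)
        if sd <= 0:
            logger.warning("global metric %r has zero SD across controls; excluded", metric)
            continue
        g_rows[metric] = {"mean": mean, "sd": sd}
    global_stats = pd.DataFrame.from_dict(g_rows, orient="index")
    global_stats.index.name = "metric"

    labels = control_metric_sets[0].roi_labels
    n_rows = {}
    for metric in NODE_METRICS:
        mat = np.vstack([getattr(ms, metric) for ms in control_metric_sets])
        means = mat.mean(axis=0)
        sds = mat.std(axis=0, ddof=1)
        for j, roi in enumerate(labels):
            if sds[j] <= 0:
                logger.warning(
                    "node metric %r at %s has zero SD across controls; excluded", metric, roi
                )
                continue
            n_rows[(metric, roi)] = {"mean": means[j], "sd": sds[j]}
    node_stats = pd.DataFrame.from_dict(n_rows, orient="index")
    node_stats.index = pd.MultiIndex.from_tuples(node_stats.index, names=["metric", "roi"])

    return ControlNorms(
        hemisphere=hemisphere,
        sparsity=sparsity,
        n_controls=len(control_metric_sets),
        global_stats=global_stats,
        node_stats=node_stats,
    )


def zscore_patients(
    patient_metric_sets: list[tuple[str, str, MetricSet]],
    norms_by_hemisphere: dict[str, ControlNorms],
) -> ZScoreTable:
    """Score patients against their matching hemisphere's norms.

    ``patient_metric_sets`` holds ``(subject_id, hemisphere, MetricSet)``
    for each patient's analyzed (contralateral) hemisphere. Metrics that
    are undefined for a patient (NaN assortativity) or missing from the
    norms are skipped with a logged count.
    """
    if not patient_metric_sets:
        raise ValueError("no patient metric sets to score")
    sparsities = {norms.sparsity for norms in norms_by_hemisphere.values()}
    if len(sparsities) != 1:
        raise ValueError(f"norms mix sparsity levels: {sorted(sparsities)}")
    sparsity = sparsities.pop()

    g_rows, n_rows = [], []
    skipped: dict[str, int] = {}
    for sid, hemi, ms in patient_metric_sets:
        if hemi not in norms_by_hemisphere:
            raise ValueError(f"no control norms for hemisphere {hemi!r} (patient {sid})")
        if not np.isclose(ms.sparsity, sparsity):
            raise ValueError(
                f"patient {sid} metrics at sparsity {ms.sparsity} but norms at {sparsity}"
            )
        norms = norms_by_hemisphere[hemi]
        summary = ms.global_summary()
        for metric in GLOBAL_METRICS:
            if metric not in norms.global_stats.index or np.isnan(summary[metric]):
                skipped[metric] = skipped.get(metric, 0) + 1
                continue
            mu, sd = norms.global_stats.loc[metric, ["mean", "sd"]]
            g_rows.append(
                {
                    "subject_id": sid,
                    "hemisphere": hemi,
                    "metric": metric,
                    "z": (summary[metric] - mu) / sd,
                }
            )
        for metric in NODE_METRICS:
            values = getattr(ms, metric)
            for j, roi in enumerate(ms.roi_labels):
                key = (metric, roi)
                if key not in norms.node_stats.index:
                    continue
                mu, sd = norms.node_stats.loc[key, ["mean", "sd"]]
                n_rows.append(
                    {
                        "subject_id": sid,
                        "hemisphere": hemi,
                        "metric": metric,
                        "roi": roi,
                        "z": (values[j] - mu) / sd,
                    }
                )
    for metric, count in skipped.items():
        logger.info("skipped %d patient value(s) of %r (undefined or unnormed)", count, metric)
    return ZScoreTable(
        sparsity=sparsity,
        global_z=pd.DataFrame(g_rows),
        node_z=pd.DataFrame(n_rows),
        n_excluded=skipped,
    )


def one_sample_test(z_values: np.ndarray) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of mean zero; returns (t, df, p)."""
    z = np.asarray(z_values, dtype=float)
    if z.size < 2:
        raise ValueError(f"one-sample test requires n >= 2, got {z.size}")
    if np.std(z, ddof=1) == 0:
        if np.allclose(z, 0):
            return 0.0, z.size - 1, 1.0
        raise ValueError("z-scores have zero variance; t-test undefined")
    res = stats.ttest_1samp(z, popmean=0.0)
    return float(res.statistic), z.size - 1, float(res.pvalue)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _testable(z: np.ndarray, label: str) -> bool:
    if z.size < 2:
        return False
    if np.std(z, ddof=1) == 0 and not np.allclose(z, 0):
        logger.info("z-scores of %s are constant and nonzero; t-test skipped", label)
        return False
    return True


def summarize_global(ztable: ZScoreTable) -> pd.DataFrame:
    """Per-metric mean z, SD, t, p and FDR q (family = the global metrics)."""
    rows = []
    for metric in GLOBAL_METRICS:
        z = ztable.global_z.loc[ztable.global_z["metric"] == metric, "z"].to_numpy()
        if not _testable(z, metric):
            continue
        t, df, p = one_sample_test(z)
        rows.append(
            {
                "sparsity": ztable.sparsity,
                "metric": metric,
                "n_patients": z.size,
                "mean_z": z.mean(),
                "sd_z": z.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def summarize_nodes(ztable: ZScoreTable) -> pd.DataFrame:
    """Per-node tests, FDR-corrected across nodes within each metric."""
    frames = []
    for metric in NODE_METRICS:
        sub = ztable.node_z[ztable.node_z["metric"] == metric]
        rows = []
        for roi, grp in sub.groupby("roi", sort=True):
            z = grp["z"].to_numpy()
            if not _testable(z, f"{metric}/{roi}"):
                continue
            t, df, p = one_sample_test(z)
            rows.append(
                {
                    "sparsity": ztable.sparsity,
                    "metric": metric,
                    "roi": roi,
                    "n_patients": z.size,
                    "mean_z": z.mean(),
                    "sd_z": z.std(ddof=1),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
        df_m = pd.DataFrame(rows)
        if not df_m.empty:
            df_m["q"] = fdr_adjust(df_m["p"].to_numpy())
        frames.append(df_m)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
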