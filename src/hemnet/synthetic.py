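"""Synthetic two-group cohort generator.

Generates control and patient cohorts of hemispheric ROI time series with
planted, recoverable structure so that every downstream stage (preprocessing,
CVR mapping, network construction, graph metrics, normative scoring,
CVR association) can be exercised and validated without any imaging data.

The signal model is a band-limited multivariate Gaussian process: white
multivariate-normal draws with a block-modular correlation matrix are
band-pass filtered to 0.01-0.08 Hz, standardized, and scaled onto a raw
signal baseline. Patients' analyzed (contralateral-to-disease) hemispheres
have their off-diagonal correlations multiplied by ``attenuation_alpha``
(group-level connectivity attenuation) and perturbed node-wise in
proportion to the node's cerebrovascular reactivity (CVR), which plants a
within-subject metric-CVR association. Patient scans additionally carry an
additive acetazolamide (ACZ) step of amplitude CVR_i percent of the
baseline mean, ramping in over ``acz_response_shape`` volumes from
``acz_onset_volume``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import CohortConfig
from .timeseries import (
    CONFOUND_COLUMNS,
    MOTION_COLUMNS,
    RoiTimeSeries,
    default_roi_labels,
    write_atlas_table,
)

__all__ = [
    "SubjectRecord",
    "build_block_correlation",
    "module_assignment",
    "attenuate_correlation",
    "apply_cvr_coupling",
    "patient_correlation",
    "simulate_subject",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-6


def module_assignment(n_roi: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal-size planted community labels (0-based)."""
    labels = np.empty(n_roi, dtype=int)
    for m, idx in enumerate(np.array_split(np.arange(n_roi), n_modules)):
        labels[idx] = m
    return labels


def build_block_covariance(
    n_roi: int, n_modules: int, rho_within: float, rho_between: float
) -> np.ndarray:
    """Block-modular correlation-structure matrix.

    Unit diagonal; entries equal ``rho_within`` inside planted blocks and
    ``rho_between`` across blocks. Positive definiteness is verified at
    build time.
    """
    if not (0.0 <= rho_between <= rho_within < 1.0):
        raise ValueError(
            "require 0 <= rho_between <= rho_within < 1; got "
            f"rho_between={rho_between}, rho_within={rho_within}"
        )
    if n_modules <= 0 or n_roi <= 0 or n_modules > n_roi:
        raise ValueError(f"invalid n_roi={n_roi}, n_modules={n_modules}")
    labels = module_assignment(n_roi, n_modules)
    same = labels[:, None] == labels[None, :]
    r = np.where(same, rho_within, rho_between)
    np.fill_diagonal(r, 1.0)
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin <= 0:
        raise ValueError(
            "block correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}) for rho_within={rho_within}, "
            f"rho_between={rho_between}, n_roi={n_roi}, n_modules={n_modules}"
        )
    return r


# alias matching the correlation-structure role of the matrix
build_block_correlation = build_block_covariance


def _project_correlation(r: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Nearest valid correlation matrix by eigenvalue clipping.

    Symmetrizes, clips eigenvalues at ``eig_floor`` and rescales to unit
    diagonal, guaranteeing a usable sampling distribution after the
    attenuation / CVR-coupling perturbations.
    """
    r = 0.5 * (r + r.T)
    w, v = np.linalg.eigh(r)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def attenuate_correlation(r: np.ndarray, alpha: float) -> np.ndarray:
    """Multiply all off-diagonal correlations by ``alpha`` in (0, 1]."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"attenuation alpha must be in (0, 1], got {alpha}")
    out = r * alpha
    np.fill_diagonal(out, 1.0)
    return _project_correlation(out)


def apply_cvr_coupling(r: np.ndarray, cvr_pct: np.ndarray, beta: float) -> np.ndarray:
    """Perturb each node's correlation column by its CVR deviation.

    Off-diagonal entry (i, j) receives ``beta * (dCVR_i + dCVR_j)`` where
    dCVR is the CVR field centred on its mean; nodes with above-average
    reactivity gain connectivity. The result is clipped to valid
    correlation range and re-projected to the nearest positive definite
    correlation matrix.
    """
    cvr_pct = np.asarray(cvr_pct, dtype=float)
    if cvr_pct.shape != (r.shape[0],):
        raise ValueError(f"cvr field shape {cvr_pct.shape} does not match {r.shape[0]} ROIs")
    if beta == 0.0:
        return r.copy()
    d = cvr_pct - cvr_pct.mean()
    out = r + beta * (d[:, None] + d[None, :])
    out = np.clip(out, -0.99, 0.99)
    np.fill_diagonal(out, 1.0)
    return _project_correlation(out)


def patient_correlation(config: CohortConfig, cvr_pct: np.ndarray | None = None) -> np.ndarray:
    """Generating correlation matrix of a patient's analyzed hemisphere."""
    base = build_block_correlation(
        config.n_roi, config.n_modules, config.rho_within, config.rho_between
    )
    r = attenuate_correlation(base, config.attenuation_alpha)
    if cvr_pct is not None and config.cvr_coupling_beta != 0.0:
        r = apply_cvr_coupling(r, cvr_pct, config.cvr_coupling_beta)
    return r


@dataclass
class SubjectRecord:
    """One simulated subject: per-hemisphere series plus ground truth."""

    subject_id: str
    group: str  # 'control' | 'patient'
    diseased_side: str  # 'left' | 'right' | 'none'
    hemispheres: dict[str, RoiTimeSeries] = field(default_factory=dict)
    cvr_true_pct: np.ndarray | None = None  # analyzed hemisphere, patients only

    def __post_init__(self):
        if self.group not in ("control", "patient"):
            raise ValueError(f"group must be 'control' or 'patient', got {self.group!r}")
        if self.group == "control" and self.diseased_side != "none":
            raise ValueError("controls must have diseased_side='none'")
        if self.group == "patient" and self.diseased_side not in ("left", "right"):
            raise ValueError("patients must have exactly one diseased side")

    @property
    def analyzed_hemisphere(self) -> str:
        """Hemisphere entering network analysis (contralateral to disease)."""
        if self.group == "patient":
            return "left" if self.diseased_side == "right" else "right"
        raise ValueError("controls contribute both hemispheres; no single analyzed side")


def _draw_cvr_field(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-ROI CVR (%), i.i.d. normal truncated at zero (redrawn)."""
    cvr = rng.normal(config.cvr_mean_pct, config.cvr_sd_pct, size=config.n_roi)
    for _ in range(100):
        bad = cvr < 0
        if not bad.any():
            break
        cvr[bad] = rng.normal(config.cvr_mean_pct, config.cvr_sd_pct, size=int(bad.sum()))
    return np.clip(cvr, 0.0, None)


def _smooth_noise(n: int, rng: np.random.Generator, cutoff: float = 0.1) -> np.ndarray:
    """Standardized low-frequency noise trace (surrogate nuisance signal)."""
    x = rng.standard_normal(n)
    b, a = sps.butter(2, cutoff)
    x = sps.filtfilt(b, a, x)
    sd = x.std()
    if sd < 1e-12:  # pathological draw; fall back to white noise
        x = rng.standard_normal(n)
        sd = x.std()
    return (x - x.mean()) / sd


def _draw_motion(n: int, rng: np.random.Generator) -> np.ndarray:
    """Six standardized slow-drift head-motion surrogate traces."""
    return np.column_stack([_smooth_noise(n, rng, cutoff=0.05) for _ in range(6)])


def _band_limited_process(
    corr: np.ndarray, n_volumes: int, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-SD band-limited Gaussian process with spatial corr."""
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))
    white = rng.standard_normal((corr.shape[0], n_volumes))
    x = chol @ white
    lo, hi = config.gen_band_hz
    b, a = sps.butter(2, [lo, hi], btype="bandpass", fs=1.0 / config.tr_seconds)
    x = sps.filtfilt(b, a, x, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _simulate_hemisphere(
    corr: np.ndarray,
    n_volumes: int,
    config: CohortConfig,
    rng: np.random.Generator,
    motion: np.ndarray,
    hemisphere: str,
    meta: dict,
    acz_cvr_pct: np.ndarray | None = None,
) -> RoiTimeSeries:
    x = _band_limited_process(corr, n_volumes, config, rng)
    data = config.baseline_mean + config.signal_sd * x

    wm = _smooth_noise(n_volumes, rng)
    csf = _smooth_noise(n_volumes, rng)
    conf = np.column_stack([motion, wm, csf])

    # mix confounds into the signal at a small, fixed fraction of signal SD
    loadings = rng.standard_normal((config.n_roi, conf.shape[1]))
    loadings *= (
        config.confound_amplitude
        * config.signal_sd
        / np.linalg.norm(loadings, axis=1, keepdims=True)
    )
    data = data + loadings @ conf.T

    if acz_cvr_pct is not None:
        t = np.arange(n_volumes, dtype=float)
        if config.acz_response_shape > 0:
            ramp = np.clip((t - config.acz_onset_volume) / config.acz_response_shape, 0.0, 1.0)
        else:
            ramp = (t >= config.acz_onset_volume).astype(float)
        step = (acz_cvr_pct / 100.0 * config.baseline_mean)[:, None] * ramp[None, :]
        data = data + step

    confounds = pd.DataFrame(conf, columns=CONFOUND_COLUMNS)
    return RoiTimeSeries(
        roi_labels=default_roi_labels(config.n_roi),
        data=data,
        tr_seconds=config.tr_seconds,
        confounds=confounds,
        hemisphere=hemisphere,
        meta=dict(meta),
    )


def simulate_subject(
    config: CohortConfig,
    group: str,
    diseased_side: str,
    rng: np.random.Generator,
    subject_id: str = "S00",
) -> SubjectRecord:
    """Simulate one subject's two hemispheres from the planted model.

    Controls: both hemispheres follow the base block-modular correlation
    structure over 400 volumes. Patients: 600 volumes; the analyzed
    (contralateral) hemisphere uses the attenuated, CVR-coupled structure
    and both hemispheres carry the additive ACZ response; the ipsilateral
    (diseased) hemisphere uses the attenuated structure without coupling
    and is not analyzed downstream.
    """
    config.validate()
    base = build_block_correlation(
        config.n_roi, config.n_modules, config.rho_within, config.rho_between
    )
    record = SubjectRecord(subject_id=subject_id, group=group, diseased_side=diseased_side)
    meta = {
        "subject_id": subject_id,
        "group": group,
        "diseased_side": diseased_side,
        "acz_onset_volume": config.acz_onset_volume if group == "patient" else None,
    }

    if group == "control":
        n_vol = config.n_volumes_control
        motion = _draw_motion(n_vol, rng)
        for hemi in ("left", "right"):
            record.hemispheres[hemi] = _simulate_hemisphere(
                base, n_vol, config, rng, motion, hemi, meta
            )
        return record

    n_vol = config.n_volumes_patient
    motion = _draw_motion(n_vol, rng)
    cvr = _draw_cvr_field(config, rng)
    record.cvr_true_pct = cvr
    contra = "left" if diseased_side == "right" else "right"

    r_contra = attenuate_correlation(base, config.attenuation_alpha)
    if config.cvr_coupling_beta != 0.0:
        r_contra = apply_cvr_coupling(r_contra, cvr, config.cvr_coupling_beta)
    r_ipsi = attenuate_correlation(base, config.attenuation_alpha)

    for hemi, r in ((contra, r_contra), (diseased_side, r_ipsi)):
        record.hemispheres[hemi] = _simulate_hemisphere(
            r, n_vol, config, rng, motion, hemi, meta, acz_cvr_pct=cvr
        )
    record.hemispheres[contra].meta["cvr_true_pct"] = [float(v) for v in cvr]
    return record


def _diseased_sides(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    n_right = int(round(config.right_sided_fraction * config.n_patients))
    sides = ["right"] * n_right + ["left"] * (config.n_patients - n_right)
    rng.shuffle(sides)
    return sides


def generate_cohort(
    config: CohortConfig,
    output_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate the full cohort and its manifest.

    With ``output_dir`` set, writes each subject-hemisphere's signal TSV,
    confound TSV and JSON sidecar plus the cohort manifest CSV and atlas
    label table; refuses to write into an existing non-empty directory
    unless ``overwrite`` is given. Fixed ``config.seed`` yields
    byte-identical outputs.
    """
    config.validate()
    n_total = config.n_controls + config.n_patients
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_total + 1)
    side_rng = np.random.default_rng(children[-1])
    sides = _diseased_sides(config, side_rng)

    records: list[SubjectRecord] = []
    rows = []
    out = None
    if output_dir is not None:
        out = Path(output_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(
                f"output directory {out} exists and is not empty; pass overwrite=True"
            )
        out.mkdir(parents=True, exist_ok=True)
        write_atlas_table(out / "atlas.tsv", default_roi_labels(config.n_roi))

    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        if i < config.n_controls:
            sid, group, side = f"C{i + 1:02d}", "control", "none"
        else:
            j = i - config.n_controls
            sid, group, side = f"P{j + 1:02d}", "patient", sides[j]
        rec = simulate_subject(config, group, side, rng, subject_id=sid)
        records.append(rec)

        paths = {}
        if out is not None:
            for hemi, ts in rec.hemispheres.items():
                stem = out / f"{sid}_{hemi}"
                ts.write(f"{stem}_bold.tsv", f"{stem}_confounds.tsv", f"{stem}_meta.json")
                paths[f"{hemi}_bold"] = f"{sid}_{hemi}_bold.tsv"
                paths[f"{hemi}_confounds"] = f"{sid}_{hemi}_confounds.tsv"
                paths[f"{hemi}_meta"] = f"{sid}_{hemi}_meta.json"
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "diseased_side": side,
                "seed": config.seed,
                "subject_index": i,
                **paths,
            }
        )

    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        logger.info("wrote cohort of %d subjects to %s", n_total, out)
    return records, manifest


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
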