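"""Temporal preprocessing of ROI time series.

The chain mirrors standard resting-state practice for hemispheric network
analysis: discard initial volumes, keep a fixed analysis window, remove a
per-ROI linear trend, regress nuisance signals (six motion traces plus WM
and CSF surrogates), and apply a zero-phase Butterworth band-pass
(0.01-0.1 Hz by default). Spatial steps (realignment, normalization,
smoothing) are upstream of this package; inputs are already ROI-level.

WM/CSF nuisance regressors are hemisphere-dependent: for patients they are
taken from the hemisphere contralateral to the disease (the normal-appearing
hemisphere, avoiding lesion contamination), for controls from the average
of both hemispheres.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import PreprocessConfig
from .timeseries import MOTION_COLUMNS, RoiTimeSeries

__all__ = [
    "discard_and_window",
    "detrend_linear",
    "regress_nuisance",
    "bandpass",
    "build_nuisance_design",
    "preprocess_timeseries",
]

logger = logging.getLogger(__name__)


def discard_and_window(ts: RoiTimeSeries, config: PreprocessConfig) -> RoiTimeSeries:
    """Drop the first ``n_discard_volumes`` and keep the analysis window.

    The window covers ``analysis_window_seconds`` of data starting at the
    first retained (non-discarded) volume; confounds are cut identically.
    """
    n_window = int(round(config.analysis_window_seconds / ts.tr_seconds))
    needed = config.n_discard_volumes + n_window
    if ts.n_volumes < needed:
        raise ValueError(
            f"series has {ts.n_volumes} volumes but discard={config.n_discard_volumes} "
            f"plus a {n_window}-volume window requires {needed}"
        )
    sl = slice(config.n_discard_volumes, config.n_discard_volumes + n_window)
    return ts.copy_with(
        data=ts.data[:, sl],
        confounds=ts.confounds.iloc[sl].reset_index(drop=True),
    )


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the least-squares line (intercept + slope) from each ROI."""
    n = ts.n_volumes
    if n < 3:
        raise ValueError(f"detrending requires at least 3 time points, got {n}")
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data - (design @ coef).T
    return ts.copy_with(data=resid)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (reported on failure)."""
    rank = np.linalg.matrix_rank(design)
    bad = []
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(names[j])
    return bad


def regress_nuisance(ts: RoiTimeSeries, confounds: pd.DataFrame) -> RoiTimeSeries:
    """OLS residuals of each ROI series on [intercept, confound columns]."""
    if len(confounds) != ts.n_volumes:
        raise ValueError(
            f"confound rows ({len(confounds)}) do not match series length ({ts.n_volumes})"
        )
    names = ["intercept"] + list(confounds.columns)
    design = np.column_stack([np.ones(ts.n_volumes), confounds.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(
            f"nuisance design is rank-deficient (rank {rank} of {design.shape[1]}); "
            f"collinear columns: {', '.join(bad)}"
        )
    coef, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data - (design @ coef).T
    return ts.copy_with(data=resid)


def build_nuisance_design(
    analyzed: RoiTimeSeries,
    other_hemisphere: RoiTimeSeries | None,
    nuisance_source: str,
) -> pd.DataFrame:
    """Assemble the nuisance table for one analyzed hemisphere.

    Motion comes from the analyzed hemisphere's confound file (head motion
    is subject-level). WM/CSF depend on ``nuisance_source``:

    - ``"contralateral"`` (patients): WM/CSF from the hemisphere
      contralateral to disease — i.e. the analyzed hemisphere itself.
    - ``"bilateral"`` (controls): arithmetic mean of the two hemispheres'
      WM/CSF columns.
    """
    motion = analyzed.confounds[MOTION_COLUMNS]
    if nuisance_source == "contralateral":
        wmcsf = analyzed.confounds[["wm", "csf"]]
    elif nuisance_source == "bilateral":
        if other_hemisphere is None:
            raise ValueError("bilateral nuisance_source requires both hemispheres")
        wmcsf = (
            analyzed.confounds[["wm", "csf"]] + other_hemisphere.confounds[["wm", "csf"]]
        ) / 2.0
    else:
        raise ValueError(
            f"nuisance_source must be 'contralateral' or 'bilateral', got {nuisance_source!r}"
        )
    return pd.concat([motion.reset_index(drop=True), wmcsf.reset_index(drop=True)], axis=1)


def bandpass(ts: RoiTimeSeries, config: PreprocessConfig) -> RoiTimeSeries:
    """Zero-phase two-pass Butterworth band-pass of order ``filter_order``.

    Uses odd-symmetric padding of three times the filter order to suppress
    edge transients on short analysis windows; the forward-backward pass
    leaves in-band components with no phase shift.
    """
    nyq = 0.5 / ts.tr_seconds
    if not (0.0 < config.band_low_hz < config.band_high_hz < nyq):
        raise ValueError(
            f"pass band ({config.band_low_hz}, {config.band_high_hz}) Hz must lie "
            f"inside (0, Nyquist={nyq:g}) at TR={ts.tr_seconds:g} s"
        )
    # scipy's butter order is per section; N//2 sections give a band-pass
    # of total order filter_order
    b, a = sps.butter(
        config.filter_order // 2,
        [config.band_low_hz, config.band_high_hz],
        btype="bandpass",
        fs=1.0 / ts.tr_seconds,
    )
    padlen = min(3 * config.filter_order, ts.n_volumes - 1)
    filtered = sps.filtfilt(b, a, ts.data, axis=1, padtype="odd", padlen=padlen)
    return ts.copy_with(data=filtered)


def preprocess_timeseries(
    ts: RoiTimeSeries,
    config: PreprocessConfig,
    nuisance_source: str,
    other_hemisphere: RoiTimeSeries | None = None,
) -> RoiTimeSeries:
    """Full temporal chain: window -> detrend -> nuisance -> band-pass.

    The stage order is fixed; nuisance confounds are windowed with the
    series and entered unfiltered (regression precedes the band-pass).
    """
    windowed = discard_and_window(ts, config)
    other_w = (
        discard_and_window(other_hemisphere, config) if other_hemisphere is not None else None
    )
    detrended = detrend_linear(windowed)
    design = build_nuisance_design(windowed, other_w, nuisance_source)
    cleaned = regress_nuisance(detrended, design)
    out = bandpass(cleaned, config)
    logger.debug(
        "preprocessed %s hemisphere: %d ROIs x %d volumes",
        ts.hemisphere, out.n_roi, out.n_volumes,
    )
    return out
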