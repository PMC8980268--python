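"""ROI-level cerebrovascular reactivity (CVR) from the ACZ challenge.

CVR is the percent BOLD signal change between the pre- and post-ACZ
window means:

    CVR = (BOLD_post - BOLD_pre) / BOLD_pre x 100%

computed per ROI from the minimally processed patient series (after the
initial volume discard only — detrending or band-pass filtering would
remove the very step being measured). The pre window is the first
``window_volumes`` retained volumes, the post window the last
``window_volumes`` volumes of the full acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import RoiTimeSeries

__all__ = ["CvrTable", "window_means", "compute_cvr", "cvr_from_timeseries"]

logger = logging.getLogger(__name__)


@dataclass
class CvrTable:
    """Per-ROI CVR (%) plus the window indices used to compute it."""

    roi_labels: list[str]
    cvr_pct: np.ndarray
    pre_window: tuple[int, int]  # [start, stop) volume indices
    post_window: tuple[int, int]
    valid: np.ndarray  # False where pre-mean was ~0 and CVR is undefined

    def __post_init__(self):
        self.cvr_pct = np.asarray(self.cvr_pct, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.roi_labels) != self.cvr_pct.size or self.valid.size != self.cvr_pct.size:
            raise ValueError("roi_labels, cvr_pct and valid must have equal length")
        if self.pre_window[1] > self.post_window[0]:
            raise ValueError(
                f"pre window {self.pre_window} overlaps post window {self.post_window}"
            )
        if not np.all(np.isfinite(self.cvr_pct[self.valid])):
            raise ValueError("valid CVR entries must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": np.arange(1, len(self.roi_labels) + 1),
                "roi_name": self.roi_labels,
                "cvr_pct": self.cvr_pct,
                "valid": self.valid,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def window_means(
    ts: RoiTimeSeries, window_volumes: int = 30
) -> tuple[np.ndarray, np.ndarray, tuple[int, int], tuple[int, int]]:
    """Per-ROI means of the first and last ``window_volumes`` volumes."""
    if window_volumes <= 0:
        raise ValueError(f"window_volumes must be positive, got {window_volumes}")
    if ts.n_volumes < 2 * window_volumes:
        raise ValueError(
            f"series has {ts.n_volumes} volumes; two disjoint {window_volumes}-volume "
            f"windows require at least {2 * window_volumes}"
        )
    pre = (0, window_volumes)
    post = (ts.n_volumes - window_volumes, ts.n_volumes)
    pre_mean = ts.data[:, pre[0]:pre[1]].mean(axis=1)
    post_mean = ts.data[:, post[0]:post[1]].mean(axis=1)
    return pre_mean, post_mean, pre, post


def compute_cvr(
    pre_mean: np.ndarray,
    post_mean: np.ndarray,
    roi_labels: list[str],
    pre_window: tuple[int, int] = (0, 30),
    post_window: tuple[int, int] = (560, 590),
) -> CvrTable:
    """Percent-change CVR; ROIs with ~zero pre-mean are flagged invalid."""
    pre_mean = np.asarray(pre_mean, dtype=float)
    post_mean = np.asarray(post_mean, dtype=float)
    valid = np.abs(pre_mean) > 1e-12
    cvr = np.full(pre_mean.shape, np.nan)
    cvr[valid] = (post_mean[valid] - pre_mean[valid]) / pre_mean[valid] * 100.0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d ROI(s) have zero pre-ACZ mean; CVR undefined there", n_bad)
    return CvrTable(
        roi_labels=list(roi_labels),
        cvr_pct=cvr,
        pre_window=pre_window,
        post_window=post_window,
        valid=valid,
    )


def cvr_from_timeseries(
    ts: RoiTimeSeries, n_discard_volumes: int = 10, window_volumes: int = 30
) -> CvrTable:
    """CVR from a raw patient series: discard, then window means, then CVR."""
    if ts.n_volumes <= n_discard_volumes:
        raise ValueError(
            f"series has {ts.n_volumes} volumes; cannot discard {n_discard_volumes}"
        )
    trimmed = ts.copy_with(
        data=ts.data[:, n_discard_volumes:],
        confounds=ts.confounds.iloc[n_discard_volumes:].reset_index(drop=True),
    )
    pre_mean, post_mean, pre, post = window_means(trimmed, window_volumes)
    return compute_cvr(pre_mean, post_mean, trimmed.roi_labels, pre, post)
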