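"""ROI time-series container and its on-disk text formats.

A :class:`RoiTimeSeries` holds one subject-hemisphere's ROI x time BOLD
signal block together with its nuisance confounds (six head-motion traces
plus white-matter and CSF surrogate signals) and protocol metadata. The
disk dialect is deliberately plain: a headered TSV per signal block, a
headered TSV per confound table, and a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RoiTimeSeries", "CONFOUND_COLUMNS", "MOTION_COLUMNS", "default_roi_labels"]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
CONFOUND_COLUMNS = MOTION_COLUMNS + ["wm", "csf"]

_FLOAT_FMT = "%.10g"


def default_roi_labels(n_roi: int) -> list[str]:
    """Atlas-style ROI labels, one hemisphere ('roi01' ... 'roi45')."""
    width = max(2, len(str(n_roi)))
    return [f"roi{i + 1:0{width}d}" for i in range(n_roi)]


@dataclass
class RoiTimeSeries:
    """One hemisphere's ROI x time signal block plus confounds.

    Attributes
    ----------
    roi_labels : ordered atlas labels, one per data row.
    data : (n_roi, n_volumes) float array in arbitrary signal units.
    tr_seconds : sampling interval.
    confounds : (n_volumes, k) DataFrame; columns are the six motion
        traces plus ``wm`` and ``csf``.
    hemisphere : ``"left"`` or ``"right"``.
    meta : free-form protocol metadata (group, diseased side, ACZ onset).
    """

    roi_labels: list[str]
    data: np.ndarray
    tr_seconds: float
    confounds: pd.DataFrame
    hemisphere: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (ROI x time), got shape {self.data.shape}")
        if len(self.roi_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.roi_labels)} roi_labels but {self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if len(self.confounds) != self.data.shape[1]:
            raise ValueError(
                f"confounds have {len(self.confounds)} rows but data has "
                f"{self.data.shape[1]} volumes"
            )

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **changes) -> "RoiTimeSeries":
        out = replace(self, **changes)
        return out

    # ------------------------------------------------------------------ IO
    def write(self, data_path: str | Path, confounds_path: str | Path,
              meta_path: str | Path) -> None:
        data_path, confounds_path, meta_path = map(Path, (data_path, confounds_path, meta_path))
        cols = [f"t{i:03d}" for i in range(self.n_volumes)]
        df = pd.DataFrame(self.data, index=pd.Index(self.roi_labels, name="roi"), columns=cols)
        df.to_csv(data_path, sep="\t", float_format=_FLOAT_FMT)
        self.confounds.to_csv(confounds_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        meta = dict(self.meta)
        meta.update({"tr_seconds": self.tr_seconds, "hemisphere": self.hemisphere})
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, data_path: str | Path, confounds_path: str | Path,
             meta_path: str | Path) -> "RoiTimeSeries":
        df = pd.read_csv(data_path, sep="\t", index_col=0)
        confounds = pd.read_csv(confounds_path, sep="\t")
        with open(meta_path) as fh:
            meta = json.load(fh)
        tr = float(meta.pop("tr_seconds"))
        hemisphere = meta.pop("hemisphere")
        return cls(
            roi_labels=list(df.index),
            data=df.to_numpy(dtype=float),
            tr_seconds=tr,
            confounds=confounds,
            hemisphere=hemisphere,
            meta=meta,
        )


def write_atlas_table(path: str | Path, roi_labels: list[str]) -> None:
    """Two-column atlas label table (roi_id, roi_name)."""
    df = pd.DataFrame(
        {"roi_id": np.arange(1, len(roi_labels) + 1), "roi_name": roi_labels}
    )
    df.to_csv(path, sep="\t", index=False)
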