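"""Configuration objects for the hemispheric-network study pipeline.

Every protocol constant of the emulated study (TR, volume counts, analysis
window, pass band, sparsity levels, modularity repetitions, FDR threshold)
is surfaced here as a named, validated default rather than hard-coded in the
stages that consume it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "CohortConfig",
    "PreprocessConfig",
    "PipelineConfig",
    "load_config",
    "validate_config",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic two-group cohort.

    The defaults reproduce the emulated acquisition protocol: 45 ROIs per
    hemisphere sampled at TR = 2 s, 600-volume patient scans with a
    mid-scan acetazolamide (ACZ) response, and 400-volume control scans.
    Connectivity is block-modular (``n_modules`` planted communities with
    within/between target correlations); patients' analyzed (contralateral)
    hemispheres have all off-diagonal correlations multiplied by
    ``attenuation_alpha`` and node-wise perturbed in proportion to each
    node's cerebrovascular reactivity (CVR), which plants a recoverable
    metric-CVR coupling.
    """

    n_controls: int = 20
    n_patients: int = 20
    n_roi: int = 45
    tr_seconds: float = 2.0
    n_volumes_patient: int = 600
    n_volumes_control: int = 400
    n_modules: int = 5
    rho_within: float = 0.5
    rho_between: float = 0.05
    attenuation_alpha: float = 0.8
    cvr_mean_pct: float = 6.0
    cvr_sd_pct: float = 2.0
    cvr_coupling_beta: float = 0.02
    acz_onset_volume: int = 160
    acz_response_shape: int = 60
    seed: int = 0
    # signal-scale parameters; 1% fluctuation about a raw-units baseline
    baseline_mean: float = 1000.0
    signal_sd: float = 10.0
    confound_amplitude: float = 0.10
    gen_band_hz: tuple[float, float] = (0.01, 0.08)
    # 7 of 20 patients in the emulated cohort have right-sided disease
    right_sided_fraction: float = 0.35

    def validate(self) -> "CohortConfig":
        for name in ("n_controls", "n_patients"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("n_roi", "n_modules", "n_volumes_patient", "n_volumes_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_modules > self.n_roi:
            raise ValueError(
                f"n_modules ({self.n_modules}) cannot exceed n_roi ({self.n_roi})"
            )
        if not (0.0 <= self.rho_between < self.rho_within < 1.0):
            raise ValueError(
                "require 0 <= rho_between < rho_within < 1; got "
                f"rho_between={self.rho_between}, rho_within={self.rho_within}"
            )
        if not (0.0 < self.attenuation_alpha <= 1.0):
            raise ValueError(
                f"attenuation_alpha must be in (0, 1], got {self.attenuation_alpha}"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.cvr_sd_pct < 0:
            raise ValueError(f"cvr_sd_pct must be non-negative, got {self.cvr_sd_pct}")
        if not (0 <= self.acz_onset_volume < self.n_volumes_patient):
            raise ValueError(
                f"acz_onset_volume={self.acz_onset_volume} outside patient series "
                f"of {self.n_volumes_patient} volumes"
            )
        if self.acz_response_shape < 0:
            raise ValueError(
                f"acz_response_shape must be non-negative, got {self.acz_response_shape}"
            )
        lo, hi = self.gen_band_hz
        if not (0.0 < lo < hi < 0.5 / self.tr_seconds):
            raise ValueError(
                f"gen_band_hz={self.gen_band_hz} must lie inside (0, Nyquist="
                f"{0.5 / self.tr_seconds:g})"
            )
        return self


@dataclass
class PreprocessConfig:
    """Temporal preprocessing settings.

    The chain is: discard the first ``n_discard_volumes`` volumes, keep the
    next ``analysis_window_seconds`` of data, remove a per-ROI linear trend,
    regress nuisance signals (six motion traces plus WM and CSF), and apply
    a zero-phase Butterworth band-pass of order ``filter_order``.

    ``nuisance_source`` determines where WM/CSF regressors come from:
    ``"contralateral"`` (patients; the hemisphere opposite the disease)
    or ``"bilateral"`` (controls; mean of the two hemispheres).
    """

    n_discard_volumes: int = 10
    analysis_window_seconds: float = 300.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    filter_order: int = 4

    def validate(self, tr_seconds: float | None = None) -> "PreprocessConfig":
        if self.n_discard_volumes < 0:
            raise ValueError(
                f"n_discard_volumes must be non-negative, got {self.n_discard_volumes}"
            )
        if self.analysis_window_seconds <= 0:
            raise ValueError(
                f"analysis_window_seconds must be positive, got {self.analysis_window_seconds}"
            )
        if not (0.0 < self.band_low_hz < self.band_high_hz):
            raise ValueError(
                f"require 0 < band_low_hz < band_high_hz; got "
                f"({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.filter_order <= 0 or self.filter_order % 2:
            raise ValueError(f"filter_order must be a positive even count, got {self.filter_order}")
        if tr_seconds is not None:
            nyq = 0.5 / tr_seconds
            if self.band_high_hz >= nyq:
                raise ValueError(
                    f"band_high_hz={self.band_high_hz} must be below Nyquist "
                    f"({nyq:g} Hz at TR={tr_seconds:g} s)"
                )
        return self


@dataclass
class PipelineConfig:
    """End-to-end study configuration (nested per-stage configs)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sparsity_levels: tuple[float, ...] = (0.20, 0.30, 0.40)
    modularity_runs: int = 500
    cvr_window_volumes: int = 30
    association_sparsity: float = 0.40
    fdr_q_threshold: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> "PipelineConfig":
        self.cohort.validate()
        self.preprocess.validate(tr_seconds=self.cohort.tr_seconds)
        if not self.sparsity_levels:
            raise ValueError("sparsity_levels must not be empty")
        for s in self.sparsity_levels:
            if not (0.0 < s <= 1.0):
                raise ValueError(f"sparsity level {s} outside (0, 1]")
        if not (0.0 < self.association_sparsity <= 1.0):
            raise ValueError(
                f"association_sparsity {self.association_sparsity} outside (0, 1]"
            )
        if self.modularity_runs <= 0:
            raise ValueError(f"modularity_runs must be positive, got {self.modularity_runs}")
        if self.cvr_window_volumes <= 0:
            raise ValueError(
                f"cvr_window_volumes must be positive, got {self.cvr_window_volumes}"
            )
        if not (0.0 < self.fdr_q_threshold < 1.0):
            raise ValueError(
                f"fdr_q_threshold must be in (0, 1), got {self.fdr_q_threshold}"
            )
        # analysis window must fit in both protocols after the discard
        n_window = int(round(self.preprocess.analysis_window_seconds / self.cohort.tr_seconds))
        for name, total in (
            ("n_volumes_patient", self.cohort.n_volumes_patient),
            ("n_volumes_control", self.cohort.n_volumes_control),
        ):
            if self.preprocess.n_discard_volumes + n_window > total:
                raise ValueError(
                    f"analysis window needs {self.preprocess.n_discard_volumes + n_window} "
                    f"volumes but {name} is only {total}"
                )
        return self

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cohort"]["gen_band_hz"] = list(self.cohort.gen_band_hz)
        d["sparsity_levels"] = list(self.sparsity_levels)
        return d


def _build_dataclass(cls, data: dict[str, Any], context: str):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown {context} config keys: {', '.join(unknown)}")
    return cls(**data)


def validate_config(data: dict[str, Any] | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a (possibly empty) mapping.

    Unknown keys are rejected at every nesting level so that typos fail
    loudly instead of silently falling back to defaults.
    """
    data = dict(data or {})
    cohort = _build_dataclass(CohortConfig, dict(data.pop("cohort", {}) or {}), "cohort")
    if isinstance(cohort.gen_band_hz, list):
        cohort.gen_band_hz = tuple(cohort.gen_band_hz)
    preprocess = _build_dataclass(
        PreprocessConfig, dict(data.pop("preprocess", {}) or {}), "preprocess"
    )
    known = {f.name for f in fields(PipelineConfig)} - {"cohort", "preprocess"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {', '.join(unknown)}")
    if "sparsity_levels" in data:
        data["sparsity_levels"] = tuple(data["sparsity_levels"])
    cfg = PipelineConfig(cohort=cohort, preprocess=preprocess, **data)
    return cfg.validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse, default, and invariant-check a YAML pipeline config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping, got {type(data).__name__}")
    return validate_config(data)
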