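import numpy as np
import pandas as pd
import pytest

from hemnet import CohortConfig, PreprocessConfig
from hemnet.preprocess import preprocess_timeseries
from hemnet.synthetic import simulate_subject
from hemnet.timeseries import CONFOUND_COLUMNS, RoiTimeSeries, default_roi_labels


def make_ts(data, tr=2.0, hemisphere="left", confounds=None, labels=None):
    """Build a RoiTimeSeries around a raw data matrix (test helper)."""
    data = np.asarray(data, dtype=float)
    n_roi, n_vol = data.shape
    if confounds is None:
        rng = np.random.default_rng(12345)
        confounds = pd.DataFrame(
            rng.standard_normal((n_vol, len(CONFOUND_COLUMNS))), columns=CONFOUND_COLUMNS
        )
    if labels is None:
        labels = default_roi_labels(n_roi)
    return RoiTimeSeries(
        roi_labels=labels, data=data, tr_seconds=tr, confounds=confounds, hemisphere=hemisphere
    )


@pytest.fixture(scope="session")
def default_cohort_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def control_subject(default_cohort_config):
    rng = np.random.default_rng(777)
    return simulate_subject(default_cohort_config, "control", "none", rng, "C01")


@pytest.fixture(scope="session")
def patient_subject(default_cohort_config):
    rng = np.random.default_rng(778)
    return simulate_subject(default_cohort_config, "patient", "left", rng, "P01")


@pytest.fixture(scope="session")
def preprocessed_control(control_subject):
    """One preprocessed control hemisphere at protocol defaults."""
    return preprocess_timeseries(
        control_subject.hemispheres["left"],
        PreprocessConfig(),
        nuisance_source="bilateral",
        other_hemisphere=control_subject.hemispheres["right"],
    )
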