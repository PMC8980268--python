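"""Temporal preprocessing: windowing, detrend, nuisance regression, filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemnet.preprocess as pp
from hemnet import PreprocessConfig
from hemnet.timeseries import CONFOUND_COLUMNS

from conftest import make_ts


class TestDiscardAndWindow:
    def test_protocol_arithmetic(self):
        """600 volumes at TR=2, discard 10, 300-s window -> 150 retained."""
        ts = make_ts(np.random.default_rng(0).standard_normal((3, 600)))
        out = pp.discard_and_window(ts, PreprocessConfig())
        assert out.n_volumes == 150
        np.testing.assert_array_equal(out.data, ts.data[:, 10:160])
        assert len(out.confounds) == 150

    def test_zero_discard_full_window_is_identity(self):
        ts = make_ts(np.random.default_rng(1).standard_normal((2, 100)))
        cfg = PreprocessConfig(n_discard_volumes=0, analysis_window_seconds=200.0)
        out = pp.discard_and_window(ts, cfg)
        np.testing.assert_array_equal(out.data, ts.data)

    def test_too_short_series_error_names_counts(self):
        ts = make_ts(np.random.default_rng(2).standard_normal((2, 100)))
        with pytest.raises(ValueError, match="100 volumes.*requires 160"):
            pp.discard_and_window(ts, PreprocessConfig())


class TestDetrend:
    def test_pure_line_removed(self):
        t = np.arange(50, dtype=float)
        ts = make_ts(np.vstack([3.0 + 0.5 * t, -1.0 + 2.0 * t]))
        out = pp.detrend_linear(ts)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_constant_series_zeroed(self):
        ts = make_ts(np.full((2, 30), 7.5))
        np.testing.assert_allclose(pp.detrend_linear(ts).data, 0.0, atol=1e-12)

    def test_sinusoid_recovered_against_projection_oracle(self):
        t = np.arange(200, dtype=float)
        sig = np.sin(2 * np.pi * t / 40.0)
        ts = make_ts((sig + 0.3 * t + 2.0)[None, :])
        out = pp.detrend_linear(ts)
        # explicit least-squares projection oracle
        design = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(design.T @ design, design.T @ (sig + 0.3 * t + 2.0))
        oracle = sig + 0.3 * t + 2.0 - design @ beta
        assert np.sqrt(np.mean((out.data[0] - oracle) ** 2)) < 1e-8

    def test_idempotent_and_trend_free(self):
        rng = np.random.default_rng(3)
        ts = make_ts(rng.standard_normal((4, 120)))
        once = pp.detrend_linear(ts)
        twice = pp.detrend_linear(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)
        t = np.arange(120)
        for row in once.data:
            slope = np.polyfit(t, row, 1)[0]
            assert abs(slope) < 1e-10
            assert abs(row.mean()) < 1e-10


class TestNuisanceRegression:
    def _confounds(self, n, rng):
        return pd.DataFrame(rng.standard_normal((n, 8)), columns=CONFOUND_COLUMNS)

    def test_series_equal_to_confound_zeroed(self):
        rng = np.random.default_rng(4)
        conf = self._confounds(80, rng)
        ts = make_ts(conf["wm"].to_numpy()[None, :], confounds=conf)
        out = pp.regress_nuisance(ts, conf)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_orthogonal_confounds_leave_series_demeaned(self):
        n = 64
        t = np.arange(n)
        sig = np.sin(2 * np.pi * t / 8.0) + 5.0
        conf = pd.DataFrame(
            {c: np.cos(2 * np.pi * (k + 1) * t / n) for k, c in enumerate(CONFOUND_COLUMNS)}
        )
        ts = make_ts(sig[None, :], confounds=conf)
        out = pp.regress_nuisance(ts, conf)
        np.testing.assert_allclose(out.data[0], sig - sig.mean(), atol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        conf = self._confounds(100, rng)
        ts = make_ts(rng.standard_normal((6, 100)), confounds=conf)
        out = pp.regress_nuisance(ts, conf)
        design = np.column_stack([np.ones(100), conf.to_numpy()])
        assert np.max(np.abs(design.T @ out.data.T)) < 1e-6

    def test_rank_deficient_design_lists_columns(self):
        rng = np.random.default_rng(6)
        conf = self._confounds(50, rng)
        conf["csf"] = conf["wm"]  # exact collinearity
        ts = make_ts(rng.standard_normal((2, 50)), confounds=conf)
        with pytest.raises(ValueError, match="wm.*csf"):
            pp.regress_nuisance(ts, conf)

    def test_bilateral_design_averages_wm_csf(self):
        rng = np.random.default_rng(7)
        a = make_ts(rng.standard_normal((2, 40)), confounds=self._confounds(40, rng),
                    hemisphere="left")
        b = make_ts(rng.standard_normal((2, 40)), confounds=self._confounds(40, rng),
                    hemisphere="right")
        design = pp.build_nuisance_design(a, b, "bilateral")
        np.testing.assert_allclose(
            design["wm"], (a.confounds["wm"] + b.confounds["wm"]) / 2
        )
        # motion comes from the analyzed hemisphere unchanged
        np.testing.assert_allclose(design["trans_x"], a.confounds["trans_x"])

    def test_contralateral_design_uses_own_hemisphere(self):
        rng = np.random.default_rng(8)
        a = make_ts(rng.standard_normal((2, 40)), confounds=self._confounds(40, rng))
        design = pp.build_nuisance_design(a, None, "contralateral")
        np.testing.assert_allclose(design["wm"], a.confounds["wm"])


class TestBandpass:
    def _sine_ts(self, freq, tr, n=2000):
        t = np.arange(n) * tr
        return make_ts(np.sin(2 * np.pi * freq * t)[None, :], tr=tr)

    def test_in_band_amplitude_retained(self):
        ts = self._sine_ts(0.05, tr=2.0)
        out = pp.bandpass(ts, PreprocessConfig())
        ratio = out.data[0].std() / ts.data[0].std()
        assert abs(ratio - 1.0) < 0.1

    @pytest.mark.parametrize("freq,tr", [(0.005, 2.0), (0.3, 1.0)])
    def test_stop_band_attenuated_20db(self, freq, tr):
        ts = self._sine_ts(freq, tr=tr)
        out = pp.bandpass(ts, PreprocessConfig())
        core = slice(200, 1800)  # avoid edge transients
        ratio = out.data[0][core].std() / ts.data[0][core].std()
        assert 20 * np.log10(1.0 / ratio) >= 20.0

    def test_zero_series_stays_zero(self):
        ts = make_ts(np.zeros((2, 200)))
        np.testing.assert_allclose(pp.bandpass(ts, PreprocessConfig()).data, 0.0)

    def test_band_above_nyquist_rejected(self):
        ts = make_ts(np.random.default_rng(9).standard_normal((1, 100)), tr=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass(ts, PreprocessConfig(band_high_hz=0.3))

    def test_zero_phase_for_in_band_component(self):
        ts = self._sine_ts(0.05, tr=2.0)
        out = pp.bandpass(ts, PreprocessConfig())
        core = slice(200, 1800)
        x, y = ts.data[0][core], out.data[0][core]
        lags = np.arange(-5, 6)
        xc = [np.corrcoef(x, np.roll(y, lag))[0, 1] for lag in lags]
        assert lags[int(np.argmax(xc))] == 0


class TestOrchestration:
    def test_stage_order(self, monkeypatch, control_subject):
        calls = []
        for name in ("discard_and_window", "detrend_linear", "regress_nuisance", "bandpass"):
            real = getattr(pp, name)

            def wrapper(*a, _real=real, _name=name, **k):
                calls.append(_name)
                return _real(*a, **k)

            monkeypatch.setattr(pp, name, wrapper)
        pp.preprocess_timeseries(
            control_subject.hemispheres["left"], PreprocessConfig(), "bilateral",
            other_hemisphere=control_subject.hemispheres["right"],
        )
        # the other hemisphere is windowed too; the analyzed chain order holds
        assert [c for c in calls if c != "discard_and_window"] == [
            "detrend_linear", "regress_nuisance", "bandpass"
        ]
        assert calls[0] == "discard_and_window"

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_roi_labels_and_order_preserved(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"region_{i}" for i in range(5)]
        ts = make_ts(rng.standard_normal((5, 200)) + 100.0, labels=labels)
        cfg = PreprocessConfig(n_discard_volumes=5, analysis_window_seconds=300.0)
        out = pp.preprocess_timeseries(ts, cfg, "contralateral")
        assert out.roi_labels == labels
        assert out.n_volumes == 150
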