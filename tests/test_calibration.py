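import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crcal import (
    CompetingRiskDataset,
    KnotDegeneracyError,
    RiskPredictionSet,
    binned_calibration,
    calibration_curve,
    calibration_metrics,
    cloglog,
    fine_gray,
    predict_cif,
)
from crcal.errors import BinDegeneracyError
from crcal.simulate import DGPConfig, generate


def _self_consistent(n, seed, t_quantile=0.5, **dgp_kwargs):
    """Dataset plus predictions from a Fine-Gray fit on that same dataset."""
    d = generate(DGPConfig(n=n, p=0.5, beta1=1.0, beta2=0.25, seed=seed, **dgp_kwargs))
    fit = fine_gray(d, d.covariate_names)
    t0 = float(np.quantile(d.time, t_quantile))
    return d, predict_cif(fit, d.covariate_matrix(), t0)


class TestCloglog:
    def test_closed_form_values(self):
        assert cloglog([1 - np.exp(-1)])[0] == pytest.approx(0.0, abs=1e-12)
        assert cloglog([0.5])[0] == pytest.approx(np.log(np.log(2)))

    def test_boundaries_are_clipped_finite(self):
        out = cloglog([0.0, 1.0])
        assert np.all(np.isfinite(out))
        assert out[0] == pytest.approx(np.log(-np.log(1 - 1e-10)))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cloglog([-0.1])
        with pytest.raises(ValueError):
            cloglog([1.1])


class TestMetrics:
    def test_printed_example(self):
        m = calibration_metrics([0.10, 0.20, 0.30, 0.40], [0.12, 0.18, 0.36, 0.38])
        assert m.ici == pytest.approx(0.03)
        assert m.e50 == pytest.approx(0.02)
        assert m.e90 == pytest.approx(0.048)
        assert m.emax == pytest.approx(0.06)

    def test_perfect_calibration_is_all_zero(self):
        p = np.linspace(0.05, 0.9, 13)
        assert calibration_metrics(p, p).as_tuple() == (0, 0, 0, 0)

    def test_one_signed_shift_moves_ici_exactly(self):
        pred = np.array([0.1, 0.2, 0.3])
        obs = pred + 0.02
        m0 = calibration_metrics(pred, obs)
        m1 = calibration_metrics(pred, obs + 0.05)
        assert m1.ici == pytest.approx(m0.ici + 0.05)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            calibration_metrics([0.1, 0.2], [0.1])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
    )
    def test_metric_ordering_invariants(self, pred, obs):
        n = min(len(pred), len(obs))
        m = calibration_metrics(pred[:n], obs[:n])
        assert m.e50 <= m.e90 + 1e-12
        assert m.e90 <= m.emax + 1e-12
        assert m.ici <= m.emax + 1e-12


class TestCalibrationCurve:
    def test_self_consistent_predictions_near_diagonal(self):
        d, preds = _self_consistent(10_000, seed=21)
        res = calibration_curve(d, preds, n_knots=3)
        assert np.max(np.abs(res.curve_observed - res.curve_predicted)) < 0.02
        assert res.metrics.ici < 0.01

    def test_three_knots_give_two_covariate_columns(self):
        d, preds = _self_consistent(500, seed=22)
        res = calibration_curve(d, preds, n_knots=3)
        assert len(res.fit.covariate_names) == 2

    @pytest.mark.parametrize("k", [4, 5])
    def test_more_knots_add_columns(self, k):
        d, preds = _self_consistent(500, seed=23)
        res = calibration_curve(d, preds, n_knots=k)
        assert len(res.fit.covariate_names) == k - 1

    def test_observed_in_unit_interval(self):
        d, preds = _self_consistent(1000, seed=24, censor_proportion=0.3)
        res = calibration_curve(d, preds)
        assert np.all((res.observed_smoothed >= 0) & (res.observed_smoothed <= 1))

    def test_constant_predictions_degenerate(self):
        d = generate(DGPConfig(n=100, seed=25))
        preds = RiskPredictionSet(float(np.median(d.time)), np.full(100, 0.3))
        with pytest.raises(KnotDegeneracyError):
            calibration_curve(d, preds)

    def test_permutation_invariance(self):
        d, preds = _self_consistent(800, seed=26)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(d))
        d_p = d.subset(perm)
        preds_p = RiskPredictionSet(preds.horizon_t0, preds.predicted[perm])
        a = calibration_curve(d, preds)
        b = calibration_curve(d_p, preds_p)
        assert b.metrics.as_tuple() == pytest.approx(a.metrics.as_tuple(), abs=1e-10)
        assert b.curve_observed == pytest.approx(a.curve_observed, abs=1e-10)

    def test_metrics_use_subjects_not_grid(self):
        d, preds = _self_consistent(800, seed=27)
        res = calibration_curve(d, preds)
        direct = calibration_metrics(res.predicted, res.observed_smoothed)
        assert res.metrics.as_tuple() == direct.as_tuple()

    def test_admin_censoring_option_runs_and_differs(self):
        d, preds = _self_consistent(1500, seed=28, t_quantile=0.4)
        plain = calibration_curve(d, preds)
        admin = calibration_curve(d, preds, administrative_censor_at_t0=True)
        # both near-diagonal for a correct model; fits differ but agree closely
        assert admin.metrics.ici < 0.05
        assert not np.array_equal(plain.observed_smoothed, admin.observed_smoothed)

    def test_grid_spans_1st_to_99th_percentile(self):
        d, preds = _self_consistent(1000, seed=29)
        res = calibration_curve(d, preds)
        lo, hi = np.percentile(preds.predicted, [1, 99])
        assert res.curve_predicted[0] == pytest.approx(lo)
        assert res.curve_predicted[-1] == pytest.approx(hi)
        assert len(res.curve_predicted) == 100


class TestBinnedCalibration:
    def test_counts_balanced_for_distinct_predictions(self):
        d, preds = _self_consistent(1000, seed=30)
        b = binned_calibration(d, preds, n_bins=10)
        assert b.counts.sum() == 1000
        assert b.counts.max() - b.counts.min() <= 1

    def test_near_diagonal_for_correct_model(self):
        d, preds = _self_consistent(20_000, seed=31)
        b = binned_calibration(d, preds, n_bins=10)
        central = slice(2, 8)
        assert np.max(
            np.abs(b.observed[central] - b.mean_predicted[central])
        ) < 0.03

    def test_ties_not_split(self):
        d = generate(DGPConfig(n=100, seed=32))
        pred = np.repeat([0.1, 0.2, 0.3, 0.4], 25)
        b = binned_calibration(
            d, RiskPredictionSet(float(np.median(d.time)), pred), n_bins=4
        )
        assert b.counts.tolist() == [25, 25, 25, 25]

    def test_too_many_bins_for_ties_degenerate(self):
        d = generate(DGPConfig(n=100, seed=33))
        pred = np.repeat([0.1, 0.9], 50)
        with pytest.raises(BinDegeneracyError):
            binned_calibration(
                d, RiskPredictionSet(float(np.median(d.time)), pred), n_bins=4
            )
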