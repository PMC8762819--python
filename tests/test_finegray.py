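import numpy as np
import pandas as pd
import pytest

from crcal import (
    CompetingRiskDataset,
    DegenerateWeightError,
    FineGrayFit,
    StepFunction,
    expand_weighted,
    fine_gray,
    fit_weighted_cox,
    predict_cif,
)
from crcal.simulate import DGPConfig, generate, true_cif


def _cox_lifelines(df, duration="time", event="event", covs=("x",)):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter().fit(
        df[[duration, event, *covs]], duration, event,
        fit_options={"precision": 1e-10, "max_steps": 500},
    )
    return cph.params_.to_numpy()


class TestExpansion:
    def test_identity_without_competing_events(self):
        d = generate(DGPConfig(n=100, p=1.0, seed=0))
        assert np.all(d.status == 1)
        rows = expand_weighted(d)
        assert len(rows) == 100
        assert np.all(rows.weight == 1.0)
        assert np.all(rows.start == 0.0)
        assert np.array_equal(rows.stop, d.time)

    def test_hand_example_weight(self, four_record_expansion):
        rows = expand_weighted(four_record_expansion)
        df = rows.to_frame()
        # competing subject (T=2) stays at risk; at primary-event time 4 its
        # weight is G(4-)/G(2-) = (1/2)/1
        ext = df[(df.subject_id == 1) & (df.start > 0)]
        covering4 = ext[(ext.start < 4.0) & (ext.stop >= 4.0)]
        assert len(covering4) == 1
        assert covering4.weight.iloc[0] == pytest.approx(0.5)
        # status 0/1 subjects contribute exactly one row with weight 1
        for sid in (0, 2, 3):
            sub = df[df.subject_id == sid]
            assert len(sub) == 1 and sub.weight.iloc[0] == 1.0

    def test_weights_nonincreasing_within_subject(self):
        d = generate(DGPConfig(n=400, censor_proportion=0.4, seed=6))
        df = expand_weighted(d).to_frame().sort_values(["subject_id", "start"])
        for _, g in df.groupby("subject_id"):
            assert np.all(np.diff(g.weight.to_numpy()) <= 1e-12)

    def test_intervals_disjoint_and_contiguous(self):
        d = generate(DGPConfig(n=200, censor_proportion=0.3, seed=7))
        df = expand_weighted(d).to_frame().sort_values(["subject_id", "start"])
        for _, g in df.groupby("subject_id"):
            assert np.all(g.stop.to_numpy() > g.start.to_numpy())
            assert np.allclose(g.start.to_numpy()[1:], g.stop.to_numpy()[:-1])

    def test_zero_G_raises_degenerate_weight(self):
        # a censoring survival that has already hit 0 before a competing
        # event leaves that subject's weight undefined
        d = CompetingRiskDataset(
            np.arange(3), [1.0, 2.0, 3.0], [1, 2, 1]
        )
        G0 = StepFunction([1.5], [0.0], initial_value=1.0)
        with pytest.raises(DegenerateWeightError):
            expand_weighted(d, G=G0)

    def test_granularities_give_identical_fits(self):
        d = generate(DGPConfig(n=300, censor_proportion=0.3, seed=11))
        fits = [
            fit_weighted_cox(expand_weighted(d, granularity=g), ["x"])
            for g in ("censoring", "event")
        ]
        assert fits[0].coefficients == pytest.approx(fits[1].coefficients, abs=1e-12)
        assert fits[0].log_partial_likelihood == pytest.approx(
            fits[1].log_partial_likelihood
        )


class TestWeightedCox:
    def test_reduces_to_cox_without_competing_events(self):
        for seed in range(5):
            d = generate(DGPConfig(n=300, p=1.0, beta1=0.7, seed=seed))
            fit = fine_gray(d, ["x"])
            df = d.to_frame().assign(event=1)
            expected = _cox_lifelines(df)
            assert fit.coefficients == pytest.approx(expected, abs=1e-6)

    def test_no_censoring_equals_cox_with_retained_competing(self):
        """With no censoring the Fine-Gray risk set is a Cox risk set in
        which competing-event subjects never leave."""
        for seed in range(5):
            d = generate(DGPConfig(n=500, p=0.5, beta1=1.0, beta2=0.25, seed=seed))
            fg = fine_gray(d, ["x"])
            df = d.to_frame()
            df["event"] = (df.status == 1).astype(int)
            df.loc[df.status == 2, "time"] = df.time.max() + 1.0
            expected = _cox_lifelines(df)
            assert fg.coefficients == pytest.approx(expected, abs=1e-6)

    def test_four_subject_brute_force(self):
        """beta-hat maximizes the explicit 4-term partial likelihood."""
        d = CompetingRiskDataset(
            np.arange(4), [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
            pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]}),
        )
        fit = fine_gray(d, ["x"])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def pl(beta):
            ll = 0.0
            for i in range(4):
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[i:])))
            return ll

        grid = np.linspace(-5, 5, 200_001)
        best = grid[np.argmax([pl(b) for b in grid])]
        assert fit.coefficients[0] == pytest.approx(best, abs=1e-4)

    def test_sign_symmetry(self):
        d = generate(DGPConfig(n=300, p=0.5, seed=12))
        fit = fine_gray(d, ["x"])
        d_neg = CompetingRiskDataset(
            d.subject_id, d.time, d.status, -d.covariates
        )
        fit_neg = fine_gray(d_neg, ["x"])
        assert fit_neg.coefficients[0] == pytest.approx(-fit.coefficients[0], abs=1e-9)

    def test_converged_fits_have_small_gradient_proxy(self):
        d = generate(DGPConfig(n=500, censor_proportion=0.2, seed=13))
        fit = fine_gray(d, ["x"])
        assert fit.converged
        assert fit.iterations <= 50
        assert fit.info_diagonal is not None and np.all(fit.info_diagonal > 0)

    def test_parameter_recovery_no_censoring(self):
        betas = [
            fine_gray(generate(DGPConfig(n=2000, p=0.5, beta1=1.0, beta2=0.25,
                                         seed=s)), ["x"]).coefficients[0]
            for s in range(30)
        ]
        assert np.mean(betas) == pytest.approx(1.0, abs=0.05)


class TestPredictCIF:
    def test_zero_before_first_event(self, four_record_expansion):
        fit = fine_gray(
            CompetingRiskDataset(
                four_record_expansion.subject_id,
                four_record_expansion.time,
                four_record_expansion.status,
                pd.DataFrame({"x": [0.5, -0.5, 1.0, 0.0]}),
            ),
            ["x"],
        )
        assert np.all(predict_cif(fit, [[0.3]], 0.5).predicted == 0.0)

    def test_monotone_in_t0(self):
        d = generate(DGPConfig(n=400, p=0.5, seed=14))
        fit = fine_gray(d, ["x"])
        X = d.covariate_matrix(["x"])[:20]
        grid = np.quantile(d.time, np.linspace(0.05, 0.95, 10))
        preds = np.column_stack([predict_cif(fit, X, t).predicted for t in grid])
        assert np.all(np.diff(preds, axis=1) >= -1e-15)

    def test_large_sample_matches_true_cif_at_x0(self):
        d = generate(DGPConfig(n=20_000, p=0.5, beta1=1.0, beta2=0.25, seed=15))
        fit = fine_gray(d, ["x"])
        t50 = np.percentile(d.time, 50)
        pred = predict_cif(fit, [[0.0]], float(t50)).predicted[0]
        assert pred == pytest.approx(true_cif(0.0, t50, 0.5, 1.0), abs=0.02)

    def test_cif_at_last_event_time_near_p_for_x0(self):
        d = generate(DGPConfig(n=20_000, p=0.5, beta1=1.0, beta2=0.25, seed=16))
        fit = fine_gray(d, ["x"])
        tmax = d.time[d.status == 1].max()
        pred = predict_cif(fit, [[0.0]], float(tmax)).predicted[0]
        assert pred == pytest.approx(0.5, abs=0.03)


class TestFitSerialization:
    def test_json_round_trip(self):
        d = generate(DGPConfig(n=200, censor_proportion=0.2, seed=17))
        fit = fine_gray(d, ["x"])
        restored = FineGrayFit.from_json(fit.to_json())
        assert restored.coefficients == pytest.approx(fit.coefficients)
        assert restored.covariate_names == fit.covariate_names
        assert restored.converged == fit.converged
        t = np.linspace(0.1, d.time.max(), 20)
        assert restored.baseline_cum_hazard(t) == pytest.approx(
            fit.baseline_cum_hazard(t)
        )

    def test_baseline_is_nondecreasing_from_zero(self):
        d = generate(DGPConfig(n=300, censor_proportion=0.3, seed=18))
        fit = fine_gray(d, ["x"])
        lam = fit.baseline_cum_hazard
        assert lam(0.0) == 0.0
        assert np.all(np.diff(lam.values) >= 0)
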