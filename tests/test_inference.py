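"""Fitting machinery: objective arithmetic, recovery, nesting, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tchase.cohort import generate_cohort
from tchase.inference import (
    FitResult,
    FitSpec,
    bootstrap,
    f_test_nested,
    fit_model,
    fit_nested_pair,
    transformed_ssr,
)
from tchase.preprocess import derive_observables


class TestTransformedSSR:
    def test_perfect_fit_is_zero(self):
        assert transformed_ssr([1.0, 2.0], [1.0, 2.0], "log") == 0.0

    def test_log_hand_evaluation(self):
        assert transformed_ssr([10.0], [1.0], "log") == pytest.approx(np.log(10) ** 2)

    def test_logit_antisymmetry_about_half(self):
        a = transformed_ssr([0.2], [0.4], "logit")
        b = transformed_ssr([0.8], [0.6], "logit")
        assert a == pytest.approx(b)

    def test_missing_observations_skipped(self):
        full = transformed_ssr([0.1, np.nan, 0.3], [0.2, 0.2, 0.2], "logit")
        part = transformed_ssr([0.1, 0.3], [0.2, 0.2], "logit")
        assert full == pytest.approx(part)

    @settings(max_examples=30, derandomize=True)
    @given(
        o=st.floats(0.01, 0.99),
        p=st.floats(0.01, 0.99),
    )
    def test_nonnegative_and_zero_iff_equal(self, o, p):
        s = transformed_ssr([o], [p], "logit")
        assert s >= 0.0
        if o == p:
            assert s == 0.0

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            transformed_ssr([1.0], [1.0], "sqrt")


class TestZeroNoiseRecovery:
    def test_frequency_separate_and_simultaneous_agree(self, design, freq_truth_quiet):
        obs = derive_observables(generate_cohort(freq_truth_quiet, design, seed=2))
        obs = obs[obs.lineage == "CD4"]
        truth = freq_truth_quiet.lineages["CD4"].kinetic
        for strategy in ("separate", "simultaneous"):
            fit = fit_model(
                FitSpec(model="frequency_p0", strategy=strategy, n_starts=30,
                        n_refine=3, seed=4),
                obs,
            )
            assert fit.estimates["theta"] == pytest.approx(truth.theta, rel=1e-3)
            assert fit.estimates["mu"] == pytest.approx(truth.mu, rel=1e-3)

    def test_ki67_full_simultaneous_recovers_all_rates(self, quiet_obs_cd4,
                                                       ki67_truth_quiet):
        truth = ki67_truth_quiet.lineages["CD4"].kinetic
        fit = fit_model(
            FitSpec(model="ki67_full", strategy="simultaneous", n_starts=60,
                    n_refine=3, seed=4),
            quiet_obs_cd4,
        )
        for name, val in [("theta", truth.theta), ("mu", truth.mu),
                          ("p", truth.p), ("beta", truth.beta)]:
            assert fit.estimates[name] == pytest.approx(val, rel=1e-3)


class TestObjectiveProperties:
    def test_row_order_invariance(self, noisy_obs_cd4):
        spec = FitSpec(model="frequency_p0", strategy="separate", n_starts=20,
                       n_refine=2, seed=5)
        shuffled = noisy_obs_cd4.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = fit_model(spec, noisy_obs_cd4)
        b = fit_model(spec, shuffled)
        # the objective is exactly order-invariant; the optimizer's float
        # path may differ negligibly, so the optimum is compared loosely
        ssr = transformed_ssr(
            noisy_obs_cd4.sort_values("mouse_id")["l"],
            shuffled.sort_values("mouse_id")["l"],
            "logit",
        )
        assert ssr == 0.0
        assert a.rss == pytest.approx(b.rss, rel=1e-4)
        assert a.estimates["mu"] == pytest.approx(b.estimates["mu"], rel=1e-3)

    def test_determinism_under_seed(self, noisy_obs_cd4):
        spec = FitSpec(model="ki67_p0", strategy="separate", n_starts=15,
                       n_refine=2, seed=9)
        a = fit_model(spec, noisy_obs_cd4)
        b = fit_model(spec, noisy_obs_cd4)
        assert a.estimates == b.estimates

    def test_more_starts_never_worse(self, noisy_obs_cd4):
        base = fit_model(
            FitSpec(model="frequency_p0", strategy="separate", n_starts=15,
                    n_refine=3, seed=6),
            noisy_obs_cd4,
        )
        more = fit_model(
            FitSpec(model="frequency_p0", strategy="separate", n_starts=30,
                    n_refine=6, seed=6),
            noisy_obs_cd4,
        )
        assert more.rss <= base.rss * (1 + 1e-8)


class TestNestedComparison:
    def test_f_statistic_hand_arithmetic(self):
        fit0 = FitResult(estimates={}, rss=12.0, n_obs=60, n_params=2,
                         stream_rss={}, residuals={}, converged=True, seed=0,
                         best_start=0, model="ki67_p0", strategy="separate",
                         at_bounds=[], sources={})
        fit1 = FitResult(estimates={}, rss=10.0, n_obs=60, n_params=3,
                         stream_rss={}, residuals={}, converged=True, seed=0,
                         best_start=0, model="ki67_full", strategy="separate",
                         at_bounds=[], sources={})
        F, p = f_test_nested(fit0, fit1)
        assert F == pytest.approx(2.0 / (10.0 / 57.0))
        # frozen from R: 1 - pf(2/(10/57), 1, 57)
        assert p == pytest.approx(0.0013281732, rel=1e-6)

    def test_no_improvement_gives_f_zero_p_one(self):
        kw = dict(estimates={}, stream_rss={}, residuals={}, converged=True,
                  seed=0, best_start=0, strategy="separate", at_bounds=[],
                  sources={})
        fit0 = FitResult(rss=5.0, n_obs=40, n_params=2, model="ki67_p0", **kw)
        fit1 = FitResult(rss=5.0, n_obs=40, n_params=3, model="ki67_full", **kw)
        F, p = f_test_nested(fit0, fit1)
        assert F == 0.0 and p == pytest.approx(1.0)

    def test_non_nested_inputs_rejected(self):
        kw = dict(estimates={}, stream_rss={}, residuals={}, converged=True,
                  seed=0, best_start=0, strategy="separate", at_bounds=[],
                  sources={})
        fit0 = FitResult(rss=5.0, n_obs=40, n_params=3, model="a", **kw)
        fit1 = FitResult(rss=4.0, n_obs=40, n_params=3, model="b", **kw)
        with pytest.raises(ValueError):
            f_test_nested(fit0, fit1)

    def test_full_model_never_fits_worse(self, noisy_obs_cd4):
        fit0, fit1, F, p = fit_nested_pair(
            noisy_obs_cd4, strategy="separate", n_starts=12, n_refine=2,
            seed=3, h=0.25,
        )
        assert fit1.rss <= fit0.rss + 1e-12
        assert F >= 0.0 and 0.0 <= p <= 1.0


class TestBootstrap:
    def test_determinism_and_ci_ordering(self, noisy_obs_cd4):
        spec = FitSpec(model="frequency_p0", strategy="separate", n_starts=15,
                       n_refine=2, seed=2, h=0.25)
        base = fit_model(spec, noisy_obs_cd4)
        a = bootstrap(spec, noisy_obs_cd4, n_boot=8, seed=21, base_fit=base)
        b = bootstrap(spec, noisy_obs_cd4, n_boot=8, seed=21, base_fit=base)
        assert a.replicates.equals(b.replicates)
        for lo, hi in a.ci.values():
            assert lo <= hi

    def test_replicates_vary_across_resamples(self, noisy_obs_cd4):
        spec = FitSpec(model="frequency_p0", strategy="separate", n_starts=15,
                       n_refine=2, seed=2, h=0.25)
        boot = bootstrap(spec, noisy_obs_cd4, n_boot=8, seed=21)
        assert boot.replicates["theta"].nunique() > 1


class TestValidation:
    def test_single_lineage_required(self, design):
        from tchase.cohort import default_truth

        obs = derive_observables(generate_cohort(default_truth("ki67"), design, 1))
        with pytest.raises(ValueError):
            fit_model(FitSpec(model="counts_p0"), obs)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(model="magic")

    def test_too_few_observations_rejected(self, noisy_obs_cd4):
        tiny = noisy_obs_cd4.iloc[:1]
        with pytest.raises((ValueError, RuntimeError)):
            fit_model(
                FitSpec(model="frequency_p0", strategy="separate", n_starts=5,
                        n_refine=1, seed=0),
                tiny,
            )
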