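"""Forward-model tests: closed forms, independent ODE oracles, equivalences."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tchase.kinetics import (
    KineticParams,
    predict_ki67_fraction,
    simulate_ki67_split,
    simulate_labeled_counts,
    simulate_labeled_frequency,
    simulate_recast,
)
from tchase.sources import BumpSourceParams, bump_curve

TS = np.array([0.0, 0.7, 4.0, 13.5, 33.0, 66.0])


def const(value):
    return lambda t: np.full_like(np.asarray(t, dtype=float), value)


class TestLabeledCounts:
    def test_no_source_no_label(self):
        par = KineticParams(theta=0.0, mu=0.05)
        assert np.allclose(simulate_labeled_counts(par, const(100.0), TS, L0=0.0), 0.0)

    def test_constant_source_steady_state(self):
        par = KineticParams(theta=1.0, mu=0.1)
        L = simulate_labeled_counts(par, const(100.0), np.array([400.0]))
        assert L[0] == pytest.approx(1000.0, rel=1e-8)

    def test_constant_source_closed_form(self):
        """L(t) = theta Y/mu + (L0 - theta Y/mu) e^{-mu t}, any L0."""
        par = KineticParams(theta=0.7, mu=0.04)
        for L0 in (0.0, 250.0, 5000.0):
            L = simulate_labeled_counts(par, const(180.0), TS, L0=L0)
            ss = par.theta * 180.0 / par.mu
            exact = ss + (L0 - ss) * np.exp(-par.mu * TS)
            assert np.allclose(L, exact, rtol=1e-6)


class TestLabeledFrequency:
    def test_pure_decay_without_source(self):
        par = KineticParams(theta=0.5, mu=0.03)
        ell = simulate_labeled_frequency(par, const(0.0), TS, l0=0.1)
        assert np.allclose(ell, 0.1 * np.exp(-par.mu * TS), rtol=1e-9)

    def test_constant_ratio_steady_state(self):
        par = KineticParams(theta=0.6, mu=0.05)
        ell = simulate_labeled_frequency(par, const(2e-3), np.array([600.0]))
        assert ell[0] == pytest.approx(0.6 * 2e-3 / 0.05, rel=1e-8)

    def test_agrees_with_count_model_at_steady_pool(self):
        """With Z = Y/N and constant N, the frequency solution equals the
        count solution divided by N, pointwise."""
        par = KineticParams(theta=0.59, mu=1 / 35)
        N = 2e7
        bump = BumpSourceParams(Y0=3000.0, a=-2000.0, b=2.0, c=0.2)
        ell = simulate_labeled_frequency(par, lambda t: bump_curve(bump, t) / N, TS)
        L = simulate_labeled_counts(par, lambda t: bump_curve(bump, t), TS)
        assert np.allclose(ell, L / N, rtol=1e-10)


class TestKi67Split:
    def test_decoupled_exponential_decay(self):
        par = KineticParams(theta=0.0, mu=0.08, p=0.0, beta=0.0)
        out = simulate_ki67_split(par, const(0.0), const(0.0), TS, x0=(40.0, 160.0))
        assert np.allclose(out[:, 0], 40.0 * np.exp(-0.08 * TS), rtol=1e-8)
        assert np.allclose(out[:, 1], 160.0 * np.exp(-0.08 * TS), rtol=1e-8)

    def test_total_decay_insensitive_to_beta(self):
        """With no source and no division, beta only shuffles cells between
        Ki67 states: L = L+ + L- decays exactly at rate mu."""
        par = KineticParams(theta=0.0, mu=0.05, p=0.0, beta=0.7)
        out = simulate_ki67_split(par, const(0.0), const(0.0), TS, x0=(30.0, 70.0))
        assert np.allclose(out.sum(axis=1), 100.0 * np.exp(-0.05 * TS), rtol=1e-8)

    def test_division_feeds_ki67_positive_at_twice_p(self):
        par = KineticParams(theta=0.0, mu=0.0, p=0.01, beta=0.0)
        dt = 1e-3
        out = simulate_ki67_split(
            par, const(0.0), const(0.0), np.array([dt]), x0=(0.0, 1000.0)
        )
        assert out[0, 0] / dt == pytest.approx(2 * par.p * 1000.0, rel=1e-3)

    def test_matches_adaptive_integrator(self):
        """Independent oracle: scipy's stiff-capable solver on the same RHS."""
        par = KineticParams(theta=0.84, mu=1 / 21, p=1 / 300, beta=1 / 1.7)
        kp = BumpSourceParams(Y0=600.0, a=-1600.0, b=2.0, c=0.25)
        km = BumpSourceParams(Y0=2400.0, a=-400.0, b=2.0, c=0.2)

        def rhs(t, x):
            kpv = bump_curve(kp, t)
            kmv = bump_curve(km, t)
            return [
                par.theta * kpv - x[0] * (par.mu + par.beta)
                + par.p * (2 * x[1] + x[0]),
                par.theta * kmv - x[1] * (par.mu + par.p) + par.beta * x[0],
            ]

        ref = solve_ivp(rhs, (0, 66), [0, 0], t_eval=TS, rtol=1e-10, atol=1e-12,
                        method="LSODA")
        out = simulate_ki67_split(
            par, lambda t: bump_curve(kp, t), lambda t: bump_curve(km, t), TS
        )
        assert np.allclose(out.T[:, 1:], ref.y[:, 1:], rtol=1e-7)

    def test_halving_step_changes_nothing_measurable(self):
        par = KineticParams(theta=0.84, mu=1 / 21, p=1 / 300, beta=1 / 1.7)
        kp = BumpSourceParams(Y0=600.0, a=-1600.0, b=2.0, c=0.25)
        km = BumpSourceParams(Y0=2400.0, a=-400.0, b=2.0, c=0.2)
        args = (par, lambda t: bump_curve(kp, t), lambda t: bump_curve(km, t), TS[1:])
        a = simulate_ki67_split(*args, h=0.05)
        b = simulate_ki67_split(*args, h=0.025)
        assert np.allclose(a, b, rtol=1e-6)


class TestRecast:
    def test_all_ki67_positive_input_saturates(self):
        """K+ = Y with no Ki67 loss and no division: every labeled cell is
        Ki67+, so l+ -> 1."""
        par = KineticParams(theta=0.5, mu=0.05, p=0.0, beta=0.0)
        Y = const(1000.0)
        _, lplus = simulate_recast(par, Y, Y, np.array([5.0, 30.0]))
        assert np.allclose(lplus, 1.0, atol=1e-9)

    def test_source_free_ki67_fraction_decays_at_beta(self):
        par = KineticParams(theta=0.0, mu=0.04, p=0.0, beta=0.3)
        L, lplus = simulate_recast(
            par, const(0.0), const(0.0), TS, x0=(60.0, 40.0)
        )
        assert np.allclose(lplus, 0.6 * np.exp(-par.beta * TS), rtol=1e-8)

    def test_undefined_fraction_reported_missing_at_empty_start(self):
        par = KineticParams(theta=0.5, mu=0.05, p=0.0, beta=0.2)
        _, lplus = simulate_recast(par, const(10.0), const(5.0), np.array([0.0, 1.0]))
        assert np.isnan(lplus[0]) and np.isfinite(lplus[1])

    def test_kplus_clamped_to_total(self):
        """A K+ curve exceeding Y is clamped, keeping l+ within [0, 1]."""
        par = KineticParams(theta=0.5, mu=0.05, p=0.0, beta=0.1)
        _, lplus = simulate_recast(par, const(100.0), const(500.0), TS[1:])
        assert np.all(lplus <= 1.0 + 1e-12)


class TestKi67Prediction:
    def test_no_input_no_ki67(self):
        assert predict_ki67_fraction(1.0, 0.25, 0.0, 0.0, 1e6) == 0.0

    def test_direct_arithmetic(self):
        assert predict_ki67_fraction(1.0, 0.25, 0.0, 1e3, 1e6) == pytest.approx(4e-3)

    def test_count_and_fraction_forms_agree(self):
        theta, beta, p, kmsp, N = 0.8, 0.4, 0.002, 5e3, 2e7
        frac = predict_ki67_fraction(theta, beta, p, kmsp, N)
        count_form = theta * kmsp / beta + 2 * p * N / beta
        assert frac * N == pytest.approx(count_form, rel=1e-12)

    def test_rejects_degenerate_rates(self):
        with pytest.raises(ValueError):
            predict_ki67_fraction(1.0, 0.0, 0.0, 1e3, 1e6)
        with pytest.raises(ValueError):
            predict_ki67_fraction(1.0, 0.3, 0.0, 1e3, 0.0)

    def test_quasi_steady_state_matches_full_dynamics(self):
        """Long-time Ki67+ fraction of the full bulk dynamics agrees with the
        closed-form prediction within 10% when beta >> mu, p and the thymic
        sources are constant."""
        theta, mu, p, beta = 0.8, 0.02, 0.001, 0.5
        msp, kfrac, = 1e6, 0.35
        kplus_msp = kfrac * msp
        par = KineticParams(theta=theta, mu=mu, p=p, beta=beta)
        out = simulate_ki67_split(
            par, const(kplus_msp), const(msp - kplus_msp), np.array([600.0])
        )
        N_ss = out.sum()
        k_full = out[0, 0] / N_ss
        k_qss = predict_ki67_fraction(theta, beta, p, kplus_msp, N_ss)
        assert k_full == pytest.approx(k_qss, rel=0.10)
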