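"""Bik turnover model: steady states, chase decay, hypothesis profile, fitting."""


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from apoptosim.bik import (
    PARENTAL_BIK,
    SRC_BIK,
    BikParams,
    BikState,
    DecayTimecourse,
    accumulation_profile,
    apply_herbimycin,
    bik_rhs,
    bik_steady_state,
    decay_curve,
    fit_bik_params,
    src_vmax_for_steady_state,
)
from apoptosim.synth import NoiseModel, gen_bik_decay

valid_params = st.builds(
    BikParams,
    k_syn=st.floats(0.001, 1.0),
    k_ubi=st.floats(1e-4, 0.1),
    v_max=st.floats(0.0, 1.0),
    k_m=st.floats(0.1, 200.0),
)


class TestRhs:
    def test_zero_at_analytic_steady_state(self):
        for p in (PARENTAL_BIK, SRC_BIK, BikParams(0.2, 0.01, 0.5, 30.0)):
            ss = bik_steady_state(p)
            d_bik, d_ub = bik_rhs(ss, p)
            assert abs(d_bik) < 1e-9 and abs(d_ub) < 1e-9

    def test_parental_steady_state_is_50nM(self):
        # synthesis balances spontaneous ubiquitylation at the anchored level
        d_bik, _ = bik_rhs(BikState(bik=50.0), PARENTAL_BIK)
        assert d_bik == pytest.approx(0.0, abs=1e-12)

    def test_src_balance_at_9p2nM(self):
        p = BikParams(k_syn=0.139, k_ubi=1 / 360, v_max=0.36, k_m=20.0)
        d_bik, _ = bik_rhs(BikState(bik=9.2), p)
        assert abs(d_bik) < 1e-3

    def test_rejects_negative_state(self):
        with pytest.raises(ValueError):
            BikState(bik=-1.0)
        with pytest.raises(ValueError):
            BikParams(k_syn=-0.1, k_ubi=0.01)


class TestSteadyState:
    def test_parental_is_50(self):
        assert bik_steady_state(PARENTAL_BIK).bik == pytest.approx(50.0)

    def test_zero_synthesis_gives_zero(self):
        assert bik_steady_state(BikParams(0.0, 0.01)).bik == 0.0

    def test_src_over_parental_ratio(self):
        ratio = bik_steady_state(SRC_BIK).bik / bik_steady_state(PARENTAL_BIK).bik
        assert ratio == pytest.approx(0.18, abs=0.005)

    def test_no_removal_raises(self):
        with pytest.raises(ValueError):
            bik_steady_state(BikParams(0.1, 0.0, 0.0, 1.0))

    @settings(max_examples=30, deadline=None)
    @given(valid_params)
    def test_matches_long_integration(self, p):
        """The closed-form fixed point is where the ODE actually converges."""
        ss = bik_steady_state(p)

        def rhs(_t, y):
            return bik_rhs(BikState(bik=max(y[0], 0.0), bik_ub=max(y[1], 0.0)), p)

        # horizon scaled to the slowest relaxation rate so every parameter
        # set gets enough e-folds to reach the fixed point numerically
        k_eff = p.k_ubi + p.v_max * p.k_m / (p.k_m + ss.bik) ** 2
        t_end = max(5000.0, 35.0 / k_eff)
        sol = solve_ivp(rhs, (0, t_end), [ss.bik * 0.1 + 1.0, 0.0],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert abs(sol.y[0, -1] - ss.bik) < 1e-6

    @settings(max_examples=20, deadline=None)
    @given(valid_params)
    def test_flux_balance_of_ubiquitylated_pool(self, p):
        """At steady state, total degradation k_deg*BikUb equals synthesis."""
        ss = bik_steady_state(p)
        assert p.k_deg * ss.bik_ub == pytest.approx(p.k_syn, rel=1e-6)

    def test_monotone_in_each_parameter(self):
        base = dict(k_syn=0.14, k_ubi=1 / 360, v_max=0.3, k_m=20.0)
        ss = lambda **kw: bik_steady_state(BikParams(**{**base, **kw})).bik
        grid = np.linspace(0.5, 2.0, 5)
        assert all(np.diff([ss(k_ubi=base["k_ubi"] * g) for g in grid]) < 0)
        assert all(np.diff([ss(v_max=base["v_max"] * g) for g in grid]) < 0)
        assert all(np.diff([ss(k_syn=base["k_syn"] * g) for g in grid]) > 0)
        assert all(np.diff([ss(k_m=base["k_m"] * g) for g in grid]) > 0)


class TestAccumulationProfile:
    def test_identity_at_t0(self):
        assert accumulation_profile(0.0, 37.0, 0.2) == 37.0

    def test_parental_doubles_in_six_hours(self):
        # the prediction that ruled the accumulation hypothesis out
        out = accumulation_profile(360.0, 50.0, PARENTAL_BIK.k_syn)
        assert out == pytest.approx(100.0)

    def test_closed_form_at_12h(self):
        assert accumulation_profile(720.0, 50.0, 0.139) == pytest.approx(150.08)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            accumulation_profile(-1.0, 50.0, 0.1)


class TestHerbimycin:
    def test_zero_inhibition_is_identity(self):
        assert apply_herbimycin(SRC_BIK, 0.0) == SRC_BIK

    def test_default_scales_vmax_by_002(self):
        out = apply_herbimycin(SRC_BIK)
        assert out.v_max == pytest.approx(SRC_BIK.v_max * 0.02)
        assert (out.k_syn, out.k_ubi, out.k_m) == (SRC_BIK.k_syn, SRC_BIK.k_ubi, SRC_BIK.k_m)

    def test_full_inhibition_restores_parental_steady_state(self):
        ss = bik_steady_state(apply_herbimycin(SRC_BIK, 1.0)).bik
        assert ss == pytest.approx(50.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_herbimycin(SRC_BIK, 1.5)


class TestDecayAndVmaxHelper:
    def test_parental_decay_is_exponential(self):
        t = np.array([0.0, 60.0, 180.0, 360.0])
        assert decay_curve(PARENTAL_BIK, t) == pytest.approx(np.exp(-PARENTAL_BIK.k_ubi * t))

    def test_src_decays_faster_than_parental(self):
        t = np.linspace(0, 360, 13)
        src, par = decay_curve(SRC_BIK, t), decay_curve(PARENTAL_BIK, t)
        assert np.all(src[1:] < par[1:])

    def test_src_vmax_reproduces_target(self):
        v = src_vmax_for_steady_state(9.2, k_m=20.0)
        assert bik_steady_state(BikParams(50 / 360, 1 / 360, v, 20.0)).bik == pytest.approx(9.2)


class TestFit:
    def test_noise_free_recovery(self):
        """kubi and the lumped Src sink recover to <=5% from clean chases."""
        courses = [
            gen_bik_decay(PARENTAL_BIK, "parental"),
            gen_bik_decay(SRC_BIK, "src"),
            gen_bik_decay(SRC_BIK, "src", herbimycin=True),
        ]
        fit = fit_bik_params(courses, shared_kubi=True)
        kubi_hat = fit["params"]["parental"].k_ubi
        assert abs(kubi_hat - PARENTAL_BIK.k_ubi) / PARENTAL_BIK.k_ubi < 0.05
        true_lump = SRC_BIK.v_max / (SRC_BIK.k_m + bik_steady_state(SRC_BIK).bik)
        lump_hat = fit["lumped_src_sink"]["src"]
        assert abs(lump_hat - true_lump) / true_lump < 0.05

    def test_parental_src_branch_predicted_inactive(self):
        courses = [
            gen_bik_decay(PARENTAL_BIK, "parental"),
            gen_bik_decay(SRC_BIK, "src"),
        ]
        fit = fit_bik_params(courses, shared_kubi=True)
        kubi_hat = fit["params"]["parental"].k_ubi
        assert fit["lumped_src_sink"]["parental"] < 0.05 * kubi_hat

    def test_constant_course_handled(self):
        flat = DecayTimecourse(times=tuple(range(0, 361, 30)),
                               values=(1.0,) * 13, cell_line="parental")
        fit = fit_bik_params([flat])
        assert fit["residual_norm"] >= 0.0
        assert fit["params"]["parental"].k_ubi >= 1e-6  # optimizer floor

    def test_too_few_points_rejected(self):
        short = DecayTimecourse(times=(0.0, 30.0), values=(1.0, 0.9), cell_line="x")
        with pytest.raises(ValueError):
            fit_bik_params([short])

    def test_noisy_recovery_median_error(self):
        """10% multiplicative noise: median kubi error over 20 seeds <= 25%."""
        errors = []
        for seed in range(20):
            noise = NoiseModel(kind="multiplicative-lognormal", scale=0.10, seed=seed)
            courses = [
                gen_bik_decay(PARENTAL_BIK, "parental", noise=noise),
                gen_bik_decay(SRC_BIK, "src",
                              noise=NoiseModel(scale=0.10, seed=seed + 1000)),
            ]
            fit = fit_bik_params(courses, shared_kubi=True, seed=seed)
            kubi_hat = fit["params"]["parental"].k_ubi
            errors.append(abs(kubi_hat - PARENTAL_BIK.k_ubi) / PARENTAL_BIK.k_ubi)
        assert float(np.median(errors)) <= 0.25


class TestTimecourseContracts:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            DecayTimecourse(times=(0.0, 30.0, 20.0), values=(1.0, 0.9, 0.8),
                            cell_line="x")

    def test_out_of_range_levels_rejected(self):
        with pytest.raises(ValueError):
            DecayTimecourse(times=(0.0, 30.0), values=(1.0, 1.9), cell_line="x")
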