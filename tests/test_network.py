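"""Apoptosis network: rate laws, conservation, initial conditions, survival."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apoptosim.network import (
    SPECIES,
    ApoptosisParams,
    CellLineSpec,
    NetworkState,
    PARENTAL_CELL,
    SRC_CELL,
    SEED_NETWORK_PARAMS,
    build_initial_state,
    estimate_kact,
    network_rhs,
    simulate,
    survival_rhs,
    threshold_fraction,
)

IDX = {s: i for i, s in enumerate(SPECIES)}


def stoichiometry_oracle(y, p, k_act, k_trunc):
    """Independent flux-vector x stoichiometry-matrix evaluation.

    Species order as SPECIES; one column per reaction R1..R10 with explicit
    stoichiometric coefficients (R7 converts two monomers per event).
    """
    bik_er, bik_act, c_bik, bid, tbid, c_tbid, bax_c, bax_o, bax_oligo, bcl2, c_bax = y
    fluxes = np.array([
        k_act * bik_er,
        p.k_bik_bcl2 * bik_act * bcl2,
        k_trunc * bid,
        p.k_tbid_bcl2 * tbid * bcl2,
        p.k_disp * c_tbid * bik_act,
        p.kcat_bax * tbid * bax_c / (p.km_bax + bax_c),
        p.k_dim * bax_o ** 2,
        p.k_auto * bax_o * bax_oligo,
        p.k_bax_bcl2 * bax_o * bcl2,
        p.k_back * bax_o,
    ])
    S = np.zeros((11, 10))
    S[IDX["bik_er"], 0] = -1
    S[IDX["bik_act"], 0] = 1
    S[IDX["bik_act"], 1] = -1
    S[IDX["bcl2"], 1] = -1
    S[IDX["c_bik"], 1] = 1
    S[IDX["bid"], 2] = -1
    S[IDX["tbid"], 2] = 1
    S[IDX["tbid"], 3] = -1
    S[IDX["bcl2"], 3] = -1
    S[IDX["c_tbid"], 3] = 1
    S[IDX["c_tbid"], 4] = -1
    S[IDX["bik_act"], 4] = -1
    S[IDX["c_bik"], 4] = 1
    S[IDX["tbid"], 4] = 1
    S[IDX["bax_c"], 5] = -1
    S[IDX["bax_o"], 5] = 1
    S[IDX["bax_o"], 6] = -2
    S[IDX["bax_oligo"], 6] = 2
    S[IDX["bax_o"], 7] = -1
    S[IDX["bax_oligo"], 7] = 2
    S[IDX["bax_oligo"], 7] -= 1  # one oligo consumed as template, two produced
    S[IDX["bax_o"], 8] = -1
    S[IDX["bcl2"], 8] = -1
    S[IDX["c_bax"], 8] = 1
    S[IDX["bax_o"], 9] = -1
    S[IDX["bax_c"], 9] = 1
    return S @ fluxes


random_state = st.lists(st.floats(0.0, 500.0), min_size=11, max_size=11)
random_params = st.builds(
    ApoptosisParams,
    k_trunc=st.floats(1e-5, 0.1),
    k_disp=st.floats(1e-5, 1.0),
    kcat_bax=st.floats(1e-4, 1.0),
    k_dim=st.floats(1e-6, 0.01),
    k_auto=st.floats(1e-4, 0.5),
    k_bax_bcl2=st.floats(1e-6, 0.01),
    k_back=st.floats(1e-4, 0.1),
)


class TestRhs:
    def test_zero_state_gives_zero_derivatives(self):
        dy = network_rhs(np.zeros(11), SEED_NETWORK_PARAMS)
        assert np.all(dy == 0)

    def test_initial_state_is_fixed_point_without_stimulus(self):
        y0 = build_initial_state(PARENTAL_CELL).concentrations
        dy = network_rhs(y0, SEED_NETWORK_PARAMS, k_act=0.0, k_trunc=0.0)
        assert np.allclose(dy, 0.0, atol=1e-14)

    def test_autocatalysis_dominates_nucleation(self):
        """At equal open/oligomer levels the template route carries ~39x
        the nucleation flux, as required of the dominant pathway."""
        p = SEED_NETWORK_PARAMS
        bax_o = bax_oligo = 10.0
        r7 = 2 * p.k_dim * bax_o**2
        r8 = p.k_auto * bax_o * bax_oligo
        assert r8 / r7 == pytest.approx(0.0144 * 100 / (2 * 0.000185 * 100), rel=1e-12)
        assert r8 > 10 * r7

    def test_negative_state_rejected(self):
        y = np.zeros(11)
        y[0] = -1.0
        with pytest.raises(ValueError):
            network_rhs(y, SEED_NETWORK_PARAMS)

    @settings(max_examples=50, deadline=None)
    @given(random_state, random_params)
    def test_matches_stoichiometry_oracle(self, y, p):
        y = np.asarray(y)
        dy = network_rhs(y, p)
        oracle = stoichiometry_oracle(y, p, p.k_act, p.k_trunc)
        assert np.allclose(dy, oracle, rtol=1e-12, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(random_state, random_params)
    def test_conserved_sums_have_zero_derivative(self, y, p):
        dy = network_rhs(np.asarray(y), p)
        groups = [
            ("bik_er", "bik_act", "c_bik"),
            ("bid", "tbid", "c_tbid"),
            ("bax_c", "bax_o", "bax_oligo", "c_bax"),
            ("bcl2", "c_bik", "c_tbid", "c_bax"),
        ]
        for grp in groups:
            assert abs(sum(dy[IDX[s]] for s in grp)) < 1e-9


class TestInitialState:
    def test_parental_layout(self):
        s = build_initial_state(PARENTAL_CELL)
        assert s["bax_c"] == 48.0
        assert s["bcl2"] == 544.0
        assert s["bid"] == 51.0
        assert s["c_tbid"] == 1.0
        assert s["bik_er"] == 50.0
        assert s["bik_act"] == s["c_bik"] == s["bax_o"] == s["bax_oligo"] == s["c_bax"] == 0.0
        assert s.n == 100.0

    def test_src_layout(self):
        s = build_initial_state(SRC_CELL)
        assert s["bax_c"] == 100.0
        assert s["bcl2"] == 599.0
        assert s["bid"] == 39.0

    def test_no_preexisting_tbid(self):
        cell = CellLineSpec("x", bik_ss=10, bax_total=50, bcl2_total=500,
                            bid_total=40, tbid0=0.0)
        s = build_initial_state(cell)
        assert s["c_tbid"] == 0.0 and s["bcl2"] == 500.0

    def test_conservation_totals_match_spec(self):
        s = build_initial_state(SRC_CELL)
        totals = s.conserved_totals()
        assert totals["bik"] == SRC_CELL.bik_ss
        assert totals["bid"] == SRC_CELL.bid_total
        assert totals["bax"] == SRC_CELL.bax_total
        assert totals["bcl2"] == SRC_CELL.bcl2_total

    def test_invalid_cell_spec_rejected(self):
        with pytest.raises(ValueError):
            CellLineSpec("x", bik_ss=10, bax_total=50, bcl2_total=500,
                         bid_total=40, tbid0=45.0)  # tbid0 > bid_total


class TestSurvival:
    def test_zero_oligo_no_death(self):
        assert survival_rhs(100.0, 0.0, SEED_NETWORK_PARAMS) == 0.0

    def test_half_saturation_at_threshold(self):
        p = SEED_NETWORK_PARAMS
        dn = survival_rhs(80.0, p.bax_star, p)
        assert dn == pytest.approx(-p.death_rate * 80.0 / 2.0)

    def test_saturates_at_max_rate(self):
        p = SEED_NETWORK_PARAMS
        dn = survival_rhs(100.0, 1e6 * p.bax_star, p)
        assert dn == pytest.approx(-p.death_rate * 100.0, rel=1e-4)

    def test_exponential_limit_far_above_threshold(self):
        """Sustained saturation kills the population exponentially at rate a:
        n(480) = 100*exp(-0.0205*480) ~ 0.0053%."""
        from scipy.integrate import solve_ivp

        p = SEED_NETWORK_PARAMS
        sol = solve_ivp(lambda _t, y: [survival_rhs(y[0], 1e8, p)], (0, 480.0),
                        [100.0], method="LSODA", rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(100.0 * np.exp(-0.0205 * 480.0), rel=1e-4)
        assert sol.y[0, -1] == pytest.approx(0.0053, abs=2e-4)

    def test_tiny_oligo_large_gamma_is_safe(self):
        p = SEED_NETWORK_PARAMS.replace(gamma=10.0)
        assert survival_rhs(50.0, 1e-200, p) == 0.0


class TestSimulate:
    def test_no_stimulus_no_death(self):
        for cell in (PARENTAL_CELL, SRC_CELL):
            res = simulate(cell, SEED_NETWORK_PARAMS, staurosporine=False)
            assert res.apoptotic_pct < 0.1
            assert res.conservation_drift < 1e-6

    def test_conservation_and_nonnegativity_under_stimulus(self):
        res = simulate(PARENTAL_CELL, SEED_NETWORK_PARAMS, staurosporine=True)
        assert res.conservation_drift < 1e-6
        assert float(res.states.min()) > -1e-9

    def test_survival_is_non_increasing(self):
        res = simulate(PARENTAL_CELL, SEED_NETWORK_PARAMS, staurosporine=True)
        assert np.all(np.diff(res.n) <= 1e-12)

    def test_apoptosis_monotone_in_duration(self):
        pcts = [simulate(PARENTAL_CELL, SEED_NETWORK_PARAMS, t_end=t).apoptotic_pct
                for t in (120.0, 480.0)]
        assert pcts[0] <= pcts[1] + 1e-12

    def test_bad_t_end_rejected(self):
        with pytest.raises(ValueError):
            simulate(PARENTAL_CELL, SEED_NETWORK_PARAMS, t_end=0.0)


class TestScalarEstimators:
    def test_kact_from_colocalization(self):
        # 45% at mitochondria after 2 h -> ~0.005/min relocation rate
        assert estimate_kact(0.45, 120.0) == pytest.approx(0.005, abs=0.0002)

    def test_kact_zero_fraction(self):
        assert estimate_kact(0.0, 60.0) == 0.0

    def test_kact_closed_form_inverse(self):
        assert estimate_kact(0.632, 100.0) == pytest.approx(0.01, abs=1e-4)

    def test_kact_rejects_full_fraction(self):
        with pytest.raises(ValueError):
            estimate_kact(1.0, 60.0)

    def test_threshold_fraction_product(self):
        # 33% of Bax at mitochondria x 38% of that activated ~ 13% of total
        assert threshold_fraction(0.33, 0.38) == pytest.approx(0.1254)
        assert threshold_fraction(1.0, 1.0) == 1.0
        assert threshold_fraction(0.5, 0.2) == pytest.approx(0.10)
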