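"""Kinetic core: rate-matrix structure, exact propagation, ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tamoxsim.params import CYP2D6Activity, InputError, NetworkParams, \
    ParameterError
from tamoxsim.pkmodel import (COMPOUNDS, N_STATES, build_rate_matrix,
                              ode_oracle, simulate)
from tamoxsim.dosing import DoseEvent

from conftest import daily_tam


def hand_rhs(p: NetworkParams, theta: float, x: np.ndarray) -> np.ndarray:
    """Independently hand-expanded ODE right-hand side (oracle)."""
    d_tam, d_end, tam, ndm, oh, end = x
    return np.array([
        -p.ka_TAM * d_tam,
        -p.ka_END * d_end,
        p.ka_TAM * p.F_TAM * d_tam
        - (p.CLf_TAM_NDM + theta * p.CLf_TAM_4OH + p.CLe_TAM) / p.V_TAM * tam,
        p.CLf_TAM_NDM / p.V_TAM * tam
        - (theta * p.CLf_NDM_END + p.CLe_NDM) / p.V_NDM * ndm,
        theta * p.CLf_TAM_4OH / p.V_TAM * tam
        - (p.CLf_4OH_END + p.CLe_4OH) / p.V_4OH * oh,
        theta * p.CLf_NDM_END / p.V_NDM * ndm
        + p.CLf_4OH_END / p.V_4OH * oh + p.ka_END * p.F_END * d_end
        - p.CLe_END / p.V_END * end,
    ])


class TestRateMatrix:
    def test_matches_hand_expanded_rhs(self, typical_net, rng):
        A = build_rate_matrix(typical_net, CYP2D6Activity("IM", 0.6))
        for _ in range(20):
            x = rng.uniform(0.1, 10.0, N_STATES)
            np.testing.assert_allclose(A @ x, hand_rhs(typical_net, 0.6, x),
                                       rtol=1e-12)

    def test_total_amount_derivative_is_elimination_only(self, typical_net, em):
        # with F=1 the only mass losses are the CLe routes
        A = build_rate_matrix(typical_net, em)
        x = np.array([5.0, 1.0, 4.0, 3.0, 0.5, 0.2])
        p = typical_net
        expected = -(p.CLe_TAM / p.V_TAM * x[2] + p.CLe_NDM / p.V_NDM * x[3]
                     + p.CLe_4OH / p.V_4OH * x[4] + p.CLe_END / p.V_END * x[5]
                     + (1 - p.F_TAM) * p.ka_TAM * x[0]
                     + (1 - p.F_END) * p.ka_END * x[1])
        assert np.isclose((A @ x).sum(), expected, rtol=1e-12)

    def test_pm_limit_zeroes_cyp2d6_edges(self, typical_net, pm):
        A = build_rate_matrix(typical_net, pm)
        assert A[4, 2] == 0.0   # TAM -> 4OH
        assert A[5, 3] == 0.0   # NDM -> END
        assert A[5, 4] > 0.0    # 4OH -> END (CYP3A4) intact
        assert A[5, 1] > 0.0    # END depot intact

    def test_theta_scaling_is_linear(self, typical_net):
        A1 = build_rate_matrix(typical_net, CYP2D6Activity("IM", 0.4))
        A2 = build_rate_matrix(typical_net, CYP2D6Activity("IM", 0.8))
        assert np.isclose(A2[4, 2], 2 * A1[4, 2])
        assert np.isclose(A2[5, 3], 2 * A1[5, 3])
        assert A2[3, 2] == A1[3, 2]          # CYP3A4 edge unchanged
        assert A2[5, 4] == A1[5, 4]

    def test_column_sums_are_nonpositive(self, typical_net, em):
        A = build_rate_matrix(typical_net, em)
        sums = A.sum(axis=0)
        assert np.all(sums <= 1e-12)
        assert np.all(sums[2:] < 0)  # every central species eliminates

    def test_invalid_parameters_raise(self, typical_net):
        with pytest.raises(ParameterError):
            NetworkParams(**{**typical_net.to_dict(), "V_TAM": 0.0})
        with pytest.raises(ParameterError):
            CYP2D6Activity("IM", -0.1)


class TestSimulate:
    def test_no_doses_gives_zero(self, typical_net, em):
        ts = simulate(typical_net, em, [], 10.0, np.linspace(0, 10, 11))
        assert np.all(ts.concentrations == 0.0)

    def test_single_dose_matches_bateman_curve(self, typical_net, em):
        # decouple the cascade: formation clearances to zero
        p = NetworkParams(**{**typical_net.to_dict(), "CLf_TAM_NDM": 0.0,
                             "CLf_TAM_4OH": 0.0})
        D, F, ka = 20.0, p.F_TAM, p.ka_TAM
        ke = p.CLe_TAM / p.V_TAM
        t = np.linspace(0.25, 30, 40)
        ts = simulate(p, em, [DoseEvent(0.0, "TAM", D)], 30.0, t)
        bateman = (F * D * ka / (p.V_TAM * (ka - ke))
                   * (np.exp(-ke * t) - np.exp(-ka * t)) * 1000.0)
        np.testing.assert_allclose(ts.compound("TAM"), bateman, rtol=1e-9)
        for c in ("NDM", "4OH", "END"):
            assert np.all(ts.compound(c) == 0.0)

    def test_superposition_of_two_doses(self, typical_net, em):
        t = np.linspace(0, 20, 81)
        both = simulate(typical_net, em,
                        [DoseEvent(0.0, "TAM", 20.0), DoseEvent(1.0, "TAM", 20.0)],
                        20.0, t)
        one = simulate(typical_net, em, [DoseEvent(0.0, "TAM", 20.0)], 20.0, t)
        two = simulate(typical_net, em, [DoseEvent(1.0, "TAM", 20.0)], 20.0, t)
        np.testing.assert_allclose(both.concentrations,
                                   one.concentrations + two.concentrations,
                                   rtol=1e-9, atol=1e-12)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_dose_proportionality(self, typical_net, em, c):
        t = np.linspace(0, 15, 16)
        events = [DoseEvent(0.0, "TAM", 20.0), DoseEvent(2.0, "END", 3.0)]
        scaled = [DoseEvent(e.time, e.compound, e.amount * c) for e in events]
        base = simulate(typical_net, em, events, 15.0, t)
        up = simulate(typical_net, em, scaled, 15.0, t)
        np.testing.assert_allclose(up.concentrations, c * base.concentrations,
                                   rtol=1e-9, atol=1e-12)

    def test_washout_total_amount_nonincreasing(self, typical_net, em):
        # well after the last dose (depot drained), total drug can only decline
        t = np.linspace(8.0, 40.0, 200)
        events = daily_tam(5)
        ts = simulate(typical_net, em, events, 40.0, t)
        p = typical_net
        vols = np.array([p.V_TAM, p.V_NDM, p.V_4OH, p.V_END])
        total_mg = (ts.concentrations / 1000.0 * vols).sum(axis=1)
        assert np.all(np.diff(total_mg) <= 1e-9 * total_mg[0])
        assert np.all(ts.concentrations >= 0.0)
        # TAM itself is strictly declining once its depot is empty
        assert np.all(np.diff(ts.compound("TAM")) < 0)

    def test_input_validation(self, typical_net, em):
        bad_order = [DoseEvent(2.0, "TAM", 1.0), DoseEvent(1.0, "TAM", 1.0)]
        with pytest.raises(InputError):
            simulate(typical_net, em, bad_order, 5.0, [0.0])
        with pytest.raises(InputError):
            simulate(typical_net, em, [DoseEvent(0.0, "NDM", 1.0)], 5.0, [0.0])
        with pytest.raises(InputError):
            simulate(typical_net, em, [], 5.0, [0.0, 6.0])


class TestOdeOracle:
    def test_agrees_with_matrix_exponential_path(self, typical_net, rng):
        # randomized dosing, all phenotypes: rel. deviation < 1e-6
        for theta, phen in ((1.0, "EM"), (0.45, "IM"), (0.0, "PM")):
            act = CYP2D6Activity(phen, theta)
            times = np.sort(rng.uniform(0, 10, 5))
            events = [DoseEvent(float(t), comp, float(rng.uniform(1, 30)))
                      for t, comp in zip(times, ["TAM", "END", "TAM", "TAM", "END"])]
            sample = np.linspace(0.5, 14.5, 29)
            a = simulate(typical_net, act, events, 15.0, sample)
            b = ode_oracle(typical_net, act, events, 15.0, sample)
            scale = np.abs(a.concentrations).max()
            assert np.abs(a.concentrations - b.concentrations).max() < 1e-6 * scale

    def test_zero_dose_exact_zero(self, typical_net, em):
        ts = ode_oracle(typical_net, em, [], 5.0, [0.0, 2.5, 5.0])
        assert np.all(ts.concentrations == 0.0)

    def test_pm_limit_blocks_tam_derived_endoxifen(self, typical_net, pm):
        # both endoxifen-forming branches carry exactly one CYP2D6 step, so
        # with theta=0 TAM-only dosing yields neither 4OH nor END; dosed
        # endoxifen still appears via its own depot
        sample = np.linspace(1, 20, 20)
        a = simulate(typical_net, pm, [DoseEvent(0.0, "TAM", 20.0)], 20.0, sample)
        b = ode_oracle(typical_net, pm, [DoseEvent(0.0, "TAM", 20.0)], 20.0, sample)
        assert np.all(a.compound("4OH") == 0.0)
        assert np.all(a.compound("END") == 0.0)
        scale = np.abs(a.concentrations).max()
        assert np.abs(a.concentrations - b.concentrations).max() < 1e-6 * scale
        c = simulate(typical_net, pm, [DoseEvent(0.0, "END", 3.0)], 20.0, sample)
        assert np.all(c.compound("END") > 0.0)
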