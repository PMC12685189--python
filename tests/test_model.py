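"""Unit and property tests for the model equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofilmchemostat.model import (ParameterSet, SystemState, ParameterError,
                                    monod_uptake, occupancy, rhs, rhs_array,
                                    validate_parameters, analytic_jacobian,
                                    STABLE_MEDIANS)
from conftest import random_valid_params, random_state


class TestMonodUptake:
    @pytest.mark.parametrize("S,E", [(0.0, 1.0), (1.0, 0.0), (0.0, 0.0)])
    def test_vanishes_without_nutrient_or_enzyme(self, S, E):
        assert monod_uptake(S, E, mu=5.0, K_S=0.1) == 0.0

    def test_scalar_value(self):
        # independent one-line arithmetic: mu*S*E/(K_S+S)
        expected = 68.07673 * 0.5 * 0.14 / (0.25 + 0.5)
        assert monod_uptake(0.5, 0.14, mu=68.07673, K_S=0.25) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(S=st.floats(1e-6, 10), E=st.floats(1e-6, 10),
           dS=st.floats(1e-6, 1), dE=st.floats(1e-6, 1))
    def test_strictly_increasing_in_both_arguments(self, S, E, dS, dE):
        base = monod_uptake(S, E, 5.0, 0.1)
        assert monod_uptake(S + dS, E, 5.0, 0.1) > base
        assert monod_uptake(S, E + dE, 5.0, 0.1) > base

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            monod_uptake(-0.1, 1.0, 5.0, 0.1)
        with pytest.raises(ValueError):
            monod_uptake(0.1, -1.0, 5.0, 0.1)


class TestOccupancy:
    @pytest.mark.parametrize("level,capacity,expected", [
        (0.0, 0.19065, 0.0),
        (0.19065, 0.19065, 1.0),
        (0.095325, 0.19065, 0.5),
    ])
    def test_fraction_of_capacity(self, level, capacity, expected):
        assert occupancy(level, capacity) == pytest.approx(expected, rel=1e-12)

    def test_above_capacity_signals_overflow(self):
        # ratios above 1 flip the sign of the retention term downstream
        assert occupancy(0.4, 0.2) == pytest.approx(2.0)

    def test_nonpositive_capacity_rejected(self):
        with pytest.raises(ValueError):
            occupancy(0.1, 0.0)


class TestValidateParameters:
    def test_reference_medians_accepted(self, medians):
        assert validate_parameters(medians) is medians

    @pytest.mark.parametrize("changes", [
        {"Q": 1.0}, {"Q": -0.1}, {"K_S": 0.76202}, {"K_S": 1.0},
        {"D": 1.0}, {"beta_X": 1.2}, {"alpha": -0.01}, {"gamma": 0.0},
        {"mu": -5.0}, {"S0": float("nan")},
    ])
    def test_invariant_violations_rejected(self, medians, changes):
        with pytest.raises(ParameterError):
            validate_parameters(medians.replace(**changes))

    def test_alpha_zero_allowed(self, medians):
        validate_parameters(medians.replace(alpha=0.0))

    def test_round_trip_uses_symbol_names(self, medians):
        d = medians.to_dict()
        assert set(d) == {"S0", "D", "Q", "eta", "gamma", "delta", "alpha",
                          "beta_X", "beta_E", "E2_max", "X2_max", "mu", "K_S"}
        assert ParameterSet.from_dict(d) == medians
        with pytest.raises(ParameterError):
            ParameterSet.from_dict({**d, "bogus": 1.0})


def _rhs_reference(y, p):
    """Independent term-by-term re-summation of the balance equations."""
    S, E1, E2, X1, X2, X3 = y
    F1 = p.mu * S * E1 / (p.K_S + S)
    F2 = p.mu * S * E2 / (p.K_S + S)
    M = E2 / p.E2_max
    W = X2 / p.X2_max
    out = np.zeros(6)
    # nutrient: inflow - outflow - fluid uptake - biofilm uptake
    out[0] = p.D * p.S0 - p.D * S - F1 * X1 / p.gamma - F1 * X3 / p.gamma \
        - p.delta * F2 * X2 / p.gamma
    # fluid enzyme: -washout + fluid production + slough + biofilm overflow
    out[1] = -p.D * E1 + p.eta * p.Q * F1 * X1 + p.delta * p.beta_E * E2 \
        + p.delta * p.eta * p.Q * F2 * X2 * M
    # biofilm enzyme: retained production - slough
    out[2] = p.eta * p.Q * F2 * X2 - p.eta * p.Q * F2 * X2 * M - p.beta_E * E2
    # fluid cooperators
    out[3] = (1 - p.Q) * F1 * X1 - p.D * X1 - p.alpha * X1 \
        + p.delta * p.beta_X * X2 + p.delta * (1 - p.Q) * F2 * X2 * W
    # biofilm cooperators
    out[4] = (1 - p.Q) * F2 * X2 - (1 - p.Q) * F2 * X2 * W \
        + p.alpha * X1 / p.delta - p.beta_X * X2
    # cheaters
    out[5] = F1 * X3 - p.D * X3
    return out


class TestRhs:
    def test_no_organisms_only_washout_terms(self, medians):
        y = np.array([0.3, 0.2, 0.05, 0.0, 0.0, 0.0])
        d = rhs(y, medians)
        assert d[0] == pytest.approx(medians.D * (medians.S0 - 0.3), rel=1e-12)
        assert d[2] == pytest.approx(-medians.beta_E * 0.05, rel=1e-12)
        assert d[3] == d[5] == 0.0

    def test_zero_nutrient_kills_all_uptake(self, medians):
        y = np.array([0.0, 0.5, 0.1, 0.4, 0.2, 0.3])
        d = rhs(y, medians)
        assert d[0] == pytest.approx(medians.D * medians.S0, rel=1e-12)
        assert d[5] == pytest.approx(-medians.D * 0.3, rel=1e-12)

    def test_agrees_with_independent_resummation(self, medians):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = random_valid_params(rng)
            y = random_state(rng)
            np.testing.assert_allclose(rhs_array(y, p), _rhs_reference(y, p),
                                       rtol=1e-12, atol=1e-14)

    def test_rejects_nonfinite_and_negative_states(self, medians):
        with pytest.raises(ValueError):
            rhs(np.array([np.nan, 0, 0, 0, 0, 0]), medians)
        with pytest.raises(ValueError):
            rhs(np.array([-0.1, 0, 0, 0, 0, 0]), medians)


class TestStructuralProperties:
    def test_flux_conservation_between_compartments(self):
        """Every boundary-crossing term balances under the delta convention.

        Adding the fluid-phase gain (per volume) and delta times the biofilm
        loss (per area) must cancel exactly, term by term: adhesion,
        sloughing (cells and enzyme), and the two overflow leakage fluxes.
        """
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = random_valid_params(rng)
            S, E1, E2, X1, X2, X3 = random_state(rng)
            F2 = p.mu * S * E2 / (p.K_S + S)
            M, W = E2 / p.E2_max, X2 / p.X2_max
            # adhesion: fluid loses alpha*X1 per volume, biofilm gains
            # (alpha/delta)*X1 per area
            assert p.alpha * X1 == pytest.approx(p.delta * (p.alpha / p.delta) * X1, rel=1e-12)
            # cell sloughing: biofilm loses beta_X*X2 per area, fluid gains
            # delta*beta_X*X2 per volume
            assert p.delta * p.beta_X * X2 == pytest.approx(p.delta * (p.beta_X * X2), rel=1e-12)
            # growth overflow: biofilm production splits into retained
            # (1-W) and leaked W; the leaked part reappears in the fluid
            leaked = (1 - p.Q) * F2 * X2 * W
            total = (1 - p.Q) * F2 * X2
            retained = (1 - p.Q) * F2 * X2 * (1 - W)
            assert retained + leaked == pytest.approx(total, rel=1e-12)
            # enzyme overflow likewise
            e_leak = p.eta * p.Q * F2 * X2 * M
            e_total = p.eta * p.Q * F2 * X2
            assert e_total - e_leak == pytest.approx(
                p.eta * p.Q * F2 * X2 * (1 - M), rel=1e-12)

    def test_biomass_conservation_in_cooperator_exchange(self):
        """Total cooperator biomass (X1 + delta*X2) changes only through
        growth, dilution, and sloughing-neutral exchange: the adhesion terms
        cancel in the combined budget."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            p = random_valid_params(rng)
            y = random_state(rng)
            d = rhs_array(y, p)
            combined = d[3] + p.delta * d[4]
            S, E1, E2, X1, X2, X3 = y
            F1 = p.mu * S * E1 / (p.K_S + S)
            F2 = p.mu * S * E2 / (p.K_S + S)
            expected = ((1 - p.Q) * F1 * X1 - p.D * X1
                        + p.delta * ((1 - p.Q) * F2 * X2 - 0.0))
            # alpha and the W-mediated exchange cancel; beta_X terms cancel
            assert combined == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_growth_terms_nondecreasing_in_S_and_E(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            p = random_valid_params(rng)
            y = random_state(rng)
            d0 = rhs_array(y, p)
            yS = y.copy(); yS[0] += 0.1
            # cheater equation is pure growth - dilution: monotone in S, E1
            assert rhs_array(yS, p)[5] >= d0[5] - 1e-12
            yE = y.copy(); yE[1] += 0.1
            assert rhs_array(yE, p)[5] >= d0[5] - 1e-12

    def test_boundary_invariance(self, medians):
        rng = np.random.default_rng(14)
        y = random_state(rng)
        y[5] = 0.0
        assert rhs_array(y, medians)[5] == 0.0
        p0 = medians.replace(alpha=0.0)
        y = random_state(rng)
        y[2] = y[4] = 0.0
        d = rhs_array(y, p0)
        assert d[2] == 0.0 and d[4] == 0.0

    def test_q_zero_stops_enzyme_production(self, medians):
        p = medians.replace(Q=0.0)
        y = np.array([0.5, 0.3, 0.1, 0.4, 0.2, 0.0])
        d = rhs_array(y, p)
        # E1 balance reduces to washout + slough, E2 to pure slough
        assert d[1] == pytest.approx(-p.D * 0.3 + p.delta * p.beta_E * 0.1, rel=1e-12)
        assert d[2] == pytest.approx(-p.beta_E * 0.1, rel=1e-12)


class TestAnalyticJacobian:
    def test_cheater_row_structure(self, medians):
        y = np.array([0.5, 0.3, 0.1, 0.4, 0.2, 0.15])
        J = analytic_jacobian(y, medians)
        F1 = medians.mu * 0.5 * 0.3 / (medians.K_S + 0.5)
        assert J[5, 5] == pytest.approx(F1 - medians.D, rel=1e-12)
        assert J[5, 2] == J[5, 3] == J[5, 4] == 0.0
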