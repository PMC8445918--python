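"""Unit and property tests for the reaction network and its ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tamres.errors import InvalidParameterError, InvalidStateError
from tamres.model import (
    N_PARAMETERS,
    PARAM_NAMES,
    REACTION_NAMES,
    CellState,
    ModelParameters,
    hill_activation,
    reaction_rates,
    rhs,
)

rates = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)
shapes = st.floats(min_value=0.2, max_value=10.0, allow_nan=False)
counts = st.floats(min_value=0.0, max_value=1e7, allow_nan=False)


def params_strategy():
    return st.builds(
        ModelParameters,
        **{name: rates for name in PARAM_NAMES
           if name not in ("n_SP", "n_PR1", "n_PR2", "K_SP", "K_PR1", "K_PR2", "f_P0")},
        **{name: shapes for name in ("n_SP", "n_PR1", "n_PR2", "K_SP", "K_PR1", "K_PR2")},
        f_P0=st.floats(min_value=0.0, max_value=0.9, exclude_max=True),
    )


def state_strategy():
    return st.builds(
        CellState,
        X_S=counts, X_P=counts, X_R1=counts, X_R2=counts,
        U=st.floats(min_value=0.0, max_value=20.0),
    )


class TestHillActivation:
    @pytest.mark.parametrize(
        "U, n, K, expected",
        [
            (0.0, 3.0, 2.0, 0.0),          # no exposure, no activation
            (2.0, 3.0, 2.0, 0.5),          # half-saturation at U = K
            (5.0, 1.7, 5.0, 0.5),          # half-saturation for any steepness
            (2.0, 1.0, 1.0, 2.0 / 3.0),    # direct evaluation of the Hill form
        ],
    )
    def test_known_values(self, U, n, K, expected):
        assert hill_activation(U, n, K) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, K", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_rejects_nonpositive_shape(self, n, K):
        with pytest.raises(InvalidParameterError):
            hill_activation(1.0, n, K)

    @given(
        n=shapes, K=shapes,
        U=st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=10),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_and_bounded(self, n, K, U):
        values = [hill_activation(u, n, K) for u in sorted(U)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_saturates_to_one(self):
        assert hill_activation(1e12, 2.0, 1.0) == pytest.approx(1.0, abs=1e-9)


class TestModelParameters:
    def test_exactly_19_free_parameters(self):
        assert N_PARAMETERS == 19
        assert len(PARAM_NAMES) == 19

    def test_json_round_trip(self, truth):
        assert ModelParameters.from_json(truth.to_json()) == truth

    def test_unknown_key_rejected(self, truth):
        data = truth.to_dict() | {"g_R3": 1.0}
        with pytest.raises(InvalidParameterError, match="unknown"):
            ModelParameters.from_dict(data)

    def test_missing_key_rejected(self, truth):
        data = truth.to_dict()
        del data["f_P0"]
        with pytest.raises(InvalidParameterError, match="missing"):
            ModelParameters.from_dict(data)

    @pytest.mark.parametrize("field, value", [
        ("g_S", -0.1), ("n_SP", 0.0), ("K_PR2", -1.0), ("f_P0", 1.0),
    ])
    def test_domain_violations_rejected(self, truth, field, value):
        with pytest.raises(InvalidParameterError):
            truth.replace(**{field: value})


class TestReactionRates:
    def test_twelve_reactions(self):
        assert len(REACTION_NAMES) == 12

    def test_zero_state_gives_zero_fluxes(self, truth):
        state = CellState(0.0, 0.0, 0.0, 0.0, 5.0)
        v = reaction_rates(state, truth, tam_dose=1.0).to_array()
        assert np.all(v == 0.0)

    def test_no_drug_limit(self, truth):
        """Without TAM (dose 0, U=0), death and forward transitions vanish and
        the remaining fluxes are plain mass-action terms."""
        state = CellState(100.0, 50.0, 20.0, 10.0, 0.0)
        v = reaction_rates(state, truth, tam_dose=0.0)
        assert v.v2 == v.v3 == v.v6 == v.v7 == v.v10 == 0.0
        assert v.v1 == pytest.approx(truth.g_S * 100.0)
        assert v.v4 == pytest.approx(truth.k_PS * 50.0)
        assert v.v5 == pytest.approx(truth.g_P * 50.0)
        assert v.v8 == pytest.approx(truth.k_R1P * 20.0)
        assert v.v9 == pytest.approx(truth.g_R1 * 20.0)
        assert v.v11 == pytest.approx(truth.k_R2P * 10.0)
        assert v.v12 == pytest.approx(truth.g_R2 * 10.0)

    def test_forward_flux_at_half_saturation(self, truth):
        """v10 = k_PR2 · 0.5 · X_P when the exposure sits at the half-effect."""
        params = truth.replace(k_PR2=0.5)
        state = CellState(0.0, 100.0, 0.0, 0.0, params.K_PR2)
        v = reaction_rates(state, params, tam_dose=1.0)
        assert v.v10 == pytest.approx(0.5 * 0.5 * 100.0, rel=1e-12)

    def test_negative_state_rejected(self, truth):
        with pytest.raises(InvalidStateError):
            CellState(-1.0, 0.0, 0.0, 0.0, 0.0)

    @given(params=params_strategy(), state=state_strategy(),
           dose=st.sampled_from([0.0, 1.0]))
    @settings(deadline=None, max_examples=100)
    def test_fluxes_nonnegative(self, params, state, dose):
        assert np.all(reaction_rates(state, params, dose).to_array() >= 0.0)


class TestRhs:
    def test_pure_exponential_no_drug(self, truth):
        state = CellState(1e6, 0.0, 0.0, 0.0, 0.0)
        d = rhs(0.0, state, truth, tam_dose=0.0)
        assert d[0] == pytest.approx(truth.g_S * 1e6)
        assert d[4] == 0.0

    def test_hand_evaluated_death_and_transition(self):
        """dX_S = −d_S·X_S − k_SP·0.5·X_S at the half-effect exposure."""
        params = ModelParameters(
            g_S=0.0, g_P=0.0, g_R1=0.0, g_R2=0.0, d_S=0.1, d_P=0.0,
            k_SP=0.2, k_PR1=0.0, k_PR2=0.0,
            n_SP=2.0, n_PR1=1.0, n_PR2=1.0,
            K_SP=3.0, K_PR1=1.0, K_PR2=1.0,
            k_PS=0.0, k_R1P=0.0, k_R2P=0.0, f_P0=0.0,
        )
        state = CellState(100.0, 0.0, 0.0, 0.0, params.K_SP)
        d = rhs(0.0, state, params, tam_dose=1.0)
        assert d[0] == pytest.approx(-0.1 * 100.0 - 0.2 * 0.5 * 100.0, rel=1e-12)

    @given(params=params_strategy(), state=state_strategy(),
           dose=st.sampled_from([0.0, 1.0]))
    @settings(deadline=None, max_examples=100)
    def test_conservation_identity(self, params, state, dose):
        """Summed cell derivatives equal total growth minus total death flux:
        transitions only move cells between states."""
        d = rhs(0.0, state, params, dose)
        v = reaction_rates(state, params, dose)
        growth = v.v1 + v.v5 + v.v9 + v.v12
        death = v.v2 + v.v6
        assert d[:4].sum() == pytest.approx(growth - death, rel=1e-9, abs=1e-6)

    @given(params=params_strategy(), state=state_strategy(),
           c=st.floats(min_value=1e-3, max_value=1e3),
           dose=st.sampled_from([0.0, 1.0]))
    @settings(deadline=None, max_examples=100)
    def test_linearity_in_cell_counts(self, params, state, c, dose):
        """Scaling all four cell counts by c scales fluxes and derivatives by c."""
        y = state.to_array()
        scaled = y.copy()
        scaled[:4] *= c
        d1 = rhs(0.0, CellState.from_array(y), params, dose)
        d2 = rhs(0.0, CellState.from_array(scaled), params, dose)
        np.testing.assert_allclose(d2[:4], c * d1[:4], rtol=1e-9, atol=1e-6)
        assert d2[4] == d1[4]

    def test_negative_dose_rejected(self, truth):
        with pytest.raises(InvalidParameterError):
            rhs(0.0, CellState(1.0, 0.0, 0.0, 0.0, 0.0), truth, tam_dose=-1.0)
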