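"""Observation assembly, the wSSPE objective, and the rank-test comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from tamres._fast import predict_flat_batch
from tamres.errors import (
    AlignmentError,
    InsufficientSampleError,
    InvalidParameterError,
    SchemaError,
)
from tamres.fitting import (
    ExperimentDataset,
    FitResult,
    ObservationSet,
    assemble_observations,
    compare_paired_values,
    compare_parameter_distributions,
    effective_constraint_count,
    predict_observations,
    wsspe,
)


def _single_point_set(value):
    return ObservationSet(("growth",), ("tam",), (1,), ("",), np.array([value]))


class TestAssembleObservations:
    def test_standard_design_yields_38_points(self, noise_free_observations):
        assert len(noise_free_observations) == 38

    def test_deterministic_ordering(self, noise_free_observations):
        obs = noise_free_observations
        assert obs.kinds[:22] == ("growth",) * 22
        assert obs.conditions[:11] == ("tam",) * 11
        assert obs.conditions[11:22] == ("ctrl",) * 11
        assert obs.weeks[:11] == tuple(range(1, 12))
        # proportions grouped by week, subpopulations in S, P, R1, R2 order
        assert obs.weeks[22:] == (0, 0, 0, 0, 3, 3, 3, 3, 6, 6, 6, 6, 9, 9, 9, 9)
        assert obs.subpopulations[22:26] == ("S", "P", "R1", "R2")

    def test_incomplete_dataset_rejected(self):
        with pytest.raises(SchemaError, match="growth_ctrl"):
            ExperimentDataset(
                growth_tam=np.ones(11),
                growth_ctrl=np.array([]),
                proportions=np.full((4, 4), 0.25),
            )

    def test_malformed_proportions_rejected(self):
        bad = np.full((4, 4), 0.25)
        bad[2] = [0.5, 0.5, 0.5, 0.5]
        with pytest.raises(SchemaError, match="week 6"):
            ExperimentDataset(
                growth_tam=np.ones(11), growth_ctrl=np.ones(11), proportions=bad
            )

    def test_metadata_round_trips_through_frame(self, noise_free_observations, tmp_path):
        path = tmp_path / "obs.csv"
        noise_free_observations.to_frame().to_csv(path, index=False)
        import pandas as pd

        restored = ObservationSet.from_frame(pd.read_csv(path, keep_default_na=False))
        assert restored.labels == noise_free_observations.labels
        np.testing.assert_allclose(restored.values, noise_free_observations.values)


class TestEffectiveConstraintCount:
    def test_standard_design_is_23(self, noise_free_observations):
        assert effective_constraint_count(noise_free_observations) == 23

    def test_single_proportion_timepoint(self):
        data = ExperimentDataset(
            growth_tam=np.ones(11), growth_ctrl=np.ones(11),
            proportions=np.full((1, 4), 0.25), proportion_weeks=(0,),
        )
        assert effective_constraint_count(assemble_observations(data)) == 14

    def test_growth_only(self):
        obs = ObservationSet(
            ("growth",) * 11, ("tam",) * 11, tuple(range(1, 12)), ("",) * 11,
            np.ones(11),
        )
        assert effective_constraint_count(obs) == 11


class TestWsspe:
    def test_zero_iff_equal(self, noise_free_observations):
        assert wsspe(noise_free_observations, noise_free_observations) == 0.0
        bumped = noise_free_observations.with_values(
            noise_free_observations.values + 1e-6
        )
        assert wsspe(bumped, noise_free_observations) > 0.0

    def test_hand_computed_single_point(self):
        exp = _single_point_set(1.0)
        sim = _single_point_set(1.2)
        assert wsspe(sim, exp) == pytest.approx((0.2 / 1.1) ** 2, abs=1e-12)

    def test_zero_denominator_guard(self):
        """x_exp = 0 is safe: the +0.1 offset keeps the term finite."""
        exp = _single_point_set(0.0)
        sim = _single_point_set(0.05)
        assert wsspe(sim, exp) == pytest.approx(0.25, abs=1e-12)

    def test_label_mismatch_rejected(self, noise_free_observations):
        other = ObservationSet(
            noise_free_observations.kinds,
            noise_free_observations.conditions,
            tuple(w + 1 for w in noise_free_observations.weeks),
            noise_free_observations.subpopulations,
            noise_free_observations.values,
        )
        with pytest.raises(AlignmentError):
            wsspe(other, noise_free_observations)

    @given(st.permutations(range(10)))
    @settings(deadline=None, max_examples=30)
    def test_permutation_invariance(self, perm):
        """Relabeling both sets consistently leaves the loss unchanged."""
        rng = np.random.default_rng(7)
        e = rng.uniform(0.0, 2.0, 10)
        s = rng.uniform(0.0, 2.0, 10)

        def make(values):
            return ObservationSet(
                ("growth",) * 10, ("tam",) * 10, tuple(range(1, 11)), ("",) * 10,
                values,
            )

        def make_perm(values):
            weeks = tuple(int(np.arange(1, 11)[p]) for p in perm)
            return ObservationSet(
                ("growth",) * 10, ("tam",) * 10, weeks, ("",) * 10, values[list(perm)]
            )

        assert wsspe(make(s), make(e)) == pytest.approx(
            wsspe(make_perm(s), make_perm(e)), rel=1e-12
        )


class TestPredictObservations:
    def test_shape_and_alignment(self, truth, noise_free_observations):
        pred = predict_observations(truth)
        assert pred.labels == noise_free_observations.labels

    def test_truth_round_trip_is_exact(self, truth, noise_free_observations):
        """Predictions at the generating parameters equal the noise-free data."""
        pred = predict_observations(truth)
        assert wsspe(pred, noise_free_observations) == pytest.approx(0.0, abs=1e-12)

    def test_no_transition_no_death_makes_conditions_identical(self, exponential_params):
        p = exponential_params.replace(g_S=0.5, f_P0=0.1, g_P=0.3)
        pred = predict_observations(p)
        np.testing.assert_allclose(pred.values[:11], pred.values[11:22], rtol=1e-8)

    def test_fast_path_matches_reference(self, truth):
        """The optimizer's propagator integrator agrees with the adaptive solver."""
        fast = predict_flat_batch(truth.to_array()[None, :])[0]
        ref = predict_observations(truth).values
        np.testing.assert_allclose(fast, ref, rtol=1e-6, atol=1e-8)


class TestSignedRankComparison:
    def test_strictly_greater_gives_extreme_statistic(self, truth):
        rng = np.random.default_rng(0)
        fits = []
        for i in range(20):
            a = 0.5 + 0.01 * rng.random()
            fits.append(FitResult(truth.replace(g_R2=0.6 + a, g_R1=a), 0.0, i, 1, 1, True))
        res = compare_parameter_distributions(fits, "g_R2", "g_R1")
        assert res.statistic == 0.0  # all differences positive
        assert res.p_value < 1e-3
        assert res.median_difference == pytest.approx(0.6, abs=0.02)

    def test_identical_vectors_give_p_one(self, truth):
        fits = [FitResult(truth, 0.0, i, 1, 1, True) for i in range(8)]
        res = compare_parameter_distributions(fits, "g_R1", "g_R1")
        assert res.p_value == 1.0
        assert res.median_difference == 0.0

    def test_too_few_fits_rejected(self, truth):
        fits = [FitResult(truth, 0.0, i, 1, 1, True) for i in range(5)]
        with pytest.raises(InsufficientSampleError):
            compare_parameter_distributions(fits, "g_R1", "g_R2")

    def test_unknown_parameter_rejected(self, truth):
        fits = [FitResult(truth, 0.0, i, 1, 1, True) for i in range(6)]
        with pytest.raises(InvalidParameterError):
            compare_parameter_distributions(fits, "g_R1", "nope")

    @pytest.mark.parametrize(
        "diffs",
        [
            (1.0, 2.0, 3.0, 4.0, 5.0, -1.0),
            (0.5, -0.2, 1.5, -2.5, 3.0, 0.1, -0.7),
            (1.0, 2.0, 3.0, -4.0, 5.0, -6.0, 7.0, 8.0),
        ],
    )
    def test_exact_enumeration_oracle(self, diffs):
        """Two-sided exact p equals the tail fraction over all 2^n sign flips."""
        d = np.array(diffs)
        res = compare_paired_values(d, np.zeros_like(d))
        ranks = rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        total = ranks.sum()
        hits = 0
        for signs in itertools.product((1, -1), repeat=len(d)):
            w_plus = ranks[np.array(signs) > 0].sum()
            if min(w_plus, total - w_plus) <= w_obs:
                hits += 1
        expected_p = hits / 2 ** len(d)
        assert res.statistic == pytest.approx(w_obs)
        assert res.p_value == pytest.approx(expected_p, rel=1e-12)
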