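"""Median-distance statistics, permutation nulls, empirical p and Holm."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brcalike.catalog import GroupDefinition
from brcalike.embedding import Embedding
from brcalike.errors import InvalidInputError, UndefinedStatisticError, ValidationError
from brcalike.resampling import (
    cross_group_median_distance,
    empirical_p,
    group_median_distance,
    holm_adjust,
    permutation_null,
    run_comparison_suite,
)


def _embedding(coords):
    coords = np.asarray(coords, dtype=float)
    return Embedding(
        sample_ids=[f"s{i}" for i in range(len(coords))],
        coords=coords,
        eigenvalues=np.array([1.0, 0.5]),
        captured_fraction=1.0,
    )


class TestMedianStatistics:
    def test_hand_computed_within_median(self):
        coords = np.array([[0.0, 0.0], [0.0, 3.0], [4.0, 0.0]])
        # pair distances 3, 4, 5
        assert group_median_distance(coords, [0, 1, 2]) == 4.0

    def test_pair_group_is_single_distance(self):
        coords = np.array([[0.0, 0.0], [0.0, 2.0]])
        assert group_median_distance(coords, [0, 1]) == 2.0

    def test_coincident_pair_zero(self):
        coords = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert group_median_distance(coords, [0, 1]) == 0.0

    def test_even_count_uses_midpoint(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        # distances 1, 2, 3 -> median 2; add a fourth collinear point
        coords4 = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        # six pair distances: 1,2,4,1,3,2 -> sorted 1,1,2,2,3,4 -> median 2
        assert group_median_distance(coords4, [0, 1, 2, 3]) == 2.0
        assert group_median_distance(coords, [0, 1, 2]) == 2.0

    def test_singleton_group_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            group_median_distance(np.zeros((3, 2)), [0])

    def test_hand_computed_cross_median(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        # cross distances 1 and sqrt(2)
        expected = (1.0 + np.sqrt(2.0)) / 2.0
        assert cross_group_median_distance(coords, [0, 1], [2]) == pytest.approx(expected)

    def test_cross_median_singletons(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert cross_group_median_distance(coords, [0], [1]) == 5.0

    def test_overlapping_groups_refused(self):
        with pytest.raises(ValidationError):
            cross_group_median_distance(np.zeros((3, 2)), [0, 1], [1, 2])


class TestEmpiricalP:
    def test_floor_at_one_over_B(self):
        null = np.ones(100_000)
        p, b = empirical_p(0.5, null)
        assert b == 0
        assert p == pytest.approx(1e-5)

    def test_maximal_p(self):
        null = np.zeros(1000)
        p, b = empirical_p(0.5, null)
        assert (p, b) == (1.0, 1000)

    def test_proportion(self):
        null = np.concatenate([np.zeros(50), np.ones(950)])
        p, b = empirical_p(0.5, null, 1000)
        assert (p, b) == (0.05, 50)

    def test_add_one_convention(self):
        null = np.ones(999)
        p, _ = empirical_p(0.5, null, convention="add-one")
        assert p == pytest.approx(1 / 1000)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_step_down_hand_example(self):
        np.testing.assert_allclose(holm_adjust(np.array([0.01, 0.04])), [0.02, 0.04])

    def test_family_of_fourteen_ties_at_floor(self):
        # five raw values at the 1/100000 floor in a family of 14 adjust
        # to 14e-5 = 1.4e-04 by the cumulative-maximum rule
        raw = np.array([1e-5] * 5 + [6e-5, 1.625e-3, 0.3 / 7, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        adj = holm_adjust(raw)
        np.testing.assert_allclose(adj[:5], 1.4e-4)
        assert adj[5] == pytest.approx(5.4e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust(np.array([0.5, 1.5]))
        with pytest.raises(ValidationError):
            holm_adjust(np.array([0.0, 0.5]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False), min_size=1, max_size=25))
    def test_properties_hold_for_arbitrary_p_vectors(self, p_list):
        p = np.array(p_list)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)  # adjustment never shrinks a p-value
        assert np.all(adj <= 1.0)
        # monotone: ordering of adjusted values follows ordering of raw values
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_brute_force_oracle(self, rng):
        def brute_force(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                adj[idx] = min(running, 1.0)
            return adj

        for _ in range(200):
            m = int(rng.integers(1, 20))
            p = rng.random(m) * 0.999 + 1e-6
            np.testing.assert_allclose(holm_adjust(p), brute_force(p), atol=1e-12)


class TestPermutationNull:
    def test_group_equals_eligible_set_is_degenerate(self, rng):
        coords = rng.normal(size=(6, 2))
        emb = _embedding(coords)
        obs = group_median_distance(coords, np.arange(6))
        null = permutation_null(emb, 6, "within", B=50, seed=1)
        np.testing.assert_allclose(null, obs)

    def test_seed_reproducibility(self, rng):
        emb = _embedding(rng.normal(size=(30, 2)))
        a = permutation_null(emb, 5, "within", B=500, seed=7)
        b = permutation_null(emb, 5, "within", B=500, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        # cohort of 8, groups of 3: 56 possible subsets
        coords = rng.normal(size=(8, 2))
        emb = _embedding(coords)
        exact_stats = np.array(
            [
                group_median_distance(coords, list(s))
                for s in itertools.combinations(range(8), 3)
            ]
        )
        null = permutation_null(emb, 3, "within", B=50_000, seed=11)
        se = exact_stats.std() / np.sqrt(50_000)
        assert abs(null.mean() - exact_stats.mean()) <= 2 * se + 1e-9

    def test_infeasible_sizes_rejected(self, rng):
        emb = _embedding(rng.normal(size=(5, 2)))
        with pytest.raises(InvalidInputError):
            permutation_null(emb, (4, 3), "between", B=10, seed=0)

    def test_between_null_draws_disjoint_groups(self, rng):
        coords = np.zeros((10, 2))
        coords[:5] = [10.0, 0.0]  # two coincident clumps
        emb = _embedding(coords)
        null = permutation_null(emb, (2, 2), "between", B=200, seed=3)
        # cross-medians are 0 or 10: both occur, never negative
        assert set(np.round(np.unique(null), 6)) <= {0.0, 5.0, 10.0}


class TestComparisonSuite:
    def test_group_identical_to_reference_skipped(self, rng):
        emb = _embedding(rng.normal(size=(20, 2)))
        members = frozenset({"s1", "s2", "s3"})
        g = GroupDefinition("G:any", "G", ("somatic_mutation",), members)
        ref = GroupDefinition("BRCA-like", "BRCA1|BRCA2", ("germline_mutation",), members)
        results, skipped = run_comparison_suite(emb, [g], reference=ref, B=100, seed=0)
        assert results == []
        assert any("empty after overlap exclusion" in s for s in skipped)

    def test_holm_applied_across_family(self, rng):
        emb = _embedding(rng.normal(size=(40, 2)))
        groups = [
            GroupDefinition(f"G{i}", f"G{i}", ("somatic_mutation",), frozenset({f"s{3*i}", f"s{3*i+1}", f"s{3*i+2}"}))
            for i in range(4)
        ]
        results, _ = run_comparison_suite(emb, groups, reference=None, B=200, seed=5)
        assert len(results) == 4
        raws = np.array([r.p_raw for r in results])
        np.testing.assert_allclose([r.p_holm for r in results], holm_adjust(raws))
        for r in results:
            assert r.p_holm >= r.p_raw
            assert r.b <= r.B
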