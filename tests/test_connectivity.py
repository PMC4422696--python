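"""Unit and property tests for the rank-based connectivity statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugrepo.connectivity import (
    ConnectivityResult,
    QuerySignature,
    RankedProfile,
    classify_support,
    connectivity_query,
    instance_score,
    ks_enrichment,
    permutation_p,
    ranks_from_expression,
    scale_scores,
    set_enrichment,
)
from drugrepo.errors import ConfigurationError, ValidationError


def brute_force_ks(positions, n):
    """Independent re-derivation: explicit loop over j for both maxima."""
    t = len(positions)
    a = max(j / t - positions[j - 1] / n for j in range(1, t + 1))
    b = max(positions[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


class TestKsEnrichment:
    @pytest.mark.parametrize(
        "positions, n, expected",
        [
            ([1, 2], 10, 0.8),      # tags at the very top
            ([9, 10], 10, -0.9),    # tags at the very bottom
            ([1], 10, 0.9),         # single-tag closed form
        ],
    )
    def test_hand_evaluated_cases(self, positions, n, expected):
        assert ks_enrichment(positions, n) == pytest.approx(expected)

    def test_exhaustive_against_brute_force_oracle(self):
        """Equality with the explicit maximisation on every t<=4, n<=12 case."""
        for n in range(1, 13):
            for t in range(1, min(4, n) + 1):
                for subset in itertools.combinations(range(1, n + 1), t):
                    assert ks_enrichment(list(subset), n) == pytest.approx(
                        brute_force_ks(list(subset), n)
                    ), (subset, n)

    def test_bounded_and_signed(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(5, 50))
            t = int(rng.integers(1, n))
            subset = np.sort(rng.choice(n, size=t, replace=False) + 1)
            score = ks_enrichment(subset, n)
            assert -1 <= score <= 1

    def test_rejects_unsorted_and_out_of_range(self):
        with pytest.raises(ValidationError):
            ks_enrichment([3, 2], 10)
        with pytest.raises(ValidationError):
            ks_enrichment([0, 5], 10)
        with pytest.raises(ValidationError):
            ks_enrichment([5, 11], 10)
        with pytest.raises(ValidationError):
            ks_enrichment([], 10)


def _profile(rank_of, pert="p"):
    return RankedProfile(instance_id="i", perturbagen=pert, ranks=rank_of)


def _uniform_profile(genes, order):
    return _profile({g: r for r, g in enumerate(order, start=1)})


class TestInstanceScore:
    def setup_method(self):
        self.genes = [f"g{i}" for i in range(10)]

    def test_opposed_tag_sets_score_positive(self):
        # up tags at the top, down tags at the bottom
        sig = QuerySignature(up_tags={"g0", "g1"}, down_tags={"g8", "g9"})
        profile = _uniform_profile(self.genes, self.genes)
        assert instance_score(sig, profile) > 0

    def test_same_sign_statistics_give_zero(self):
        # both tag sets concentrated at the top: ks_up and ks_down both positive
        sig = QuerySignature(up_tags={"g0", "g1"}, down_tags={"g2", "g3"})
        profile = _uniform_profile(self.genes, self.genes)
        assert instance_score(sig, profile) == 0.0

    def test_profile_reversal_flips_or_zeroes_the_score(self):
        sig = QuerySignature(up_tags={"g0", "g1"}, down_tags={"g8", "g9"})
        fwd = _uniform_profile(self.genes, self.genes)
        rev = _profile({g: 11 - r for g, r in fwd.ranks.items()})
        s_fwd, s_rev = instance_score(sig, fwd), instance_score(sig, rev)
        assert s_rev == pytest.approx(-s_fwd) or s_rev == 0.0

    def test_missing_tag_is_named_in_the_error(self):
        sig = QuerySignature(up_tags={"absent"}, down_tags={"g9"})
        with pytest.raises(ValidationError, match="absent"):
            instance_score(sig, _uniform_profile(self.genes, self.genes))

    def test_score_bounded_in_two(self):
        rng = np.random.default_rng(3)
        sig = QuerySignature(up_tags={"g0", "g3"}, down_tags={"g7", "g9"})
        for _ in range(50):
            order = list(rng.permutation(self.genes))
            assert abs(instance_score(sig, _uniform_profile(self.genes, order))) <= 2

    def test_overlapping_tag_sets_rejected(self):
        with pytest.raises(ValidationError):
            QuerySignature(up_tags={"g0"}, down_tags={"g0", "g1"})


class TestScaleScores:
    def test_direct_normalisation(self):
        assert scale_scores([2, 1, 0, -0.5]).tolist() == [1.0, 0.5, 0.0, -1.0]

    def test_all_zeros_stay_zero(self):
        assert scale_scores([0.0, 0.0]).tolist() == [0.0, 0.0]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30))
    def test_rank_order_preserved(self, raw):
        scaled = scale_scores(raw)
        assert np.argsort(raw, kind="stable").tolist() == \
            np.argsort(scaled, kind="stable").tolist()
        assert np.all(np.abs(scaled) <= 1 + 1e-12)


class TestSetEnrichment:
    def test_members_at_the_top_reach_the_maximum(self):
        for n, t in [(10, 2), (50, 5), (100, 10)]:
            assert set_enrichment(list(range(1, t + 1)), n) == pytest.approx(1 - t / n)

    def test_members_at_the_bottom_strongly_negative(self):
        assert set_enrichment([9, 10], 10) < -0.5
        assert set_enrichment(list(range(91, 101)), 100) < -0.8

    def test_same_statistic_as_tag_enrichment(self):
        assert set_enrichment([2, 5, 7], 12) == ks_enrichment([2, 5, 7], 12)


class TestPermutationP:
    def test_exact_enumeration_oracle_small_n(self):
        """MC tail probability matches exhaustive subset enumeration at N<=8."""
        for n, t in [(6, 2), (8, 3), (8, 7)]:
            subsets = list(itertools.combinations(range(1, n + 1), t))
            for observed_set in [subsets[0], subsets[-1], subsets[len(subsets) // 2]]:
                observed = set_enrichment(list(observed_set), n)
                exact = sum(
                    abs(set_enrichment(list(s), n)) >= abs(observed) - 1e-12
                    for s in subsets
                ) / len(subsets)
                p = permutation_p(observed, t, n, n_perm=4000, seed=5)
                # add-one MC estimate of an exact discrete tail
                assert p == pytest.approx(exact, abs=3 * math.sqrt(exact / 4000) + 2e-3)

    def test_observed_zero_is_unremarkable(self):
        assert permutation_p(0.0, 3, 30, n_perm=500, seed=1) > 0.9

    def test_deterministic_under_seed(self):
        a = permutation_p(0.5, 4, 40, n_perm=300, seed=11)
        b = permutation_p(0.5, 4, 40, n_perm=300, seed=11)
        assert a == b

    def test_validates_arguments(self):
        with pytest.raises(ValidationError):
            permutation_p(0.5, 10, 10, n_perm=200, seed=0)
        with pytest.raises(ConfigurationError):
            permutation_p(0.5, 2, 10, n_perm=50, seed=0)


class TestClassifySupport:
    def _res(self, subject, enrichment, p, direction):
        return ConnectivityResult(
            subject=subject, reference="ref", enrichment=enrichment,
            p_value=p, n_instances=5, direction_of_reference=direction,
        )

    def test_published_association_pattern(self):
        results = [
            self._res("diflorasone", -0.709, 0.015, "diabetogenic"),
            self._res("valdecoxib", 0.412, 0.047, "anti_diabetic"),
            self._res("phenoxybenzamine", 0.799, 0.034, "glucose_improving"),
        ]
        out = classify_support(results, alpha=0.05)
        assert set(out.values()) == {"supported"}

    def test_insignificant_or_wrong_direction_is_data_no_link(self):
        results = [
            self._res("a", 0.9, 0.2, "anti_diabetic"),       # fails significance
            self._res("b", -0.8, 0.01, "anti_diabetic"),      # wrong direction
            self._res("c", 0.8, 0.01, "diabetogenic"),        # wrong direction
        ]
        out = classify_support(results, alpha=0.05)
        assert out == {"a": "data_no_link", "b": "data_no_link", "c": "data_no_link"}

    def test_alpha_validated(self):
        with pytest.raises(ConfigurationError):
            classify_support([], alpha=1.5)


class TestConnectivityQuery:
    def test_planted_perturbagen_ranks_first(self, small_config):
        from drugrepo.simulate import generate_profiles, generate_signature

        sig = generate_signature(small_config)
        labels = ["hit", "null_a", "null_b", "null_c"]
        profiles = generate_profiles(
            small_config, sig, linked_labels=["hit"], all_labels=labels
        )
        query = connectivity_query(sig, profiles, n_perm=200, seed=9)
        best = query.sort_values("enrichment", ascending=False).iloc[0]
        assert best["subject"] == "hit"
        assert best["enrichment"] > 0

    def test_deterministic_under_seed(self, small_config):
        from drugrepo.simulate import generate_profiles, generate_signature

        sig = generate_signature(small_config)
        profiles = generate_profiles(small_config, sig, linked_labels=["x"])
        q1 = connectivity_query(sig, profiles, n_perm=150, seed=3)
        q2 = connectivity_query(sig, profiles, n_perm=150, seed=3)
        assert q1.equals(q2)


def test_ranks_from_expression_breaks_ties_by_input_order():
    values = {"a": 2.0, "b": 5.0, "c": 2.0, "d": -1.0}
    ranks = ranks_from_expression(values)
    assert ranks == {"b": 1, "a": 2, "c": 3, "d": 4}
    # output is always a strict permutation, so it feeds the KS statistic
    RankedProfile(instance_id="i", perturbagen="p", ranks=ranks)
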