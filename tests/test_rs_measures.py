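import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regsim as rs
from regsim.rs_measures import DEFAULT_CONFIG, PoissonBackground, infer_total_tf_count

from conftest import make_profile


def profile(gene_id, sites, L=1000):
    return rs.PromoterProfile(
        gene_id=gene_id,
        length_L=L,
        sites={tf: np.array(sorted(offs), dtype=np.int64) for tf, offs in sites.items()},
    )


# ---------------------------------------------------------------------------
# offset distance
# ---------------------------------------------------------------------------


class TestOffsetDistance:
    def test_minimum_over_all_cross_pairs(self):
        a = profile("A", {"X": [50, 200]})
        b = profile("B", {"X": [60, 300]})
        assert rs.offset_distance(a, b, "X") == 10  # min of {10, 250, 140, 100}

    def test_identical_singletons_give_zero(self):
        a = profile("A", {"X": [77]})
        b = profile("B", {"X": [77]})
        assert rs.offset_distance(a, b, "X") == 0

    def test_absent_tf_gives_none(self):
        a = profile("A", {"X": [1]})
        b = profile("B", {"Y": [1]})
        assert rs.offset_distance(a, b, "X") is None

    @given(
        xs=st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=12),
        ys=st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_pairwise_minimum(self, xs, ys):
        a = profile("A", {"X": xs}, L=2 * 10**6)
        b = profile("B", {"X": ys}, L=2 * 10**6)
        oracle = min(abs(x - y) for x in xs for y in ys)
        assert rs.offset_distance(a, b, "X") == oracle


# ---------------------------------------------------------------------------
# the location-aware measure
# ---------------------------------------------------------------------------


class TestProposed:
    @given(
        L=st.integers(min_value=10, max_value=5000),
        d1_frac=st.floats(min_value=0, max_value=1),
        d2_frac=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_two_common_of_three_tfs_symbolic_form(self, L, d1_frac, d2_frac):
        # union of three TFs, two common at offset distances d1, d2:
        # RS = (1/3) ((L - d1)/L + (L - d2)/L)
        d1 = int(d1_frac * (L - 1))
        d2 = int(d2_frac * (L - 1))
        a = profile("A", {"T1": [1], "T2": [1]}, L=L)
        b = profile("B", {"T1": [1 + d1], "T2": [1 + d2], "T3": [5]}, L=L)
        expected = ((L - d1) / L + (L - d2) / L) / 3
        assert rs.rs_proposed(a, b) == pytest.approx(expected, abs=1e-12)

    def test_substitution_example_two_thirds(self):
        a = profile("A", {"A": [10], "B": [20]}, L=100)
        b = profile("B", {"A": [10], "B": [20], "C": [30]}, L=100)
        assert rs.rs_proposed(a, b) == pytest.approx(2 / 3)

    def test_identical_profiles_score_one(self):
        a = profile("A", {"A": [10], "B": [20], "C": [900]}, L=1000)
        assert rs.rs_proposed(a, a) == pytest.approx(1.0)

    def test_empty_union_and_no_common_tf(self):
        empty = profile("E", {}, L=0)
        assert rs.rs_proposed(empty, empty) == 0.0
        a = profile("A", {"X": [1]})
        b = profile("B", {"Y": [1]})
        assert rs.rs_proposed(a, b) == 0.0

    def test_equals_jaccard_when_all_distances_zero_else_below(self):
        rng = np.random.default_rng(3)
        tf_pool = [f"T{i}" for i in range(8)]
        for _ in range(300):
            a = make_profile(rng, "A", tf_pool)
            b = make_profile(rng, "B", tf_pool)
            prop = rs.rs_proposed(a, b)
            jac = rs.rs_jaccard(a.tf_set, b.tf_set)
            assert prop <= jac + 1e-12
            common = a.tf_set & b.tf_set
            if common and all(
                rs.offset_distance(a, b, tf) == 0 for tf in common
            ):
                assert prop == pytest.approx(jac)

    def test_monotone_nonincreasing_in_each_distance(self):
        L = 500
        for d_small, d_big in [(0, 1), (10, 100), (100, 499)]:
            a = profile("A", {"T1": [1], "T2": [250]}, L=L)
            near = profile("B", {"T1": [1 + d_small], "T2": [250]}, L=L)
            far = profile("B", {"T1": [1 + d_big], "T2": [250]}, L=L)
            assert rs.rs_proposed(a, near) >= rs.rs_proposed(a, far)

    def test_translation_invariance_of_offsets(self):
        a = profile("A", {"T1": [10, 40], "T2": [100]}, L=1000)
        b = profile("B", {"T1": [25], "T2": [300], "T3": [7]}, L=1000)
        shift = 123
        a2 = profile("A", {tf: list(o + shift) for tf, o in a.sites.items()}, L=1000)
        b2 = profile("B", {tf: list(o + shift) for tf, o in b.sites.items()}, L=1000)
        assert rs.rs_proposed(a, b) == pytest.approx(rs.rs_proposed(a2, b2))


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------


def hypergeom_tail_oracle(N, m, n, k):
    """Exhaustive enumeration of P(X >= k) for overlap of m- and n-sets."""
    total = 0.0
    for x in range(k, min(m, n) + 1):
        total += math.comb(m, x) * math.comb(N - m, n - x) / math.comb(N, n)
    return total


class TestGarten:
    def test_fully_overlapping_triplets(self):
        # N=10, m=n=k=3 -> p = 1/C(10,3) = 1/120
        score = rs.rs_garten({"A", "B", "C"}, {"A", "B", "C"}, N=10)
        assert score == pytest.approx(-math.log10(1 / 120), abs=1e-12)

    def test_no_overlap_scores_zero(self):
        assert rs.rs_garten({"A"}, {"B"}, N=10) == 0.0

    def test_population_smaller_than_set_rejected(self):
        with pytest.raises(rs.ValidationError):
            rs.rs_garten({"A", "B", "C"}, {"A"}, N=2)

    def test_matches_enumeration_oracle_small_populations(self):
        rng = np.random.default_rng(12)
        pool = [f"T{i}" for i in range(25)]
        for _ in range(400):
            N = int(rng.integers(2, 26))
            m = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            a = set(rng.choice(pool[:N], size=m, replace=False))
            b = set(rng.choice(pool[:N], size=n, replace=False))
            k = len(a & b)
            got = rs.rs_garten(a, b, N=N)
            if k == 0:
                assert got == 0.0
            else:
                expected = -math.log10(hypergeom_tail_oracle(N, m, n, k))
                assert got == pytest.approx(expected, abs=1e-9)

    def test_log_base_e_option(self):
        cfg = rs.RSConfig(log_base_eq1=math.e)
        score = rs.rs_garten({"A", "B", "C"}, {"A", "B", "C"}, N=10, cfg=cfg)
        assert score == pytest.approx(-math.log(1 / 120))


# ---------------------------------------------------------------------------
# Jaccard / Shalgi
# ---------------------------------------------------------------------------


class TestSetRatios:
    @pytest.mark.parametrize(
        "a, b, jaccard, shalgi",
        [
            ({"A", "B"}, {"B", "C"}, 1 / 3, 1 / 2),
            ({"A", "B"}, {"A", "B"}, 1.0, 1.0),
            ({"A", "B"}, {"C", "D"}, 0.0, 0.0),
            ({"A", "B", "C"}, {"A"}, 1 / 3, 1.0),
        ],
    )
    def test_examples(self, a, b, jaccard, shalgi):
        assert rs.rs_jaccard(a, b) == pytest.approx(jaccard)
        assert rs.rs_shalgi(a, b) == pytest.approx(shalgi)

    def test_empty_inputs_use_empty_union_score(self):
        cfg = rs.RSConfig(empty_union_score=-1.0)
        assert rs.rs_jaccard(set(), set(), cfg) == -1.0
        assert rs.rs_shalgi(set(), {"A"}, cfg) == -1.0

    def test_shalgi_dominates_jaccard(self):
        rng = np.random.default_rng(5)
        pool = [f"T{i}" for i in range(10)]
        for _ in range(300):
            a = set(rng.choice(pool, size=int(rng.integers(1, 8)), replace=False))
            b = set(rng.choice(pool, size=int(rng.integers(1, 8)), replace=False))
            assert rs.rs_shalgi(a, b) >= rs.rs_jaccard(a, b) - 1e-12


# ---------------------------------------------------------------------------
# copy-count measures
# ---------------------------------------------------------------------------


class TestPark:
    def test_balanced_shared_tfs_reduce_to_alpha_times_copies(self):
        a = profile("A", {"T1": [1, 2], "T2": [3]})
        b = profile("B", {"T1": [5, 6], "T2": [9]})
        cfg = rs.RSConfig(park_alpha=2.0, park_beta=0.5)
        assert rs.rs_park(a, b, cfg) == pytest.approx(2.0 * (2 + 1))

    def test_disjoint_tfs_give_pure_penalty(self):
        a = profile("A", {"T1": [1, 2]})
        b = profile("B", {"T2": [5], "T3": [6]})
        cfg = rs.RSConfig(park_beta=0.5)
        assert rs.rs_park(a, b, cfg) == pytest.approx(-0.5 * 4)

    def test_unbalanced_counts_add_weighted_agreement_term(self):
        a = profile("A", {"T1": [1, 2, 3]})
        b = profile("B", {"T1": [9]})
        # f = 3/4 -> (1/4)^2 * 4 + alpha * 1
        assert rs.rs_park(a, b) == pytest.approx(0.25**2 * 4 + 1.0)


class TestVanHelden:
    def make_pair(self, rng, tf_pool):
        a = make_profile(rng, "A", tf_pool)
        b = make_profile(rng, "B", tf_pool)
        bg = PoissonBackground.from_profiles([a, b])
        return a, b, bg

    def test_identical_profiles_have_zero_dissimilarity(self):
        a = profile("A", {"T1": [5], "T2": [70]})
        bg = PoissonBackground.from_profiles([a, a])
        cfg = rs.RSConfig(vanhelden_alpha=1.0, vanhelden_beta=0.25)
        score = rs.rs_vanhelden(a, a, bg, cfg)
        from scipy import stats

        mu = sum(bg.presence_prob(tf, a.length_L) ** 2 for tf in bg.per_tf_rate)
        s_aa = float(stats.poisson.cdf(1, mu))  # c = 2 common TFs
        assert score == pytest.approx(s_aa + 0.25)

    def test_no_common_tfs_scores_minus_alpha_d_plus_beta(self):
        a = profile("A", {"T1": [5]}, L=100)
        b = profile("B", {"T2": [5, 50, 80]}, L=4000)
        bg = PoissonBackground.from_profiles([a, b])
        from scipy import stats

        p_a = float(stats.poisson.sf(0, bg.total_rate * a.length_L))
        p_b = float(stats.poisson.sf(2, bg.total_rate * b.length_L))
        cfg = rs.RSConfig(vanhelden_alpha=2.0, vanhelden_beta=0.1)
        assert rs.rs_vanhelden(a, b, bg, cfg) == pytest.approx(-2.0 * abs(p_a - p_b) + 0.1)


# ---------------------------------------------------------------------------
# symmetry of all six measures
# ---------------------------------------------------------------------------


def test_all_measures_symmetric_in_gene_order():
    rng = np.random.default_rng(99)
    tf_pool = [f"T{i}" for i in range(9)]
    N = len(tf_pool)
    for _ in range(200):
        a = make_profile(rng, "A", tf_pool, length=int(rng.integers(100, 2000)))
        b = make_profile(rng, "B", tf_pool, length=int(rng.integers(100, 2000)))
        bg = PoissonBackground.from_profiles([a, b])
        assert rs.rs_proposed(a, b) == pytest.approx(rs.rs_proposed(b, a))
        assert rs.rs_garten(a.tf_set, b.tf_set, N) == pytest.approx(
            rs.rs_garten(b.tf_set, a.tf_set, N)
        )
        assert rs.rs_jaccard(a.tf_set, b.tf_set) == pytest.approx(
            rs.rs_jaccard(b.tf_set, a.tf_set)
        )
        assert rs.rs_shalgi(a.tf_set, b.tf_set) == pytest.approx(
            rs.rs_shalgi(b.tf_set, a.tf_set)
        )
        assert rs.rs_park(a, b) == pytest.approx(rs.rs_park(b, a))
        assert rs.rs_vanhelden(a, b, bg) == pytest.approx(rs.rs_vanhelden(b, a, bg))


# ---------------------------------------------------------------------------
# all-pairs scoring
# ---------------------------------------------------------------------------


class TestScoreAllPairs:
    def test_empty_profile_dropped_and_head_to_head_removed(self):
        profiles = [
            profile("G1", {"A": [1]}),
            profile("G2", {"A": [2]}),
            profile("G3", {"B": [3]}),
            profile("G4", {"A": [4], "B": [5]}),
            profile("G5", {}, L=0),
        ]
        table = rs.score_all_pairs(
            profiles, ["jaccard"], exclusions={("G1", "G2")}
        )
        assert len(table) == 6 - 1  # C(4,2) - 1
        assert "G5" not in set(table["gene_a"]) | set(table["gene_b"])

    def test_pair_count_without_exclusions(self):
        profiles = [profile(f"G{i}", {"A": [i + 1]}) for i in range(6)]
        assert rs.score_all_pairs(profiles, [], count_only=True) == 15

    def test_count_only_matches_scored_row_count(self, pipeline):
        profiles = pipeline["profiles"]
        h2h = pipeline["head_to_head"]
        n = rs.score_all_pairs(profiles, [], exclusions=h2h, count_only=True)
        table = rs.score_all_pairs(profiles, ["jaccard"], exclusions=h2h)
        assert len(table) == n

    def test_unknown_measure_rejected(self):
        with pytest.raises(rs.ValidationError, match="unknown measure"):
            rs.score_all_pairs([], ["sorensen"])

    def test_rows_ordered_gene_a_before_gene_b(self, scored):
        table, _ = scored
        assert (table["gene_a"] < table["gene_b"]).all()

    def test_inferred_population_size(self, pipeline):
        assert infer_total_tf_count(pipeline["profiles"]) == 12
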