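"""COXSIM, maxCOXSIM, the exact/Monte-Carlo null, P-values and stars."""

import numpy as np
import pytest

import coxnet
from coxnet import (CoxsimConfig, DataError, OrthologMap, Platform,
                    coxsim, resolve_k, stars, p_value)
from coxnet.quality import (overlap_counts, max_coxsim, null_distribution,
                            exact_null_sf, assess_supportability)
from coxnet.coexpression import mutual_rank, pearson_all_pairs

from conftest import random_expr


IDENT = {c: {c} for c in "abcdefghij"}


def naive_coxsim(list_g, list_r, mapping, k):
    """Double-loop oracle straight from the definition."""
    total = 0
    for i in range(1, k + 1):
        top_g, top_r = list_g[:i], set(list_r[:i])
        total += sum(1 for g in top_g if mapping.get(g, set()) & top_r)
    return total / (k * (k + 1) / 2)


class TestOverlapCounts:
    def test_identical_lists_count_everything(self):
        n = overlap_counts(list("abcd"), list("abcd"), IDENT, 4)
        np.testing.assert_array_equal(n, [1, 2, 3, 4])

    def test_correspondence_free_genes_count_nothing(self):
        n = overlap_counts(list("abcd"), list("abcd"), {}, 4)
        np.testing.assert_array_equal(n, [0, 0, 0, 0])

    def test_swapped_pairs_by_hand(self):
        n = overlap_counts(list("abcd"), list("badc"), IDENT, 4)
        np.testing.assert_array_equal(n, [0, 2, 2, 4])

    def test_k_beyond_list_length_rejected(self):
        with pytest.raises(DataError, match="exceeds"):
            overlap_counts(list("ab"), list("ab"), IDENT, 3)

    def test_counts_are_monotone_and_bounded(self, rng):
        for _ in range(20):
            g = [f"x{i}" for i in rng.permutation(30)]
            r = [f"x{i}" for i in rng.permutation(30)]
            mapping = {x: {x} for x in g}
            n = overlap_counts(g, r, mapping, 10)
            assert np.all(np.diff(n) >= 0)
            assert np.all(n <= np.arange(1, 11))


class TestCoxsim:
    def test_identical_lists_score_one(self):
        assert coxsim(list("abcd"), list("abcd"), IDENT, 4) == 1.0

    def test_hand_worked_example(self):
        assert coxsim(list("abcd"), list("badc"), IDENT, 4) == pytest.approx(0.8)

    def test_disjoint_lists_score_zero(self):
        assert coxsim(list("abcd"), list("efgh"), IDENT, 4) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(30):
            na, nb = rng.integers(20, 100, size=2)
            g = [f"x{i}" for i in rng.permutation(na)]
            r = [f"x{i}" for i in rng.permutation(nb)]
            mapping = {x: {x} for x in g}
            k = int(rng.integers(1, min(na, nb) + 1))
            assert coxsim(g, r, mapping, k) == pytest.approx(
                naive_coxsim(g, r, mapping, k), abs=1e-12)

    def test_symmetric_for_one_to_one_map_and_equal_lengths(self, rng):
        n = 25
        g = [f"x{i}" for i in rng.permutation(n)]
        r = [f"x{i}" for i in rng.permutation(n)]
        fwd = {x: {x} for x in g}
        assert coxsim(g, r, fwd, 8) == pytest.approx(coxsim(r, g, fwd, 8))


class TestResolveK:
    @pytest.mark.parametrize("n,frac,expect", [
        (19_803, 0.01, 198),
        (50, 0.01, 1),
        (120, 1.0, 120),
        (999, 0.01, 10),
        (150, 0.01, 2),  # 1.5 rounds half-up
    ])
    def test_rounding_rule(self, n, frac, expect):
        assert resolve_k(n, frac) == expect


def _platform_pair_tables(rng, n=30, samples=12):
    ex_a = random_expr(rng, n, samples)
    mrt_a = mutual_rank(pearson_all_pairs(ex_a))
    ex_b = random_expr(rng, n, samples)
    mrt_b = mutual_rank(pearson_all_pairs(ex_b))
    return mrt_a, mrt_b


class TestMaxCoxsim:
    def test_same_platform_reference_scores_one(self, rng):
        mrt, _ = _platform_pair_tables(rng)
        pa = Platform("A", "sp1", set(mrt.gene_ids))
        pa2 = Platform("A2", "sp1", set(mrt.gene_ids))
        best, val, n_refs = max_coxsim("g0", pa, mrt, [(pa2, mrt)],
                                       OrthologMap({}),
                                       CoxsimConfig(k_fraction=0.1))
        assert best == ("A2", "g0")
        assert val == pytest.approx(1.0)
        assert n_refs == 1

    def test_empty_reference_set_flags_no_reference(self, rng):
        mrt, mrt_b = _platform_pair_tables(rng)
        pa = Platform("A", "sp1", set(mrt.gene_ids))
        pb = Platform("B", "sp2", set(mrt_b.gene_ids))
        best, val, n_refs = max_coxsim("g0", pa, mrt, [(pb, mrt_b)],
                                       OrthologMap({}))
        assert best is None and np.isnan(val) and n_refs == 0

    def test_returns_argmax_over_enumerated_references(self, rng):
        mrt_a, mrt_b = _platform_pair_tables(rng)
        pa = Platform("A", "sp1", set(mrt_a.gene_ids))
        pb = Platform("B", "sp2", {f"h_{g}" for g in mrt_b.gene_ids})
        renamed = mutual_rank(pearson_all_pairs(
            random_expr(rng, 30, 12)))
        renamed.gene_ids = [f"h_{g}" for g in renamed.gene_ids]
        # guide's ortholog group holds 3 candidate reference genes in B;
        # the remaining genes map one-to-one through their own groups
        group_of = {("A", "g0"): "GX", ("B", "h_g0"): "GX",
                    ("B", "h_g5"): "GX", ("B", "h_g9"): "GX"}
        for g in mrt_a.gene_ids[1:]:
            if g in ("g5", "g9"):
                continue  # their B counterparts already belong to GX
            group_of[("A", g)] = f"G_{g}"
            group_of[("B", f"h_{g}")] = f"G_{g}"
        omap = OrthologMap(group_of)
        cfg = CoxsimConfig(k_fraction=0.2)
        best, val, n_refs = max_coxsim("g0", pa, mrt_a, [(pb, renamed)],
                                       omap, cfg)
        assert n_refs == 3
        k = resolve_k(29, 0.2)
        gi = mrt_a.gene_ids.index("g0")
        top_g = [mrt_a.gene_ids[j] for j in mrt_a.list_order()[gi, :k]]
        from coxnet.network import map_gene
        corr = {g: map_gene(omap, pa, g, pb) for g in mrt_a.gene_ids}
        by_hand = {}
        for cand in ["h_g0", "h_g5", "h_g9"]:
            ri = renamed.gene_ids.index(cand)
            top_r = [renamed.gene_ids[j] for j in renamed.list_order()[ri, :k]]
            by_hand[cand] = coxsim(top_g, top_r, corr, k)
        assert val == pytest.approx(max(by_hand.values()))
        assert best == ("B", max(sorted(by_hand), key=lambda c: by_hand[c]))


class TestNullDistribution:
    def test_monte_carlo_mean_matches_analytic_expectation(self):
        cfg = CoxsimConfig(null_reps=10_000, seed=42)
        null = null_distribution(500, 500, 1, 5, cfg)
        se = null.samples.std(ddof=1) / np.sqrt(len(null.samples))
        assert abs(null.samples.mean() - null.analytic_mean) < 3 * se
        assert null.analytic_mean == pytest.approx((2 * 5 + 1) / (3 * 500))

    def test_saturated_k_equals_n_attains_full_final_overlap(self):
        # k = N: every gene is matched at depth N, so n(N) = N in every
        # draw and the numerator never falls below N
        cfg = CoxsimConfig(null_reps=200, seed=0)
        null = null_distribution(6, 6, 1, 6, cfg)
        numer = null.samples * null.denom
        assert numer.min() >= 6 - 1e-9
        assert null.samples.max() <= 1.0
        assert null.exact_sf[6] == pytest.approx(1.0)

    def test_equal_seeds_reproduce_samples(self):
        cfg = CoxsimConfig(null_reps=500, seed=9)
        a = null_distribution(200, 200, 1, 4, cfg)
        b = null_distribution(200, 200, 1, 4, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_exact_sf_is_a_probability_distribution(self):
        sf = exact_null_sf(6, 80)
        assert sf[0] == pytest.approx(1.0)
        assert np.all(np.diff(sf) <= 1e-15)
        assert sf[-1] > 0

    def test_exact_sf_matches_monte_carlo_body(self):
        cfg = CoxsimConfig(null_reps=10_000, seed=5)
        null = null_distribution(100, 100, 1, 6, cfg)
        denom = 21
        for s in (1, 3, 6):
            emp = np.mean(null.samples >= s / denom)
            exact = null.exact_sf[s]
            se = np.sqrt(exact * (1 - exact) / cfg.null_reps)
            assert abs(emp - exact) < 4 * se + 1e-12

    def test_exact_sf_matches_enumeration_at_tiny_size(self):
        # k = N = 2: the correspondence is a uniform bijection of 2 genes.
        # S = n(1) + n(2); n(2) = 2 always; n(1) = 1 iff the top genes pair
        # up (prob 1/2). So P(S>=3) = 1, P(S>=3)... S in {2, 3} each 1/2.
        sf = exact_null_sf(2, 2)
        assert sf[2] == pytest.approx(1.0)
        assert sf[3] == pytest.approx(0.5)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            null_distribution(10, 10, 1, 11, CoxsimConfig(null_reps=100))


class TestPValue:
    def test_observation_below_null_mean_is_not_significant(self):
        null = null_distribution(500, 500, 1, 5,
                                 CoxsimConfig(null_reps=1000, seed=1))
        assert p_value(0.0, null) == 1.0

    def test_perfect_concordance_at_realistic_depth_is_extreme(self):
        # top 1% of a 10 000-gene list: k = 100
        null = null_distribution(10_000, 10_000, 1, 100,
                                 CoxsimConfig(null_reps=100, seed=1))
        assert p_value(1.0, null) < 1e-32

    def test_single_reference_correction_is_identity(self):
        null = null_distribution(300, 300, 1, 5,
                                 CoxsimConfig(null_reps=500, seed=2))
        obs = 0.4
        assert p_value(obs, null, n_refs=1) == null.sf(obs)

    def test_sidak_correction_grows_with_references(self):
        null = null_distribution(300, 300, 1, 5,
                                 CoxsimConfig(null_reps=500, seed=2))
        p1 = p_value(0.5, null, n_refs=1)
        p5 = p_value(0.5, null, n_refs=5)
        assert p1 < p5 <= 1.0
        assert p5 == pytest.approx(1 - (1 - p1) ** 5)

    def test_out_of_range_observation_rejected(self):
        null = null_distribution(300, 300, 1, 5,
                                 CoxsimConfig(null_reps=500, seed=2))
        with pytest.raises(DataError, match="outside"):
            p_value(1.5, null)


class TestStars:
    @pytest.mark.parametrize("p,expect", [
        (1e-5, 1), (1e-20, 2), (1e-33, 3), (0.5, 0),
        (1e-4, 0), (1e-16, 1), (1e-32, 2),  # strict thresholds
    ])
    def test_thresholds(self, p, expect):
        assert stars(p) == expect

    def test_monotone_non_increasing_in_p(self):
        ps = np.logspace(-40, 0, 60)
        vals = [stars(p) for p in ps]
        assert vals == sorted(vals, reverse=True)


class TestAssessSupportability:
    def test_no_reference_genes_reported_as_blank(self, rng):
        mrt_a, mrt_b = _platform_pair_tables(rng)
        pa = Platform("A", "sp1", set(mrt_a.gene_ids))
        pb = Platform("B", "sp2", set(mrt_b.gene_ids))
        res = assess_supportability(["g0", "g1"], pa, mrt_a, [(pb, mrt_b)],
                                    OrthologMap({}),
                                    CoxsimConfig(null_reps=200))
        assert all(r.best_reference is None and r.stars == 0 for r in res)

    def test_stars_consistent_with_p_values(self, rng):
        mrt_a, mrt_b = _platform_pair_tables(rng)
        pa = Platform("A", "sp1", set(mrt_a.gene_ids))
        pa2 = Platform("A2", "sp1", set(mrt_b.gene_ids) | set(mrt_a.gene_ids))
        res = assess_supportability(mrt_a.gene_ids[:5], pa, mrt_a,
                                    [(pa2, mrt_a)], OrthologMap({}),
                                    CoxsimConfig(null_reps=500, seed=3))
        for r in res:
            assert r.stars == stars(r.p_value)
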