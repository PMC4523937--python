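import itertools
import math

import numpy as np
import pytest

from fdmrank.core_genomics import GenomicInterval, IntervalTrack, SignalTrack
from fdmrank.coupling import CouplingRecord
from fdmrank.rank_aggregation import AggregationResult
from fdmrank.validation import (
    GeneSet,
    SamplingError,
    annotation_enrichment_ratio,
    gene_set_permutation_test,
    hypergeometric_overlap,
    matched_random_regions,
    mean_relative_rank_of_gene_set,
    region_signal_empirical_p,
    top_tail_comparison,
)


def make_agg(ordered_ids, label="agg"):
    n = len(ordered_ids)
    rho = {r: (i + 1) / n for i, r in enumerate(ordered_ids)}
    return AggregationResult(label, rho, list(ordered_ids), n_lists=1)


def coupling(dmr, gene):
    return CouplingRecord(dmr, gene, "coding", "gene-proximal", 100)


class TestMeanRelativeRankOfGeneSet:
    def test_mean_of_best_ranks(self):
        agg = make_agg([f"d{i}" for i in range(10)])
        couplings = [coupling("d0", "gA"), coupling("d4", "gB")]
        gs = GeneSet("known", frozenset({"gA", "gB"}))
        # gA best rank 0.1, gB best rank 0.5
        assert mean_relative_rank_of_gene_set(gs, agg, couplings) == pytest.approx(0.3)

    def test_gene_takes_smallest_rank_over_many_dmrs(self):
        agg = make_agg([f"d{i}" for i in range(10)])
        couplings = [coupling("d8", "gA"), coupling("d1", "gA")]
        gs = GeneSet("known", frozenset({"gA"}))
        assert mean_relative_rank_of_gene_set(gs, agg, couplings) == pytest.approx(0.2)

    def test_all_genes_at_worst_rank(self):
        agg = make_agg(["d0", "d1"])
        couplings = [coupling("d1", "gA")]
        gs = GeneSet("known", frozenset({"gA"}))
        assert mean_relative_rank_of_gene_set(gs, agg, couplings) == pytest.approx(1.0)

    def test_uncoupled_gene_set_errors(self):
        agg = make_agg(["d0"])
        with pytest.raises(ValueError):
            mean_relative_rank_of_gene_set(
                GeneSet("known", frozenset({"gX"})), agg, []
            )


class TestGeneSetPermutationTest:
    def setup_universe(self, n_genes=40, seed=0):
        rng = np.random.default_rng(seed)
        dmrs = [f"d{i}" for i in range(n_genes)]
        order = list(rng.permutation(dmrs))
        agg = make_agg(order)
        couplings = [coupling(f"d{i}", f"g{i}") for i in range(n_genes)]
        return agg, couplings

    def test_reproducible_under_fixed_seed(self):
        agg, couplings = self.setup_universe()
        gs = GeneSet("s", frozenset({"g0", "g1", "g2"}))
        r1 = gene_set_permutation_test(gs, agg, couplings, n_reps=500, seed=42)
        r2 = gene_set_permutation_test(gs, agg, couplings, n_reps=500, seed=42)
        assert r1.p_value == r2.p_value and r1.null_mean == r2.null_mean

    def test_global_minimum_reported_as_bound(self):
        agg, couplings = self.setup_universe()
        # genes coupled to the top-3 ranked DMRs: no random mean is smaller
        top = [agg.ordering[i] for i in range(3)]
        gs = GeneSet("s", frozenset(f"g{d[1:]}" for d in top))
        res = gene_set_permutation_test(gs, agg, couplings, n_reps=200, seed=1)
        assert res.p_is_bound and res.p_value == pytest.approx(1 / 200)

    def test_tiny_replay_oracle(self):
        """With n_reps=4, the p equals a hand count over the replayed draws."""
        agg, couplings = self.setup_universe()
        gs = GeneSet("s", frozenset({"g5", "g11"}))
        observed = mean_relative_rank_of_gene_set(gs, agg, couplings)
        res = gene_set_permutation_test(gs, agg, couplings, n_reps=4, seed=9)
        # replay the identical generator stream
        min_ranks = {f"g{i}": agg.relative_ranks[f"d{i}"] for i in range(40)}
        universe = sorted(min_ranks)
        pool = np.array([min_ranks[g] for g in universe])
        rng = np.random.default_rng(9)
        draws = [
            pool[rng.choice(len(pool), size=2, replace=False)].mean()
            for _ in range(4)
        ]
        count = sum(d < observed for d in draws)
        expected = count / 4 if count else 1 / 4
        assert res.p_value == pytest.approx(expected)

    def test_inclusive_variant_is_at_least_strict(self):
        agg, couplings = self.setup_universe()
        gs = GeneSet("s", frozenset({"g3", "g7", "g20"}))
        strict = gene_set_permutation_test(gs, agg, couplings, n_reps=300, seed=5)
        incl = gene_set_permutation_test(
            gs, agg, couplings, n_reps=300, seed=5, inclusive=True
        )
        assert incl.p_value >= strict.p_value


class TestHypergeometricOverlap:
    def test_full_overlap_of_top_two_in_ten(self):
        ids = [f"d{i}" for i in range(10)]
        a = make_agg(ids, "a")
        b = make_agg(ids, "b")
        res = hypergeometric_overlap(a, b, fraction=0.2)
        assert res.observed == 2
        assert res.p_value == pytest.approx(1 / 45)

    def test_zero_overlap_in_large_universe_near_one(self):
        ids = [f"d{i}" for i in range(200)]
        a = make_agg(ids, "a")
        b = make_agg(list(reversed(ids)), "b")
        res = hypergeometric_overlap(a, b, fraction=0.02)
        assert res.observed == 0
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_identical_orderings_maximal_overlap(self):
        ids = [f"d{i}" for i in range(30)]
        a = make_agg(ids, "a")
        res = hypergeometric_overlap(a, make_agg(ids, "b"), fraction=0.1)
        assert res.observed == 3  # |top| = ceil(0.1*30)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(3)
        for n in (6, 9, 12):
            ids = [f"d{i}" for i in range(n)]
            a = make_agg(ids, "a")
            b = make_agg(list(rng.permutation(ids)), "b")
            for fraction in (0.2, 0.34, 0.5):
                k = math.ceil(fraction * n)
                top_a = set(a.ordering[:k])
                top_b = set(b.ordering[:k])
                obs = len(top_a & top_b)
                # enumerate all possible draws of |top_a| from the universe
                count = sum(
                    1
                    for draw in itertools.combinations(range(n), k)
                    if len({ids[i] for i in draw} & top_b) >= obs
                )
                expected = count / math.comb(n, k)
                res = hypergeometric_overlap(a, b, fraction)
                assert res.p_value == pytest.approx(expected, abs=1e-12)


def uniform_cpg(chroms, length, step=50):
    return {c: list(range(0, length, step)) for c in chroms}


class TestMatchedRandomRegions:
    def universe(self, chroms=("chr1", "chr2"), length=100_000):
        return IntervalTrack("uni", [GenomicInterval(c, 0, length) for c in chroms])

    def test_hard_constraints_hold(self):
        rng = np.random.default_rng(0)
        template = IntervalTrack("t", [
            GenomicInterval("chr1", int(s), int(s) + int(l), id=f"t{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 50_000, 20), rng.integers(500, 3_000, 20))
            )
        ])
        uni = self.universe()
        cpg = uniform_cpg(("chr1", "chr2"), 100_000)
        sets = matched_random_regions(template, uni, cpg, n_sets=5, seed=1)
        assert len(sets) == 5
        for rset in sets:
            for t, r in zip(template, rset):
                assert r.chrom == t.chrom
                assert r.length == t.length
                assert 0 <= r.start and r.end <= 100_000

    def test_template_on_single_chromosome(self):
        template = IntervalTrack("t", [GenomicInterval("chr2", 100, 1_100, id="a")])
        sets = matched_random_regions(template, self.universe(), None, n_sets=10, seed=2)
        assert all(rset.intervals[0].chrom == "chr2" for rset in sets)

    def test_uniform_cpg_densities_within_tolerance(self):
        length = 100_000
        cpg = uniform_cpg(("chr1",), length, step=40)
        template = IntervalTrack("t", [
            GenomicInterval("chr1", 1_000, 5_000, id="a"),
            GenomicInterval("chr1", 20_000, 22_000, id="b"),
        ])
        uni = IntervalTrack("u", [GenomicInterval("chr1", 0, length)])
        sets = matched_random_regions(template, uni, cpg, n_sets=20, tolerance=0.2, seed=3)
        pos = np.array(cpg["chr1"])
        for rset in sets:
            for t, r in zip(template, rset):
                d_t = ((pos >= t.start) & (pos < t.end)).sum() / t.length
                d_r = ((pos >= r.start) & (pos < r.end)).sum() / r.length
                assert abs(d_r - d_t) <= 0.2 * d_t + 1e-12

    def test_unsatisfiable_length_raises_naming_region(self):
        template = IntervalTrack("t", [GenomicInterval("chr1", 0, 5_000, id="huge")])
        uni = IntervalTrack("u", [GenomicInterval("chr1", 0, 1_000)])
        with pytest.raises(SamplingError, match="huge"):
            matched_random_regions(template, uni, None, n_sets=1, seed=0)

    def test_unsatisfiable_density_raises(self):
        # template dense in CpG, universe offers only CpG deserts
        cpg = {"chr1": list(range(0, 1_000, 10))}
        template = IntervalTrack("t", [GenomicInterval("chr1", 0, 1_000, id="dense")])
        uni = IntervalTrack("u", [GenomicInterval("chr1", 50_000, 90_000)])
        with pytest.raises(SamplingError, match="dense"):
            matched_random_regions(template, uni, cpg, n_sets=1, seed=0,
                                   max_retries=50)


class TestAnnotationEnrichmentRatio:
    def test_genome_wide_element_gives_ratio_one(self):
        uni = IntervalTrack("u", [GenomicInterval("chr1", 0, 50_000)])
        dmrs = IntervalTrack("d", [
            GenomicInterval("chr1", 1_000 + 2_000 * i, 1_500 + 2_000 * i, id=f"d{i}")
            for i in range(10)
        ])
        element = IntervalTrack("e", [GenomicInterval("chr1", 0, 50_000)])
        res = annotation_enrichment_ratio(dmrs, element, uni, n_reps=20, seed=4)
        assert res.observed == pytest.approx(1.0)

    def test_constructed_tenfold_enrichment(self):
        # all DMRs inside the element; the element covers ~10% of the universe
        uni = IntervalTrack("u", [GenomicInterval("chr1", 0, 100_000)])
        element = IntervalTrack("e", [GenomicInterval("chr1", 0, 10_000)])
        dmrs = IntervalTrack("d", [
            GenomicInterval("chr1", 500 * i, 500 * i + 300, id=f"d{i}")
            for i in range(15)
        ])
        res = annotation_enrichment_ratio(dmrs, element, uni, n_reps=200, seed=5)
        assert 6 < res.observed < 16
        assert res.p_value <= 0.05

    def test_self_sampled_regions_near_unity(self):
        uni = IntervalTrack("u", [GenomicInterval("chr1", 0, 100_000)])
        element = IntervalTrack("e", [
            GenomicInterval("chr1", 10_000 * i, 10_000 * i + 3_000) for i in range(10)
        ])
        rng = np.random.default_rng(6)
        dmrs = IntervalTrack("d", [
            GenomicInterval("chr1", int(s), int(s) + 400, id=f"d{i}")
            for i, s in enumerate(rng.integers(0, 99_000, 40))
        ])
        res = annotation_enrichment_ratio(dmrs, element, uni, n_reps=100, seed=7)
        assert abs(res.observed - 1.0) < 3 * (res.null_sd / res.null_mean + 0.1)


class TestRegionSignalEmpiricalP:
    SIGNAL = SignalTrack(
        [("chr1", i * 10, (i + 1) * 10, float(v)) for i, v in enumerate(
            [1, 2, 3, 4, 5, 4.5]
        )]
    )

    def regions(self):
        return [GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(5)]

    def test_hand_counted_two_sided_p(self):
        # null levels {1..5}, observed 4.5: P_ge=1/5, P_le=4/5 -> p=0.4
        obs = GenomicInterval("chr1", 50, 60)
        res = region_signal_empirical_p(obs, self.regions(), self.SIGNAL)
        assert res.observed == pytest.approx(4.5)
        assert res.p_value == pytest.approx(0.4)

    def test_extreme_observation_reported_as_bound(self):
        sig = SignalTrack(
            [("chr1", i * 10, (i + 1) * 10, float(v)) for i, v in enumerate(
                [1, 2, 3, 4, 5, 100.0]
            )]
        )
        obs = GenomicInterval("chr1", 50, 60)
        res = region_signal_empirical_p(obs, self.regions(), sig)
        assert res.p_is_bound and res.p_value == pytest.approx(1 / 5)

    def test_null_median_observation_near_one(self):
        sig = SignalTrack(
            [("chr1", i * 10, (i + 1) * 10, float(v)) for i, v in enumerate(
                [1, 2, 3, 4, 5, 3.0]
            )]
        )
        obs = GenomicInterval("chr1", 50, 60)
        res = region_signal_empirical_p(obs, self.regions(), sig)
        assert res.p_value == pytest.approx(1.0)


class TestTopTailComparison:
    def test_identical_samples_rank_sum_near_one(self):
        levels = list(np.linspace(0, 1, 30))
        p_rank, p_chi = top_tail_comparison(levels, levels, [True] * 30, [True] * 30)
        assert p_rank > 0.9
        assert p_chi is None  # degenerate table: nothing non-significant

    def test_fully_separated_significance_counts(self):
        rng = np.random.default_rng(8)
        top = list(rng.normal(5, 1, 50))
        tail = list(rng.normal(0, 1, 50))
        p_rank, p_chi = top_tail_comparison(
            top, tail, [True] * 50, [False] * 50
        )
        assert p_rank < 1e-10
        assert p_chi is not None and p_chi < 1e-10

    def test_exchangeable_null_rejection_rate_controlled(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            pool = rng.normal(0, 1, 60)
            top, tail = pool[:30], pool[30:]
            sig_top = rng.random(30) < 0.2
            sig_tail = rng.random(30) < 0.2
            p_rank, _ = top_tail_comparison(top, tail, sig_top, sig_tail)
            if p_rank < 0.05:
                rejections += 1
        assert rejections / n_sims <= 0.07  # alpha + 2%
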