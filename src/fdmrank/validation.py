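"""Evaluation statistics for a prioritized DMR ranking.

Covers the gene-set permutation test (does a curated set of known
methylated genes sit unusually high in the ranking?), hypergeometric
overlap of two top lists, annotation enrichment against random regions,
a matched-random-region sampler (same chromosome, same length, similar
CpG density), per-region empirical signal p-values, and the top-versus-
tail comparison (Wilcoxon rank-sum on levels, chi-squared on counts of
significant regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core_genomics import (
    GenomicInterval,
    IntervalTrack,
    OverlapIndex,
    SignalTrack,
    logger,
    mean_signal,
)
from .coupling import CouplingRecord
from .rank_aggregation import AggregationResult


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_set(path: str, name: Optional[str] = None) -> GeneSet:
    genes = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip().split("\t")[0]
            if tok and not tok.startswith("#") and tok != "gene":
                genes.append(tok)
    return GeneSet(name or path, frozenset(genes))


@dataclass
class EnrichmentResult:
    """Observed statistic vs a null, with an empirical or analytic p.

    When no null replicate is as extreme as the observation, the p-value
    is reported as the bound 1/n_reps with ``p_is_bound`` set (an
    empirical p of exactly 0 is never reported).
    """

    observed: float
    null_mean: float
    null_sd: float
    n_reps: int
    p_value: float
    p_is_bound: bool = False
    direction: str = ""

    def __post_init__(self) -> None:
        if not self.p_is_bound and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


# ---------------------------------------------------------------------------
# Known-gene-set permutation test
# ---------------------------------------------------------------------------

def _gene_min_ranks(
    agg: AggregationResult, couplings: Iterable[CouplingRecord]
) -> dict[str, float]:
    """Per gene, the minimum relative rank over its coupled ranked DMRs."""
    out: dict[str, float] = {}
    for c in couplings:
        rr = agg.relative_ranks.get(c.dmr_id)
        if rr is None:
            continue
        if c.gene_id not in out or rr < out[c.gene_id]:
            out[c.gene_id] = rr
    return out


def mean_relative_rank_of_gene_set(
    genes: GeneSet,
    agg: AggregationResult,
    couplings: Iterable[CouplingRecord],
) -> float:
    """Mean over genes of each gene's best (smallest) coupled-DMR rank.

    Genes with no coupled ranked DMR are dropped with a warning; if none
    remains this is an error.
    """
    min_ranks = _gene_min_ranks(agg, couplings)
    vals = [min_ranks[g] for g in genes.genes if g in min_ranks]
    n_dropped = len(genes.genes) - len(vals)
    if n_dropped:
        logger.warning(
            "%d/%d genes in %s have no coupled ranked DMR; dropped",
            n_dropped, len(genes.genes), genes.name,
        )
    if not vals:
        raise ValueError(f"no gene in {genes.name!r} couples to a ranked DMR")
    return float(np.mean(vals))


def gene_set_permutation_test(
    genes: GeneSet,
    agg: AggregationResult,
    couplings: Sequence[CouplingRecord],
    n_reps: int = 10_000,
    seed: int = 0,
    inclusive: bool = False,
) -> EnrichmentResult:
    """Permutation test of the gene set's mean relative rank.

    Random gene sets of the same size are drawn from the universe of all
    coupled genes; the p-value is the fraction of random mean ranks
    strictly smaller than (``inclusive=True``: <=) the observed one.
    """
    min_ranks = _gene_min_ranks(agg, couplings)
    universe = sorted(min_ranks)
    members = [g for g in genes.genes if g in min_ranks]
    if not members:
        raise ValueError("no gene in the set couples to a ranked DMR")
    if len(universe) <= len(members):
        raise ValueError("gene universe not larger than the gene set")
    observed = float(np.mean([min_ranks[g] for g in members]))
    rng = np.random.default_rng(seed)
    pool = np.array([min_ranks[g] for g in universe])
    k = len(members)
    draws = np.empty(n_reps)
    for i in range(n_reps):
        draws[i] = pool[rng.choice(len(pool), size=k, replace=False)].mean()
    count = int((draws <= observed).sum() if inclusive else (draws < observed).sum())
    bound = count == 0
    p = (1.0 / n_reps) if bound else count / n_reps
    return EnrichmentResult(
        observed=observed,
        null_mean=float(draws.mean()),
        null_sd=float(draws.std()),
        n_reps=n_reps,
        p_value=p,
        p_is_bound=bound,
        direction="smaller",
    )


# ---------------------------------------------------------------------------
# Hypergeometric top-fraction overlap
# ---------------------------------------------------------------------------

def hypergeometric_overlap(
    a: AggregationResult, b: AggregationResult, fraction: float
) -> EnrichmentResult:
    """Upper-tail hypergeometric test on the overlap of the two top lists.

    The universe is the id intersection of the two orderings; top sets
    are the first ceil(fraction * N) regions of each.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    shared = set(a.ordering) & set(b.ordering)
    if not shared:
        raise ValueError("orderings share no regions")
    n_universe = len(shared)
    k = int(np.ceil(fraction * n_universe))
    top_a = [r for r in a.ordering if r in shared][:k]
    top_b = set([r for r in b.ordering if r in shared][:k])
    overlap = len(set(top_a) & top_b)
    p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(top_b), len(top_a)))
    return EnrichmentResult(
        observed=float(overlap),
        null_mean=len(top_a) * len(top_b) / n_universe,
        null_sd=float("nan"),
        n_reps=0,
        p_value=p,
        direction="greater",
    )


# ---------------------------------------------------------------------------
# Matched random regions
# ---------------------------------------------------------------------------

class SamplingError(RuntimeError):
    pass


def _cpg_count(
    iv: GenomicInterval, cpg_positions: Mapping[str, np.ndarray]
) -> int:
    pos = cpg_positions.get(iv.chrom)
    if pos is None:
        return 0
    lo = np.searchsorted(pos, iv.start, side="left")
    hi = np.searchsorted(pos, iv.end, side="left")
    return int(hi - lo)


def matched_random_regions(
    template: IntervalTrack,
    universe: IntervalTrack,
    cpg_positions: Optional[Mapping[str, Sequence[int]]] = None,
    n_sets: int = 1_000,
    tolerance: float = 0.2,
    seed: int = 0,
    max_retries: int = 10_000,
) -> list[IntervalTrack]:
    """Random region sets matched to a template, by rejection sampling.

    Each set contains one region per template region, on the same
    chromosome, with identical length, fully inside the universe, and —
    when CpG positions are supplied — with CpG density within the given
    relative tolerance of the template region's density.  Because the
    lengths are identical the density band is applied to CpG counts,
    with a one-count absolute floor so that sparse regions (where the
    relative band may contain no integer) remain matchable.
    """
    cpg = (
        {c: np.asarray(sorted(p), dtype=np.int64) for c, p in cpg_positions.items()}
        if cpg_positions is not None
        else None
    )
    rng = np.random.default_rng(seed)
    uni_by_chrom = universe.by_chrom()
    sets: list[IntervalTrack] = []
    for si in range(n_sets):
        out: list[GenomicInterval] = []
        for t in template:
            blocks = [b for b in uni_by_chrom.get(t.chrom, ()) if b.length >= t.length]
            if not blocks:
                raise SamplingError(
                    f"no universe block on {t.chrom} can hold a region of "
                    f"length {t.length} (template {t.id})"
                )
            weights = np.array([b.length - t.length + 1 for b in blocks], dtype=float)
            weights /= weights.sum()
            target = _cpg_count(t, cpg) if cpg is not None else None
            for _ in range(max_retries):
                b = blocks[rng.choice(len(blocks), p=weights)]
                start = int(rng.integers(b.start, b.end - t.length + 1))
                cand = GenomicInterval(
                    t.chrom, start, start + t.length, id=f"{t.id}_rand{si}"
                )
                assert cand.length == t.length and cand.chrom == t.chrom
                assert cand.start >= b.start and cand.end <= b.end
                if target is None:
                    out.append(cand)
                    break
                band = max(tolerance * target, 1.0)
                if abs(_cpg_count(cand, cpg) - target) <= band:
                    out.append(cand)
                    break
            else:
                raise SamplingError(
                    f"could not match CpG density for template region {t.id} "
                    f"after {max_retries} retries"
                )
        sets.append(IntervalTrack(name=f"{template.name}_rand{si}", intervals=out))
    return sets


# ---------------------------------------------------------------------------
# Annotation enrichment
# ---------------------------------------------------------------------------

def annotation_enrichment_ratio(
    dmrs: IntervalTrack,
    element: IntervalTrack,
    universe: IntervalTrack,
    cpg_positions: Optional[Mapping[str, Sequence[int]]] = None,
    n_reps: int = 100,
    tolerance: float = 0.2,
    seed: int = 0,
) -> EnrichmentResult:
    """Fold enrichment of DMR/element overlap over matched random regions.

    ratio = (fraction of DMRs overlapping the element) divided by the
    mean such fraction over random region sets.  A ratio over an all-zero
    null is reported as +inf with the bound flag set.
    """
    index = OverlapIndex(element)
    obs = float(np.mean([index.count(iv) > 0 for iv in dmrs]))
    randoms = matched_random_regions(
        dmrs, universe, cpg_positions, n_sets=n_reps, tolerance=tolerance, seed=seed
    )
    null = np.array(
        [np.mean([index.count(iv) > 0 for iv in rset]) for rset in randoms]
    )
    if null.mean() == 0:
        return EnrichmentResult(
            observed=obs, null_mean=0.0, null_sd=0.0, n_reps=n_reps,
            p_value=1.0 / n_reps, p_is_bound=True, direction="greater",
        )
    ratio = obs / null.mean()
    exceed = int((null >= obs).sum())
    bound = exceed == 0
    p = (1.0 / n_reps) if bound else exceed / n_reps
    res = EnrichmentResult(
        observed=ratio,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_reps=n_reps,
        p_value=p,
        p_is_bound=bound,
        direction="greater",
    )
    return res


# ---------------------------------------------------------------------------
# Per-region empirical signal p and top/tail comparison
# ---------------------------------------------------------------------------

def region_signal_empirical_p(
    region: GenomicInterval,
    random_regions: Sequence[GenomicInterval],
    signal: SignalTrack,
) -> EnrichmentResult:
    """Two-sided empirical p for a region's mean signal against matched
    random regions: p = min(1, 2 * min(P_ge, P_le))."""
    if not random_regions:
        raise ValueError("need >=1 random region")
    obs = mean_signal(region, signal)
    null = np.array([mean_signal(r, signal) for r in random_regions])
    n = len(null)
    n_ge = int((null >= obs).sum())
    n_le = int((null <= obs).sum())
    bound = min(n_ge, n_le) == 0
    # a zero-exceedance tail is reported as the one-sided bound p < 1/n,
    # never 0; otherwise the doubled two-sided empirical p, capped at 1
    p = (1.0 / n) if bound else min(1.0, 2 * min(n_ge, n_le) / n)
    return EnrichmentResult(
        observed=float(obs),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_reps=n,
        p_value=p,
        p_is_bound=bound,
        direction="two-sided",
    )


def top_tail_comparison(
    top_levels: Sequence[float],
    tail_levels: Sequence[float],
    top_significant: Sequence[bool],
    tail_significant: Sequence[bool],
) -> tuple[float, Optional[float]]:
    """Compare top- vs tail-ranked regions.

    Returns (Wilcoxon rank-sum p on signal levels, chi-squared p on the
    2x2 significant/not table).  The chi-squared p is None when a table
    margin is zero.
    """
    if not len(top_levels) or not len(tail_levels):
        raise ValueError("both region sets must be non-empty")
    rank_p = float(
        stats.mannwhitneyu(top_levels, tail_levels, alternative="two-sided").pvalue
    )
    a = int(np.sum(top_significant))
    b = len(top_significant) - a
    c = int(np.sum(tail_significant))
    d = len(tail_significant) - c
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return rank_p, None
    chi_p = float(stats.chi2_contingency(table)[1])
    return rank_p, chi_p


def write_enrichment(res: EnrichmentResult, path: str, statistic: str) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tobserved\tnull_mean\tnull_sd\tn_reps\tp_value\tbound_flag\tdirection\n")
        fh.write(
            f"{statistic}\t{res.observed:.10g}\t{res.null_mean:.10g}\t"
            f"{res.null_sd:.10g}\t{res.n_reps}\t{res.p_value:.10g}\t"
            f"{int(res.p_is_bound)}\t{res.direction}\n"
        )
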