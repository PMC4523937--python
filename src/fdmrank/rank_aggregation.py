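"""Order-statistics rank aggregation.

Each feature produces relative ranks r_j in (0, 1] over the same region
set.  Under the null that ranks are i.i.d. uniform, the probability that
the k-th smallest of n relative ranks is <= x is the binomial upper tail

    beta_{k,n}(x) = sum_{j=k}^{n} C(n, j) x^j (1-x)^{n-j},

equivalently the regularized incomplete beta function I_x(k, n-k+1).
A region's rho score is min_k beta_{k,n}(r_(k)) over its sorted rank
vector; regions are ordered by ascending rho, so small rho means
"consistently near the top of several lists".  rho is used directly for
ordering, without any factorial normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy import special, stats


@dataclass
class RankVector:
    """Relative ranks in (0,1] for one feature over a region set."""

    name: str
    ranks: dict[str, float]

    def __post_init__(self) -> None:
        for rid, r in self.ranks.items():
            if not (0.0 < r <= 1.0):
                raise ValueError(f"{self.name}: relative rank {r} for {rid} not in (0,1]")

    def regions(self) -> set[str]:
        return set(self.ranks)

    def values_for(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.ranks[r] for r in order], dtype=float)


@dataclass
class AggregationResult:
    """rho scores and the resulting ordering for one feature combination."""

    label: str
    rho: dict[str, float]
    ordering: list[str]  # region ids, ascending rho
    n_lists: int
    relative_ranks: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ordering)
        self.relative_ranks = {
            rid: (i + 1) / n for i, rid in enumerate(self.ordering)
        }

    def as_rank_vector(self) -> RankVector:
        return RankVector(self.label, dict(self.relative_ranks))


def order_statistic_probability(k: int, n: int, x: float) -> float:
    """beta_{k,n}(x): P(k-th smallest of n i.i.d. U(0,1) <= x)."""
    if not (1 <= k <= n):
        raise ValueError(f"require 1 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"require 0 <= x <= 1, got x={x}")
    # binomial upper tail == regularized incomplete beta I_x(k, n-k+1)
    return float(special.betainc(k, n - k + 1, x))


def rho_score(r: Sequence[float]) -> float:
    """min_k beta_{k,n}(r_(k)) over the ascending-sorted rank vector."""
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("relative ranks must lie in (0, 1]")
    n = r.size
    rs = np.sort(r)
    ks = np.arange(1, n + 1)
    return float(special.betainc(ks, n - ks + 1, rs).min())


def aggregate_ranks(
    vectors: Sequence[RankVector], label: str | None = None
) -> AggregationResult:
    """Combine rank vectors over an identical region set into one ordering.

    Ties in rho are broken by mean relative rank, then lexicographic
    region id, so output files are deterministic.
    """
    if not vectors:
        raise ValueError("need at least one rank vector")
    universe = vectors[0].regions()
    for v in vectors[1:]:
        if v.regions() != universe:
            diff = sorted(universe ^ v.regions())
            raise ValueError(
                f"region sets differ between {vectors[0].name!r} and "
                f"{v.name!r}; symmetric difference: {diff[:20]}"
            )
    order = sorted(universe)
    mat = np.stack([v.values_for(order) for v in vectors], axis=1)  # regions x n
    n = mat.shape[1]
    rs = np.sort(mat, axis=1)
    ks = np.arange(1, n + 1)
    rho = special.betainc(ks[None, :], n - ks[None, :] + 1, rs).min(axis=1)
    mean_rank = mat.mean(axis=1)
    key = sorted(
        range(len(order)), key=lambda i: (rho[i], mean_rank[i], order[i])
    )
    ordering = [order[i] for i in key]
    return AggregationResult(
        label=label or "+".join(v.name for v in vectors),
        rho={rid: float(rho[i]) for i, rid in enumerate(order)},
        ordering=ordering,
        n_lists=n,
    )


def enumerate_rank_combinations(
    vectors: Sequence[RankVector],
) -> dict[str, AggregationResult]:
    """One aggregation per non-empty feature subset (2^n - 1 results)."""
    results: dict[str, AggregationResult] = {}
    for size in range(1, len(vectors) + 1):
        for combo in itertools.combinations(vectors, size):
            label = "+".join(v.name for v in combo)
            results[label] = aggregate_ranks(list(combo), label=label)
    return results


def rank_correlation(
    a: Union[AggregationResult, RankVector],
    b: Union[AggregationResult, RankVector],
) -> float:
    """Pearson correlation between two relative-rank assignments."""
    ra = a.relative_ranks if isinstance(a, AggregationResult) else a.ranks
    rb = b.relative_ranks if isinstance(b, AggregationResult) else b.ranks
    if set(ra) != set(rb):
        raise ValueError("rank correlation requires identical region sets")
    order = sorted(ra)
    xa = np.array([ra[r] for r in order])
    xb = np.array([rb[r] for r in order])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(stats.pearsonr(xa, xb)[0])


def write_aggregation(result: AggregationResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("dmr_id\trho\tposition\trelative_rank\n")
        for pos, rid in enumerate(result.ordering, start=1):
            fh.write(
                f"{rid}\t{result.rho[rid]:.10g}\t{pos}\t"
                f"{result.relative_ranks[rid]:.10g}\n"
            )


def read_rank_vector(path: str, name: str | None = None) -> RankVector:
    """Read a rank TSV (dmr_id ... relative_rank in last column)."""
    ranks: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = header.index("relative_rank")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ranks[f[0]] = float(f[col])
    return RankVector(name or path, ranks)
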