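"""DMR-to-gene coupling by distance category.

Each DMR is associated with every coding or noncoding gene that overlaps
it or lies within 2 kb / 10 kb / 100 kb flanks of the gene; the tightest
applicable category wins.  DMRs with no coupled gene are dropped from
prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_genomics import GeneModel, GenomicInterval, IntervalTrack, logger

# ordered tightest-first: (label, max gap in bp)
CATEGORIES: tuple[tuple[str, int], ...] = (
    ("gene-overlapping", 0),
    ("gene-proximal", 2_000),
    ("gene-distal-10kb", 10_000),
    ("gene-distal-100kb", 100_000),
)
MAX_COUPLING_DISTANCE = 100_000


@dataclass(frozen=True)
class CouplingRecord:
    dmr_id: str
    gene_id: str
    biotype: str
    category: str
    distance: int

    def __post_init__(self) -> None:
        limits = dict(CATEGORIES)
        if self.category not in limits:
            raise ValueError(f"unknown category {self.category!r}")
        if self.distance > limits[self.category] or self.distance < 0:
            raise ValueError(
                f"distance {self.distance} outside {self.category} window"
            )
        if (self.distance == 0) != (self.category == "gene-overlapping"):
            raise ValueError("distance 0 iff gene-overlapping")


def _category_for_gap(gap: int, overlapping: bool) -> str | None:
    # Touching intervals (gap 0, no shared base) are treated as
    # overlapping, keeping "distance 0 iff gene-overlapping" consistent
    # with base-union merge semantics.
    if overlapping or gap == 0:
        return "gene-overlapping"
    for label, limit in CATEGORIES[1:]:
        if gap <= limit:
            return label
    return None


def couple_dmrs_to_genes(
    dmrs: IntervalTrack, genes: Sequence[GeneModel]
) -> list[CouplingRecord]:
    """All (DMR, gene) pairs within 100 kb, labelled with the tightest
    distance category.  Many-to-many: a DMR may couple several genes and
    vice versa."""
    records: list[CouplingRecord] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for dmr in dmrs:
        if dmr.id is None:
            raise ValueError("coupling requires DMR ids")
        for g in genes_by_chrom.get(dmr.chrom, ()):
            gap = dmr.gap_to(g.interval)
            if gap is None or gap > MAX_COUPLING_DISTANCE:
                continue
            cat = _category_for_gap(gap, dmr.overlaps(g.interval))
            if cat is None:
                continue
            dist = 0 if cat == "gene-overlapping" else gap
            records.append(
                CouplingRecord(dmr.id, g.id, g.biotype, cat, dist)
            )
    logger.info(
        "coupled %d DMR-gene pairs (%d DMRs, %d genes)",
        len(records), len(dmrs), len(genes),
    )
    return records


def filter_uncoupled_dmrs(
    dmrs: IntervalTrack, couplings: Iterable[CouplingRecord]
) -> IntervalTrack:
    """Retain, in input order, exactly the DMRs with >=1 coupling record."""
    coupled_ids = {c.dmr_id for c in couplings}
    kept = [iv for iv in dmrs if iv.id in coupled_ids]
    logger.info("retained %d/%d DMRs with >=1 coupled gene", len(kept), len(dmrs))
    return IntervalTrack(name=dmrs.name, intervals=kept)


def classify_relative_position(dmr: GenomicInterval, gene: GeneModel) -> str:
    """Positional label of a DMR relative to its coupled gene.

    contained: DMR contains the gene; inside: DMR lies within the gene;
    olup/oldown: partial overlap on the gene's 5'/3' side; upstream/
    downstream: no overlap, on the 5'/3' side.  Strand-aware: for a
    minus-strand gene the 5' end is the higher coordinate.
    """
    g = gene.interval
    if dmr.chrom != g.chrom:
        raise ValueError("DMR and gene on different chromosomes")
    five_prime_left = gene.strand == "+"  # 5' end at g.start on + strand
    if dmr.start <= g.start and dmr.end >= g.end:
        return "contained"
    if dmr.start >= g.start and dmr.end <= g.end:
        return "inside"
    if dmr.overlaps(g):
        # partial overlap: exactly one gene boundary lies inside the DMR
        left_boundary_in = dmr.start < g.start < dmr.end
        if left_boundary_in:
            return "olup" if five_prime_left else "oldown"
        return "oldown" if five_prime_left else "olup"
    dmr_left = dmr.end <= g.start
    if dmr_left:
        return "upstream" if five_prime_left else "downstream"
    return "downstream" if five_prime_left else "upstream"


def write_couplings(couplings: Sequence[CouplingRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("dmr_id\tgene_id\tbiotype\tcategory\tdistance\n")
        for c in couplings:
            fh.write(f"{c.dmr_id}\t{c.gene_id}\t{c.biotype}\t{c.category}\t{c.distance}\n")


def read_couplings(path: str) -> list[CouplingRecord]:
    out: list[CouplingRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("dmr_id"):
            raise ValueError(f"{path}: missing coupling header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(CouplingRecord(f[0], f[1], f[2], f[3], int(f[4])))
    return out
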