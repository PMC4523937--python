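"""Genomic coordinate primitives: intervals, tracks, signals, and flat-file I/O.

All internal coordinates are 0-based half-open ``[start, end)``, the BED
convention.  Coordinates printed 1-based inclusive (the usual
``chrN:a-b`` browser style) are converted on read by decrementing the
start.  Chromosome names are matched as exact strings; an optional
normalizer hook can be supplied by callers that need ``chr1``/``1``
aliasing, but none is applied by default.
"""

from __future__ import annotations

import logging
import sys
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger("fdmrank")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ParseError(ValueError):
    """Raised when an on-disk record violates the format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    Invariants: ``0 <= start < end``.
    """

    chrom: str
    start: int
    end: int
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Base-pair gap between closest boundaries; 0 if overlapping or
        touching; None if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, self.start - other.end, other.start - self.end)

    @classmethod
    def from_region_string(cls, s: str, id: Optional[str] = None) -> "GenomicInterval":
        """Parse a 1-based inclusive ``chrN:a-b`` browser-style string."""
        chrom, _, span = s.partition(":")
        a, _, b = span.replace("–", "-").partition("-")
        return cls(chrom, int(a.replace(",", "")) - 1, int(b.replace(",", "")), id=id)


@dataclass
class IntervalTrack:
    """A named collection of intervals (may overlap unless merged)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def ids(self) -> list[Optional[str]]:
        return [iv.id for iv in self.intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass
class GeneModel:
    """A gene locus with strand and coding/noncoding biotype."""

    interval: GenomicInterval
    strand: str
    biotype: str
    id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"gene {self.id}: biotype must be coding|noncoding")


class SignalTrack:
    """Per-base real-valued signal, stored as sorted non-overlapping runs.

    Internally keeps, per chromosome, arrays (starts, ends, values) so a
    per-base value is ``values[i]`` for any position in ``[starts[i],
    ends[i])``.  Bases not covered by any run are *missing*, not zero.
    """

    def __init__(self, runs: Iterable[tuple[str, int, int, float]] = ()) -> None:
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if start >= end:
                raise ValueError(f"empty signal run {chrom}:{start}-{end}")
            per.setdefault(chrom, []).append((start, end, float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rs in per.items():
            rs.sort()
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping signal runs on {chrom}")
            vals = np.array([r[2] for r in rs], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite signal value on {chrom}")
            self._data[chrom] = (starts, ends, vals)

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def runs(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms():
            starts, ends, vals = self._data[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)

    def coverage_and_sum(self, query: GenomicInterval) -> tuple[int, float]:
        """(number of covered bases, sum of per-base values) within query."""
        if query.chrom not in self._data:
            return 0, 0.0
        starts, ends, vals = self._data[query.chrom]
        lo = int(np.searchsorted(ends, query.start, side="right"))
        hi = int(np.searchsorted(starts, query.end, side="left"))
        if lo >= hi:
            return 0, 0.0
        s = np.maximum(starts[lo:hi], query.start)
        e = np.minimum(ends[lo:hi], query.end)
        widths = e - s
        return int(widths.sum()), float((widths * vals[lo:hi]).sum())


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(track: IntervalTrack) -> IntervalTrack:
    """Merge overlapping *and touching* intervals into a sorted disjoint set.

    The output's base-pair union equals the input's; touching intervals
    ([a,b) and [b,c)) are merged, matching base-union semantics.
    Idempotent.  Record ids are dropped (a merged interval has no single
    provenance).
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in track.intervals}):
        ivs = sorted(
            (iv for iv in track.intervals if iv.chrom == chrom),
            key=lambda iv: (iv.start, iv.end),
        )
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # touching counts
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalTrack(name=track.name, intervals=merged)


class _ChromIndex:
    """Sorted-array overlap index for one chromosome."""

    def __init__(self, intervals: Sequence[GenomicInterval]) -> None:
        self.starts = np.array(sorted(iv.start for iv in intervals), dtype=np.int64)
        self.ends = np.array(sorted(iv.end for iv in intervals), dtype=np.int64)

    def count_overlapping(self, start: int, end: int) -> int:
        # intervals with start < end(query) minus intervals with end <= start(query)
        n_start_before = int(np.searchsorted(self.starts, end, side="left"))
        n_end_before = int(np.searchsorted(self.ends, start, side="right"))
        return n_start_before - n_end_before


class OverlapIndex:
    """Counts track intervals overlapping a query in O(log n) per query."""

    def __init__(self, track: IntervalTrack) -> None:
        self._per_chrom = {
            chrom: _ChromIndex(ivs) for chrom, ivs in track.by_chrom().items()
        }

    def count(self, query: GenomicInterval) -> int:
        idx = self._per_chrom.get(query.chrom)
        if idx is None:
            return 0
        return idx.count_overlapping(query.start, query.end)


def overlap_count(query: GenomicInterval, track: IntervalTrack) -> int:
    """Number of track intervals sharing >= 1 bp with the query."""
    return OverlapIndex(track).count(query)


def mean_signal(
    query: GenomicInterval,
    signal: SignalTrack,
    missing: str = "exclude",
) -> float:
    """Arithmetic mean of per-base signal over a query interval.

    missing="exclude" (default): mean over covered bases only; a query
    with zero covered bases scores 0.0 with a warning.
    missing="zero": uncovered bases contribute 0 and the divisor is the
    full query length.
    """
    if missing not in ("exclude", "zero"):
        raise ValueError(f"unknown missing policy {missing!r}")
    covered, total = signal.coverage_and_sum(query)
    if missing == "zero":
        return total / query.length
    if covered == 0:
        logger.warning(
            "region %s:%d-%d has no signal coverage; mean set to 0",
            query.chrom, query.start, query.end,
        )
        return 0.0
    return total / covered


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _is_comment(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def parse_bed(
    path: str,
    one_based: bool = False,
    name: Optional[str] = None,
    chrom_normalizer: Optional[Callable[[str], str]] = None,
) -> IntervalTrack:
    """Read a BED3/BED4 file into an IntervalTrack.

    ``one_based=True`` treats the start column as 1-based inclusive
    (browser style) and decrements it on read.  Malformed lines raise
    :class:`ParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            if chrom_normalizer is not None:
                chrom = chrom_normalizer(chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            rec_id = fields[3] if len(fields) >= 4 else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, id=rec_id))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read %d intervals from %s", len(intervals), path)
    return IntervalTrack(name=name or path, intervals=intervals)


def write_bed(track: IntervalTrack, path: str) -> None:
    """Write BED3/BED4 (tab-separated; id column only when present)."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None:
                cols.append(iv.id)
            fh.write("\t".join(cols) + "\n")
    logger.info("wrote %d intervals to %s", len(track), path)


def parse_bedgraph(path: str) -> SignalTrack:
    """Read a bedGraph (chrom start end value; 0-based half-open)."""
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                runs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates or value") from exc
    logger.info("read %d signal runs from %s", len(runs), path)
    return SignalTrack(runs)


def write_bedgraph(signal: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in signal.runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def parse_genes(path: str) -> list[GeneModel]:
    """Read a gene table: chrom start end id strand biotype (tab-separated,
    header line starting with 'chrom' allowed)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line) or line.startswith("chrom"):
                continue
            f = line.split()
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]), id=f[3])
                genes.append(GeneModel(iv, strand=f[4], biotype=f[5], id=f[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read %d genes from %s", len(genes), path)
    return genes


def write_genes(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tid\tstrand\tbiotype\n")
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
                f"\t{g.id}\t{g.strand}\t{g.biotype}\n"
            )


def union_length(track: IntervalTrack) -> int:
    """Total number of distinct bases covered by the track."""
    return sum(iv.length for iv in merge_intervals(track).intervals)
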