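"""Seeded miniature-genome fixtures with planted functional DMRs.

The generator emulates the statistical structure of the real inputs — a
region set in which a small planted subset is jointly elevated in all
four evidence types — without any claim of biological realism:

* expression noise is normal on the log2 scale; planted DMRs' dedicated
  genes get a case-vs-control group-mean difference;
* per-region conservation means are Beta(2, 5) for background regions,
  shifted upward for planted ones;
* regulatory-track elements are placed by a homogeneous process, with
  extra elements inside planted regions;
* per-CpG methylation columns share a region base profile plus
  condition noise; planted regions invert a random subset of condition
  profiles, inflating the variance of pairwise correlations;
* survival times are exponential with the hazard tied to one planted
  gene's expression.

Every DMR is given one dedicated gene, cycling through the four coupling
categories so all category code paths are exercised; planted DMRs
therefore always couple at least one gene.  All randomness flows from a
single seed, so the same configuration writes byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_genomics import (
    GeneModel,
    GenomicInterval,
    IntervalTrack,
    SignalTrack,
    parse_bed,
    parse_bedgraph,
    parse_genes,
    write_bed,
    write_bedgraph,
    write_genes,
)
from .coupling import couple_dmrs_to_genes
from .feature_ranks import (
    ExpressionMatrix,
    MethylationProfile,
    read_expression,
    read_methylation_profiles,
    write_expression,
    write_methylation_profiles,
)
from .biomarkers import SurvivalRecord, read_survival, write_survival
from .validation import GeneSet
from .rank_aggregation import AggregationResult, RankVector


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Effect sizes are all "planted minus background" style and may be set
    to 0 to produce a pure-null fixture: ``expression_delta`` is the
    case-vs-control log2 group-mean difference for planted genes;
    ``conservation_shift`` is added to planted regions' mean conservation;
    ``track_boost`` multiplies the expected number of *extra* regulatory
    elements planted inside each planted region (relative to the
    background per-region expectation); ``dynamics_effect`` in [0, 2]
    scales the probability (effect/2) that a planted region's condition
    profile is inverted.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 1_200_000
    n_dmrs: int = 200
    planted_fraction: float = 0.05
    n_extra_genes: int = 50
    dmr_length_range: tuple[int, int] = (1_000, 4_000)
    # effect sizes
    expression_delta: float = 0.75
    conservation_shift: float = 0.15
    track_boost: float = 1.5
    dynamics_effect: float = 1.0
    # methylation
    n_conditions: int = 8
    cpg_density: float = 0.006
    # expression / survival
    n_case: int = 40
    n_control: int = 12
    baseline_hazard: float = 0.1
    hazard_ratio: float = 3.0
    # regulatory tracks
    n_tfbs_cell_lines: int = 3
    n_dhs_cell_lines: int = 3
    element_density: float = 8e-4  # elements per bp per track
    element_length_range: tuple[int, int] = (200, 500)

    def __post_init__(self) -> None:
        if not (0.0 < self.planted_fraction < 1.0):
            raise ValueError("planted_fraction must lie in (0, 1)")
        if self.n_dmrs <= 0 or self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("counts and lengths must be positive")
        for name in ("expression_delta", "conservation_shift", "track_boost",
                     "dynamics_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FixtureBundle:
    config: FixtureConfig
    dmrs: IntervalTrack
    truth: dict[str, str]  # dmr_id -> {"planted", "background"}
    genes: list[GeneModel]
    tfbs: list[IntervalTrack]
    dhs: list[IntervalTrack]
    enhancers: IntervalTrack
    insulators: IntervalTrack
    conservation: SignalTrack
    methylation: list[MethylationProfile]
    expression: ExpressionMatrix
    survival: list[SurvivalRecord]
    known_genes: GeneSet
    cpg_positions: dict[str, np.ndarray]

    def planted_ids(self) -> list[str]:
        return [d for d, lab in self.truth.items() if lab == "planted"]


# category cycle: gap to place the dedicated gene at (0 = overlapping)
_CATEGORY_GAPS = (0, 1_500, 8_000, 60_000)


def _place_dmrs(cfg: FixtureConfig, rng: np.random.Generator) -> IntervalTrack:
    """Non-overlapping DMRs in evenly spaced slots, leaving right margin
    for dedicated genes up to 100 kb away."""
    per_chrom = int(np.ceil(cfg.n_dmrs / cfg.n_chromosomes))
    margin_r = _CATEGORY_GAPS[-1] + 10_000
    usable = cfg.chrom_length - margin_r - 10_000
    slot = usable // per_chrom
    if slot < cfg.dmr_length_range[1] + 2_000:
        raise ValueError("chromosomes too short for the requested DMR count")
    intervals = []
    i = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for si in range(per_chrom):
            if i >= cfg.n_dmrs:
                break
            length = int(rng.integers(*cfg.dmr_length_range))
            lo = 10_000 + si * slot
            start = int(rng.integers(lo, lo + slot - length - 1_000))
            intervals.append(
                GenomicInterval(chrom, start, start + length, id=f"dmr{i:04d}")
            )
            i += 1
    return IntervalTrack("dmrs", intervals)


def _place_genes(
    cfg: FixtureConfig, dmrs: IntervalTrack, rng: np.random.Generator
) -> tuple[list[GeneModel], dict[str, str]]:
    """One dedicated gene per DMR (cycling coupling categories) plus
    random extra genes; returns genes and the dmr_id -> gene_id map."""
    genes: list[GeneModel] = []
    dedicated: dict[str, str] = {}
    for i, dmr in enumerate(dmrs):
        gid = f"gene_{dmr.id}"
        gap = _CATEGORY_GAPS[i % len(_CATEGORY_GAPS)]
        glen = int(rng.integers(800, 3_000))
        if gap == 0:
            gstart = dmr.start + dmr.length // 2  # overlaps the DMR
        else:
            gstart = dmr.end + gap
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "coding" if rng.random() < 0.7 else "noncoding"
        genes.append(
            GeneModel(
                GenomicInterval(dmr.chrom, gstart, gstart + glen, id=gid),
                strand=strand, biotype=biotype, id=gid,
            )
        )
        dedicated[dmr.id] = gid
    for j in range(cfg.n_extra_genes):
        chrom = f"chr{int(rng.integers(1, cfg.n_chromosomes + 1))}"
        glen = int(rng.integers(800, 3_000))
        gstart = int(rng.integers(0, cfg.chrom_length - glen))
        gid = f"gene_extra{j:03d}"
        genes.append(
            GeneModel(
                GenomicInterval(chrom, gstart, gstart + glen, id=gid),
                strand="+" if rng.random() < 0.5 else "-",
                biotype="coding" if rng.random() < 0.7 else "noncoding",
                id=gid,
            )
        )
    return genes, dedicated


def _place_track(
    cfg: FixtureConfig,
    name: str,
    planted: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> IntervalTrack:
    """Homogeneously placed elements plus extra elements in planted DMRs."""
    lmin, lmax = cfg.element_length_range
    intervals: list[GenomicInterval] = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_bg = rng.poisson(cfg.element_density * cfg.chrom_length)
        starts = rng.integers(0, cfg.chrom_length - lmax, size=n_bg)
        lens = rng.integers(lmin, lmax, size=n_bg)
        intervals.extend(
            GenomicInterval(chrom, int(s), int(s + l))
            for s, l in zip(starts, lens)
        )
    # expected background overlaps per region of mean DMR length
    mean_len = float(np.mean(cfg.dmr_length_range))
    lam0 = cfg.element_density * (mean_len + (lmin + lmax) / 2)
    for dmr in planted:
        n_extra = rng.poisson(lam0 * cfg.track_boost)
        for _ in range(n_extra):
            l = int(rng.integers(lmin, lmax))
            s = int(rng.integers(max(0, dmr.start - l + 1), dmr.end - 1))
            intervals.append(GenomicInterval(dmr.chrom, s, s + l))
    return IntervalTrack(name, intervals)


def _conservation(
    cfg: FixtureConfig,
    dmrs: IntervalTrack,
    planted: set[str],
    rng: np.random.Generator,
) -> SignalTrack:
    runs = []
    for dmr in dmrs:
        mean = float(rng.beta(2, 5))
        if dmr.id in planted:
            mean = min(0.98, mean + cfg.conservation_shift)
        # four sub-runs with jitter around the region mean
        bounds = np.linspace(dmr.start, dmr.end, 5).astype(int)
        for a, b in zip(bounds[:-1], bounds[1:]):
            v = float(np.clip(mean + rng.normal(0, 0.03), 0.0, 1.0))
            runs.append((dmr.chrom, int(a), int(b), v))
    return SignalTrack(runs)


def _cpg_map(
    cfg: FixtureConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    out = {}
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = rng.poisson(cfg.cpg_density * cfg.chrom_length)
        out[chrom] = np.unique(rng.integers(0, cfg.chrom_length, size=n))
    return out


def _methylation(
    cfg: FixtureConfig,
    dmrs: IntervalTrack,
    planted: set[str],
    cpg: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> list[MethylationProfile]:
    conds = [f"cond{c + 1}" for c in range(cfg.n_conditions)]
    profiles = []
    q = min(1.0, cfg.dynamics_effect / 2.0)
    for dmr in dmrs:
        pos = cpg[dmr.chrom]
        pos = pos[(pos >= dmr.start) & (pos < dmr.end)]
        if pos.size < 3:  # guarantee enough CpGs for correlations
            pos = np.unique(
                np.concatenate([pos, rng.integers(dmr.start, dmr.end, size=5)])
            )
        base = rng.uniform(0.1, 0.9, size=pos.size)
        noise_sd = float(rng.uniform(0.05, 0.2))  # region-level heterogeneity
        cols = {}
        for c in conds:
            # condition-specific slope: tissues track the base profile to
            # varying degrees, so even background regions show a spread of
            # pairwise correlations
            slope = float(rng.normal(1.0, 0.6))
            if dmr.id in planted and rng.random() < q:
                slope = -slope  # inverted condition profile
            col = 0.5 + slope * (base - 0.5)
            cols[c] = np.clip(col + rng.normal(0, noise_sd, size=pos.size), 0, 1)
        profiles.append(
            MethylationProfile(dmr.id, pd.DataFrame(cols, index=pos))
        )
    return profiles


def _expression(
    cfg: FixtureConfig,
    genes: Sequence[GeneModel],
    dedicated: Mapping[str, str],
    planted: set[str],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    samples = [f"case{i + 1:03d}" for i in range(cfg.n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(cfg.n_control)
    ]
    labels = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=samples
    )
    planted_genes = {dedicated[d] for d in planted}
    gids = [g.id for g in genes]
    base = rng.normal(7.0, 1.0, size=len(gids))
    mat = base[:, None] + rng.normal(0, 1.0, size=(len(gids), len(samples)))
    for i, gid in enumerate(gids):
        if gid in planted_genes:
            sign = 1.0 if rng.random() < 0.5 else -1.0  # hyper/hypo alike
            mat[i, : cfg.n_case] += sign * cfg.expression_delta
    return ExpressionMatrix(pd.DataFrame(mat, index=gids, columns=samples), labels)


def _survival(
    cfg: FixtureConfig,
    expr: ExpressionMatrix,
    dedicated: Mapping[str, str],
    planted: Sequence[str],
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Exponential survival for case samples, hazard tied to the first
    planted gene's standardized expression."""
    cases = expr.group_columns("case")
    marker = dedicated[sorted(planted)[0]]
    x = expr.values.loc[marker, cases].to_numpy(dtype=float)
    z = (x - x.mean()) / x.std()
    hazard = cfg.baseline_hazard * cfg.hazard_ratio ** z
    times = rng.exponential(1.0 / hazard)
    censor = rng.exponential(3.0 / cfg.baseline_hazard, size=len(cases))
    out = []
    for s, t, c in zip(cases, times, censor):
        event = int(t <= c)
        out.append(SurvivalRecord(s, float(min(t, c)), event, stage="III"))
    return out


def generate_fixture(
    config: FixtureConfig, out_dir: Optional[str] = None
) -> FixtureBundle:
    """Generate one fixture bundle; optionally write all files to a
    directory (BED / bedGraph / TSV, all parseable by the package's own
    readers)."""
    rng = np.random.default_rng(config.seed)
    dmrs = _place_dmrs(config, rng)
    n_planted = int(round(config.n_dmrs * config.planted_fraction))
    planted_idx = rng.choice(len(dmrs), size=n_planted, replace=False)
    planted = {dmrs.intervals[i].id for i in planted_idx}
    truth = {
        iv.id: ("planted" if iv.id in planted else "background") for iv in dmrs
    }
    genes, dedicated = _place_genes(config, dmrs, rng)
    planted_ivs = [iv for iv in dmrs if iv.id in planted]
    tfbs = [
        _place_track(config, f"tfbs_cell{c + 1}", planted_ivs, rng)
        for c in range(config.n_tfbs_cell_lines)
    ]
    dhs = [
        _place_track(config, f"dhs_cell{c + 1}", planted_ivs, rng)
        for c in range(config.n_dhs_cell_lines)
    ]
    enhancers = _place_track(config, "enhancers", planted_ivs, rng)
    insulators = _place_track(config, "insulators", planted_ivs, rng)
    conservation = _conservation(config, dmrs, planted, rng)
    cpg = _cpg_map(config, rng)
    methylation = _methylation(config, dmrs, planted, cpg, rng)
    expression = _expression(config, genes, dedicated, planted, rng)
    survival = _survival(config, expression, dedicated, sorted(planted), rng)
    known = GeneSet("planted_genes", frozenset(dedicated[d] for d in planted))
    bundle = FixtureBundle(
        config=config, dmrs=dmrs, truth=truth, genes=genes, tfbs=tfbs,
        dhs=dhs, enhancers=enhancers, insulators=insulators,
        conservation=conservation, methylation=methylation,
        expression=expression, survival=survival, known_genes=known,
        cpg_positions=cpg,
    )
    if out_dir is not None:
        write_fixture(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------

def write_fixture(bundle: FixtureBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    j = lambda name: os.path.join(out_dir, name)
    write_bed(bundle.dmrs, j("dmrs.bed"))
    write_genes(bundle.genes, j("genes.tsv"))
    for t in bundle.tfbs + bundle.dhs:
        write_bed(t, j(f"{t.name}.bed"))
    write_bed(bundle.enhancers, j("enhancers.bed"))
    write_bed(bundle.insulators, j("insulators.bed"))
    write_bedgraph(bundle.conservation, j("conservation.bedgraph"))
    chroms = {iv.id: iv.chrom for iv in bundle.dmrs}
    write_methylation_profiles(bundle.methylation, chroms, j("methylation.tsv"))
    write_expression(bundle.expression, j("expression.tsv"), j("sample_labels.tsv"))
    write_survival(bundle.survival, j("survival.tsv"))
    with open(j("known_genes.tsv"), "w") as fh:
        fh.write("gene\n")
        for g in sorted(bundle.known_genes.genes):
            fh.write(g + "\n")
    with open(j("truth.tsv"), "w") as fh:
        fh.write("dmr_id\tlabel\n")
        for iv in bundle.dmrs:
            fh.write(f"{iv.id}\t{bundle.truth[iv.id]}\n")
    with open(j("cpg_positions.tsv"), "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom in sorted(bundle.cpg_positions):
            for p in bundle.cpg_positions[chrom]:
                fh.write(f"{chrom}\t{p}\n")


def load_fixture(out_dir: str, config: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Read a written fixture back through the package's own readers."""
    j = lambda name: os.path.join(out_dir, name)
    cfg = config or FixtureConfig()
    dmrs = parse_bed(j("dmrs.bed"), name="dmrs")
    genes = parse_genes(j("genes.tsv"))
    tfbs = [
        parse_bed(j(f"tfbs_cell{c + 1}.bed"), name=f"tfbs_cell{c + 1}")
        for c in range(cfg.n_tfbs_cell_lines)
    ]
    dhs = [
        parse_bed(j(f"dhs_cell{c + 1}.bed"), name=f"dhs_cell{c + 1}")
        for c in range(cfg.n_dhs_cell_lines)
    ]
    truth = {}
    with open(j("truth.tsv")) as fh:
        fh.readline()
        for line in fh:
            d, lab = line.split()
            truth[d] = lab
    cpg: dict[str, list[int]] = {}
    with open(j("cpg_positions.tsv")) as fh:
        fh.readline()
        for line in fh:
            chrom, p = line.split()
            cpg.setdefault(chrom, []).append(int(p))
    known = None
    from .validation import read_gene_set

    known = read_gene_set(j("known_genes.tsv"), name="planted_genes")
    return FixtureBundle(
        config=cfg,
        dmrs=dmrs,
        truth=truth,
        genes=genes,
        tfbs=tfbs,
        dhs=dhs,
        enhancers=parse_bed(j("enhancers.bed"), name="enhancers"),
        insulators=parse_bed(j("insulators.bed"), name="insulators"),
        conservation=parse_bedgraph(j("conservation.bedgraph")),
        methylation=read_methylation_profiles(j("methylation.tsv")),
        expression=read_expression(j("expression.tsv"), j("sample_labels.tsv")),
        survival=read_survival(j("survival.tsv")),
        known_genes=known,
        cpg_positions={c: np.asarray(p) for c, p in cpg.items()},
    )


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def evaluate_recovery(
    agg: AggregationResult | RankVector, truth: Mapping[str, str]
) -> dict[str, float]:
    """How well an ordering recovers the planted regions.

    Returns the planted set's mean relative rank, the fraction of
    planted regions in the top decile, and the area under the
    planted-vs-background ranking curve (Mann-Whitney AUC: probability a
    planted region outranks a background one).
    """
    rr = agg.relative_ranks if isinstance(agg, AggregationResult) else agg.ranks
    missing = set(rr) ^ set(truth)
    if missing:
        raise ValueError(f"truth and ranking universes differ: {sorted(missing)[:5]}")
    planted = np.array([rr[d] for d, l in truth.items() if l == "planted"])
    background = np.array([rr[d] for d, l in truth.items() if l == "background"])
    if planted.size == 0 or background.size == 0:
        raise ValueError("need both planted and background regions")
    u = stats.mannwhitneyu(background, planted, alternative="two-sided").statistic
    auc = float(u) / (planted.size * background.size)
    return {
        "planted_mean_relative_rank": float(planted.mean()),
        "top_decile_fraction": float((planted <= 0.1).mean()),
        "recovery_auc": auc,
    }
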