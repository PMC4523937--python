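"""Per-DMR feature scores and their conversion to relative ranks.

Four evidence types are scored per region, each higher-is-better:

* expression alteration — the largest absolute log2 fold change among the
  region's coupled genes;
* conservation — the mean per-base PhastCons probability over the region;
* genomic-feature occupancy — overlap counts against TFBS (summed over
  cell lines), DHS (one merged peak set), enhancer and insulator tracks,
  combined into a single rank;
* methylation dynamics — the variance of all pairwise Pearson
  correlations between condition-wise CpG methylation profiles.

Scores become relative ranks (position / N, ties averaged) in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_genomics import (
    GenomicInterval,
    IntervalTrack,
    OverlapIndex,
    SignalTrack,
    logger,
    mean_signal,
    merge_intervals,
)
from .coupling import CouplingRecord
from .rank_aggregation import RankVector, aggregate_ranks

FEATURE_NAMES = ("expression", "conservation", "genomic_features", "dynamics")


@dataclass
class FeatureScoreTable:
    """Higher-is-better scores for one feature over the prioritized DMRs."""

    feature: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.scores.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"{self.feature}: non-finite score for {bad[:5]}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, with case/control labels."""

    values: pd.DataFrame  # index: gene ids; columns: sample ids
    labels: pd.Series  # sample id -> {"case", "control"}

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene ids in expression matrix")
        lab = set(self.labels.unique())
        if not lab <= {"case", "control"}:
            raise ValueError(f"unknown sample labels {lab - {'case', 'control'}}")
        if "case" not in lab or "control" not in lab:
            raise ValueError("need >=1 case and >=1 control sample")
        missing = set(self.values.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == group]


@dataclass
class MethylationProfile:
    """Per-region CpG-by-condition methylation matrix, values in [0,1]."""

    region_id: str
    values: pd.DataFrame  # index: CpG positions; columns: condition names

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        present = v[~np.isnan(v)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError(f"{self.region_id}: methylation outside [0,1]")
        if len(self.values) < 1:
            raise ValueError(f"{self.region_id}: no CpG rows")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def absolute_fold_change(expr: ExpressionMatrix) -> dict[str, float]:
    """|mean(case) - mean(control)| per gene on the log2 scale.

    Genes with all-missing values in either group are excluded with a
    warning.
    """
    case = expr.values[expr.group_columns("case")]
    control = expr.values[expr.group_columns("control")]
    fc = (case.mean(axis=1, skipna=True) - control.mean(axis=1, skipna=True)).abs()
    dropped = fc.index[fc.isna()]
    if len(dropped):
        logger.warning(
            "excluding %d genes with an all-missing expression group", len(dropped)
        )
    return {g: float(v) for g, v in fc.dropna().items()}


def expression_score(
    couplings: Iterable[CouplingRecord],
    fold_changes: Mapping[str, float],
    dmr_ids: Sequence[str],
) -> FeatureScoreTable:
    """Per DMR, the maximum |FC| over its coupled genes.

    DMRs whose coupled genes all lack expression score 0 (worst) so the
    region set stays fixed for aggregation.
    """
    best: dict[str, float] = {d: 0.0 for d in dmr_ids}
    for c in couplings:
        if c.dmr_id not in best:
            continue
        fc = fold_changes.get(c.gene_id)
        if fc is not None and fc > best[c.dmr_id]:
            best[c.dmr_id] = fc
    return FeatureScoreTable("expression", best)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def conservation_score(
    dmrs: IntervalTrack, phastcons: SignalTrack, missing: str = "exclude"
) -> FeatureScoreTable:
    """Mean PhastCons probability per region (covered bases by default)."""
    scores = {
        iv.id: mean_signal(iv, phastcons, missing=missing) for iv in dmrs
    }
    return FeatureScoreTable("conservation", scores)


# ---------------------------------------------------------------------------
# Genomic features (TFBS / DHS / enhancers / insulators)
# ---------------------------------------------------------------------------

def genomic_feature_frequencies(
    dmrs: IntervalTrack,
    tfbs: Sequence[IntervalTrack],
    dhs: Sequence[IntervalTrack],
    enhancers: IntervalTrack,
    insulators: IntervalTrack,
) -> dict[str, FeatureScoreTable]:
    """Overlap counts per DMR for each of the four regulatory features.

    DHS narrow peaks from all cell lines are merged into one peak set
    first; TFBS counts are summed across cell lines.
    """
    dhs_merged = merge_intervals(
        IntervalTrack("dhs", [iv for t in dhs for iv in t.intervals])
    )
    tf_indexes = [OverlapIndex(t) for t in tfbs]
    dhs_index = OverlapIndex(dhs_merged)
    enh_index = OverlapIndex(enhancers)
    ins_index = OverlapIndex(insulators)

    tf_scores, dhs_scores, enh_scores, ins_scores = {}, {}, {}, {}
    for iv in dmrs:
        tf_scores[iv.id] = float(sum(ix.count(iv) for ix in tf_indexes))
        dhs_scores[iv.id] = float(dhs_index.count(iv))
        enh_scores[iv.id] = float(enh_index.count(iv))
        ins_scores[iv.id] = float(ins_index.count(iv))
    return {
        "tfbs": FeatureScoreTable("tfbs", tf_scores),
        "dhs": FeatureScoreTable("dhs", dhs_scores),
        "enhancers": FeatureScoreTable("enhancers", enh_scores),
        "insulators": FeatureScoreTable("insulators", ins_scores),
    }


def genomic_feature_rank(
    freqs: Mapping[str, FeatureScoreTable], method: str = "orderstat"
) -> tuple[RankVector, dict[str, RankVector]]:
    """Combined genomic-feature rank plus the four sub-ranks.

    method="orderstat" (default) aggregates the four sub-ranks by order
    statistics; method="total" ranks the per-DMR total count.
    """
    expected = {"tfbs", "dhs", "enhancers", "insulators"}
    if set(freqs) != expected:
        raise ValueError(f"expected feature tables {sorted(expected)}")
    sub = {name: score_to_rank(tab) for name, tab in freqs.items()}
    if method == "orderstat":
        agg = aggregate_ranks(
            [sub[n] for n in ("tfbs", "dhs", "enhancers", "insulators")],
            label="genomic_features",
        )
        combined = agg.as_rank_vector()
    elif method == "total":
        ids = list(freqs["tfbs"].scores)
        totals = {
            d: sum(freqs[n].scores[d] for n in expected) for d in ids
        }
        combined = score_to_rank(FeatureScoreTable("genomic_features", totals))
    else:
        raise ValueError(f"unknown method {method!r}")
    return combined, sub


# ---------------------------------------------------------------------------
# Methylation dynamics
# ---------------------------------------------------------------------------

def dynamic_variation_score(profile: MethylationProfile) -> float:
    """Variance of pairwise Pearson correlations between condition columns.

    Conventions: fewer than 3 usable conditions -> 0; a pair needs >=2
    commonly covered CpGs; pairs with a constant column are dropped; the
    variance is the population variance over the retained correlations.
    """
    df = profile.values
    cols = list(df.columns)
    if len(cols) < 3 or len(df) < 2:
        return 0.0
    arr = df.to_numpy(dtype=float)
    corrs: list[float] = []
    if not np.isnan(arr).any():
        keep = [i for i in range(len(cols)) if np.ptp(arr[:, i]) > 0]
        if len(keep) < len(cols):
            logger.warning(
                "%s: %d constant methylation column(s); their pairs dropped",
                profile.region_id, len(cols) - len(keep),
            )
        if len(keep) >= 2:
            cm = np.corrcoef(arr[:, keep].T)
            corrs = list(cm[np.triu_indices(len(keep), k=1)])
    else:
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                xi, xj = arr[:, i], arr[:, j]
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() < 2:
                    continue
                a, b = xi[ok], xj[ok]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    logger.warning(
                        "%s: constant methylation column in pair (%s, %s); dropped",
                        profile.region_id, cols[i], cols[j],
                    )
                    continue
                corrs.append(float(stats.pearsonr(a, b)[0]))
    if len(corrs) < 2:
        return 0.0
    return float(np.var(corrs))  # population variance


def dynamics_scores(
    profiles: Iterable[MethylationProfile], dmr_ids: Sequence[str]
) -> FeatureScoreTable:
    """Dynamic variation score per DMR; regions without a profile score 0."""
    scores = {d: 0.0 for d in dmr_ids}
    for p in profiles:
        if p.region_id in scores:
            scores[p.region_id] = dynamic_variation_score(p)
    return FeatureScoreTable("dynamics", scores)


# ---------------------------------------------------------------------------
# Score -> rank
# ---------------------------------------------------------------------------

def score_to_rank(scores: FeatureScoreTable) -> RankVector:
    """Relative ranks in decreasing score order; ties share the average
    position, then positions are divided by N."""
    ids = list(scores.scores)
    if not ids:
        return RankVector(scores.feature, {})
    vals = pd.Series({k: scores.scores[k] for k in ids})
    positions = vals.rank(ascending=False, method="average")
    n = len(ids)
    return RankVector(
        scores.feature, {k: float(positions[k]) / n for k in ids}
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_feature_rank(
    scores: FeatureScoreTable, ranks: RankVector, path: str
) -> None:
    n = len(ranks.ranks)
    with open(path, "w") as fh:
        fh.write("dmr_id\tscore\tposition\trelative_rank\n")
        for rid in sorted(ranks.ranks, key=lambda r: ranks.ranks[r]):
            rr = ranks.ranks[rid]
            fh.write(f"{rid}\t{scores.scores[rid]:.10g}\t{rr * n:.10g}\t{rr:.10g}\n")


def read_methylation_profiles(path: str) -> list[MethylationProfile]:
    """Read a long methylation TSV: region_id, chrom, pos, then one column
    per condition; NA allowed."""
    df = pd.read_csv(path, sep="\t")
    cond_cols = [c for c in df.columns if c not in ("region_id", "chrom", "pos")]
    out = []
    for rid, grp in df.groupby("region_id", sort=True):
        mat = grp.set_index("pos")[cond_cols].astype(float)
        out.append(MethylationProfile(str(rid), mat))
    return out


def write_methylation_profiles(
    profiles: Sequence[MethylationProfile],
    chroms: Mapping[str, str],
    path: str,
) -> None:
    """Write the long methylation TSV; `chroms` maps region_id -> chrom."""
    if not profiles:
        raise ValueError("no profiles to write")
    conds = list(profiles[0].values.columns)
    with open(path, "w") as fh:
        fh.write("region_id\tchrom\tpos\t" + "\t".join(conds) + "\n")
        for p in profiles:
            for pos, row in p.values.iterrows():
                vals = "\t".join(
                    "NA" if np.isnan(v) else f"{v:.6g}" for v in row.to_numpy()
                )
                fh.write(f"{p.region_id}\t{chroms[p.region_id]}\t{pos}\t{vals}\n")


def read_expression(path: str, labels_path: str) -> ExpressionMatrix:
    """Expression TSV (gene x sample, first column 'gene') plus a two-column
    labels TSV (sample, label)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, lab.iloc[:, 0])


def write_expression(expr: ExpressionMatrix, path: str, labels_path: str) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
    expr.labels.rename("label").to_csv(labels_path, sep="\t", index_label="sample")
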