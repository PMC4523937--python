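"""End-to-end orchestration: couple -> rank -> aggregate -> validate.

`compute_individual_ranks` produces the four feature rank vectors over
the coupled DMR set; `run_pipeline` drives the whole file-based run and
writes a manifest (inputs, seeds, parameters, output hashes).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from .core_genomics import (
    GeneModel,
    IntervalTrack,
    SignalTrack,
    logger,
    parse_bed,
    parse_bedgraph,
    parse_genes,
    write_bed,
)
from .coupling import (
    CouplingRecord,
    couple_dmrs_to_genes,
    filter_uncoupled_dmrs,
    write_couplings,
)
from .feature_ranks import (
    ExpressionMatrix,
    MethylationProfile,
    absolute_fold_change,
    conservation_score,
    dynamics_scores,
    expression_score,
    genomic_feature_frequencies,
    genomic_feature_rank,
    read_expression,
    read_methylation_profiles,
    score_to_rank,
    write_feature_rank,
)
from .rank_aggregation import (
    AggregationResult,
    RankVector,
    aggregate_ranks,
    enumerate_rank_combinations,
    write_aggregation,
)
from .validation import gene_set_permutation_test, read_gene_set, write_enrichment

DEFAULT_SEED = 20_150_101  # fixed constant; never wall-clock


@dataclass
class RankingOutput:
    couplings: list[CouplingRecord]
    prioritized: IntervalTrack
    ranks: dict[str, RankVector]  # the four individual rank vectors
    sub_ranks: dict[str, RankVector]  # TFBS/DHS/enhancer/insulator sub-ranks
    scores: dict[str, dict[str, float]]


def compute_individual_ranks(
    dmrs: IntervalTrack,
    genes: Sequence[GeneModel],
    expression: ExpressionMatrix,
    conservation: SignalTrack,
    tfbs: Sequence[IntervalTrack],
    dhs: Sequence[IntervalTrack],
    enhancers: IntervalTrack,
    insulators: IntervalTrack,
    methylation: Sequence[MethylationProfile],
    genomic_method: str = "orderstat",
) -> RankingOutput:
    """Couple DMRs to genes, drop uncoupled DMRs, and build the four
    individual feature rank vectors over the retained region set."""
    couplings = couple_dmrs_to_genes(dmrs, genes)
    prioritized = filter_uncoupled_dmrs(dmrs, couplings)
    ids = [iv.id for iv in prioritized]

    fc = absolute_fold_change(expression)
    expr_scores = expression_score(couplings, fc, ids)
    cons_scores = conservation_score(prioritized, conservation)
    freqs = genomic_feature_frequencies(prioritized, tfbs, dhs, enhancers, insulators)
    gf_rank, sub_ranks = genomic_feature_rank(freqs, method=genomic_method)
    dyn_scores = dynamics_scores(methylation, ids)

    ranks = {
        "expression": score_to_rank(expr_scores),
        "conservation": score_to_rank(cons_scores),
        "genomic_features": gf_rank,
        "dynamics": score_to_rank(dyn_scores),
    }
    scores = {
        "expression": expr_scores.scores,
        "conservation": cons_scores.scores,
        "dynamics": dyn_scores.scores,
        **{k: v.scores for k, v in freqs.items()},
    }
    return RankingOutput(couplings, prioritized, ranks, sub_ranks, scores)


@dataclass
class RunConfig:
    """File-based run configuration (YAML-loadable)."""

    inputs: dict[str, Any]
    out_dir: str
    seed: int = DEFAULT_SEED
    combinations: str = "all"  # all | full
    genomic_method: str = "orderstat"
    n_permutations: int = 10_000
    gene_set_fraction: Optional[float] = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for role, p in cfg.inputs.items():
            paths = p if isinstance(p, list) else [p]
            for q in paths:
                if not os.path.exists(q):
                    raise FileNotFoundError(f"input role {role!r}: {q} does not exist")
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_REQUIRED_ROLES = (
    "dmrs", "genes", "expression", "sample_labels", "conservation",
    "tfbs", "dhs", "enhancers", "insulators", "methylation",
)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute coupling, the four feature ranks, the requested
    aggregations, and the known-gene-set validation; return the manifest."""
    missing = [r for r in _REQUIRED_ROLES if r not in config.inputs]
    if missing:
        raise ValueError(f"missing input roles: {missing}")
    os.makedirs(config.out_dir, exist_ok=True)
    inp = config.inputs

    dmrs = parse_bed(inp["dmrs"], name="dmrs")
    genes = parse_genes(inp["genes"])
    expression = read_expression(inp["expression"], inp["sample_labels"])
    conservation = parse_bedgraph(inp["conservation"])
    tfbs = [parse_bed(p, name=os.path.basename(p)) for p in inp["tfbs"]]
    dhs = [parse_bed(p, name=os.path.basename(p)) for p in inp["dhs"]]
    enhancers = parse_bed(inp["enhancers"], name="enhancers")
    insulators = parse_bed(inp["insulators"], name="insulators")
    methylation = read_methylation_profiles(inp["methylation"])

    out = compute_individual_ranks(
        dmrs, genes, expression, conservation, tfbs, dhs, enhancers,
        insulators, methylation, genomic_method=config.genomic_method,
    )
    outputs: list[str] = []

    def emit(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        outputs.append(path)
        return path

    write_bed(out.prioritized, emit("prioritized_dmrs.bed"))
    write_couplings(out.couplings, emit("couplings.tsv"))
    from .feature_ranks import FeatureScoreTable

    for feat, rv in out.ranks.items():
        if feat == "genomic_features":
            totals = {
                d: sum(out.scores[k][d] for k in ("tfbs", "dhs", "enhancers", "insulators"))
                for d in rv.ranks
            }
            tab = FeatureScoreTable(feat, totals)
        else:
            tab = FeatureScoreTable(feat, out.scores[feat])
        write_feature_rank(tab, rv, emit(f"rank_{feat}.tsv"))

    vectors = [out.ranks[f] for f in ("expression", "conservation", "genomic_features", "dynamics")]
    if config.combinations == "all":
        results = enumerate_rank_combinations(vectors)
    elif config.combinations == "full":
        full = aggregate_ranks(vectors, label="+".join(v.name for v in vectors))
        results = {full.label: full}
    else:
        raise ValueError(f"combinations must be all|full, got {config.combinations!r}")
    for label, res in results.items():
        write_aggregation(res, emit(f"aggregated_{label.replace('+', '_')}.tsv"))

    full_label = "+".join(v.name for v in vectors)
    validations: dict[str, Any] = {}
    if "known_genes" in inp:
        known = read_gene_set(inp["known_genes"], name="known_genes")
        enr = gene_set_permutation_test(
            known, results[full_label], out.couplings,
            n_reps=config.n_permutations, seed=config.seed,
        )
        write_enrichment(enr, emit("geneset_permutation.tsv"), "mean_relative_rank")
        validations["geneset_permutation"] = {
            "observed": enr.observed, "p_value": enr.p_value,
            "p_is_bound": enr.p_is_bound,
        }

    manifest = {
        "inputs": {
            role: ({k: _sha256(k) for k in p} if isinstance(p, list) else {p: _sha256(p)})
            for role, p in inp.items()
        },
        "parameters": {
            "seed": config.seed,
            "combinations": config.combinations,
            "genomic_method": config.genomic_method,
            "n_permutations": config.n_permutations,
        },
        "n_dmrs_input": len(dmrs),
        "n_dmrs_prioritized": len(out.prioritized),
        "n_aggregations": len(results),
        "validations": validations,
        "outputs": {p: _sha256(p) for p in outputs},
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d outputs in %s", len(outputs), config.out_dir)
    return manifest
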