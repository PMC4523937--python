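# fdmrank

Prioritization of **functional differentially methylated regions (fDMRs)**
by order-statistics rank aggregation of multi-omics evidence.

Genome-wide methylation screens in cancer produce thousands of
differentially methylated regions (DMRs), most of which are passengers.
`fdmrank` is for computational epigenomics researchers who want to rank a
DMR set by converging functional evidence rather than by methylation
difference alone. Each region is scored on four independent feature axes:

1. **Expression alteration** — the largest absolute log2 fold change
   (case vs control group means) among the genes coupled to the DMR.
   DMRs are coupled to every coding or noncoding gene they overlap or
   that lies within 2 kb / 10 kb / 100 kb flanks; regions coupling no
   gene are dropped from prioritization.
2. **Conservation** — the mean per-base PhastCons probability over the
   region.
3. **Regulatory occupancy** — overlap counts against TFBS (summed over
   cell lines), DNase hypersensitive sites (cell-line peaks merged into
   one set first), enhancers and insulators, themselves combined into a
   single genomic-feature rank.
4. **Methylation dynamics** — the variance of all pairwise Pearson
   correlations between condition-wise CpG methylation profiles of the
   region across tissues/cell lines.

## The aggregation statistic

Each feature yields relative ranks *r<sub>j</sub>* ∈ (0, 1] (position
divided by list length, ties averaged). Under the null that a region's
ranks are i.i.d. uniform, the probability that the *k*-th smallest of
*n* relative ranks is ≤ *x* is the binomial upper tail

&nbsp;&nbsp;&nbsp;&nbsp;β<sub>k,n</sub>(x) = Σ<sub>j=k..n</sub> C(n, j) x<sup>j</sup> (1 − x)<sup>n−j</sup> = I<sub>x</sub>(k, n − k + 1),

computed here through the regularized incomplete beta function. A
region's score over its sorted rank vector r<sub>(1)</sub> ≤ … ≤
r<sub>(n)</sub> is

&nbsp;&nbsp;&nbsp;&nbsp;ρ = min<sub>k</sub> β<sub>k,n</sub>(r<sub>(k)</sub>),

and regions are ordered by ascending ρ: a small ρ means "improbably
near the top of several independent lists". All 2⁴ − 1 = 15 feature
combinations can be aggregated and compared. Validation utilities
include a gene-set permutation test (mean of per-gene best ranks against
random gene sets), a hypergeometric test on top-list overlap, enrichment
against chromosome/length/CpG-density–matched random regions, and
biomarker procedures (Cox-screened expression risk score with median
split and log-rank test; stratified cross-validated ROC).

## Worked example

Everything is testable without downloads through the synthetic fixture
generator, which plants a 5% subset of regions jointly elevated in all
four features:

```python
import fdmrank as f

bundle = f.generate_fixture(f.FixtureConfig(seed=0))
out = f.compute_individual_ranks(
    bundle.dmrs, bundle.genes, bundle.expression, bundle.conservation,
    bundle.tfbs, bundle.dhs, bundle.enhancers, bundle.insulators,
    bundle.methylation,
)
agg = f.aggregate_ranks(
    [out.ranks[k] for k in ("expression", "conservation",
                            "genomic_features", "dynamics")], label="full")
for rid in agg.ordering[:5]:
    print(rid, round(agg.rho[rid], 6), bundle.truth[rid])
print(f.evaluate_recovery(agg, bundle.truth))
```

prints

```
dmr0061 0.000506 planted
dmr0111 0.000638 background
dmr0198 0.001168 planted
dmr0137 0.003185 background
dmr0155 0.003318 background
{'planted_mean_relative_rank': 0.064, 'top_decile_fraction': 0.8,
 'recovery_auc': 0.9616}
```

Two of the top five regions (and 8 of the 10 planted regions inside the
top decile) are true planted fDMRs; the planted set's mean relative rank
of 0.064 is far below the 0.5 expected by chance, and the ranking AUC of
0.96 summarizes planted-vs-background separation. The permutation test
on the planted genes gives an observed mean relative rank of 0.035 with
an empirical p reported as < 1/10000 (no random gene set did better).

A file-based run of the same pipeline (producing all 15 aggregated rank
lists plus a manifest with output hashes) is available through the CLI:

```bash
fdmrank fixture generate --seed 0 --out fixture/
fdmrank run --config run.yaml       # see RunConfig for the YAML keys
```

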