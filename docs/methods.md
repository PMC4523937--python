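# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`, the BED
convention. BED inputs are read as-is; browser-style `chrN:a-b` strings
and BED files flagged `one_based=True` are treated as 1-based inclusive
and converted on read by decrementing the start. Chromosome names are
matched as exact strings — no `chr1`/`1` aliasing — because silent
aliasing makes overlap counts irreproducible; callers who need
normalization can pass an explicit hook to `parse_bed`.

Interval merging uses base-union semantics: overlapping **and touching**
intervals merge, so the total merged length always equals the number of
distinct covered bases. The same convention propagates to coupling: a
gene that touches a DMR (zero-bp gap, no shared base) is classified
gene-overlapping with distance 0, keeping "distance 0 iff overlapping"
as an invariant of the coupling records.

Signal tracks store sorted non-overlapping runs per chromosome. The
mean signal of a region is taken over **covered bases only** by default;
a missing-as-zero mode divides by the full region length instead. A
region with no coverage scores 0 with a logged warning. Exclusion is
the default because deflating the conservation of sparsely covered
regions would conflate missingness with low conservation.

## DMR–gene coupling

A DMR couples to every coding or noncoding gene that overlaps it or lies
within 2 kb, 10 kb or 100 kb of it; each (DMR, gene) pair receives the
tightest applicable category. Windows are anchored on the gene (flanks
of the annotated gene), and distance is the gap between closest interval
boundaries, strand-agnostic — the windows are symmetric, so strand
affects only the positional labels (`olup`/`oldown`/`upstream`/
`downstream` are defined relative to the gene's 5' side). Coupling is
many-to-many; downstream statistics that need one value per gene (the
gene-set permutation test) take the gene's best-ranked coupled DMR.
DMRs coupling no gene within 100 kb are removed before ranking, and the
region set is then frozen: every feature scores exactly this set.

## Feature scores

* **Expression**: fold change is the absolute difference of group means
  on log2-scale expression (standard for RMA-processed arrays); a DMR's
  score is the maximum over its coupled genes. Regions whose coupled
  genes are all absent from the matrix score 0 (worst) rather than being
  excluded, because aggregation requires an identical region set in
  every list.
* **Conservation**: mean per-base score over the region (see above).
* **Regulatory occupancy**: enhancer and insulator scores are overlap
  counts; DHS peaks from all cell lines are merged into one peak set
  before counting; TFBS counts are summed across cell lines. The
  combined genomic-feature rank defaults to order-statistics aggregation
  of the four sub-ranks; ranking the per-DMR total count is available as
  `method="total"`. Aggregation is the default because the four
  sub-features are on incommensurable scales (a raw total would be
  dominated by the densest track).
* **Dynamics**: Pearson correlations between every unordered pair of
  condition columns, over CpGs covered in both conditions; the score is
  the **population** variance of those correlations. Conventions where
  the procedure is otherwise undefined: fewer than 3 conditions or fewer
  than 2 retained correlations → score 0; pairs with a constant column
  or fewer than 2 shared CpGs are dropped with a warning.

Scores become ranks in decreasing order; ties share the average
position; relative rank = position / N ∈ (0, 1].

## Rank aggregation

β<sub>k,n</sub>(x), the probability that the k-th smallest of n i.i.d.
uniforms is ≤ x, is computed as the regularized incomplete beta function
I<sub>x</sub>(k, n−k+1) (`scipy.special.betainc`) — mathematically
identical to the binomial upper-tail sum and numerically stable for any
n, with no underflow concerns. ρ = min<sub>k</sub>
β<sub>k,n</sub>(r<sub>(k)</sub>) is used **directly** for ordering; no
factorial normalization is applied, since only the ordering is
consumed downstream. Ties in ρ are broken by mean relative rank, then
lexicographic region id, so output files are deterministic.

## Validation statistics

* **Gene-set permutation test**: observed statistic is the mean over set
  genes of each gene's minimum relative rank; the null draws equally
  sized gene sets from the universe of all coupled genes. The p-value
  counts random means **strictly smaller** than the observed one
  (an inclusive variant is available by flag). A zero count is reported
  as the bound p < 1/n_reps, never 0.
* **Hypergeometric overlap**: top sets are the first ⌈fraction·N⌉
  regions of each ordering over the shared universe; upper-tail
  probability of at least the observed overlap.
* **Matched random regions**: per template region, rejection sampling of
  a same-chromosome, same-length region inside the universe with CpG
  density within a relative tolerance (default 20%, the data being only
  required to be "comparable") of the template; because matched regions
  have identical length the band is applied to CpG counts, with a
  one-count absolute floor so that sparse regions — where a relative
  band may contain no integer count — remain matchable; at most 10,000
  retries per region, then a hard error naming the region. Universe blocks are
  chosen with probability proportional to the number of valid start
  positions so placement is uniform over all feasible positions.
* **Per-region signal p**: a region's signal level is its mean signal
  (matching the conservation treatment). The empirical p is two-sided,
  2·min(P≥, P≤) capped at 1; a zero-exceedance tail reports the
  one-sided bound < 1/n.
* **Top vs tail**: Wilcoxon rank-sum on levels; chi-squared on the 2×2
  significant/not table, reported as not applicable when a margin is 0.

## Biomarker procedures

Cox proportional-hazards fitting and the log-rank statistic are
delegated to lifelines; this module owns the selection logic
(univariable Wald p < 0.1 by default), the linear risk score
Σ β<sub>g</sub>·expression<sub>g</sub>, the median split (ties at the
median go to the low-risk group, so groups differ by at most the tie
count) and the decision flow. Collinear candidate genes (|r| > 0.9999)
are rejected with an error naming the pair. Classification uses a
standardized regularized logistic regression under stratified k-fold
cross-validation; every sample is scored exactly once out-of-fold and
the pooled scores give a single ROC area. Samples are put in canonical
(sorted) order first, so the result depends only on the seed, not on
input column order.

## Synthetic fixtures

The generator emulates the statistical structure of the real inputs —
a region set with a small planted subset jointly elevated in all four
features — with simple, stated nulls and no claim of biological realism:

* Geometry: 200 DMRs of 1–4 kb in evenly spaced slots on 4 chromosomes
  of 1.2 Mb; 5% planted. Every DMR gets one dedicated gene, cycling
  through the four coupling categories (overlap, 1.5 kb, 8 kb, 60 kb
  gaps) so all category code paths are exercised and no region is lost
  to filtering; 50 additional genes are placed uniformly.
* Expression: log2-scale values, gene baseline N(7, 1), sample noise
  N(0, 1), 40 case / 12 control samples (a scaled-down version of a
  typical tumor-heavy array series). Planted genes get a case-mean
  shift of ±0.75 (hyper- and hypo-expression equally likely).
* Conservation: region means from Beta(2, 5), +0.15 for planted
  regions, written as four jittered sub-runs per region.
* Tracks: 3 TFBS cell lines, 3 DHS cell lines, enhancers, insulators;
  elements of 200–500 bp placed homogeneously at 8×10⁻⁴ per bp;
  planted regions receive extra elements at 1.5× the expected
  background per-region count.
* Methylation: ~0.6 CpGs per 100 bp; per region a base profile
  U(0.1, 0.9) per CpG; each of 8 conditions tracks the base profile
  with a condition-specific slope N(1, 0.6) plus noise (region-level
  noise SD drawn from U(0.05, 0.2)). The slope heterogeneity gives the
  background correlation-variance null a heavy right tail, as diverse
  tissues do. Planted regions flip the slope's sign with probability
  dynamics_effect/2 (default 0.5), inflating the correlation variance.
* Survival: exponential times for case samples with hazard
  0.1·HR^z, z the standardized expression of the first planted gene,
  HR = 3; independent exponential censoring (~25% censored).

Effect sizes were chosen so that each feature is individually
informative but imperfect (per-feature planted-vs-background ranking
AUC roughly 0.8–0.93) while the joint signal is strong — the regime the
method is designed for, in which aggregation visibly outperforms every
single feature. Setting all four effect sizes to 0 produces a pure-null
fixture in which planted and background regions are indistinguishable
feature by feature.

What passing tests on these fixtures show: the machinery (coupling
windows, rank arithmetic, β/ρ computation, permutation calibration,
sampler constraints) is correct, and aggregation recovers a jointly
planted signal that no single feature recovers as well. What they do
not show: performance on real methylation data, where features are
correlated, nulls are not exchangeable, annotation is incomplete, and
effect sizes are unknown.

## Numerical and degenerate-input choices

* Relative ranks are validated to lie in (0, 1]; empty rank vectors and
  mismatched region sets are errors (the symmetric difference is
  reported).
* Pearson rank correlation of a constant vector is reported as NaN
  rather than raising.
* All randomized procedures take explicit integer seeds; absent seeds
  default to a fixed constant, never wall-clock time.
* Problem sizes in the test suite and the acceptance script (200-region
  fixtures, 20 seeds, 10,000 permutations, 100-replicate power checks)
  were chosen as the smallest sizes at which the calibration and power
  properties are stable and clearly readable.

## Known limitations

* Transcript-level coupling (isoforms, promoter-specific association) is
  out of scope; coupling is gene-body ± flanks only.
* BigWig/BAM inputs are not parsed; signals arrive as bedGraph.
* The dynamics score drops undefined correlation pairs silently (with a
  warning); regions measured in very few conditions are conservatively
  scored 0, which can only hurt their rank.
* The matched-random sampler matches chromosome, length and CpG density
  but not GC content or mappability.
* The classifier behind the cross-validated ROC is a fixed regularized
  logistic regression; it is a measurement device for gene-set signal,
  not a tuned production classifier.
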