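# Methods

`renin-gsx` re-implements, as a tested pipeline, the transcriptional
analysis used to profile FACS-sorted cells of renin lineage (CoRL) before
and five days after abrupt podocyte ablation: array normalization,
probe-to-gene collapsing, regularized Bayesian differential expression,
over-representation analysis, gene set enrichment analysis, and the
transcription-factor x pathway integration that nominates candidate master
regulators. This note records the models, the parameters that matter, the
numerical conventions, and the limits of what the synthetic tests show.

## Pipeline model

**Normalization.** Log2 intensities are quantile-normalized: every sample
column is forced onto the common distribution given by the row-wise mean of
the column-sorted data. Ties receive the mean of the reference values their
rank span covers. The map is idempotent, preserves within-column rank
order, and makes all per-sample spread statistics identical — which is the
diagnostic `variance_summary` verifies. The bead-level variance-stabilizing
transformation applied by array-vendor toolchains operates on data below
the summarized-intensity level this package ingests; log2 + quantile
normalization is this package's normalization model.

**Probe collapsing.** Probes mapping to one gene symbol are averaged per
sample, one row per symbol. Unannotated probes are dropped with a logged
count. Collapsing commutes with mean-centering (linearity), and averaging
replicate probes reduces probe-level noise by construction.

**Differential expression.** The two-group comparison uses a regularized
t-statistic in the empirical-Bayes style of CyberT (Baldi & Long 2001).
For each group, genes are ranked by group mean and the background variance
`s0^2` of a gene is the mean sample variance over the `window_w` genes
nearest in rank (window shifted inward at the edges so it always holds
exactly `window_w` genes). The regularized variance is

    s~^2 = (v0 * s0^2 + (n - 1) * s^2) / (v0 + n - 2)

and the statistic and reference law are

    t' = (m2 - m1) / sqrt(s~1^2/n1 + s~2^2/n2),   t' ~ t(2*v0 + n1 + n2 - 4).

Defaults `window_w = 101`, `v0 = 10` are the published web-tool defaults.
Two-sided p-values are adjusted by the Benjamini-Hochberg step-up rule
(implemented from the formula; cross-checked against statsmodels in tests).
The DE gene list defaults to FDR <= 0.01; the integration stage also uses
0.001.

*Calibration caveat.* The regularized statistic is deliberately
conservative under the null: `E[s~^2] = sigma^2 (v0+n-1)/(v0+n-2)` exceeds
the true variance and the shrunken denominator is far more concentrated
than the chi-square its reference t assumes. On global-null simulations
(10,000 genes, 4 vs 4) the rejection fraction at p <= 0.05 is ~0.04 and a
KS test rejects uniformity of the p-value distribution. This is a property
of the method — it trades nominal calibration for variance stability at
n = 4 — and the test suite asserts the behaviour the statistic actually
has.

**Over-representation.** Hypergeometric upper tail `P(X >= k)` for the
overlap between a directional DE list and each catalog set, BH-adjusted
across sets. The universe defaults to all genes on the collapsed array, not
the genome, which avoids inflating enrichment when the array itself is
biased; it is switchable. Up- and downregulated lists are tested
separately. This plain hypergeometric engine stands in for annotation-
clustering web tools; no fuzzy clustering of related terms is attempted.

**GSEA.** Genes are ranked by signal-to-noise
`(m_test - m_ref) / (sd_test + sd_ref)` with each sd floored at
`max(0.2 |m|, 0.2)` (the regularized t is available as an alternative
metric). Each set is scored by the weighted Kolmogorov-Smirnov running
sum: member at rank j adds `|r_j|^p / N_R`, non-member subtracts
`1/(N - N_hits)`; ES is the extremum of the walk and the leading edge is
the members at or before it (after it, when ES < 0). The null is *gene-set
permutation*: `n_perm` random same-size sets drawn from the ranked
universe (default 1,000). NES divides ES by the mean magnitude of
same-sign permuted scores; the nominal p is the same-sign tail fraction
with a +1 pseudo-count; the FDR q is the standard ratio of pooled-null and
observed NES tail fractions, computed separately per sign and clipped to
[0, 1]. Weight `p = 1`, set-size bounds 15/500 are the desktop-tool
defaults. Gene-set permutation is used (rather than phenotype permutation)
because that is what the motivating workflow specifies, and because 4 + 4
samples admit too few label permutations anyway; its p-values are exactly
calibrated against random sets by construction, which the null-calibration
test verifies.

**Integration.** For one direction at a time, the search space holds TF
target sets and pathway/hallmark sets with matching NES sign and
`q <= fdr_set` (down: 0.01; up: 0.001, both inclusive). Every TF set is
intersected with every pathway set; a shared gene is kept iff its BH q is
at or below the direction's gene threshold and its fold-change sign
matches. The full connection map is exported; the *plotted* table
additionally drops up-direction connections with fewer than 4 genes, then
TFs connected to exactly one pathway. The contingency matrix (rows TFs,
columns pathways, cells gene counts, axes ordered by descending marginal
sum then name) is written in a Circos-tableviewer-ready layout. An
independent validator pass re-checks every exported gene against all three
predicates, and tightening any threshold can only shrink the result
(monotonicity, covered by tests). "Top" intersection genes — the
qPCR-candidate analog — are ranked by q ascending, then |log2fc|
descending, then symbol; the tie-ranking rule is a package choice since
several are defensible.

**Enrichment map.** Enriched sets (typically q <= 0.01) become nodes with
NES/q/size attributes; sets whose overlap coefficient
`|A n B| / min(|A|, |B|)` reaches 0.5 are joined by an edge weighted by the
coefficient. Node/edge TSVs are importable by standard graph tools; no
layout or rendering is done.

## Synthetic data generator

The generator emulates the study conditions: 4 vs 4 arrays, 18,138 unique
genes interrogated by ~1.4x as many probes (per-gene probe count uniform on
{1, 2}), log2 baselines uniform on [6, 12], heteroskedastic per-gene
Gaussian noise with sd uniform on [0.1, 0.6], probe-level noise at 0.2x the
gene sd, and catalogs of 615 TF-target and 1,379 pathway sets of 15-100
members. Differential expression is planted two ways: *active sets* whose
members all receive the set's signed log2 effect (a gene claimed by an
earlier listed set keeps that effect; no stacking), and a background
fraction (default 5%) of remaining genes with individual effects of
magnitude 0.5-2, 55% of them negative to mirror the downregulation excess
seen after podocyte ablation. Each pathway set draws a configurable
fraction (default 0.3) of its members from a round-robin partner TF set,
so TF x pathway intersections are non-trivial and integration precision
can be scored against the planted truth.

What the generator does **not** emulate: bead-level summarization and
background correction, intensity-dependent variance, correlated genes
within pathways beyond shared planted effects, batch structure, or
symbol-mapping noise between organisms. Passing tests therefore
demonstrate the correctness and calibration of the *computational* chain
under a clean Gaussian model, not robustness to real array artifacts.

## Numerical conventions

- Running-sum extremum: the earliest position wins among candidates whose
  |value| is within 1e-12 of the maximum; ES is clipped to [-1, 1] against
  rounding overshoot. The vectorized permutation scorer evaluates the walk
  only at hits and immediately before hits (the only possible extrema) and
  agrees with the literal walk to 1e-12 (enumeration-tested; also
  cross-checked against an independent GSEA implementation).
- Ranking ties are broken by gene symbol ascending; all writers use stable
  ordering and fixed 6-significant-digit floats, so identical inputs give
  byte-identical outputs.
- Gene symbols are uppercased at every ingestion point; the motif/pathway
  catalogs use human-centric symbols while the arrays are mouse, and
  case-insensitive joining is the only matching that works across the two.
  Matched/unmatched counts are logged.
- One global seed is expanded into per-stage sub-seeds by a fixed
  name-keyed `SeedSequence` derivation, so adding a stage never shifts
  another stage's stream; GSEA draws one permutation table per run and
  reuses its first k columns for every set size k.
- Missing values in expression input are an error, not imputed; a
  single-column matrix is its own quantile-normalization fixed point; a
  constant matrix yields all-zero PCA variance ratios rather than an error.

## Problem sizes used by the checks

The acceptance script runs the planted study at full scale (18,138 genes,
~27k probes, 615 + 1,379 sets, 1,000 permutations) and the null
calibration at 10,000 genes with 100 sets and 200 permutations; the pytest
suite uses the same designs at reduced gene/set counts. These sizes give
sub-minute runs while keeping every ratio (samples, set sizes,
permutations) at study scale.

## Applying the pipeline to the deposited study data

No downloader is built in. To reproduce the real analysis, export the
GEO series matrix of the deposited experiment to GCT (25,698 annotated
probes x 8 samples, log2 scale), write a `8 2 1` CLS for the 4 + 4 design,
obtain the MSigDB v6.0 TFT and CP+Hallmark GMT files, and chain
`renin-gsx preprocess / diffexp / gsea / integrate` (or a `RunConfig` with
the input paths set). Which ranking metric and set-size bounds the original
desktop-tool analysis used is not recorded; the defaults here are the
tool's published defaults, so reproduced NES values should be compared
with rank-order and tolerance rather than digit-for-digit.

## Known limitations

- The regularized t's p-values are conservative at n = 4 (see above);
  downstream FDR thresholds inherit that conservativeness.
- Exactly two groups; no covariates or linear-model framework.
- Gene-set permutation tests set *membership* exchangeability, not
  phenotype exchangeability; strongly correlated expression within a set
  inflates |ES| against this null, as it does in the original method.
- The enrichment-map similarity cutoff (overlap coefficient 0.5) follows
  the cited visualization tool's convention; no automated module labeling.
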