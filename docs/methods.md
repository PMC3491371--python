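# Methods

## Model and procedure

The pipeline assumes a compendium-style expression matrix (features ×
samples) in which a labeled minority *anchor* population shares a
coherent transcriptional program, and asks two questions: which genes
express that program most specifically, and how strongly does each
sample express it.

**Rank normalization.** Probe-level intensities are averaged into one
value per gene (arithmetic mean over a probe→gene map, unmapped probes
dropped), and each sample is then replaced by fractional ranks r/G in
(0, 1], ties averaged. The gene-level-then-rank order is fixed: ranking
happens on gene-centric values. The rank denominator is G (so the top
gene in a sample scores exactly 1); ties receive the average of their
ranks. Both choices are conventions of this implementation — any
monotone-equivalent variant would leave the window statistic unchanged.

**Window (FIR) score.** For one gene, samples are sorted ascending by
value with ties broken by original sample position (stable sort, so the
result is deterministic across platforms). Only full windows are
considered: S − W + 1 positions for S samples and window width W. The
score is the maximum anchor fraction over windows; the earliest window
attaining the maximum is reported. W defaults to the anchor count, under
which a score of 1.0 means the whole anchor population fits in one
frame. Binomial tail probabilities P(X ≥ k), X ~ Bin(W, p) with p the
database-wide anchor proportion, are reported raw — they are
descriptive; selection is by score, and no multiple-testing correction
is applied. The full-table tie-break chain is score descending, then
p-value ascending, then gene id; ranks are dense over distinct scores.

**Signature size.** A sweep over candidate sizes n selects the top-n
genes, computes the stemness index, and scores the one-way fixed-effects
ANOVA F of the index across a user-chosen set of phenotype groups. The
window never varies across the sweep, only n. The sweep reports the full
F(n) curve and its argmax; the final cut is left to the user. The ANOVA
returns F = 0 on zero-total-variance input (rather than erroring) so
sweeps over degenerate synthetic inputs complete, and +inf when group
means differ with zero within-group variance.

**Stemness index.** The matrix is restricted to the signature genes
present (an error is raised below 50% coverage — the threshold is this
package's convention; missingness is not otherwise modeled), each gene
row is mean-centered with **no variance scaling** (the gene–gene
covariance matrix, not the correlation matrix, is decomposed; inputs are
already rank-bounded), and PC1 is taken via SVD of the centered block.
The per-sample index is the PC1 projection, centered at 0 by
construction. The sign of PC1 is arbitrary; it is fixed by forcing a
chosen orientation group's mean index non-negative, with a deterministic
fallback (largest-|loading| gene positive) when no orientation group is
available. For external data series the PCA is refit inside each series,
never pooled and never projected onto frozen loadings (a deliberate
design choice; projection onto frozen loadings is out of scope).
Single-gene signatures are permitted — the index degenerates to the
centered gene itself, which is the correct limit.

**Cross-species transfer.** Signatures translate through a one-to-one
ortholog map. Non-unique entries are removed at load time in *both*
directions (a source or target appearing more than once drops all its
entries); this bidirectional rule is the conservative reading of
"unique match" and every drop is logged. If two signature genes collapse
onto one target despite that, the collision group is excluded before
PCA.

**Ordered evaluation.** Stage and grade recovery are scored
orientation-free: |Spearman ρ| between the index and integer level
codes, per-level medians, and pairwise rank-sum AUC folded to ≥ 0.5.

**Diagnostics.** (1) Correlation null: all m(m−1)/2 signature pairwise
Pearson correlations per sample group versus the pooled correlations of
R random same-size gene sets (drawn uniformly without replacement from
the full universe, signature genes included by default); the location
shift (median difference) is reported together with the per-set median
distribution, from which a Monte-Carlo band can be formed — no p-value
is claimed. Pairs containing a within-group-constant gene are excluded
with a logged count. (2) Coexpression modules: per-gene normalization
(z-score default; per-gene quantile ranks as the alternative — both
modes exist because the two are common in heatmap practice and differ
only in tail weighting), agglomerative clustering with Euclidean
distance and complete linkage (average available), dendrogram cut at k;
module labels are renumbered by dendrogram left-to-right leaf order and
rows are processed in lexicographic gene order, making the output
invariant to caller row order. k is a parameter, not inferred. (3)
Hypergeometric over-representation against user-supplied GMT
collections, sets intersected with the universe first; raw p-values by
default, Benjamini–Hochberg by flag. GO-specific machinery (DAG
propagation, conditional tests) is out of scope.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the analysis assumes,
with planted ground truth for exact scoring:

- **Landscape** (`simulate_landscape`): groups with configurable sizes
  and latent stemness means (defaults: pluripotent 1.0 > multipotent
  0.75 > progenitor 0.55 > cancer 0.4 > normal 0.1; 40 anchors among
  400 samples — a ~10% anchor minority in a tissue-dominated
  compendium). *Gradient genes* are linear read-outs of the latent
  stemness s: amplitude · (s − mean(s)) + Gaussian noise, with the
  amplitude set so the per-gene signal-to-noise ratio equals
  `gradient_snr` (default 4). The latent term is centered so gradient
  genes straddle the background intensity distribution — high in
  stem-like samples, low in differentiated ones — rather than sitting
  uniformly above it; without centering, per-sample rank normalization
  would saturate these genes at the top ranks of every sample and erase
  the signal. *Band genes* give anchors a uniform band of width
  `band_width` (default 0.1 of the unit range) at a random center;
  non-anchors are either broad-uniform or, for the bimodal fraction, an
  equal-weight two-component Gaussian mixture with components
  equidistant from the band center — symmetric by construction, so the
  anchor/non-anchor means match and a mean-difference t-test is nearly
  blind while the window statistic is not. Background genes are iid
  Gaussian.
- **Time course** (`simulate_time_course`): strictly decreasing latent
  stemness across stages (defaults: 4 stages × 6 samples, levels 1.0 /
  0.7 / 0.4 / 0.1), gradient genes as above; with zero noise and zero
  latent jitter, samples within a stage are identical.
- **Graded tumors** (`simulate_graded_tumors`): latent stemness
  increases with grade (defaults: 3 grades × 20 samples, means 0.2 /
  0.5 / 0.8, overlap sd 0.1); every grade except the first and last has
  its latent noise inflated (default ×2), so mid-grade distributions
  overlap their neighbours more than the extremes do.

All generators are pure functions of (config, seed).

The latent model is deliberately minimal: stemness is one-dimensional
and acts linearly on gradient genes — exactly the regime in which PC1 is
the right summary. Passing the recovery tests therefore shows the
pipeline is correct *under its own model assumptions*; it does not show
robustness to what real microarray data adds: probe- and batch-level
artifacts, tissue-specific covariance structure (a strong PC2 in real
compendia), nonlinear saturation, or anchor-label noise. None of these
are modeled.

## Numerical choices and degenerate inputs

- Window counts are computed by cumulative sums over the 0/1 anchor
  vector in sorted order; exact integer arithmetic, no floating-point
  windowing.
- Binomial and hypergeometric tails use scipy's survival functions,
  verified against direct PMF summation to 1e-12 absolute for all
  n ≤ 60.
- The PC1 decomposition uses SVD of the centered block (never forming
  the covariance explicitly), which is stable for both tall and wide
  signature blocks; an identically-zero centered block is an error.
- Variance-explained fractions are s²ᵢ/Σs²ᵢ over all singular values:
  non-increasing, summing to 1.
- `fir_score` and `rank_genes` errors: W outside [1, S], zero anchors,
  zero non-anchors, phenotype samples missing from the matrix.
- Two-sample t statistics use pooled variance by default (Welch by
  flag); genes with zero variance in both groups get t = 0 so
  percentiles remain defined.
- Percentiles (window score and |t|) are inclusive — the fraction of
  genes with a statistic ≤ the target gene's — so identical genes share
  a percentile and 100 means "no gene is stronger".

## Problem sizes

The test and acceptance workloads run at desk scale, chosen to hold
Monte-Carlo noise well below the asserted margins: landscapes of
500–2,000 genes × 160–400 samples, 20-seed replicate sets for recovery
and calibration checks, 100 planted gene instances for the
window-vs-t-test discordance rate, and R = 200 random sets for the
correlation null. The full suite completes in well under a minute.

## Known limitations

- Missing values are unsupported; inputs must be complete matrices.
- The discovery statistic needs a large, diverse sample collection to be
  well-powered; on small series (tens of samples) the null distribution
  of window scores is coarse and background genes saturate low scores.
- Rank normalization is only approximately a shared monotone map across
  samples (each sample's map carries quantization noise of order
  1/√G), so band structure narrower than that noise is degraded at
  small gene counts; recovery tests account for this by using
  compendium-scale gene counts.
- The ANOVA sweep optimizes separation of the *given* groups; with
  strongly informative planted genes the F(n) curve can be flat or
  monotone over wide ranges of n, and the argmax is then not a sharp
  model-selection rule.
- No false-discovery-rate machinery for the binomial p-values; they are
  descriptive only.
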