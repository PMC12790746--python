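# Methods

## The generative model

The synthetic-data module emulates bulk RNA-seq of an autosomally isogenic
cell-line panel whose members differ only in sex-chromosome complement
(XX, XY, XXY, XO). Its purpose is to encode, explicitly and testably, the
X-dosage-compensation biology the analysis modules are meant to detect:

* **X-upregulation.** The single active X produces `u`-fold output per
  copy; `u = 2` means X expression from one active copy matches a diploid
  autosomal pair, so the X:A ratio is 1.0. XCI-subject genes therefore have
  effective dose `d = u` in every genotype — the number of *silent* copies
  is irrelevant as long as inactivation is intact.
* **Escape from X inactivation.** Escapees additionally express a fraction
  `e` from each inactive X: `d = u (1 + e·max(n_X − 1, 0))`. With the
  defaults (u = 2, e = 0.3) an escapee is 1.3-fold up in XX/XXY relative to
  XY/XO — log2FC ≈ 0.38, deliberately *below* the 0.5 DE threshold, so
  escape contributes expression signal without inflating the XX–XY DE
  count, matching the modest male–female differences the analysis should
  recover.
* **An XIST-like marker** expressed (d = 2) exactly when an intact inactive
  X exists; it makes genotype/erosion sanity checks possible.
* **Y genes**: `d = n_Y`; exactly zero counts in XX and XO by default. An
  optional `bleed_fraction` adds cross-mapping background (default 0; real
  pipelines handle this upstream with a Y-masked reference for Y-less
  genotypes).
* **Erosion** (optional, probability per XX/XXY line): the XIST-like gene
  switches off and XCI-subject genes reactivate fully
  (`d = u(1 + n_inactive)`); in the allele model their silent-copy allele
  fraction jumps to 0.5. Intent: erosion in culture is approximately
  complete reactivation of the affected genes; partial erosion is not
  modeled.
* **Trans effects on autosomes.** A fixed subset of autosomal targets
  responds to the regulator dose `r = n_Y + max(n_X − 1, 0)` — the count of
  "extra" sex chromosomes (inactive X plus Y): XX 1, XY 1, XXY 2, XO 0 —
  as `d = 2·2^(β_g (1 − r))` with `|β_g|` half-normal (scale 1) and random
  sign. This is a *generator design construct*, not a mechanistic claim: it
  is the simplest dose-response that makes XX and XY transcriptomes
  near-identical (equal r) while X-monosomy (r = 0), which removes both
  dosage-sensitive regulators, deregulates autosomes strongly. Note its
  deliberate symmetry: XXY (r = 2) deviates from XY by the same per-gene
  magnitude |β| as XO does, only in the opposite direction.

Counts are negative binomial in the standard RNA-seq parameterization,
`var = m + α m²`, drawn as a gamma–Poisson mixture with mean
`m_gj = s_j μ_g d_gj / 2` (library size factor s_j, log-normal baseline
μ_g). `α → 0` degrades to Poisson; mean 0 gives count 0 exactly. Allele
counts at one informative SNP per X gene are Binomial(coverage, p) with
Poisson coverage and p = sequencing error for monoallelic genes,
`e/(1 + e)` for escapees.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| n_autosomal / n_x_xci / n_x_escape / n_y | 12000 / 500 / 100 / 25 | desk-scale transcriptome with realistic X:autosome gene-count proportions; ~25 expressed Y genes |
| u (X-upregulation) | 2.0 | full dosage compensation |
| e (escape fraction) | 0.3 | partial escapee output; keeps XX–XY log2FC of escapees below the DE threshold |
| n_trans_targets | 1500 (12.5% of autosomes) | sized so X-monosomy deregulates hundreds-to-thousands of genes of which ≥95% are autosomal, the architecture the analysis should reproduce; ~2.4k of 17.4k autosomal genes respond in the corresponding human data |
| beta_scale | 1.0 | typical trans effect ~0.8 log2 units; roughly half the targets exceed the 0.5 threshold |
| baseline_log_mean / sd | 4.0 / 1.5 (natural log) | median ≈ 55 counts, long right tail, as in moderately sequenced bulk libraries |
| dispersion α | 0.05 | typical bulk biological replicates |
| replicates_per_genotype | 3 | triplicate lines per genotype |
| library_size_factors | all 1.0 | equal depth unless specified |
| erosion_probability | 0.0 | the panel being emulated was screened to exclude eroded lines |

All draws flow from one integer seed through four fixed substreams
(annotation/baselines, counts, allele counts, sample-sheet erosion flags),
so outputs are bitwise reproducible and independent of call order.

### What the generator does *not* emulate

Read-level artifacts (mapping bias, multi-mapping, GC effects), isoforms,
batch effects beyond a scalar library size, correlated genes, partial
erosion, and cross-individual autosomal variation. Consequently, passing
tests demonstrate that the statistics recover the encoded dosage model
under NB sampling noise — not robustness to alignment artifacts or
confounded designs.

## Analysis pipeline

**Filtering.** Genes with total count across all samples < 10 are removed
(boundary inclusive).

**Normalization** is median-of-ratios: `s_j = median_g count_gj / geomean_g`
over genes with a positive geometric mean. It is invariant to a global
rescaling of all counts (the factor cancels in the ratios) and equivariant
to per-sample scaling — both properties are tested.

**Transform.** `t = log2(count/s_j + 1)`. This stands in for a
variance-stabilizing transform; since the X:A statistic uses *medians*, any
monotone transform with the same large-count behavior gives essentially the
same ratio, which is why this simple closed form is acceptable. Divergence
from a fitted VST matters most for low counts, where medians rarely sit.

**X:A ratio** = (median over X-linked genes) / (median over autosomal
genes) of the transformed values, per sample; Y genes excluded from both
strata; even-count medians are midpoints of the central pair. Reported per
sample and aggregated per genotype (mean ± sd) — both granularities,
because pooling conventions differ across studies.

**Variable genes / structure.** Genes ranked by unbiased (n−1) sample
variance, ties broken by gene id; PCA (per-gene centering) with a fixed
orientation (each component's largest-|loading| gene positive) so runs are
comparable; Pearson correlation across samples on the same gene set.

**Differential expression.** Per gene, a two-group NB model with known
size-factor offsets:

* *Dispersion*: within-group method-of-moments on normalized counts,
  `α̂ = max((pooled within-group variance − mean)/mean², 10⁻⁸)`, blended
  with the trend `α_T` (median of positive α̂) on the log scale with weight
  `w = (n − 2)/(n + 4)` on the gene-wise value. Before blending, gene-wise
  values are floored at `0.75·α_T`: with 3 replicates per group roughly
  half the moment estimates hit zero, and blending their logs directly
  would assign those genes dispersions orders of magnitude below the trend,
  inflating the Wald type-I error (measured: 0.09 → 0.06 at nominal 0.05
  with the floor).
* *Test*: Fisher scoring for the two group means on the log scale with a
  N(0, 4²) prior (log2 units) on the fold change — the penalty keeps
  estimates finite when a group is all zeros — ≤50 iterations, gradient
  tolerance 10⁻⁸; non-converged or all-zero genes are flagged untested and
  excluded from the BH family. Standard errors come from the unpenalized
  information, `Var(ln μ̂ᵢ) = 1/Σ_j m_ij/(1 + α m_ij)`; `z = log2FC/SE`,
  two-sided normal p, BH adjustment.
* *Shrinkage*: global normal-normal empirical Bayes,
  `τ² = max(0, var(LFC) − mean(SE²))`, shrunk = raw·τ²/(τ² + SE²). This is
  a transparent, closed-form stand-in for adaptive mixture shrinkage; its
  known weakness is that when true effects are sparse, τ² is small and
  *strong* effects are over-shrunk (an adaptive prior would leave them
  nearly untouched).
* *DE call*: `padj ≤ 0.05` and `|log2FC| ≥ 0.5`, both boundaries
  inclusive, the magnitude threshold applied to the **penalized-MLE**
  (raw) LFC. Applying it to the globally shrunk LFC would, for the reason
  above, suppress exactly the sparse strong trans effects the analysis
  exists to count; the shrunk estimate is reported alongside for effect
  size interpretation. The fold-change threshold is interpreted as
  |log2FC| (both directions), consistent with symmetric volcano-plot
  cutoffs.

**Overlap significance.** The universe is the post-filter gene set. Each
resampling iteration draws |A| and |B| genes uniformly without replacement
and records the intersection; the observed overlap k is scored as
`p = Φ̄((k − ½ − mean)/sd)` against the resampled moments. The half-count
continuity correction makes the normal tail approximate the *discrete*
upper tail P(X ≥ k); without it the normal p deviates from the exact
hypergeometric value by about half a probability mass unit, which is
visible at desk scale. Because the null intersection is marginally
Hypergeometric(N, |A|, |B|), the exact tail is always computed alongside
(`p_hyper`) and serves as the analytic oracle; the empirical count p,
`(#{null ≥ k} + 1)/(n + 1)`, is reported as a conservative floor. Normal
tails below the smallest positive double are floored and flagged as
underflow — an "adjusted p = 0" is an artifact of the normal tail, and the
exact value is preferable. BH correction is applied across whatever pairs
are tested in one invocation.

**XCI calling.** A SNP is informative at coverage ≥ 10 (inclusive). With
major-allele fraction f = max(A,B)/(A+B): f ≥ 0.95 monoallelic, f ≤ 0.80
biallelic, otherwise ambiguous. The 0.95/0.80 thresholds are package
choices (qualitative descriptions like "all reads from one X" motivate but
do not pin them down); both are configurable and an exact binomial test
against f = 0.5 can be reported alongside. Multiple SNPs per gene are
classified individually (the pipeline has no phasing) and combined by
majority vote, ties → ambiguous. A line is flagged as eroded when >20% of
its informative XCI-subject genes are biallelic.

## Numerical and design choices

* Median convention: midpoint of central order statistics.
* Percentages in summaries: nearest integer, half away from zero.
* True log2 fold changes involving a zero dose are stored as signed
  infinities and excluded from recovery metrics (estimator comparison is
  undefined there).
* Infinite/NaN statistics only ever appear on genes flagged `tested=False`.
* The permutation loop draws subsets via random-key argpartition in
  memory-bounded chunks — identical in distribution to sequential
  without-replacement draws, but vectorized.
* Problem sizes in the test-suite simulations (e.g. 2,000 genes × 3 vs 3 ×
  10 seeds for calibration; the 12.6k-gene default panel for end-to-end
  patterns; 20,000 draws per overlap grid point) were chosen as the
  smallest sizes at which the Monte-Carlo tolerances quoted in the tests
  are meaningful.

## Known limitations

* The Wald test with plug-in dispersion is mildly anti-conservative at
  2–3 replicates per group (measured type-I ≈ 0.06 at nominal 0.05); for
  confirmatory analyses at that scale an exact or resampling test is
  advisable.
* The global-normal LFC shrinkage is not adaptive; its shrunk values are
  useful for ranking but should not be thresholded when effects are sparse
  (see above).
* X:A ratios inherit a small upward bias from the low-expression filter
  (the X stratum, at half dose, is truncated slightly more than the
  autosomes when baseline spread is wide).
* The trans-effect construct is symmetric in the regulator dose; it
  reproduces the XX ≈ XY ≪ XO architecture but places XXY farther from the
  XX/XY pair in expression space than real panels, where trans responses
  to a *surplus* regulator dose are weaker than to its complete loss.
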