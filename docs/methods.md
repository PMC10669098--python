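# Methods

This note records the models behind each stage of the pipeline, the defaults
that matter, the synthetic-data design, and the numerical decisions taken
where the underlying procedure left room.

## Preprocessing

Quality control removes genes expressed by fewer than `min_cells_per_gene`
(50) cells, then cells with fewer than 200 or more than 6000 expressed genes
or with more than 20% of counts on mitochondrial genes (symbol prefix
`MT-`, configurable — there is no universal rule for identifying
mitochondrial genes from symbols). The gene filter is computed before the
cell filter in a single pass; the pass is a fixed point whenever removing
cells does not push additional genes below the coverage threshold, which
holds for data that is not borderline on both rules at once.

Normalization is log(1 + scale · count / cell total) with scale 10⁴
(single-cell) or 10⁶ (bulk/pseudo-bulk, CPM-like). All-zero observations are
left at zero with a warning rather than producing NaNs.

Marker detection tests each subtype against all other cells per gene with a
two-sided Wilcoxon rank-sum (mid-ranks, tie-corrected normal approximation —
exact enumeration is pointless at single-cell group sizes). The log fold
change is ln(mean expm1(norm)+1 in-cluster) − ln(... out-of-cluster), the
convention of the major single-cell toolkits. "Fold change > 1" is ambiguous
between the natural and log scale, so the threshold is a knob (`min_lfc`,
default 0 = any positive enrichment). Both Benjamini–Hochberg and Bonferroni
adjustments are computed per cluster and reported; filtering uses the
configured one (BH by default). The ≥50%-expressing filter is applied after
testing.

## Module discovery

Relative abundance divides subtype cell counts by parent-major-type counts
per sample; a sample lacking the parent type yields a missing value, never a
zero (a zero would be a claim about composition the data cannot support).
Pairs are correlated across tumor samples by default, pairwise-complete with
a 10-sample minimum. Clustering is agglomerative with average linkage on
1 − r over the full correlation matrix; the module count maximizes the mean
silhouette over k ∈ [2, min(10, n−1)] (overridable), with ties resolved
toward more, smaller modules. The procedure's r > 0.3 / FDR < 0.05 edge
thresholds are retained as a post-hoc quality flag ("weakly assigned"
subtypes lack any such within-module edge) rather than as a hard pre-filter:
pre-thresholding the matrix would make the clustering depend on the display
convention. Tie-breaking everywhere is lexicographic in subtype name, so
module assignment is invariant to input order.

## subTME scoring

The specificity score of gene g for subtype subj is S(g) = 1 − Q/P. The
"highly expressing" threshold is the lower quartile (linear interpolation
between order statistics) of the gene's nonzero normalized values within the
subtype, and the same threshold is applied to outside cells — a
per-population threshold would make P and Q incommensurable. The quartile
direction (lower) is the permissive reading; the estimator is configurable.
Genes with no nonzero value in the subtype are ineligible and excluded
(never scored −∞ or NaN); negative scores are kept in diagnostics tables but
never selected at the 0.7 cutoff. Ssubj averages the selected genes'
scores; SsubTME averages Ssubj · Psubj over the module's subtypes per
sample, skipping subtypes with missing abundance (n reduced and recorded).
Psubj is computed per sample, not pooled.

For bulk samples each subtype signature is its top-10 markers by log fold
change and the per-sample module score is the mean of per-signature ssGSEA
scores; a mean-z-score alternative is available (`method="mean_z"`).

## ssGSEA

Genes are ranked by expression descending, ties broken by gene name for
determinism. With the top gene assigned rank N, in-set positions carry
weight rank^α (α = 0.25); the statistic is the sum over positions of the
normalized weighted in-set ECDF minus the uniform out-set ECDF. Range
normalization is cohort-level, as in the method's reference implementation:
`ssgsea_matrix` divides the whole gene-set × sample score matrix by its
range, a single global rescale that preserves every ordering. (Normalizing
each profile by the range of its own running statistic would destroy
between-sample comparability, which is the entire use of the score here.)
Note that with α > 0 the statistic has a positive expectation under random
gene sets — in-set weights decay along the ranking — so scores are
comparative, not zero-centered.

## Cell–cell interaction inference

The interaction score is (ligand summary + receptor summary) / 2, each
summary the mean normalized expression in the sending/receiving subtype,
with minimum-over-components for complexes and a 10% expressing-cell gate
per component (all three constants configurable). The null shuffles subtype
labels among participating cells; p = (1 + #{null ≥ observed}) / (1 + n_perm)
(add-one, so p is never 0), with observed score 0 assigned p = 1. BH
q-values span all pair × subtype-pair tests. Counting reports the directed
matrix of p < 0.05 interactions and its symmetrized total. Subsampling is
uniform without replacement per subtype (default 300 cells, deterministic
given the seed). Specificity retains each subtype's 100 top-scoring
interactions and ranks retained pairs by the coefficient of variation
(population SD / mean, zeros included) of their score vector across all
subtype pairs; a pair scoring s in exactly one of m subtype pairs has
cv = √(m−1). Pairs with mean score 0 have no defined cv and are dropped
with a warning.

## Risk modeling

The univariate screen fits one Cox proportional-hazards model per gene
(partial likelihood, Efron tie handling — better than Breslow when event
times look discrete); genes failing to converge or constant across samples
are dropped with a warning, and the screen requires at least 10 events.
Selected genes (p < 0.05) define the linear score risk = Σ Exp(mRNA) · coef
with no intercept; expression enters as supplied (the normalized layer by
convention — the formula applies coefficients to expression directly, and
the pipeline records which layer was used rather than silently z-scoring).
Median-split ties go to the low group. Kaplan–Meier curves use the
product-limit estimator with a two-group log-rank test. Time-dependent ROC
is the cumulative-case / dynamic-control AUC with inverse-probability-of-
censoring weights from the KM estimate of the censoring distribution;
horizons at or beyond the last follow-up, or before the first event, are
reported as missing rather than extrapolated.

## Spatial co-localization

Spots are a plain observation matrix (no platform-specific binning or
registration). Two signatures are scored per spot with ssGSEA on normalized
spot expression (normalization applied by default and recorded), and
co-localization is the Spearman correlation of the two score vectors across
spots (≥10 spots; constant vectors are an error). Gene-pair co-expression
flags a spot when both normalized values exceed 0 — the data give no
principled threshold, and zero is the only scale-free choice.

## Synthetic data

The generator produces the statistical structure the analysis assumes, with
analytic ground truth:

- **Composition.** Per sample and major type, subtype proportions are
  Dirichlet; each planted module has a per-sample latent factor f ~ N(0,1)
  entering the log-concentration as module_strength · f, plus tumor_shift
  in tumor samples. Cell counts are multinomial given proportions. Defaults:
  40 samples (half tumor), 3 major types × 4 subtypes with two planted
  modules of 6 subtypes, module_strength 2 (strong enough that
  within-module abundance correlations clear the r > 0.3 edge threshold),
  tumor_shift 2.0 on module M1 (clearly enriched, yet both modules remain
  observable in tumor samples, which discovery requires). A module that is
  essentially tumor-exclusive — the strongly enriched pattern — corresponds
  to shifts around 5; at such shifts the saturated tumor compositions no
  longer carry the latent-factor signal, so tissue enrichment and module
  recoverability trade off, and the enrichment tests plant the strong-shift
  scenario explicitly.
- **Expression.** Marker counts are zero-truncated negative binomial
  (mean 2, dispersion 2) gated by Bernoulli expressing indicators: p_in
  (0.85) inside the subtype, p_out (0.05) outside. Truncation makes the
  empirical expressing fraction equal p_in in expectation, so P, Q and S
  have analytic targets (S ≈ 1 − p_out/p_in at large n). Background and
  mitochondrial-tagged genes are expressed in 90% of cells; planted
  ligand–receptor genes follow the background distribution with the fold
  applied in the sender/receiver subtype, so specific pairs score among the
  high scorers, as the top-100-then-CV procedure presumes.
- **Survival.** Event times are exponential with hazard
  baseline · exp(Σ β z(logCPM)); censoring is independent Uniform(0, c_max)
  with c_max solved numerically for the requested censored fraction.
  Exponential times give closed-form sanity checks and clean Cox recovery.
- **Spatial.** Spot expression mixes signature profiles with spatially
  smooth weight fields (Gaussian-filtered noise, kernel width 1 spot,
  min–max scaled) on a 30×30 grid; co-localized signatures share a field.
  Poisson counts with amplitude 8 over a 0.5 base rate, against 1000
  background genes so that rank competition between signatures does not
  induce spurious anti-correlation. At these defaults the measured
  spot-score Spearman correlation is ≈0.68 for a shared field and ≈0.10 in
  magnitude for independent fields.

What the generator does **not** emulate: transcriptome-wide gene–gene
correlation structure, doublets, ambient RNA, batch effects, or realistic
library-size variation. Passing recovery tests therefore demonstrates that
the estimators are correct and calibrated under the assumed generative
model, not that they are robust to the full messiness of real scRNA-seq.

## Problem sizes in the test suite

The end-to-end suites run 20-seed replicates at deliberately desk-scale
sizes — 40-sample cohorts of ~16k cells for module recovery, ~2800-cell
cohorts for interaction power, n = 500 samples for Cox recovery, 500 null
pairs × 1000 permutations for calibration — chosen as the smallest designs
at which the planted effects are identifiable with margin.

## Known limitations

- Cell clustering and annotation are inputs, not outputs: the pipeline
  starts from labeled subtypes.
- The silhouette rule for the module count is this package's choice; the
  procedure it reproduces fixed module counts by inspection.
- The CCI score is a deliberately simple mean-of-means statistic; it ranks
  and calibrates planted effects but does not model pathway structure.
- Bulk scoring assumes marker signatures transfer from the single-cell
  cohort to bulk profiles of the same tissue; no cross-platform correction
  is attempted.
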