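# Methods

## Measurement model

All computation rests on one assumption: a marker gene is expressed at a
fixed but unknown number of copies per cell of its cell type, and at a
negligible level elsewhere. On the log2 scale the gene's bulk expression is
then the cell type's log2 abundance plus a gene-specific constant plus
measurement noise. Two consequences drive the package:

1. **Scores.** The mean log2 expression of a cell type's markers equals its
   log2 abundance up to an unknown constant. Scores therefore compare
   abundance *across samples* (one unit = one doubling) but not across cell
   types; cross-type statements need calibration against a sample of known
   composition (`calibrate_absolute`, count = ref_count · 2^Δscore) or
   anchoring to another score (`normalize_to_cell_type`), which also removes
   any per-sample normalization constant.
2. **QC.** Two genes that are both true markers of the same cell type are
   perfectly correlated with slope 1 in log2 space. The pairwise similarity
   statistic 2·cov/(var+var) (unbiased n−1 variances) equals Pearson's r
   times 2·s_x·s_y/(s_x²+s_y²), so it is 1 only for unit-slope perfect
   correlation and satisfies |similarity| ≤ |r| with equality iff the
   variances agree. For an exact line of slope b it equals 2b/(1+b²).

## Marker selection procedure

Per dataset, all-pairs similarity (and Pearson) matrices are computed over
the candidate genes present; genes with zero variance are dropped with a
warning, absent genes recorded. Across datasets, each pair is averaged with
equal dataset weight over the datasets in which both genes appear, keeping
per-pair contribution counts.

Selection then proceeds deterministically:

1. Average-linkage hierarchical clustering of 1 − similarity; every
   internal tree node is a candidate cluster.
2. The largest cluster whose mean off-diagonal similarity exceeds the
   *high* threshold (default 0.6) is selected; if none qualifies, the
   *moderate* threshold (0.4) is tried; otherwise the selection is empty.
   Ties on size break lexicographically by gene names.
3. **Slope-outlier pruning.** Within the chosen cluster, a gene whose mean
   Pearson r to the rest exceeds its mean similarity by more than
   `slope_gap` (default 0.1, with r above the moderate threshold) is
   removed, largest gap first, recomputing after each removal; a final pair
   is never split because the outlier is unidentifiable. The gap
   r − similarity = r·(1 − 2ρ/(1+ρ²)) for SD ratio ρ is exactly the
   variance-mismatch penalty, so it isolates genes that are co-regulated
   with the cluster but rise at the wrong rate (an SD ratio of 2 yields a
   gap of ≈ 0.2·r, far above the 0.1 default; ordinary measurement noise
   moves r and similarity together and leaves the gap near 0). This step
   is what mechanizes the otherwise manual judgement "highly correlated but
   slope ≠ 1 ⇒ not both markers"; it runs only when correlation matrices
   are available and is reported with the reason code
   `non_unit_slope_cluster`.
4. Domain-knowledge `exclusions` are removed last (`domain_exclusion`),
   reflecting that co-expression evidence alone cannot veto prior biology.

Cell types with exactly one candidate are retained as
`single_gene_unvalidated`: with no partner gene, co-expression can neither
support nor refute them. A final quality pass discards cell types whose
selected markers average below `discard_threshold` (default 0.4) and
attaches the mean log2 expression of the selected genes as a diagnostic —
weak marker behaviour concentrates at low expression, where measurement
error dominates.

## Composite scores

* **Total TILs** is the mean of all cell scores whose Pearson correlation
  with CD45 (PTPRC) log2 expression exceeds 0.6 (Spearman available). The
  inclusion set is recomputed per dataset by default because it genuinely
  differs between cohorts; a frozen-list mode reproduces a previously
  derived set.
* **Enrichment scores** are residuals of each cell score OLS-regressed
  (with intercept) on Total TILs, pooled over whatever samples are
  supplied: abundance relative to the expectation at that infiltrate level,
  with residual mean 0 by construction.
* **Baseline-relative scores** subtract each score's mean over a named
  baseline group (e.g. treatment-naive patients), giving log2 fold changes
  from the average baseline sample.

## Normalization

`reference_normalize` divides each sample by the geometric mean of its
reference genes and rescales by the grand geometric mean of those factors,
so output stays in count space and the operation is idempotent. Reference
genes are chosen by the geNorm stability measure: M_j is the mean, over
partner genes k, of the SD across samples of log2(x_j/x_k); the least
stable gene is removed iteratively down to `min_genes` (default 3), and the
full exclusion trajectory is reported so callers can cut anywhere. M is
invariant to per-sample scaling, which is the property that makes it safe
before normalization. Counts are log2-transformed with a configurable
pseudocount (default 1, recorded in metadata) so zero counts map to zero.

## Reproducibility and concordance

Replicate cell scores are decomposed by a linear mixed model with a random
intercept per sample, fitted by REML (statsmodels MixedLM, Powell
optimizer — converges the profiled objective to ~1e-9 relative, so
balanced-design estimates match the one-way ANOVA closed form). The noise
proportion is residual/(residual+between); negative between-sample
estimates are truncated at 0 and flagged, and the all-identical degenerate
case is defined as noise proportion 0. Cross-platform concordance reports
Pearson r, the least-squares slope (near-unit slopes mean fold changes
transfer between platforms), and RMSE after mean-centering each platform
separately, since platforms report on different scales.

## Synthetic data

The generator draws per-sample log2 abundances for each cell type from a
normal distribution (default mean 5, SD 1 — about a 16-fold 2-SD range,
typical of infiltrate variation in solid tumors), optionally sharing a
latent "total infiltrate" factor (default loading 0.7, giving pairwise
abundance correlations near 0.5, matching the strong co-movement of immune
populations in real tumors). Genes are pure markers (log2(copies/cell) +
abundance + N(0, σ), default σ = 0.1), multi-cell contaminants (linear
contributions summed before logging), non-unit-slope genes (γ·abundance +
const + noise), or independent noise genes. The canned four-gene scenario
(`four_gene_scenario`, n = 500, documented seed) instantiates the archetypes
that motivate the QC procedure.

What the generator does **not** emulate: sequencing-depth/count noise
(values are already normalized log2), expression-dependent noise (available
as an option but off by default), batch effects, tumor-intrinsic expression
of immune genes, and cell-state variation in per-cell expression. Passing
recovery tests therefore shows the statistics behave as designed under the
measurement model, not that any particular gene is a valid marker in real
tumors.

## Numerical choices and problem sizes

* Log base 2 throughout; the doubling interpretation depends on it.
* Gene symbols are upper-cased with a small alias table (PTRPC → PTPRC,
  FAM30A → KIAA0125).
* Similarity requires n ≥ 3 and positive variances; the pairwise operation
  errors on degenerate genes while the matrix operation filters them.
* Negative similarities are kept (never absolute-valued); they simply do
  not survive thresholds.
* Monte-Carlo checks use n = 500 samples for marker recovery (100 seeds)
  and 12 samples × 3 replicates for variance-component recovery (200
  seeds), sizes at which the estimators' sampling noise is small relative
  to the asserted tolerances while the full suite runs in well under a
  minute.

## Known limitations

* A contaminant gene expressed equally by two independent cell types has
  similarity ≈ 0.65 to that cell type's pure markers at abundance SD 1 —
  *above* the 0.6 acceptance threshold — and is neither low-similarity nor
  a slope outlier, so co-expression QC alone does not reject it. This is
  intrinsic to the statistic and is why the selection interface carries
  domain-knowledge exclusions.
* Single-gene cell types (CD45, Th1, Treg) are unvalidated by construction.
* Scores may track abundance × activity rather than pure abundance; the
  data cannot distinguish these.
* Enrichment regressions pool all supplied samples; per-cohort fits can be
  obtained by fitting cohorts separately.
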