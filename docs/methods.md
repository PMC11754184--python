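# Methods

## Model and pipeline

The package implements a multi-cohort diagnostic-signature workflow for
already-normalized log2 expression matrices (e.g. gcRMA output; raw
array processing is out of scope). The stages are:

1. **Ingestion** (`metasig.io`). Gene symbols are uppercased for
   cross-platform matching; duplicate symbols keep the row with the
   highest mean expression (the usual probe-collapse convention, and
   deterministic); gene rows with any missing value are dropped rather
   than imputed, because the meta-score needs a complete value per
   signature gene per sample. Class labels are mapped through an
   explicit alias table (tumor/cancer/PDAC → case, normal/healthy/
   control → control) since public series label heterogeneously. Each
   labeled cohort must keep ≥ 2 case and ≥ 2 control samples. The
   default pipeline restricts all cohorts to their shared gene
   universe.

2. **Effect sizes and pooling** (`metasig.meta`). Hedges' g with the
   small-sample correction J, its standard large-sample variance, and a
   two-sided p-value from the normal approximation z = g/√v (standard
   for meta-analysis of standardized mean differences; exact t adds
   nothing at cohort sizes of tens of samples). Genes with zero pooled
   within-group variance cannot be standardized and are excluded per
   cohort; pooling then runs over the cohorts where a gene was
   estimable, so k may vary by gene. DerSimonian–Laird is the only τ²
   estimator offered (REML/Paule–Mandel are non-goals). Fisher's method
   combines the per-cohort **two-sided** p-values, with direction taken
   from the sign of the pooled effect; the one-sided up/down split used
   by some frameworks is a defensible alternative but is not what the
   formulas here implement. p-values are floored at 1e-300 before logs.
   FDR is Benjamini–Hochberg over all genes' Fisher p-values.
   Candidates pass |pooled g| > `es_min` (default 2, applied to the
   pooled estimate, not per dataset) and q < `fdr_max` (default 0.01).

3. **Signature search** (`metasig.search`). The meta-score is
   mean(up) − mean(down) of log2 expression; an empty or fully-missing
   side contributes 0, and missing genes are dropped from their side's
   mean. Cohort performance is the midrank (Mann–Whitney) AUC — ties
   get half credit — and the search objective is the Σn_d·AUC_d/Σn_d
   weighted mean with n_d the cohort's total sample count. Forward
   search accepts an addition only if the objective improves by more
   than `forward_threshold` (default 0: strict improvement, the most
   conservative parameter-free reading of "a predefined threshold");
   backward search accepts a removal if the loss is at most
   `backward_threshold` (default 0) and never goes below one gene. The
   phases run once each, forward then backward. Ties are broken
   deterministically: additions prefer the larger |pooled effect| then
   the lexicographically earlier symbol; removals prefer dropping the
   *smaller* |pooled effect| (so strong differential genes are
   retained) then the earlier symbol. Candidates are only ever used in
   the direction assigned by the differential-expression filter. Scores
   are not re-standardized per dataset: AUC is rank-invariant within a
   dataset, so monotone per-dataset transforms cannot change any
   reported quantity.

4. **Evaluation** (`metasig.evaluate`). ROC curves come from a
   threshold sweep over unique scores; their trapezoidal area equals
   the midrank AUC exactly, ties included. AUC intervals use the DeLong
   placement-value variance, a normal interval on the logit scale,
   back-transformed and clipped; a degenerate AUC of 0 or 1 gets a
   one-sided interval via a variance floor (1e-8) and the point
   estimate clamped to [0.005, 0.995] for the transform only. The
   summary AUC pools per-dataset logit-AUCs (same clamp) by
   DerSimonian–Laird with Hanley–McNeil within-dataset variances
   propagated by the delta method. No canonical summary-ROC method
   exists for this design; this choice reuses the package's own pooling
   machinery, is well-defined down to k = 1, and should be treated as
   one reasonable convention among several. 95% is the default level
   throughout.

5. **qPCR** (`metasig.qpcr`). Technical replicates collapse to a mean
   Ct; replicate SD > 0.5 cycles flags the entry out (a common bench QC
   rule; no rule is canonical). A single replicate passes (SD treated
   as 0). ΔCt = Ct_target − Ct_reference per sample; ΔΔCt centers ΔCt
   on the control-group mean per gene; relative expression is 2^−ΔΔCt
   with amplification efficiency fixed at 2 (no efficiency correction,
   single reference gene). A sample whose *reference* triplicate fails
   QC cannot be normalized and is dropped with a warning; a reference
   gene absent from the table is an error. Signature scoring applies
   the tissue meta-score to −ΔΔCt (log2 relative expression), keeping
   both data types on the same log2 scale.

## Synthetic data: what it does and does not emulate

`metasig.simulate` draws per-gene log2 baselines uniformly on [4, 12]
(the typical microarray intensity range), Gaussian within-group noise
with SD σ (default 1), and plants differential genes by shifting case
means by δ_{g,k}·σ where δ_{g,k} ~ N(±δ, τ²) per cohort — so the true
Hedges' g of a planted gene is δ by construction and parameter recovery
is exact in expectation. Defaults describe the desk-scale study used
throughout the tests: K = 6 cohorts of 20 + 20 samples, 1000 genes,
five planted up-regulated genes at δ = 2.5, τ = 0.1. A single root seed
drives per-cohort substreams keyed by (seed, dataset index), so
increasing K extends the collection without changing earlier cohorts.

The qPCR generator emulates a triplicate-well experiment with a GAPDH
reference: per-sample reference Ct ~ N(20, 0.2²), per-gene control ΔCt
baselines uniform on [2, 10] with biological spread `biological_sd`
(default 0.5 cycles — roughly the sample-to-sample variation seen in
blood targets), case ΔCt shifted by −log2FC, and technical replicate
noise `ct_noise_sd` (default 0.2 cycles).

Not emulated: probe/platform effects, batch effects, normalization
residuals, RNA-seq count noise, correlated gene modules, or
class-imbalanced and confounded cohorts. Passing tests therefore show
that the estimators and the search recover a clean planted truth under
Gaussian noise and mild heterogeneity — not that any particular
published gene panel is correct, nor how the pipeline behaves under
real-world batch structure.

## Numerical choices and degenerate inputs

- τ² is clipped at 0; k = 1 pooling returns the study unchanged with
  τ² = Q = 0.
- Fisher p-values floored at 1e-300; AUCs clamped to [0.005, 0.995]
  before logit; DeLong variance floored at 1e-8.
- All greedy-search comparisons use exact float comparison with the
  deterministic tie-break above, so identical inputs give byte-identical
  signature files (asserted end-to-end).
- BH is implemented as the classic step-up with a reverse cumulative
  minimum; q ≥ p elementwise and q is monotone in p.
- Constant genes are excluded per cohort (cannot be standardized);
  cohorts with < 2 samples in either class are rejected at assembly.

## Problem sizes

The test-suite and acceptance-script simulations use the default
desk-scale study (up to nine cohorts of 40 samples over 1000–2000
genes, 20 seeds for calibration checks), which exercises every code
path at sizes where the vectorized meta-analysis completes in seconds
while keeping Monte-Carlo noise on calibration quantities small.

## Known limitations

- The summary-AUC convention (logit + Hanley–McNeil + DL) is one of
  several reasonable definitions; absolute values near the boundary are
  compressed by the clamp (a set of perfect datasets summarizes to
  0.995, not 1.0).
- Fisher's method assumes independent cohorts; overlapping samples
  between series would invalidate the combined p.
- The normal approximation for the per-cohort p slightly understates
  tail p-values at very small n; with the ≥ 2/≥ 2 rule this only
  matters for extreme designs.
- Greedy forward/backward search is a heuristic: it is exact against a
  per-step exhaustive oracle (tested), but is not best-subset
  selection.
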