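# Methods

This note documents the models and procedures the package implements, the
choices made where a procedure is conventionally underdetermined, what the
synthetic-data generator does and does not emulate, and the problem sizes the
shipped tests and the acceptance script use.

## Virtual-array integration

A *virtual array* is a single gene × sample log2-intensity matrix compiled
from several microarray platforms restricted to their common gene set.
Integration has three steps:

1. **Probe → gene collapsing.**  Each gene's row is the per-sample **median**
   over all probes annotated to it.  The median was chosen over the mean for
   robustness to a single aberrant probe; the mean remains selectable
   (`stat="mean"`).  Probes with an empty annotation are dropped.  Probes
   annotated to several genes contribute to *every* one of them; this choice
   keeps multi-family probes informative and is logged per probe so it can be
   audited.  A gene whose probes are all missing in some sample cannot be
   represented without imputation, so the gene is excluded from that
   platform's output (logged with the reason).
2. **Gene matching.**  Matching is by **gene symbol**.  The strict
   intersection across all platforms is used; genes absent from any platform
   are dropped entirely rather than imputed.  When the intersection is empty
   the error names the pair of platforms with the smallest pairwise overlap,
   which is the pair to investigate.
3. **Assembly.**  Column concatenation in metadata order.  Assembly refuses
   to reindex: matrices must arrive restricted to the common gene list in
   identical order, and duplicate sample ids or missing metadata are errors,
   not warnings.

All intensities are assumed to be on the log2 scale throughout; raw-scale
inputs must be transformed upstream (log2(x+1)), because every downstream
statistic (additive batch model, median collapsing, fold contrasts) relies on
log-scale additivity.

## Quantile normalization

Samples are forced onto one empirical distribution: position *k* of every
sample's sorted vector is replaced by the across-sample mean of the *k*-th
order statistics.  Ties within a sample receive the mean of the quantile
values their positions span, so tied inputs stay tied.  Two numerical
consequences are worth knowing:

* For tie-free data the transform is idempotent to 1e-12 and afterwards all
  column-sorted vectors are identical (this is the definitional check the
  tests run).  With ties, the tie-averaging step means a tied column's
  distribution deviates from the common target by construction; repeated
  application then perturbs *other* columns slightly.  This is the standard
  behaviour of rank-tie averaging, not an implementation artefact.
* A constant sample is permitted (all its values map to the grand mean of the
  target distribution) but is logged, since a constant sample usually
  indicates an upstream failure.

Quantile normalization removes the *mean* of any additive batch shift but not
its gene-to-gene structure; batch correction remains necessary afterwards.

## Empirical-Bayes batch correction

The location/scale batch model: for gene *g*, sample *j* in batch *i*,

    y_gij = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_gij,  eps ~ N(0, sigma_g^2)

The parametric empirical-Bayes variant is implemented: normal prior on the
additive effects `gamma_ig ~ N(gamma_bar_i, tau2_i)` and inverse-gamma prior
on the squared scale effects `delta2_ig ~ InvGamma(lambda_i, theta_i)`, with
hyperparameters estimated across genes by method of moments.  Fitting:

1. Per-gene least squares on the design [batch indicators | covariate
   dummies]; the grand mean `alpha_g` is the batch-size-weighted mean of the
   batch coefficients; `sigma_g` is the pooled residual SD (denominator N).
2. Standardize: `s = (y − alpha − X beta) / sigma`.
3. Per batch: `gamma_hat` = gene-wise mean of `s`, `delta2_hat` = gene-wise
   variance (ddof 1); hyperparameters by moments; `gamma*`/`delta2*` from the
   conditional-posterior-mean fixed point, iterated to relative change
   < 1e-6 with a 500-iteration cap (non-convergence raises with the last
   relative change, rather than silently returning a stale iterate).
4. Correct: `y' = sigma · (s − gamma*) / sqrt(delta2*) + alpha + X beta`.

Design choices and caveats:

* **Covariate protection.**  Cell-type labels are included as a design
  covariate by default whenever present, so biological contrasts are not
  absorbed into batch terms.  A batch perfectly confounded with a covariate
  level makes the design rank-deficient; this is detected and raised with the
  confounding named, because no location/scale model can separate batch from
  biology in that layout.
* **Identifiability.**  `gamma*` and `delta2*` live on the standardized
  scale.  Comparisons against generative truth therefore rescale by
  `sigma` (`sigma·gamma*` estimates the log2 shift) and, for scale effects,
  use the between-batch ratio `delta2*_i / delta2*_k` — the pooled
  standardization makes only relative scale effects identifiable.
* **Minimum data.**  ≥2 batches with ≥2 samples each; with one sample per
  batch the within-batch variance (ddof 1) is undefined and the model
  refuses to fit.
* **Reference anchoring.**  Every synthetic batch carries replicates of one
  fixed reference program (stand-ins for MAQC-style internal controls).  Two
  roles are exposed because the appropriate one depends on study design:
  the default fit simply includes the references as samples of their own
  covariate level; alternatively `fit_on_cell_type="reference"` estimates
  batch effects from the reference replicates alone and transfers them to all
  samples (useful when biology is unbalanced across batches).  Independently,
  `reference_anchor_check` audits any corrected (or uncorrected) array: a
  batch is flagged when its reference centroid sits further from the global
  reference centroid than 2× the pooled within-batch reference spread.  The
  multiplier is configurable; 2× flags shifts that clearly exceed replicate
  noise while tolerating the centroid error of two-replicate batches.

The implementation was cross-checked against the canonical Bioconductor
implementation (`sva::ComBat`, parametric priors, no covariates) on a small
two-batch matrix; agreement is ~1e-5, limited by the reference's looser
convergence tolerance.

## Downstream analyses

* **PCA** is run on gene-centered data with samples as observations
  (full SVD).  Sign indeterminacy is resolved deterministically: each
  component is flipped so its largest-magnitude gene loading is positive.
  Explained-variance fractions are non-increasing and sum to ≤ 1.
* **Hierarchical clustering** uses correlation distance (1 − Pearson r
  between sample profiles) with average linkage by default; Euclidean and
  complete linkage are available.  The defaults are the common choice for
  expression profiles, where profile shape matters more than level.  The
  rooted dendrogram is converted to an unrooted tree by suppressing the root
  (merging its two child edges into a trifurcation) and exported as newick.
  Correlation distance is undefined for a constant sample; the error names
  the offending sample.  A sample with zero distance to another is fine.
* **Signature subsetting** reports queried/retrieved/missing counts and the
  missing symbols; duplicates are de-duplicated with a warning.  No symbol
  alias translation is attempted — a signature must use the array's
  vocabulary.
* **Mann-Whitney comparison** is per gene, two-sided, significant at
  p < 0.01.  For group sizes ≤ 8 the exact null distribution of U is built
  by full enumeration of group assignments over midranks, which remains
  correct under ties (unlike the classical exact recursion); larger groups
  use the normal approximation with tie correction.  U is reported for the
  first group in sorted label order.
* **Marker positivity**: a gene's level is its median across samples; the
  threshold is Q3 + 1.5×IQR of the distribution of *all* per-gene medians in
  the array (array-wide, matching the idea that a positive transcript is an
  outlier against the whole transcriptome's median distribution); a gene is
  positive iff its median strictly exceeds the threshold.  Quartiles use
  linear interpolation of order statistics (position 1 + (n−1)p) — calls
  near the fence depend on this convention, so it is fixed and documented.
  Note an intrinsic property of any outlier fence: on a roughly Gaussian
  background it sits near the 99.65th percentile, so of order 0.35% of
  background genes will always be called positive.  Panel-level claims
  ("k of these 22 markers are positive") are therefore evaluated on the
  panel genes, not on the genome background.

## Phenotype scoring

* **Gating** is conjunctive threshold gating (strict >/<) over a fixed
  channel schema (PI, Hoechst-A, Hoechst-W, SSC-A, CD45, Lin, CXCR4, CD34).
  Thresholds are configuration, not learned — gates are set manually on
  cytometry plots in practice, and the synthetic channel models are built so
  fixed thresholds are essentially exact.  Conjunctive gates commute; the
  retention report depends on order, the surviving set does not.
* **Population frequencies** are fractions of a denominator gate (e.g. live
  nucleated singlets), applied on top of it, so disjoint exhaustive
  populations sum to exactly 1.
* **Density-gradient recovery**: for a population conventionally harvested
  from the interphase, loss = pellet / (interphase + pellet).  Cells lost to
  the gradient itself are not modelled; fractions conserve mass exactly.
* **Fluorescence ratios** are ratios of per-population medians (not means,
  and not per-cell ratios — with separately gated populations there is no
  cell pairing to support a per-cell definition).
* **Size comparison** returns skeletal box-plot summaries (median, Q1, Q3,
  min, max; same interpolated quartiles as the positivity caller) plus both
  Student's t and Mann-Whitney two-sided p-values.
* **FISH**: a cell is aberrant iff any probe count ≠ 2 — the definitional
  brute-force rule, applied directly; per-probe count histograms accompany
  the aberrant fraction.

## What the synthetic data emulates — and what it does not

`generate_multiplatform_study` emulates: multiple platforms measuring
overlapping but unequal gene sets with platform-specific probe multiplicity
and affine (scale/offset) transforms; distinct cell-type expression programs
(disjoint marker blocks elevated +3 log2 over a shared baseline); per-batch
additive shifts and multiplicative noise scaling exactly matching the
location/scale model; probe replicates as independent N(0, probe_sd) jitter
around the gene value; and two reference replicates per batch drawn from one
fixed reference program.  Default conditions: log2 baseline ~ N(7, 1),
marker boost +3, noise_sd 0.5, probe_sd 0.25, 2 references/batch.  The
canonical study (`default_study`) uses a 300-gene universe, three programs
(pluripotent, hematopoietic, VSEL-like), two platforms (280-gene
intersection), and a second batch with per-gene shift ~ N(2, 2) and 1.5×
noise.  The shift's gene-to-gene spread is what survives quantile
normalization and drives batch-dominated clustering in uncorrected data.

Not emulated: raw probe-level file structure and scanner artefacts, probe
sequences and cross-hybridisation, symbol aliasing between annotations,
intensity-dependent (non-affine) platform distortions, correlated gene-gene
noise, and compositional/count noise of sequencing assays.  Passing tests
therefore demonstrate that the pipeline recovers truth *under the model it
assumes* (additive batch effects on log2 scale, exchangeable Gaussian noise);
they do not certify performance on real arrays, where annotation quality and
nonlinear platform effects are the dominant risks.  The flow generator uses
well-separated Gaussian channel models, so gating recovery is limited only by
sampling noise, not by the gate-placement ambiguity of real cytometry.  The
marker-panel generator gives each background gene its own baseline
(SD 1 log2 unit around the floor) because it is this gene-to-gene spread,
not replicate noise, that sets a realistic array-wide fence.

## Problem sizes and determinism

All generators take an integer seed and are bit-reproducible; the test suite
and `scripts/acceptance.py` derive every stream from one seed.  Sizes were
chosen so the full suite runs in well under a minute of compute: parameter
recovery uses 200 genes × 50 samples/batch; the end-to-end study 280 genes ×
34 samples; gating frequencies 10⁵ events; FISH 200–2000 cells; sizes 110
cells/group.  Binomial checks use 99% intervals (z = 2.576) around the
generative fractions.

## Known limitations

* Symbol-level gene matching only; no alias resolution or probe re-mapping.
* The parametric EB priors are assumed adequate; the nonparametric variant is
  not implemented.
* Batch correction requires a complete matrix (no missing-value tolerance).
* The unrooted tree export suppresses the root but keeps the molecular-clock
  heights produced by agglomeration; branch lengths are cophenetic-height
  differences, not fitted edge lengths.
* Exact Mann-Whitney enumeration is O(C(n1+n2, n1)) per gene and is capped at
  groups of 8 for that reason.
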