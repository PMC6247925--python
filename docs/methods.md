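# Methods

## Model and procedure

methylfn re-implements functional normalization (FN) of Illumina Infinium
methylation arrays around per-sample summary objects.  The array measures,
for each CpG probe, a methylated intensity M and an unmethylated intensity
U; the methylation level is summarized as the beta value

    beta = M / (M + U + offset),        offset = 100 by default.

Arrays carry non-biological *control probes* that respond only to technical
variation.  FN's premise is that between-sample variation explained by
control probes is technical and should be removed, while unexplained
variation is (potentially) biological and must be kept.  The procedure:

1. **Per-sample summarization.**  Each sample is reduced to a QC object:
   a 42-entry control summary (mean intensity per control category), the
   empirical quantiles of its noob-corrected probe intensities on `n_q`
   evenly spaced probabilities for each of 18 subsets
   (probe class {Type I grn, Type I red, Type II} x signal {meth, unmeth}
   x chromosome group {autosomal, X, Y}), detection/bead failure sets,
   predicted sex and batch labels.  Sex chromosomes are kept in separate
   subsets so that sex differences are not normalized away.

2. **Step 1 — cross-sample quantile normalization.**  Stack the control
   summaries into a 42 x n matrix, standardize each row, and take the top k
   principal components of the sample-space SVD.  For every subset and every
   quantile index, fit

       quantile ~ 1 + PC scores + fixed effects (+ random intercepts)

   and retain `intercept + residual` as the sample's *normalized quantile*:
   the technical (PC / fixed / random) contribution is removed, the grand
   level and the unexplained deviation are kept.  Target vectors are then
   monotonized by sorting.  With k = 0 and no effects the model is empty
   and the target is the per-index cross-sample mean — classical quantile
   normalization per subset.  (This degeneracy is a deliberate contract of
   this implementation: the empty model removes all between-sample quantile
   variation.)

3. **Step 2 — per-sample finalization.**  Each sample's intensities are
   mapped through piecewise-linear interpolation from its own empirical
   quantile function to its normalized quantiles (constant extrapolation
   beyond the extreme knots), preserving ranks within subsets.  This step
   uses only the sample itself plus its targets, so samples can be
   finalized one at a time, in chunks, in any order, or on different
   servers.  All step-1 reductions iterate over samples in sorted-id order,
   which makes pooled, streaming, chunked and federated runs bit-identical.

### noob background and dye-bias correction

Observed intensity is modelled as x = s + b with signal s ~ Exp(mean θ) and
background b ~ N(μ, σ²).  μ and σ are estimated per channel from the
out-of-band intensities of Type I probes (the unused channel measures pure
background); θ by method of moments on the foreground (mean foreground − μ,
floored at 1; σ floored at 1 when degenerate).  The corrected intensity is
the posterior mean E[s | x], evaluated with a log-space Mills ratio so the
deep-background tail is stable.  Dye bias is then removed by scaling each
channel so its mean normalization-control (norm.A/T = red, norm.C/G =
green) intensity equals the geometric mean of the two channels' levels —
a symmetric, idempotent choice.

### Random effects

Random intercepts (e.g. slide) are estimated by profiled REML per
(subset, quantile index).  For a single grouping variable the generalized
least squares problem is diagonalized once by an eigendecomposition of ZZ',
and the variance ratio λ = σ²_u/σ²_e is optimized on a log-scale grid
(step 0.5, range e^-10..e^10, λ = 0 included), vectorized over all quantile
indices.  A column whose REML optimum is λ = 0 degrades gracefully to the
fixed-effect fit; thousands of small fits never abort a run.  Multiple
grouping variables use a generic Nelder–Mead path.  statsmodels MixedLM is
used as an independent oracle in the tests, never in the pipeline.

### Cross-validated choice of k

For each candidate k, samples are split into 10 folds by a seeded shuffle;
PC center/scale/loadings and regression coefficients are estimated on the
training folds only (avoiding leakage — the alternative of global loadings
is noted as an open choice), held-out samples are projected onto the
training loadings, and the fraction of their quantile variation left
unexplained is recorded per subset and averaged (a scale-free scree, so a
single bright subset cannot dominate the choice).  The selected k minimizes the mean CV residual variance, with
ties broken toward the smallest k within machine tolerance.  Two
implementation choices matter:

- the metric uses autosomal subsets only, because sex-chromosome quantile
  variation is dominated by sample sex, which control probes cannot and
  should not explain;
- the scree can be averaged over `n_repeats` independent fold splits
  (default 1), which stabilizes the argmin when the curve is nearly flat
  beyond the optimum.

## Federated protocol

Sites export their QC objects as a schema-audited bundle; a central server
runs step 1 on the pooled summaries and returns per-sample normalized
quantiles; each site finalizes locally.  Because step 1 is
sorted-order-deterministic and step 2 is per-sample, the federated result
is bit-identical to a pooled run for any partition and any processing
order.  The privacy contract is enforced structurally: the QC-object schema
has a closed field list, control summaries must have exactly 42 entries and
quantile vectors length 0 or n_q, so probe-level methylation or phenotypes
cannot ride along; the audit rejects any extra field.  Transport is out of
scope — the protocol is three file-exchange steps and can ride any channel.
Sample ids must be globally unique across sites (a duplicate id is an
error), which is what makes federated and pooled runs comparable at all.

## EWAS stage

Per-CpG ordinary least squares of beta on the variable of interest, under
four model configurations: no covariates; supplied covariates (plus
Houseman cell-count estimates when a reference is given); covariates plus
SVA surrogate variables; and a fourth slot filled by SVA with an
alternative probe-weighting scheme (association-probability weights vs
thresholded probe selection), labelled `sva.alt`.  Independent-component
surrogate analysis is out of scope; the alternative weighting preserves the
four-block output shape.  Plain OLS is the tested contract (closed-form
oracle); empirical-Bayes variance moderation is deliberately not applied.
Bonferroni and Benjamini–Hochberg columns are appended per block.

Cell composition solves min ||b − Aw||², w ≥ 0, Σw ≤ 1 on the reference's
discriminating probes (ranked by between-cell-type variance, since the
synthetic reference has one profile per type).  Nonnegative least squares
(scipy's exact active-set `nnls`) solves the interior case; if the weights
overshoot the simplex, a small exact active-set step solves the Σw = 1
face.

SVA residualizes the beta matrix on the model, takes leading right singular
vectors, and for 5 iterations reweights probes by their F-test evidence of
association with the current surrogates before re-extraction.  `n_sv="auto"`
uses a permutation test: rows of the residual matrix are permuted
independently (20 permutations), and components are kept sequentially while
their variance proportion beats the permutation distribution at alpha 0.05.

Batch association diagnostics regress PCs of the most variable probes on
each batch variable (ANOVA F, post-hoc t per level vs rest); the
normalization report shows these tables before and after normalization
(default significance threshold p < 0.01, configurable).  The
controls-as-covariates EWAS drops covariates with |r| > 0.99 against the
variable of interest, emitting a prominent CollinearityWarning — perfect
batch confounding makes such models unstable, and this is surfaced rather
than silently absorbed.

## Synthetic data generator

The generator emulates the structure FN needs, with every planted feature
recorded for recovery tests:

- **Intensities**: per-probe log-normal total intensity (median 4000,
  log-sd 0.5) split by a bimodal true beta (mixture of Beta(8,2) and
  Beta(2,8)); observed = signal + per-channel optical background (constant
  100/110 across samples, with probe-level scatter) then floored at 1.
- **Technical components**: `k_true` standard-normal scores per sample,
  with geometrically decreasing scale (`component_intensity` x 0.8^j,
  default 800 intensity units).  On assay probes the shift is
  brightness-proportional (per probe-class/signal loading), so dim probes
  never saturate at the floor and each quantile index responds linearly.
  On control probes every category carries a fixed-magnitude, random-sign
  loading (scaled to the category's intensity level); the four
  normalization-control families share one loading vector so the dye-bias
  ratio is component-free.  These two choices make the standardized control
  matrix homoscedastic with exactly `k_true` leading components — the top-k
  PCs are then a sufficient summary of the planted scores, which is what
  "recoverable planted structure" means here.
- **Batches**: slides of 12 (450k-like) or 8 (EPIC-like) samples, plates of
  8 slides; slide/plate shifts are additive on assay probes only, emulating
  batch variation that the array controls do not capture (the reason the
  random-effect extension exists).
- **Sex**: female chrY probes carry ~no signal (observed collapses to
  background); male chrX is halved.
- **SNP probes**: trimodal betas at 0.05/0.5/0.95 from Hardy–Weinberg
  genotypes (MAF uniform on 0.2–0.5).
- **Dye imbalance**: optional per-sample red-channel factor (`dye_sd`,
  default 0).  Dye imbalance leaks a sqrt(dye) scale factor through
  per-sample dye-bias correction — an extra technical component — so it is
  off by default to keep the planted technical dimension exactly `k_true`.

What the generator does **not** emulate: probe-sequence effects,
cross-hybridization, population methylation structure, realistic
correlation between neighbouring CpGs, or cell-type mixtures in the assay
samples (the cell reference is a separate synthetic object).  Passing tests
therefore demonstrate the algorithmic contracts (equivalence, recovery,
calibration), not performance on real cohorts.

## Numerical choices and defaults

| Parameter | Default | Why |
|---|---|---|
| `n_q` quantile probabilities | 500 | convention of the FN implementations this package follows; tests use 30–100 for speed |
| beta offset | 100 | standard Infinium convention |
| detection p threshold | 0.01 | standard practice |
| bead threshold | 3 | standard practice |
| outlier rule | robust z (median/MAD x 1.4826) > 3 | matches the 3-SD Gaussian rule asymptotically without masking in small cohorts |
| sample failure gates | >10% undetected or low-bead probes, sex mismatch | cohort-level review flags (ratio/dye/control outliers) are advisory, not failures |
| probe exclusion | failing in >20% of samples | meffil-style cohort rule |
| REML grid | log-lambda step 0.5 | variance-ratio resolution of ~1.3x is ample for variance removal; exactness is tested against MixedLM |
| CV folds / repeats | 10 / 1 | repeats=3 used in the recovery experiments |

Degenerate inputs: empty quantile subsets are carried as explicit empty
vectors and must be empty for all samples or none; constant control rows
get unit scale in the PCA; zero-variance REML columns fall back to OLS;
interpolation clamps beyond the extreme knots; finalized intensities are
floored at 0 (residual-based targets can dip below zero).

## Problem sizes

The test and acceptance workloads use 300–600 CpG probes, 5–40 control
probes per category, 6–100 samples, and n_q of 30–100 — sizes chosen so the
full workflow (including the 10-seed CV-recovery and random-effect
experiments) runs in a few minutes while every statistical contract is
still measurable.  The parameter-recovery experiment uses n = 100 samples,
k_true = 3, no slide/plate shifts (the experiment plants only the
components being counted), 10-fold CV averaged over 3 fold splits.

## Known limitations

- The 42 control categories are a package convention (the count is fixed,
  the list is synthetic); real-manifest ingestion must map vendor
  categories onto it, and no IDAT codec is included.
- The CV scree of real cohorts will generally keep decreasing slowly past
  the "true" dimension (real technical structure is not low-rank); argmin
  selection is exact on planted simulations but on real data the scree
  table, not the single number, is the useful output.
- Random-effect support in CV prediction uses BLUPs for levels seen in
  training and 0 otherwise; the multi-grouping REML path omits BLUPs in
  CV prediction.
- The EWAS is OLS per CpG; no variance moderation, no meta-analysis engine.
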