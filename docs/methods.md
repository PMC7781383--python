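# Methods

This note documents the models, numerical choices and limitations of the
`aptamarkers` package in the order data flows through it.

## Study design being modelled

A cohort of elderly, cognitively normal individuals is labelled
amyloid-positive or -negative by thresholding the global amyloid-PET SUVR
at 0.79. Two measurement arms feed the analysis:

* **Selection libraries.** An enriched aptamer library is applied to each
  individual's plasma for one round of selection; the surviving library is
  sequenced. Every read is `flank5 (23 nt) + random 40-mer + flank3
  (23 nt)`; a sequence's relative frequency in a sample is a surrogate for
  the abundance of whatever plasma component it binds.
* **qPCR panel.** A fixed panel of candidate aptamers is quantified per
  sample by qPCR; lower Cq means more aptamer retained, i.e. more of its
  target present.

## Synthetic-data generator

The generator exists so that every downstream stage can be tested against
known ground truth; its defaults are the study conditions above.

* **Cohort.** `n_samples = 69` (the usable set after one outlier
  exclusion), positive fraction 39/70, so 31 negative / 38 positive
  (and 31/39 at n = 70). SUVR is drawn Uniform(0.60, 0.78) for negatives
  and Uniform(0.80, 1.20) for positives — only the threshold relation
  matters downstream. Age (77.4 ± 3.1/3.7 y), sex and APOE genotype follow
  the cohort composition per class; they are metadata only and never
  modelled (the study size does not support covariate effects).
* **Amplification curves.** F(c) = baseline + plateau / (1 + e^(−k(c−c₀)))
  + N(0, σ_F), cycles 1..30 (or 35). The logistic is the standard qPCR
  shape. Defaults: baseline 100, plateau 1000 RFU, σ_F = 2 RFU, and
  k = ln 2 so the exponential phase doubles per cycle (efficiency 1.0, as
  for a well-behaved assay). Aptamer midpoints c₀ are drawn
  Uniform(19, 24): late enough that cycles 3–10 are genuinely baseline —
  the assumption the derivative-threshold Cq caller makes of real
  curves — while still crossing well before cycle 30. The first
  `n_informative = 5` panel members shift their midpoint between classes
  by `cq_shift = 2.0` cycles (direction alternating across aptamers) plus
  per-curve N(0, 0.5) jitter; the remaining aptamers are
  class-independent. True midpoints and the informative-aptamer list are
  always returned.
* **Selection reads.** A shared background pool of 200 distinct 40-mers is
  sampled uniformly; 3 additional "enriched" 40-mers carry 10× sampling
  weight in positive-class libraries (1× in negative). Reads are
  multinomial draws (10 000 per library by default), written as FASTQ with
  constant quality `I` (quality is never used). The read depth and pool
  diversity are plausible placeholders, not estimates of any real run.
* **Determinism.** Every generator is a pure function of its config
  (including the seed); identical configs give byte-identical files.

What the generator does **not** emulate: selection-round enrichment
dynamics, sequencing error (reads are exact), primer-dimer or multi-phase
qPCR artifacts, plate/batch effects, and any correlation between the NGS
and qPCR arms. Passing recovery tests therefore show the *analysis* is
correct and sensitive at the stated effect sizes, not that real plasma
data carries such signal.

## NGS extraction, counting, selection

A read is accepted iff both flanks match at their fixed positions within
`max_mismatch` substitutions (default 0 — sequencing-error tolerance is
not part of the design) and the 40-mer between them is pure A/C/G/T;
reads too short for `flank5+40+flank3` count as length rejections, all
other failures as flank rejections, so the extraction report always
partitions the input. Relative frequencies divide by the per-sample total
of extracted reads, so top-N truncation (default N = 10 000, ranked by
counts summed over all samples, ties broken lexicographically) does not
distort frequencies.

Candidate selection standardizes the relative frequencies and fits a
one-component sparse PLS-DA. The sparsity `keep_x` is chosen by
leave-one-out error over a grid, or — with `target_perfect_cv` — increased
until LOO sensitivity and specificity both reach 1.0; the achieved LOO
metrics are always reported alongside the selected sequences because this
step is known to be unstable across data realizations: different
selections emerge from different cohort draws, which is why the result
carries its own cross-validated evidence instead of promising a fixed
panel size. The procedure itself is deterministic; the `seed` argument is
kept for interface stability.

## Cq calling

Derivative = first difference d(c) = F(c) − F(c−1) (central differences
rejected for end-cycle simplicity). Threshold T = mean + k·SD of d over
cycles 3–10, with k = 6 and the *sample* SD (n−1 denominator; the choice
of denominator is a convention, documented here). The crossing search
starts at cycle 11 so the threshold is never tested inside the window that
defined it. The fractional Cq interpolates d linearly across T, making Cq
continuous in the data; an integer-cycle mode sits behind a flag. A curve
whose derivative never exceeds T is a no-call (flagged, never an
exception), including the degenerate constant-curve case (baseline
SD = 0).

Two caveats worth knowing:

* If the derivative is already above T at the window edge or is locally
  non-increasing at the crossing, interpolation is undefined and the Cq is
  pinned to the crossing cycle (flag `interp_clamped`).
* Translating a *pure* noise-free logistic shifts the baseline-window
  derivative by exactly the same exponential factor as the crossing
  region, so T co-translates and the called Cq is unchanged. Shift
  equivariance (midpoint +δ ⇒ Cq +δ) holds exactly when the baseline
  window is signal-free — the regime of real curves and of the simulator —
  and the property test constructs that regime explicitly.

Efficiency is the least-squares slope b of log10(F − baseline) over
[⌈Cq⌉, argmax d], reported as 10^b − 1 (1.0 = perfect doubling), with
baseline = mean F over cycles 3–10 and non-positive points excluded; a
log-linear fit is the standard exponential-phase model (a raw-slope mode
sits behind a flag). Values outside [0, 1.1] trigger a warning.
Efficiency is a QC output only; the classifier consumes Cq values and
ratios exclusively.

## Feature engineering

For p aptamers: the p Cq columns, then the p(p−1)/2 ratios Cq_i/Cq_j for
i < j in lexicographic panel order — one direction only, numerator
earlier. Any consistent direction is equivalent for the model; this one is
deterministic and serialized with the model. A no-call Cq propagates NaN
into every feature involving it; the default cross-validation policy drops
such samples with a warning (median imputation is available behind a
flag). A Cq of exactly 0 in a denominator is treated as upstream
corruption and raises.

Standardization is (x − mean)/SD per feature with the sample SD, fit on
training data only; zero-variance features are dropped by name, and test
samples are always transformed with the training parameters.

## Sparse PLS-DA

Class coding: a single centred −1/+1 column (equivalent to a two-column
dummy for two classes up to scaling, and giving the scalar predicted value
the decision rule needs). Per component, NIPALS iterates
w ∝ Xᵀu → soft-threshold → t = Xw → q = yᵀt/tᵀt (tolerance 1e-9, cap 500;
for one component with this coding the loop converges immediately and the
solution is closed-form — NIPALS is kept for multi-component generality),
then deflates X and Y by regression on t. Soft-thresholding uses
λ = the (keep+1)-th largest |w|: exactly `keep` survivors when |w| values
are distinct; exact ties at λ shrink to zero, so ties can only *reduce*
the count, and a fully tied candidate set falls back to equal weights on
the first `keep` indices (ranking by |w| descending, then index).

The component-1 sign is fixed so the positive class has the larger
training-score mean. When `keep_x` is not set it is chosen by
leave-one-out misclassification over the grid {10, 25, 50, 100, 250, 500,
961, p} (961 kept as a conventional dense-ish operating point for
~1000-feature panels), with per-fold re-standardization and ties going to
the sparser model.

`filter_by_loading(cutoff=0.04)` zeroes every |loading| ≤ cutoff,
renormalizes, and recomputes scores, deflation and class statistics on the
stored training data. The filter is applied to the already unit-norm
loading vector (the scale on which the 0.04 convention is meaningful).

## Decision rule and cross-validation

A new sample's component-1 score s is standardized against each class's
training scores: z_c = (s − mean_c)/SD_c; the call is the class with the
smaller |z|. Exact ties go to positive — a screening test prefers
sensitivity, and ties are a probability-zero event on continuous scores.
The rule is invariant to common affine rescaling of (score, means, SDs).

Repeated hold-out CV draws plain random 54/15 splits (5 repeats by
default), standardizes with training parameters, fits the model on the
training side only, and evaluates nearest-zero calls on the held-out side.
A split leaving either side single-class is redrawn with a warning
(training because the model requires both classes; test because
sensitivity/specificity would be undefined). Outlier exclusion is a
config list of sample ids — no automated criterion is imposed. Per-repeat
loadings are retained in the report so selection stability can be
inspected.

## Problem sizes and verification

The test suite and the results script run entirely on synthetic data at
the study's own scale: 69 × 44 curves (3036 Cq calls) per pipeline
replicate, five replicates for recovery statements; 22 × 10 000-read
libraries over a 203-sequence pool for the NGS arm; 1000 random curves for
the Cq oracle comparison and 100 random 20×8 instances for the PLS/SVD
comparison. At the default effect sizes (2-cycle shift, 0.5-cycle noise —
a per-aptamer standardized separation of ~4) held-out accuracy is
essentially perfect; the interesting failure modes appear as the shift
shrinks toward the noise floor, which the generator exposes as ordinary
parameters.

## Known limitations

* Strictly two-class; no multi-class or SUVR-regression support.
* No efficiency-corrected quantification, ΔΔCq, melt-curve or inter-plate
  normalization.
* The NGS arm models one selection round only; enrichment dynamics across
  rounds are out of scope.
* Real-data quantities that depend on the original cohort (retained
  variable counts, class score means, cross-validated averages) are not
  reproducible from synthetic data; the package instead verifies the
  machinery by oracle equivalence and ground-truth recovery.
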