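# Methods

`metabmd` implements a benchmark-dose (BMD) analysis pipeline for untargeted
metabolomics dose-response studies, together with discovery of
exposure-chemical biotransformation products (BTPs) and their correlation
with xenobiotic-metabolism gene expression. This note records the models,
the numerical choices, and the places where the design was genuinely open.

## Study design and data model

The unit of analysis is a feature × sample intensity table per assay
(`FeatureTable`): non-negative peak areas (LC-MS) or bin integrals (NMR),
with NaN marking non-detection. Samples carry a role — `study` (one animal,
one dose), `qc` (repeated injections of a pooled aliquot of all extracts),
or `blank` (extraction blanks) — and study samples carry a dose in mg/kg.
The default `DoseDesign` is a 4-day oral-gavage rat study: doses 0, 55,
110, 220, 441, 881 mg/kg with 3 animals per group except 2 at 441
(17 study samples), four LC-MS assay modes (HILIC/lipids × positive/
negative) plus one NMR assay. "Present" always means non-missing AND > 0,
because deconvolution software reports non-detections as zero peak area.

## Preprocessing

Applied per assay, in order:

1. **Quality filter** (raw intensities): keep a feature iff it is present in
   > 90% of QC injections, its QC relative standard deviation is < 30%
   (computed on detected values, ddof = 1), the mean extraction-blank signal
   is < 5% of the mean QC signal (missing blank values count as 0 — the
   conservative reading when several blanks exist), and it is present in
   > 50% of study samples. All four inequalities are strict. NMR tables
   have no blanks; the blank rule is disabled for them rather than guessed.
2. **PQN normalization**: the reference profile is the per-feature median
   over study samples (a QC-median reference is selectable — both are
   standard and the choice is exposed rather than hidden). Each sample is
   divided by the median of its feature-wise quotients against the
   reference, over features detected in both; a sample sharing fewer than
   10 features with the reference is flagged and left unscaled. The
   coefficients are returned so the sparse xenobiotic matrix can be scaled
   with the coefficients derived from the feature-rich endogenous matrix.
3. **kNN imputation** (k = 5, feature-wise): neighbour distance is the
   root-mean-square difference over co-observed samples (RMS rather than a
   raw Euclidean sum, so pairs are not penalized for having more shared
   samples); each missing cell takes the unweighted mean of the k nearest
   features observed in that sample; distance ties break by feature id for
   determinism. A feature with no co-observed partner falls back to its own
   observed mean.
4. **glog** y = ln((x + √(x² + λ))/2) with λ chosen to minimize the SD of
   per-feature QC variances after transform — a 200-point log grid on
   [1e-2, 1e10] followed by bounded refinement between the bracketing grid
   neighbours. Only the PCA overview consumes the glog scale; BMD modeling
   runs on the normalized, imputed (un-transformed) scale.

## The benchmark-dose engine

Seven continuous mean functions are fitted per feature under
y ~ Normal(μ(d), σ²) with one shared σ (constant variance): linear, power
(exponent ≥ 1), Hill (n ≥ 1, k > 0), and exponential 2–5 (see
`metabmd.models` for the exact forms). The adverse direction is not
declared in advance; it is carried by a sign parameter (exponential
families) or the sign of a linear coefficient, because metabolite classes
move in both directions. Non-monotonic families are deliberately absent:
six dose groups cannot support them confidently.

**Fitting.** σ̂² = RSS/n at the optimum, so fitting reduces to nonlinear
least squares on the mean. Each family is fitted by variable projection:
its conditionally linear parameters (intercepts/amplitudes) are solved
exactly by least squares at every trial value of the nonlinear shape
parameters (exponents, rate constants), which are optimized over a
deterministic coarse grid followed by local refinement (bounded scalar
search or Nelder-Mead in ≤ 2 dimensions). This is a deterministic,
exhaustive alternative to random multi-start heuristics: every grid node is
a start. Exponents are capped at 18; amplitude positivity (a > 0) is
enforced with a flat-model fallback. AIC = 2(p_mean + 1) − 2·loglik, σ
counting as one parameter (BMDS conventions vary; this one is fixed and
documented).

**BMD.** The BMR is a multiple of σ̂: BMD is the smallest d > 0 with
|μ(d) − μ(0)| = k·σ̂ (k = 3 in the prefilter pass, 1 in the final pass).
Linear uses the closed form k·σ̂/|β₁|; all other families use bracketed
Brent root finding on [0, 10 × highest dose]. A curve that never departs
baseline by the BMR within the bracket has no BMD and the model is
rejected downstream.

**Profile-likelihood BMDL/BMDU.** The BMR equation pins σ to
|μ(BMD) − μ(0)|/k, so for a pinned BMD value the profile is an
unconstrained optimization over the mean parameters alone, warm-started
from the MLE and from neighbouring profile points. The bound is where the
profile deviance reaches the χ²₁ quantile at 0.90 — the standard
correspondence making BMDL and BMDU *one-sided* 95% bounds (so the pair is
a 90% two-sided interval), which is the usual BMDS reading of "confidence
level = 0.95". Bracketing is geometric expansion away from the MLE
followed by bisection; a profile still inside the cutoff at the bracket
edge yields an undefined bound with a recorded reason.

**Lack-of-fit p-value.** The fitted model is compared against the
saturated dose-group-means model under the shared constant variance. The
deviance is referred to an F distribution with
(groups − p_mean, n − groups) degrees of freedom — the exact small-sample
form of the likelihood-ratio lack-of-fit test. The χ² form of the same
statistic is markedly anticonservative at 2–3 animals per group (measured:
42% of null p-values below 0.25 at n = 17), which would silently reject
well-fitting features; the F form is exactly calibrated under the normal
model and uniform under the null. Which goodness-of-fit statistic
BMDExpress labels the "fit p-value" is not documented; this choice is the
package's own.

**Best-model selection.** Drop non-converged fits, fits without a defined
BMD, fits with lack-of-fit p ≤ 0.05, and flagged Hill fits (k̂ below a
third of the lowest nonzero dose — such fits place their half-maximum
below the observable range); among survivors the lowest AIC wins, ties
breaking by a fixed family order.

## Two-pass workflow

Pass 1 fits all families at BMR = 3 SD, selects a best model, and applies
three post-filters (strict inequalities): BMD < highest dose,
BMD/BMDL < 20, fit p > 1e-4. Only survivors are evaluated at BMR = 1 SD
with identical settings and post-filtered again; the final survivor set is
therefore a subset of the prefilter's. Because the maximum-likelihood fit
does not depend on the BMR, the engine fits once and recomputes the
benchmark quantities per pass — numerically identical to refitting, at
half the cost. The prefilter pass computes BMDL only (its filters never
read BMDU).

Assay result lists are concatenated with provenance; accumulation-plot
data are the surviving BMDs sorted ascending against rank 1..N; per-class
summaries report median BMD and BMDL over annotated survivors, computed on
uncensored numeric values (published class medians sit on both sides of
the censoring limit, so censoring before aggregation would distort them).
Reporting censors BMDs below the lower limit of extrapolation — lowest
nonzero dose / 3, i.e. 18.3 mg/kg for the default design, rounded to one
decimal — as "< cutoff", keeping the numeric value internally; a BMD
exactly at the cutoff is not censored.

## Xenobiotic discovery

Runs on the raw (pre-normalization) LC-MS tables. The two-step screen
keeps features whose top-dose/control median ratio is ≥ 10 (missing = 0; a
zero control median with top-dose signal is +∞ — structural absence in
controls is the defining xenobiotic signature) and whose normalized-slope
regression lands in [0.5, 1.5] inclusive. The normalization making the
ideal dose-proportional feature have slope exactly 1 — intensities scaled
by the feature's top-dose median, doses by the highest dose, OLS with
intercept — is this package's definition; the upstream method's exact
regression is not restated in its companion description.

Retained features are rescaled with the endogenous PQN coefficients, then
imputed: control-sample holes get half the lowest intensity observed
anywhere in the study's LC-MS assays (the compound is genuinely absent
there, so a floor value, not a neighbour estimate), dosed-sample holes get
the standard kNN. Grouping connects features within 5 s retention time AND
Pearson r > 0.7 across study samples (QCs and blanks excluded — the dose
structure drives the shared signal); connected components are ion-form
groups. Within a group, neutral-mass hypotheses (each member as each
adduct, + up to two isotopologue spacings) are scored by how many members
they explain; anchors are tried lightest-first and adducts in a fixed
priority order ([M+H]⁺ / [M−H]⁻ first), so the conventional reading wins
when a single-adduct series is underdetermined. Groups explained by no
hypothesis are left unlabeled and flagged.

Biotransformation annotation compares each group's neutral mass against
the parent mass plus chains of ≤ 2 library shifts (phase I:
hydroxylation, dihydroxylation, aryl loss; phase II: glucuronide, sulfate,
glutathione-related conjugates, methylation, …) at 5 ppm; the library
stores formula deltas and derives masses from monoisotopic atomic masses
at access time, so no delta is a hand-typed number. Exact-mass ties
(2 × hydroxylation ≡ dihydroxylation) resolve to the shorter chain.
Deeper chains explode combinatorially and are out of scope. Each group is
reduced to one representative — MS/MS measured, retention time > 30 s
(outside the solvent front), then highest fragment-match fraction, then
highest median intensity — and distinct annotations are reduced to one
compound each (most intense group wins).

## Gene-metabolite correlation

Spearman ρ (average ranks for ties) of every panel gene against every
representative xenobiotic feature over shared samples (≥ 5 required).
p-values use the exact permutation distribution for n ≤ 9 and the t
approximation beyond (the emulated study has n = 17). Per gene: the count
of features with two-sided p < 0.05, the median |ρ| across features
(undefined pairs from constant vectors are excluded), and a "strong" flag
at median |ρ| ≥ 0.6. Genes with no correlation anywhere are reported and
flagged, never dropped.

## Synthetic-data generator

The generator emulates the study the analysis assumes, not any particular
raw data set. Per assay it draws null features (flat means), dose-
responsive features (family drawn uniformly from the seven shapes;
baseline log-uniform in [1e4, 1e7]; CV in [0.05, 0.15]; plateau effects of
4–10 residual SDs for the saturating families; top-dose fold changes of
unbounded families capped at 100), blank contaminants (MS only), and — in
the LC-MS assays — spiked xenobiotics: a parent compound (triphenyl
phosphate by default) plus 11 distinct BTP chains, each as a main adduct
ion and a +1 isotopologue at 20% relative intensity, structurally missing
in controls, intensity proportional to dose (normalized slope 1 before
noise), m/z = neutral mass + adduct offset with ±1 ppm jitter.

Measurement noise is multiplicative lognormal by default (positive,
heteroscedastic — realistic for peak areas), with an additive-Gaussian
switch for exact calibration studies. QC injections are lognormal draws
around the pooled mean at 8% technical CV; QC values are never masked
(repeat injections of one pool rarely miss), while study cells get 2%
missingness at random. Extraction blanks carry 0.5% background except for
contaminant features (50%).

**Ground truth.** Every feature carries one record: class, generating
family and parameters, residual SD, and — for responsive features — the
true 1-SD BMD. For additive noise the scale parameter is solved in closed
form so the BMD lands exactly on its drawn target (e.g. linear:
β₁ = σ/BMD). For multiplicative noise there is no single σ; the recorded
truth uses the *constant-variance projection* — the RMS of the per-sample
SDs over the design — because that is the σ a constant-variance fit
consistently estimates; the recorded BMD is re-solved numerically on the
generating curve at that σ. Any other convention builds a bias into the
truth that no constant-variance estimator could ever close. Gene panels
couple a configured fraction of genes (default 62% of 58) to a xenobiotic
feature through a noisy log transform — strictly monotone, so coupled
genes have |ρ| → 1 as the noise vanishes.

What the generator does *not* emulate: chromatographic drift and
batch effects, correlated feature blocks beyond the spiked ion forms,
intensity-dependent missingness, isotope fine structure beyond the +1
peak, and raw spectra. Passing tests therefore demonstrate the statistics
of the pipeline under its own assumptions, not robustness to instrument
artefacts.

## Calibration measurements and problem sizes

The acceptance suite measures, at sizes chosen to keep a full run on one
CPU comfortable: one-sided BMDL calibration on 500 simulated linear
features at 10 animals/group (measured undercoverage ≈ 4%, nominal 5%);
null-feature survival through the two-pass workflow on 1,000 flat features
(measured ≈ 0.3%, the 3-SD prefilter being the binding gate); and BMD
recovery on 200 saturating/power features at 6 animals/group with 10%
noise. On recovery, two caveats are structural rather than bugs. First,
BMDL and BMDU are one-sided 95% bounds, so [BMDL, BMDU] is a 90% interval
by construction and its truth-coverage cannot exceed ~90% (measured
~80–85% once AIC model selection conditions the interval on the chosen
family). Second, point accuracy within ±30% is reached for roughly
70–75% of survivors rather than all of them: the MLE σ̂ is biased low by
√((n−p)/n) at these sample sizes, and AIC parsimony sometimes prefers a
2-parameter exponential to the saturating truth, shifting the BMD. Both
effects are properties of the standard continuous-BMDS recipe the package
reproduces, and are reported rather than patched.

## Determinism

All randomness flows through one integer seed: the generator derives
per-assay and per-stream generators by fixed offsets
(`np.random.default_rng([seed, stream])`), the fitting engine is
deterministic by construction (grid + local refinement, fixed tie-breaks),
and equal (design, config, seed) inputs reproduce byte-identical tables
and manifests.
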