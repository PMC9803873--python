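# Methods

This note documents the statistical models implemented in `skinrhythm`, the
defaults and their rationale, the numerical choices, what the synthetic
cohort generator does and does not emulate, and the package's known
limitations. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Time axis

Internal time is wall sampling time minus the subject's chronotype MSF_sc
(mid-sleep on free days, sleep-debt corrected), in hours. Times are stored
unwrapped — a sample drawn at 32 h wall time keeps an internal time beyond
24 — and every periodic fit reduces time modulo the period internally. The
period is fixed at 24 h (configurable constant, no period scan). Because
each subject's internal-time grid is shifted by their MSF_sc, the pooled
design is non-uniform; all rhythm tests are regression-based for exactly
this reason. A `wall_time` switch re-runs any analysis on the uncorrected
axis for sensitivity checks.

## Population cosinor and the rhythm test

Per gene and layer, `y = m + a·cos(ωt) + b·sin(ωt) + ε` is fit by OLS over
all subjects' samples pooled (the population rhythm; no subject intercepts
by construction — the target of inference is the cohort-average curve).
Rhythmicity is the exact F test of `a = b = 0` with (2, n−3) degrees of
freedom; BH q-values are computed across the genes of one scan.

Matrix-wide scans optionally moderate the residual variances: per-gene
variances are shrunk toward a pooled prior whose scale and degrees of
freedom are moment-matched on log s² (digamma/trigamma inversion), and the
denominator degrees of freedom grow by the prior df. Moderation is ON in the
pipeline configuration (stabilises small-sample scans) and OFF at the
function level, so the unmoderated, exactly-F-distributed test remains the
unit-tested default.

Conventions worth pinning down:

* amplitude `A = √(a²+b²)` is half the peak-to-trough swing in log2 units;
  peak-to-trough fold change is `2^(2A)`, so the fold-change-1.5 gate equals
  an amplitude gate at `log2(1.5)/2 ≈ 0.29248`;
* acrophase `φ = (atan2(b,a)/ω) mod 24` is the peak time of
  `m + A·cos(ω(t−φ))`, reported as hours after MSF_sc on the internal axis;
* fold-change comparisons are strict (`> 1.5`).

## Differential rhythmicity

The joint per-gene model has layer-specific intercepts and harmonics (six
coefficients); its block-diagonal design makes it algebraically identical to
two independent per-layer fits, which the implementation verifies at run
time. Two nested F tests follow: any-rhythm, `H0: a_d=b_d=a_e=b_e=0`,
F(4, n−6); differential, `H0: (a_d,b_d)=(a_e,b_e)`, F(2, n−6).

Categorisation: gate = `q_any < FDR` AND max-layer fold change > threshold.
`q_diff` is BH-corrected **within the gated set only** (the hypothesis is
conditional on being rhythmic somewhere). Gated genes that the differential
test cannot distinguish are rhythmic in *both* layers even when one layer's
fold change is sub-threshold; distinguishable genes are assigned by their
per-layer fold changes. These rules make the counts obey the partition
identity `dermis calls = indistinguishable + dermis-only + differential`
(and symmetrically for epidermis), which the acceptance suite asserts on
every synthetic run.

Circular phase agreement between layers is summarised by the circular mean
of paired acrophase differences wrapped to (−12, 12], the mean resultant
length R, and a series-approximation Rayleigh p (cross-checked against
pingouin in the tests).

## Mixed-model variability decomposition

Per gene, the crossed random-effects model places one (Δm, Δa, Δb) vector
per subject with unrestricted 3×3 covariance Σ_subj and one per layer with
diagonal covariance Σ_layer (the diagonal restriction keeps a two-level
factor estimable) over the fixed cosinor coefficients, plus iid Gaussian
noise.

Estimation is maximum likelihood (not REML — the estimator choice was open
and ML keeps the likelihood-ratio ordering against the OLS sub-model exact).
Numerics:

* Σ_subj is log-Cholesky parameterised; Σ_layer's diagonal and the residual
  variance are log-parameterised, so variance components reach the boundary
  only asymptotically (floor `e^-12` on SDs); boundary fits are legitimate
  results, not errors.
* The residual variance is profiled out analytically (all covariances are
  expressed relative to it), and likelihood evaluations use the Woodbury
  identity on precomputed cross-products, so each evaluation costs O(q³)
  with q = 3·(subjects+layers) rather than O(n³).
* L-BFGS-B from three deterministic starts (random-effect/residual SD
  ratios 0.6, 0.05, 2.0), relative tolerance 1e-10 on the objective. A fit
  is flagged `converged` when at least one start terminates cleanly within
  1e-6 of the best objective; non-convergence is flagged, never silently
  returned.

Amplitude and phase variability per source x ∈ {subject, layer} come from
first-order (delta-method) propagation, `σ²_{A,x} = J_A Σ_x J_Aᵀ` and
`σ²_{φ,x} = J_φ Σ_x J_φᵀ` with `J_A = (0, a/A, b/A)` and
`J_φ = (0, −b/A², a/A²)` (radians; reported in hours via 24/2π). The
linearisation is validated against Monte-Carlo truth in the small-variance
regime (σ_A/A < 0.2, σ_φ < 1 h agree within 5%); a per-gene flag marks
phase SDs beyond a 2-h trust bound. Amplitude CV is σ_A/A on the
fixed-effect amplitude. Relative phase variability is σ_φ/period — a CV of
a circular quantity is ill-defined, so the period is the normaliser; the
alternative σ_φ/φ convention is available behind `phase_cv_mode="phase"`.
The subject variance fraction is σ²_subj/(σ²_subj+σ²_layer) per parameter
(magnitude from the covariance diagonals, amplitude/phase from the
propagated SDs).

Known estimator properties, measured by the test suite: subject covariance
components at the 11-subject design are recovered essentially unbiased
(mean within ~10% over repeated cohorts), while the two-level layer
variances carry the classic downward ML bias of a small factor (~20–25%
low on average). No shrinkage or bias correction is applied; two-level
layer estimates should be read as noisy and conservative.

## Enrichment

ORA is the upper-tail hypergeometric test per gene set, after intersecting
sets with a caller-supplied background; there is no default background
because different questions use different universes (all expressed genes vs
all rhythmic genes). Sets with fewer than `min_set` (default 20) members
**within the background** are excluded before BH correction; an alternative
reading of the exclusion rule (fewer than 20 *query* genes) exists in the
field, but the set-size rule is stable under query changes and matches the
"more than 20 genes per set" convention.

PSEA tests each set's acrophases — diurnal genes only, rounded to the full
hour — against circular uniformity with the Kuiper statistic V = D⁺ + D⁻,
whose value is invariant to rotating all phases by a constant (the property
that makes it, unlike plain Kolmogorov–Smirnov or Rayleigh, appropriate for
circular data with possibly antiphase clusters). The p-value uses the
asymptotic series with the `√n + 0.155 + 0.24/√n` small-sample factor;
calibration against a 10⁵-draw Monte-Carlo null at n = 20 shows absolute
deviations under 0.021 overall and under 0.002 in the 1–5% tail. A
Monte-Carlo p-value is available behind a flag for very small sets. Sets
with fewer than `min_set` (default 5) diurnal members are excluded before
correction.

## Internal-time predictor

Training on one layer: per-gene centre/scale (train statistics) → per-gene
periodic mean curves (harmonic basis of order `n_knots−1`, default 2;
periodic cubic B-splines behind a flag) → sparse principal components of
the row-centred curve matrix → periodic mean + constant Gaussian variance
per component score.

The sparse components solve `max uᵀXv` with `‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1,
‖v‖₁ ≤ sumabsv` by alternating soft-thresholded power iterations with
rank-1 deflation, initialised deterministically from the leading singular
vector; `sumabsv = 1` forces one gene per component, `sumabsv ≥ √(genes)`
reproduces dense PCA. Prediction maximises the Gaussian log-likelihood of
the sample's component scores over a 0.1-h grid (ties → earliest time). The
constant-variance Gaussian score model is the simplest decodable likelihood;
heteroscedastic scores around the clock are not modelled.

Evaluation is leave-one-subject-out CV over a hyperparameter grid, default
`sumabsv ∈ {1, 1.5, 2, 3} × nSPC ∈ {2, 3}`, scoring the median circular
absolute error (bounded by 12 h). Layers are trained separately. Models
serialise to a single JSON artifact.

## Synthetic cohorts

The generator draws data from exactly the generative model the variability
analysis assumes — fixed cosinor coefficients plus per-subject (full Σ_subj)
and per-layer (diagonal Σ_layer) random coefficient vectors and Gaussian
noise — observed on a shared wall-clock grid, with internal-time
non-uniformity arising from the chronotype spread precisely as in a real
cohort.

Defaults (the study conditions, chosen once): 11 subjects × 2 layers ×
7 timepoints at 8–32 h wall time; MSF_sc ~ U[2.5, 6.0] h (3.5-h spread,
consistent with intermediate chronotypes and 22:00–24:00 bedtimes); 10%
rhythmic genes; mesor ~ N(8, 1.5²) log2 units; lognormal amplitudes with
medians 0.35 (dermis) and 0.50 (epidermis) and log-SD 0.35, straddling the
0.2925 fold-change gate; acrophases from an equal-weight von Mises mixture
centred 1 h and 13 h after MSF_sc with κ = 2; Σ_subj SDs (0.2, 0.1, 0.1)
with 0.3 cross-correlation; Σ_layer diag SDs (0.3, 0.05, 0.05); residual
SD 0.2.

Design choices:

* `layer_mode="random"` (default) draws the layer coefficient deviations
  from Σ_layer per gene, matching the diagonal-covariance model;
  `layer_mode="fixed_contrast"` instead applies the deterministic
  epidermis/dermis amplitude ratio, generating the systematically-larger
  epidermal amplitudes regime on demand. `planted=` accepts an explicit
  per-layer coefficient table for category-recovery experiments.
* Flat genes receive baseline (mesor) random effects only: a gene with
  rhythmic (a, b) random effects would be genuinely rhythmic within a
  layer, which would contradict its "flat" label and break null
  calibration.
* One master seed; each gene gets a spawned child stream, so outputs are
  bit-identical per seed and stable under any parallelisation.

What the generator does **not** emulate: probe-level microarray noise, dye
or batch effects, heteroscedastic or heavy-tailed residuals, non-sinusoidal
waveforms, amplitude-dependent noise, layer-specific subject covariances,
or correlated gene modules. Tests passing on these cohorts therefore
certify the estimators under the assumed model, not robustness to real
microarray artefacts.

## Pipeline

One YAML config drives load-or-simulate → outlier flagging → per-layer
scans → differential categorisation → variability (gated to genes rhythmic
in ≥1 layer; a configurable cap, default 100 genes ordered by q_any, keeps
run times bounded) → ORA/PSEA → predictor CV, writing per-stage TSVs, a
deterministic `summary.json` and a log with versions, seed and thresholds.
Sample outliers are flagged by distance from the centroid in PC1–2
exceeding k (default 4) SDs of that distance; because that rule fires
wholesale when PC1–2 is dominated by genuine structure (e.g. tissue
separation), the pipeline ignores a flagging result that covers more than
10% of samples and logs it. Flagging is advisory at the API level — callers
decide removal.

## Problem sizes

The shipped tests and the acceptance script use: 2000-gene cohorts for
detection/calibration runs, 200 genes for category- and
variability-recovery, 10⁶ Monte-Carlo draws for the delta-method oracle,
10⁵-draw Kuiper nulls, and 50-gene clock cohorts for predictor CV — sizes
at which every targeted property is measurable with comfortable margins on
a single CPU in minutes.

## Limitations

* Rhythm detection assumes a single 24-h sinusoid; multi-harmonic or
  non-sinusoidal waveforms are out of scope.
* Two-level layer variance estimates are noisy and biased low (above); the
  subject/layer variance *fractions* inherit that conservatism.
* Delta-method phase SDs degrade for weak rhythms (σ_φ comparable to the
  period); the per-gene validity flag should gate downstream use.
* The predictor's gene selections are data- and preprocessing-sensitive;
  accuracy, not marker identity, is the reproducible quantity.
* Expression values must be complete; missing values are rejected rather
  than imputed.
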