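# skinrhythm

Diurnal rhythm analysis for paired two-tissue transcriptome time courses —
specifically cohorts in which each subject is sampled in **dermis and
epidermis** around the clock, as in microarray biopsy studies of the human
skin clock. The package is aimed at chronobiologists and computational
biologists who want population-level rhythm detection, between-layer rhythm
comparison, a principled decomposition of who drives rhythm variability
(subjects vs tissue layers), pathway-level phase statistics, and a
single-sample molecular predictor of internal time.

## The model

All analyses work on log2 expression against **internal time**
`t = wall time − MSF_sc`, where MSF_sc (sleep-corrected mid-sleep on free
days) is the subject's chronotype; this aligns subjects' clocks before any
rhythm fitting. Times are kept unwrapped; fits reduce them mod the 24-h
period.

**Population rhythms (cosinor).** Per gene and layer,

```
y(t) = m + a·cos(ωt) + b·sin(ωt) + ε,   ω = 2π/24
```

fit by OLS over all subjects pooled. Amplitude `A = √(a²+b²)` (half the
peak-to-trough swing; peak-to-trough fold change = `2^(2A)`), acrophase
`φ = atan2(b,a)/ω mod 24` (peak hours after MSF_sc). Rhythmicity is the F
test of `a = b = 0`; regression handles the non-uniform time grid that
chronotype correction produces (rank-based methods such as JTK/RAIN cannot).

**Differential rhythmicity.** A joint 6-coefficient fit per gene
(layer-specific intercept + harmonics) gives two nested F tests: *any
rhythm* (all four harmonic terms zero, F(4, n−6)) and *differential rhythm*
(harmonic terms equal across layers, F(2, n−6)). Genes passing
`q_any < 0.05` with max-layer fold change > 1.5 are gated in; within the
gated set, `q_diff` splits them into indistinguishable-in-both-layers vs
dermis-only / epidermis-only / differentially-rhythmic-in-both, with the
sub-threshold inclusion rule: indistinguishable genes count in both layers
even when one layer's fold change is below 1.5.

**Variability decomposition.** Per gene, a linear mixed model with crossed
random effects places one (Δm, Δa, Δb) vector per subject (full 3×3
covariance Σ_subj) and one per layer (diagonal Σ_layer) on top of the fixed
cosinor coefficients. Amplitude and phase SDs per source follow by
delta-method propagation, `σ²_A = J_A Σ J_Aᵀ` with `J_A = (0, a/A, b/A)` and
`J_φ = (0, −b/A², a/A²)`, and the subject share of a parameter's variance is
`σ²_subj/(σ²_subj + σ²_layer)`.

**Enrichment.** Hypergeometric over-representation against a caller-chosen
background, and phase set enrichment: the Kuiper test (rotation-invariant
Kolmogorov–Smirnov) of a set's acrophases, rounded to the full hour, against
circular uniformity.

**Internal-time prediction.** Sparse principal components of per-gene
periodic mean curves (penalized matrix decomposition with an ℓ1 bound
`sumabsv` on the gene loadings), periodic Gaussian score curves, and
maximum-likelihood decoding of a single sample's time on a 0.1-h grid;
evaluated by leave-one-subject-out CV with circular median absolute error.

A bundled generator simulates cohorts from exactly this generative model
(11 subjects × 2 layers × 7 timepoints by default, ~10% rhythmic genes,
bimodal acrophases near 1 h and 13 h after MSF_sc) with full ground truth.

## Worked example

```python
import skinrhythm as sr

cfg = sr.RunConfig(seed=42, output_dir="example_out",
                   simulate={"n_genes": 500},
                   sumabsv_grid=(1.5, 2.0, 3.0), nspc_grid=(2,),
                   max_variability_genes=20)
summary = sr.run_full_analysis(cfg)
```

On this simulated 500-gene cohort the run prints (`summary.json`):

```
categories: {"not_rhythmic": 455, "both_indistinguishable": 44,
             "both_differential": 1, "dermis_only": 0, "epidermis_only": 0,
             "dermis_total": 45, "epidermis_total": 45, "rhythmic_any": 45}
phase stats: mean_phase_difference_h = -0.068, rayleigh_R = 0.974
variability: median_f_A = 0.949, median_cv_A_subj = 0.136,
             median_cv_A_layer = 0.033
predictor (dermis): best sumabsv=3.0, nSPC=2, MAE = 0.47 h from 25 genes
```

Reading: 45 of 500 genes are called rhythmic in at least one layer (the
generator planted 10%; about half clear the fold-change bar), 44 of them
with rhythms indistinguishable between layers — so the per-layer totals obey
`45 = 44 + 0 + 1`. Acrophases agree tightly across layers (mean difference
−0.07 h, resultant length R = 0.97). The amplitude variability of these
genes is subject-dominated (median subject variance fraction 0.95; subject
amplitude CV 0.14 vs 0.03 across layers), and a 25-gene sparse predictor
recovers a held-out subject's internal time to a median 0.47 h.

The same pipeline runs on real data by replacing the `simulate` block with
`expression:`/`metadata:` (TSV: genes × samples; sample_id, subject_id,
layer, wall_time_h, msf_sc_h) and a `gmt:` gene-set file, either through the
API or the CLI:

```bash
skinrhythm all --config run.yaml --seed 1
```

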