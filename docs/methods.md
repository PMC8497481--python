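# Methods

## Measurement model

Each treatment fraction of each patient yields three measured vectors in
patient coordinates (LR, SI, AP; mm): the applied table shift, the clipbox
(bony-anatomy) setup correction, and the per-axis peak-to-peak tumor
amplitude. The baseline shift of a fraction is

    baseline = applied table shift − clipbox correction,

i.e. the residual tumor displacement relative to bone after setup
correction. Inter-fraction deltas reference fraction 1:

    baseline delta_k  = baseline_1 − baseline_k      (k ≥ 2)
    amplitude delta_k = amplitude_k − amplitude_1

The reference-minus-fraction baseline convention matches the clinical
bookkeeping this pipeline mirrors; because the literature also uses the
opposite sign, `baseline_sign="later_minus_first"` flips it. Only the sign
of the pooled mean changes; Σ, σ, exceedance frequencies and margins are
invariant. Fraction-1 rows (identically zero) are not emitted, so a
P-patient, F-fraction cohort yields P·(F−1) delta rows; all pooled
summaries use that denominator and report it explicitly.

## Population error decomposition

With d̄_p the mean and s_p the sample SD (n−1 denominator throughout; the
denominator choice is a convention we fix explicitly) of patient p's deltas
on one axis:

    Σ = SD over patients of d̄_p        (systematic error)
    σ = sqrt( mean over patients of s_p² )   (random error)

No shrinkage correction is applied to Σ: with F−1 deltas per patient,
E[Σ̂²] = Σ² + σ²/(F−1), so Σ̂ absorbs part of the random component. This
mirrors the estimator used in the clinical workflow; the bias is covered by
a dedicated test rather than corrected.

Baseline and amplitude components are treated as independent error sources
and combined in quadrature per axis (Σ² and σ² add). The margin table is
computed from the combined component by default; baseline-only or
amplitude-only tables are available via `margin_component`.

## Margin recipes

Four closed forms map (Σ, σ) to a margin: `2Σ + 0.7σ`, `2.5Σ + 0.7σ`,
`Σ + √(σ² + Σ²)` and `√(2.7²Σ² + 1.6²σ²) − 2.8 mm`. All lengths are mm
everywhere, including the last recipe's constant. That recipe can go
negative for small errors, a regime outside its derivation; the table floors
it at 0 and sets a flag. Display values are rounded half-up to 0.1 mm
(matching clinical margin tables); raw values are always retained.

## Hypothesis tests

- Between-axis comparison: paired t-test on |delta|, pairing rows by
  (patient, fraction). Magnitudes are the scale on which "more motion in
  SI" is meaningful; `absolute=False` tests signed deltas. Identical pairs
  return t = 0, p = 1 rather than NaN.
- Baseline–amplitude association: Pearson r per axis on the pooled delta
  pairs; undefined (raised, and reported as null by the pipeline) when
  either variable is constant.
- Normality: Shapiro–Wilk at α = 0.05; constant input is reported as not
  evaluable instead of raising so degenerate cohorts still produce a full
  report.

No multiple-testing adjustment is applied. The tests are descriptive
companions to the error decomposition, not a gatekeeping procedure.

## Breathing trace and acquisition emulation

The trace is the standard even-power cosine

    z(t) = z0 − b · cos^(2n)(π t / τ + φ)

with defaults n = 2, τ = 4 s and per-axis b = (2, 10, 5) mm — typical
lower-lobe motion dominated by SI. The even power concentrates dwell time
at end-exhale (z0), the asymmetry that phase sorting exploits. Cycle
periods are jittered (default 5% fractional SD, truncated at ±3 SD) so the
breathing is not resonant with the projection sampling grid; the jitter is
seeded, making every trace deterministic given its parameters.

The acquisition emulation samples the trace at `n_projections` uniform
timestamps over `arc / speed` seconds (defaults: 975 projections, 200° at
3°/s ≈ 66.7 s, i.e. ~16–17 breathing cycles at τ = 4 s). Phase sorting
uses the SI trajectory itself as the respiratory surrogate, standing in for
diaphragm tracking: end-exhale peaks are detected (prominence ≥ 25% of the
SI span), phase advances linearly between successive peaks (phase 0 at the
peak, bins half-open [i/10, (i+1)/10)), and samples outside the first/last
peak are phased by extrapolating the adjacent cycle so every projection
contributes. Fewer than two detected peaks, or an empty bin, raises an
insufficient-cycles error.

Per-bin positions are means of member samples, so the binned peak-to-peak
estimate is biased low — bin averaging can only shrink the range. At the
defaults the estimate lands within ~7% of the true 10 mm SI excursion and
converges to it as bins and sampling densify (both properties are tested).
The ITV extent is the interval union of the GTV translated to each phase
position; its length is exactly GTV length + peak-to-peak per axis.

## Cohort generator

The generator is hierarchical per axis and component: patient systematic
offsets m_p ~ N(μ, Σ_true²), per-fraction random deviations
e_pk ~ N(0, σ_true²), delta d_pk = m_p + e_pk. Defaults encode the study
conditions the package is built around: 19 patients × 5 fractions, pooled
delta means (−0.0, 0.9, 0.1) mm baseline and (−0.2, 0.4, −0.4) mm
amplitude, the published Σ/σ decomposition per axis (baseline 0.6/0.7,
0.5/0.6, 1.0/0.4 mm; amplitude 0.9/0.9, 1.2/1.2, 1.6/0.8 mm), and
baseline–amplitude correlations (0, 0.353, −0.227). Where a pooled
parameterization is more natural, `CohortConfig.from_pooled` splits a
pooled SD into Σ/σ with an even variance split by default
(`systematic_fraction=0.5`), a neutral choice in the absence of information
about the split.

The requested correlation ρ is the correlation of the *pooled* delta pairs.
A single level-correlation ρ· √(V_b V_a)/(Σ_b Σ_a + σ_b σ_a) is applied to
both the systematic and the random pair draws, which makes the pooled
sample correlation converge exactly to ρ; configurations where that level
value would exceed 1 in magnitude (extremely mismatched Σ/σ splits between
the two components) are rejected as infeasible.

Records are constructed backwards from the drawn deltas: fraction-1
reference baselines (N(0, 1 mm)) and amplitudes (N((2, 10, 5), (1, 3, 2))
mm, typical lower-lobe values) are drawn, clipbox corrections (N(0, 2 mm))
are added as plumbing, and fraction-k values are set so the metrics module
recovers the drawn deltas exactly. Amplitudes are floored at 0 mm; at the
default reference amplitudes the floor affects well under 1% of records and
perturbs recovered pooled SDs by ≲ 0.03 mm.

What the generator does **not** emulate: registration error in the clipbox
and mask alignments (deltas are exact by construction), intra-fraction
drift, amplitude-dependent baseline physics beyond the linear correlation,
non-normal tails (real cohorts contain deep-inspiration outliers), and any
coupling between the trajectory layer and the cohort layer. Passing
recovery tests therefore demonstrate that the estimators are correct under
the stated model, not that real 4DCBCT measurements meet its assumptions.

## Numerical and design choices

- Sign convention: positive = patient left / superior / anterior; results
  are symmetric under a global flip.
- Sample SD (ddof = 1) everywhere; `ddof=0` is available for per-patient
  summaries when a patient has a single delta row.
- Display rounding is decimal round-half-up on the shortest float repr,
  avoiding binary-float artifacts at the 0.05 boundary.
- The cohort CSV is written with `%.17g` and read with round-trip float
  parsing, so write→read is lossless.
- The pipeline computes everything before writing anything, so a failing
  stage leaves no partial output; `summary.json` embeds the seed and a
  config hash (excluding the output path) and is byte-identical for
  identical (config, seed).
- Problem sizes in the test-suite Monte-Carlo checks (1000–3000 patients)
  put the sampling SE of recovered parameters a factor ≳ 2 below the
  asserted tolerances.

## Known limitations

- The published per-axis SI error components are not arithmetically
  consistent with any SI margin in the reference table under quadrature (LR
  and AP are); SI margins are therefore validated by property tests, not by
  value. Back-solving the SI margins suggests combined SI values near
  Σ ≈ 2.4, σ ≈ 2.1 mm.
- Exceedance percentages are reported with the package's own denominator
  (P·(F−1) delta rows); reference percentages computed on a different,
  unexplained denominator (e.g. 6.38% ≈ 6/94) will differ slightly.
- The Σ estimator's finite-fraction bias (above) is documented and tested,
  not corrected.
- The margin recipes are taken as printed coefficients; no underlying
  dose-population or TCP simulation is performed.
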