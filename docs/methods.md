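# Methods

## The measurement-comparison model

Each patient *i* carries a latent trait x_i — their underlying daytime
BP level — drawn N(μ, τ²) across the cohort. The reference device
(ABPM) measures y₁ᵢⱼ = x_i + ε₁ᵢⱼ; the test device measures
y₂ᵢⱼ = α + β·x_i + ε₂ᵢⱼ. α (mmHg) is the differential bias, β
(unitless) the proportional bias; β < 1 is the calibration-anchoring
signature. The bias curve b(x) = α + (β−1)·x is the expected
test-minus-truth error at true value x, with sign convention
positive = test overestimates; it crosses zero at x₀ = α/(1−β).

### Estimation (three closed-form stages)

1. **Reference random-effects model, method of moments.** Pooled
   within-patient variance σ̂₁² = Σᵢ SSᵢ / Σᵢ (nᵢ−1);
   τ̂² = max(0, Var(ȳᵢ) − σ̂₁²·mean(1/nᵢ)); μ̂ the precision-weighted
   grand mean with weights 1/(τ̂² + σ̂₁²/nᵢ). The BLUP of each
   patient's trait is x̂ᵢ = μ̂ + λᵢ(ȳᵢ − μ̂), λᵢ = τ̂²/(τ̂² + σ̂₁²/nᵢ).
   Moments rather than ML keeps every quantity closed-form and is
   fully adequate at ~40 patients × ~76 readings; the shrinkage stage
   treats the reference error as homoscedastic even though the
   precision stage later allows it to vary with x — a deliberate
   two-stage approximation.
2. **Bias.** OLS of *all* test readings on the BLUP of their patient:
   intercept = α̂, slope = β̂. 95% CIs by nonparametric bootstrap with
   **patients as the resampling unit** (default 500 draws, percentile
   interval, seeded) — resampling patients rather than readings
   respects the within-patient clustering. Each bootstrap draw refits
   both stages from per-patient sufficient statistics, so 500 draws
   cost milliseconds.
3. **Precision.** Residuals r₁ = y₁ − x̂ and r₂ = y₂ − (α̂ + β̂·x̂);
   for each device, OLS of log(r² + 10⁻⁶) on x̂, converted to an SD
   curve on a 100-point BLUP grid. Because E[ln χ²₁] = ψ(½) + ln 2 ≈
   −1.2704, that constant is added back before exponentiating; without
   it the fitted SD would be biased low by a factor ≈ 0.53. The 10⁻⁶
   floor keeps exact-zero residuals finite; a genuinely noiseless
   device therefore reports an SD of ~2·10⁻³ mmHg rather than 0.

### Known bias of the design, not the code

When the test device is triggered immediately after each reference
reading, both devices sample the *same momentary* BP, which fluctuates
within the day around x_i. The test readings then share the
slot-level fluctuation with the reference mean that the BLUP is built
from: cov(y₂, ȳ₁) = β(τ² + c) with c ≈ σ_w²·k/n > 0, so the fitted
slope overshoots β by a factor (τ² + c)/τ̂² — about 4–6% under the
default generator (Monte Carlo: identity device recovers β̂ ≈ 1.046
systolic, 1.056 diastolic; with the within-day fluctuation switched
off recovery is exact). This is intrinsic to simultaneous-pairing
designs whenever within-day variability is comparable to
between-patient spread; it affects the real study design identically
and should be kept in mind when reading α̂/β̂ to the second decimal.
The test suite documents it: null-device recovery is asserted exactly
under the latent-trait model (no within-day fluctuation) and the
anchored-profile recovery is asserted against the published CIs under
the full generator.

## Bland–Altman and ISO

Differences are **reference − test** throughout. `classic_ba` reports
mean ± SD and mean ± 1.96·SD limits (a small-sample t-multiplier is a
parameter); proportional bias is flagged by the OLS slope of
difference on average with its two-sided t-test, with the Pearson r
reported alongside. `log_ba` re-runs the analysis on natural logs — a
purely multiplicative bias becomes a constant there, but an additive
anchoring (β < 1 on the mmHg scale) does not, so the association
survives the transform. `regression_ba` fits Diff = a + b·Avg and
returns the residual SD (n−2 denominator) with V-shaped limits; both
the raw difference SD and the residual SD are emitted since agreement
summaries are quoted both ways in practice. Pairs are pooled across
patients (no repeated-measures LoA correction); a per-patient summary
table is provided so cluster effects remain visible. The ISO check is
|mean difference| ≤ 5 mmHg and SD ≤ 8 mmHg, boundaries inclusive.

Pairing couples each test reading to the latest same-patient reference
reading at most `tolerance` (default 600 s) earlier, greedily in time
order and one-to-one; unpaired readings are reported, never an error.
The tolerance is configurable because real protocols only say the test
measurement follows the reference one.

## Classification

Scores are per-patient **test-device daytime means**; truth labels are
reference daytime means at the ≥135/85 mmHg cut-offs (boundary
hypertensive; day = [08:00, 24:00)). (Per-reading ROC is the obvious
alternative; per-patient means match how screening decisions are
made.) The ROC sweeps score ≥ t. The display grid uses a 0.1-mmHg
step, but AUC and the Youden optimum are computed on the exact set of
observed scores: a uniform grid can step over two scores closer than
the step and cut a staircase corner, which would break the identity
trapezoidal AUC = Mann–Whitney concordance (ties ½) that the suite
checks to 10⁻¹². Youden ties break toward the lower threshold and the
reported cut-off is the midpoint between the optimal threshold's
adjacent observed scores (hence non-integer cut-offs like 136.1).
PPV/NPV curves are evaluated on an inclusive 1-mmHg grid; undefined
values (empty denominators at extreme cut-offs) stay missing rather
than being coerced to 0 or 100, and all optima break ties toward the
lower cut-off.

## Variability indices

ARV is the mean absolute successive difference within a period, never
spanning the day/night boundary, equal-interval (a time-weighted
variant is out of scope since ABPM day sampling is uniform). SD_w
weights day and night SDs 16 h : 8 h. CV = 100·SD/mean on daytime
readings only. Night indices require > 2 night readings, otherwise
they and SD_w are missing — mirroring how sparse nocturnal smartwatch
data are handled in practice. Device comparisons use paired t-tests
across patients, pairwise-complete, suppressed below 3 pairs and
marked degenerate when all differences are equal; no multiplicity
correction is applied.

## Synthetic cohort generator

The generator is first-class, tested code and defines the study
conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 40 | cohort size |
| pop_mean_sbp/dbp | 130 / 80 mmHg | population daytime level |
| between_sd_sbp/dbp | 12 / 10 mmHg | between-patient SD |
| within_sd_sbp/dbp | 19.1 / 14.8 mmHg | stationary within-day SD |
| ar1_rho | 0.3 | lag-1 autocorrelation at 15-min spacing |
| night_dip_sbp/dbp | 12 / 8 mmHg | step nocturnal dip (00:00–07:59) |
| ref_noise | 4 mmHg | reference device error SD |
| day/night_compliance | 0.44 / 0.19 | P(test reading per slot) → ~28 day + ~3 night |
| pp_between_sd | 6 mmHg | SD of patient-level pulse pressure |
| within_corr | 0.7 | sbp–dbp fluctuation correlation |

The reference samples all 80 slots (64 day at 15 min, 16 night at
30 min); test readings occur at compliance-retained slots, stamped 1–5
min later but measuring the same slot latent (the protocol's
"measure right after the cuff deflates"). The default test profile is
the anchored device α = 50.1/β = 0.65 (systolic), 26.5/0.76
(diastolic) with noise SDs 5/4 mmHg — set at or below the reference
noise because an anchored PWA device is *smoother* than the
oscillometric reference, which is the direction real data show.
Diastolic values are generated jointly with systolic through a
bivariate patient-level distribution whose correlation is derived from
`pp_between_sd` (so marginal SDs and the pulse-pressure spread are both
honoured) and correlated within-day fluctuations; dbp < sbp is enforced
by a latent floor (PP ≥ 5 mmHg) plus noise resampling, with a clamp for
astronomically rare tails. The night dip is a step, not a cosine —
the analyses only ever see day/night windows. Determinism: per-patient
generators are spawned from the master seed.

What the generator does *not* emulate: device-side smoothing strong
enough to reproduce a smartwatch ARV as low as ~4 mmHg (an affine map
of an AR(1) latent cannot get there — with ρ = 0.3 the simulated ABPM
ARV_day is ≈ 18.8 mmHg and the test device ≈ 13.8, preserving the
direction but not the magnitudes), missing-not-at-random compliance,
medication effects, or measurement-order effects. Passing tests
therefore demonstrate that the *estimators* behave correctly under a
realistic sampling structure, not that the generator reproduces every
moment of real ABPM data.

## Numerical conventions and degenerate inputs

Timestamps are naive local clock time at minute resolution; same-minute
ties keep file order. Valid readings satisfy 40 ≤ dbp < sbp ≤ 300; CSV
rows violating this (or unparseable) are dropped and counted in the
load report, duplicate rows collapse, conflicting readings at one
minute keep the first with a warning, and patients with no reference
readings are dropped (patients with no *test* readings are retained and
flagged). Zero variance collapses shrinkage gracefully (λ → 1 when
σ₁² = 0, BLUP → μ when τ² = 0); constant BLUPs or constant BA averages
raise rather than return a pseudo-estimate; undefined metrics are NaN
end to end and serialise to JSON null. Reports are byte-reproducible
under a fixed seed because every random element (simulation, bootstrap)
derives from the config seed and no timestamps enter the report.

## Problem sizes used in the test suite

The suite simulates cohorts of 40 patients (the study's size) and uses
20-replicate Monte Carlo means for recovery checks, 3–5 replicates for
sign/recovery unit checks, and 100 random score sets for the AUC oracle
identity; the full suite runs in well under a minute on one core.
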