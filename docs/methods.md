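# Methods

## Dose conversion

The conversion anchors the human dose to a plasma-like concentration and
then dilutes it. For each drug, the total administered mass is
`M = clinical_dose (mg/m²) × BSA (m²)` and the equivalent plasma
concentration is `EPC = M / V` (mg/mL), with a reference patient of
BSA = 1.8 m² and blood volume V = 5400 mL. Both reference values are
configurable (`PatientReference`); the defaults are the conventional adult
reference values used by the packaged summary table. The fish-water
concentration of every component drug is `c_fish = EPC / ED`, where the
equivalent dose ED is a single dimensionless dilution factor shared by all
drugs of a regimen, so the human mass ratios among components are
preserved exactly. No pharmacokinetics is modelled: the embryo absorbs the
drug from the water, and the conversion deliberately bypasses allometric
scaling, which has no basis for bath exposure.

All intermediate values are carried at full precision. Display rounding
(2 decimals for concentrations, 3 significant figures for mass-ratio
strings, 1 decimal for the ratio percentiles) is applied only at the
reporting surface. One consequence worth knowing: the packaged reference
summary carries its ratio columns verbatim rather than recomputing them
from the (display-rounded) EPC and IC50/LD25 columns of the same table,
because those ratios were originally formed from unrounded fit
intermediates and recomputation from rounded inputs shifts several cells
by 2–3%.

## Safety study

Phenotype counts (normal / aberrant / dead) per concentration of the
regimen's index drug are pooled over replicates and converted to
incidences in percent, with dead embryos included in the denominator so
the three incidences sum to 100. Incidence is regressed on concentration
by ordinary least squares twice — against `c` and against `log10 c`
(zero-concentration rows are excluded from the log fit) — and the scale
with the higher R² is selected; both candidate fits are retained in the
results object for audit. A straight line is a deliberate choice over
probit/logit or four-parameter logistic models: the assays' tested ranges
are narrow enough that the observed incidences are far from both plateaus,
and the line keeps the inversion exact and auditable.

IC50 is the concentration at which the fitted normal-phenotype incidence
equals 50%; LD25 the concentration at which fitted mortality equals 25%.
Inversion of a zero-slope line raises an error; a solution outside the
tested concentration range is returned but flagged `extrapolated`, and
downstream computations accept flagged values.

The maximum tolerated dose uses the box-plot percentile convention
`rank = 0.75·(n+1)` with linear interpolation between order statistics,
clamped to the extremes when the rank falls outside [1, n] (numpy's
`weibull` method; the `(n−1)`-based convention of numpy's default gives a
visibly different upper quartile on 10 values and does not reproduce the
packaged table's percentiles). The two percentiles are rounded to one
decimal before taking their maximum — the scale at which MTD is quoted and
used — and the unrounded percentiles are reported alongside.

ED selection: candidate dilution factors at or below the MTD are excluded
as unsafe (a smaller dilution factor means a more concentrated bath);
among the remaining candidates flagged effective, the largest dilution
factor is chosen, i.e. the lowest exposure consistent with efficacy. With
no effective safe candidate the ED is undefined and the decision object
says why.

## Response analysis

Each embryo's stained-area series at 2 hpi, 1 dpi and 2 dpi is divided by
its 2 hpi baseline; using relative rather than absolute areas removes the
between-embryo variation in graft size. The baseline time point is a
configuration parameter because some analyses use 2 dpi / 1 dpi instead.

Within-group growth is tested by one-way repeated-measures ANOVA across
time points with embryo as the repeated unit, using the classical
univariate sum-of-squares decomposition without sphericity correction.
Degenerate inputs get explicit conventions: zero between-time variance
returns p = 1 (no time effect by construction), zero residual variance
with a nonzero time effect returns p = 0. Group means and SEMs are
computed from all embryos observed at each time point; the ANOVA uses
complete cases only. Treated-versus-control comparisons on the per-embryo
endpoint ratio use one-way ANOVA followed by Dunnett's many-to-one test
(multivariate-t critical values via scipy); groups with fewer than two
endpoint observations are excluded with a warning.

Response classification operates on group means of the endpoint ratio, not
per-embryo: `percent_decrease = 100·(1 − treated_mean/control_mean)`, CR at
≥ 90, PR at ≥ 30, NR otherwise, thresholds inclusive. Cohort tables count
CR inside PR (`%PR = 100·(#PR + #CR)/n`), so `%CR ≤ %PR` always; embryos
missing the endpoint are dropped (complete-case analysis) and logged.

The pyknotic-nucleus readout is a per-sample percentage with mean and SEM
across samples (SEM undefined and flagged for a single sample) and an
unpaired t-test for treated-versus-control contrasts.

## Synthetic data

`gen_safety` draws, per concentration and replicate, one trinomial with
p(dead) from a true mortality line, p(normal) from a true normal-phenotype
line and p(aberrant) the clipped remainder (rescaled with a warning if
normal + dead exceeds 1). Defaults mirror the real assay shape: 5
concentrations, 3 replicates × 30 embryos (n = 90 per concentration), true
IC50 0.10 mg/mL and true LD25 0.20 mg/mL on a linear scale, with the grid
(0.02–0.20 mg/mL) spanning both. The truth is returned analytically from
the lines.

`gen_cohort` builds each embryo's areas as
`area(t) = baseline × g^((1−e)·t) × noise`, t in days, with growth factor
g = 2/day (a control xenograft roughly quadruples its relative area by
2 dpi), baseline lognormal with median 10⁴ arbitrary units and CV 30%,
multiplicative lognormal measurement noise with CV 15% (large enough that
trend tests need ~8–15 embryos, matching practice), dropout 10% per day
(≈ 81% of embryos still contribute the 2 dpi endpoint in expectation, the
scale of attrition seen in practice), and 8 embryos per group. The treatment effect e ∈ [0, 1] multiplies log-growth; unless
effects are supplied explicitly, each patient × regimen is a responder
with probability 0.5, drawing e from U(0.35, 0.9), else from U(0, 0.15) —
a bimodal distribution chosen because drug regimens tend to either work or
not in a given tumor, and it keeps truth labels away from the 30%
classification boundary that a unimodal effect distribution would straddle.
Ground-truth labels come from the noise-free decrease
`100·(1 − g^(−2e))`.

What the generator does *not* emulate: with e ≤ 1 the treated graft can at
worst stop growing, never shrink, so at g = 2 the maximum noise-free
decrease is 75% and the generator never produces a CR truth label —
CR logic is exercised on constructed classifier inputs instead. It also
has no correlation between regimens within a patient, no time-varying
effects, and no informative dropout. Passing simulation tests therefore
demonstrate correct recovery of this growth-attenuation structure, not
performance on real image-derived areas.

## Problem sizes and determinism

Simulation-based checks (IC50 recovery, responder-label recovery) use 200
generator seeds at the default scales above; both the test suite and the
acceptance script derive all randomness from explicit seeds and are
reproducible run to run. The dose-conversion and MTD computations are
fully deterministic.

## Known limitations

* The straight-line dose-response model is only sensible within the tested
  concentration range; extrapolated IC50/LD25 values are flagged but used.
* The MTD percentile rule is a convention, not an estimator with standard
  errors; no uncertainty is propagated into the ED.
* Response calls on group means ignore within-group variance; the Dunnett
  diagnostics are reported alongside precisely because a call can rest on
  few embryos.
* The packaged reference summary mixes rounding conventions in its ratio
  columns (see Dose conversion above); exact cell-level reproduction from
  the rounded inputs is not possible in general.
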