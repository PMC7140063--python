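# fishdose

Zebrafish embryos xenotransplanted with a patient's tumor tissue
("zebrafish avatars") can screen that patient's chemotherapy options in
under a week — but only if the human dose can be translated into a
fish-water concentration. Allometric interspecies scaling does not apply,
because the drugs are dissolved in the water rather than injected.
`fishdose` implements the dose-equivalence criterion and the downstream
chemosensitivity analysis for this setting, for biologists and
biostatisticians running embryo safety assays and patient-derived-xenograft
(PDX) trials.

## The model

For a reference patient (body surface area BSA = 1.8 m², blood volume
V = 5.4 L), each drug's **equivalent plasma concentration** is

    EPC = M / V,        M = clinical dose (mg/m²) × BSA

in mg/mL. The **safety study** exposes embryos to concentration series of
each regimen (drug masses mixed at the human ratios), scores phenotypes
(normal / aberrant / dead), and fits straight incidence lines on a linear
or log10 concentration scale (whichever gives the higher R²). Inverting the
lines yields IC50 (50% loss of normal phenotype) and LD25 (25% mortality),
and the dimensionless exposure ratios EPC/IC50 and EPC/LD25. The **maximum
tolerated dose** is the percentile rule

    MTD = max( P75(EPC/IC50), P75(EPC/LD25) )

with P75 the 75th percentile (rank = 0.75·(n+1), linear interpolation)
across regimens. The **equivalent dose** ED is the largest dilution factor
above the MTD that still shows efficacy in xenografted embryos, and the
fish-water concentration of every drug is

    c_fish = (M / V) / ED.

The **response analysis** normalises each xenograft's stained tumor area to
its 2 hpi baseline (relative area), tests within-group growth by one-way
repeated-measures ANOVA, compares treated groups to control by one-way
ANOVA with Dunnett's test, and classifies each patient × regimen with a
RECIST-adapted rule on the 2 dpi / 2 hpi group means: partial response
(PR) at ≥ 30% decrease versus control, complete response (CR) at ≥ 90%
(thresholds inclusive; CR counts as PR in cohort rates).

A seeded synthetic-data module generates safety assays (trinomial
phenotype draws from true incidence lines) and PDX cohorts (multiplicative
area growth with treatment-dependent attenuation, lognormal noise and
embryo dropout) together with their ground truth, so every stage is
testable end to end.

## Worked example

```bash
$ fishdose mtd
75th percentile EPC/IC50 = 4.065 (rounded 4.1)
75th percentile EPC/LD25 = 4.515 (rounded 4.5)
MTD = 4.5
```

The two ratio columns of the packaged ten-regimen safety table have 75th
percentiles 4.065 and 4.515; rounded to one decimal and maximised they give
MTD = 4.5 — dilution factors at or below 4.5 are unsafe for the embryos.

```bash
$ fishdose ed --mtd 4.5 --candidates 8:ineffective,5:effective
ED = 5
```

Of the screened dilution factors above the MTD, 8 showed no efficacy and 5
did, so the equivalent dose is 5.

```bash
$ fishdose cfish --regimen GEM/nab-P --ed 5
Gemcitabine     0.0666667 mg/mL
nab-Paclitaxel  0.00833333 mg/mL
```

Gemcitabine's EPC (1000 mg/m² × 1.8 m² / 5400 mL = 0.333 mg/mL) divided
by ED = 5 gives the fish-water concentration 0.0667 mg/mL; the 8:1
gemcitabine:nab-paclitaxel mass ratio is preserved.

```bash
$ fishdose simulate cohort --seed 7 -o cohort.csv
truth labels written to cohort.truth.csv
$ fishdose classify cohort.csv --calls-csv calls.csv
C001    5-FU    21.4% decrease  NR
C001    FOLFIRI 64.0% decrease  PR
C001    FOLFOX  -11.8% decrease NR
C001    FOLFOXIRI       60.1% decrease  PR
...
$ fishdose cohort calls.csv
  regimen  n_patients  pct_pr  pct_cr
     5-FU           8    25.0     0.0
  FOLFIRI           8    75.0     0.0
   FOLFOX           8    37.5     0.0
FOLFOXIRI           8    62.5     0.0
```

`classify` prints one call per patient × regimen (percent decrease of the
treated group's mean 2 dpi/2 hpi relative area versus control, and the
CR/PR/NR call); `cohort` tabulates %PR and %CR per regimen. A decrease of
21.4% misses the 30% partial-response threshold (NR), while FOLFIRI's 64%
decrease clears it (PR); negative decreases mean the treated group grew
faster than control.

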