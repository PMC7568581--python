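# Methods

## The problem

`nutrisurf` implements a geometric-framework (GF) nutritional analysis
for a two-group mouse feeding experiment: control females versus
DHT-induced PCOS-model females, each confined to one of ten diets that
vary systematically in the fraction of metabolizable energy from
protein (P), carbohydrate (C) and fat (F). The questions the analysis
answers are (i) how each phenotype responds to the three-dimensional
macronutrient *intake* space (kJ/day of P, C and F), (ii) where in that
space the two groups respond differently, and (iii) how total food and
energy intake respond to diet *composition* (the P:C:F energy
proportions on the simplex).

## Response surfaces

For one outcome and one group, the model is a GAM

    g(E[y_i]) = f(P_i, C_i, F_i)

with `f` a single three-dimensional smooth and `g` the link. Intake
coordinates are cage averages assigned to every mouse in the cage
(macronutrient intake is measured per cage; all other outcomes are
individual).

**Why a 3-D smooth, not an additive one.** The biology of interest is
interactive: the ovulation-permissive region is a joint window in C and
F. A sum of univariate smooths cannot place a bump at a (C, F)
combination, so the smooth must be genuinely multidimensional.

**Basis.** Low-rank thin-plate spline: radial basis functions
`phi(r) = -r / (8*pi)` (the Green's function of the second-order
thin-plate penalty in three dimensions) centred on knots at the
observed intake coordinates, plus an unpenalized linear polynomial in
(P, C, F). Axes are standardized before the radial construction. The
polynomial side conditions are absorbed by projecting the radial
coefficients onto the null space of the constraints, turning the
bending energy into an ordinary positive-semidefinite quadratic
penalty. Knots are capped at 50 (so at most 54 coefficients); when
there are more distinct intake points than that, knots are chosen by
farthest-point sampling, which is deterministic and produces nested
knot sets. Axes with zero variance (possible in constructed test data)
are dropped from the polynomial block.

**Families.** `gaussian-identity`; `gaussian-log` (Gaussian fit to the
log-transformed outcome, so the latent scale is log outcome);
`negbin-log` for counts (corpora lutea). `family="auto"` fits the
identity-link model and switches to the log transform when a
Shapiro-Wilk test on the residuals rejects normality at alpha = 0.05
and the outcome is positive — a concrete rule for the usual
"log-transform if not normal" convention, overridable per outcome.

**Fitting.** Penalized IRLS. The smoothing parameter lambda is chosen
by a bounded search in log10(lambda) minimizing GCV,
`n * D / (n - edf)^2`, for Gaussian fits (scale unknown) and UBRE,
`D + 2 * edf` with the scale fixed at 1, for count fits — deviance-GCV
with a known-scale family rewards interpolating zero counts, which
inflates the latent variance exactly where counts are sparse. A REML
criterion would add substantial machinery without changing any
qualitative behaviour tested here. The negative-binomial dispersion alpha is
estimated by outer profile likelihood: a moment estimate seeds a
bounded search of log10(alpha), refitting the penalized model at each
candidate, after which lambda is re-selected at the chosen alpha.
Non-convergence raises a flagged error with diagnostics; it is never
silent. Pointwise standard errors come from the penalized coefficient
covariance `scale * (X'WX + lambda*S)^-1` (scale = deviance/(n-edf)
for Gaussian fits, 1 for negative binomial).

**Slices and support.** Surfaces are reported as 2-D slices: two free
nutrient axes on a 51x51 grid (configurable), the third fixed at the
median of the training intakes. The in-support region is the convex
hull of the free-axis coordinates of observations lying within a band
of +/- 25% of the fixed axis's IQR around the median (widened stepwise
if fewer than three distinct points fall in it). Cells outside the
hull are masked and carry NaN, never an extrapolated value.

## Surface subtraction

On a shared slice geometry (grid spanning the pooled training ranges,
fixed axis at the pooled median), the two group surfaces are compared
cell by cell on the latent scale:

    d = y1 - y2
    SE_d = sqrt(SE1^2 + SE2^2)
    CFL  = d +/- q * SE_d

with `q` the two-sided standard normal quantile — 1.96, 2.58, 3.29 at
95, 99, 99.9% (the conventional two-decimal presentation roundings are
returned at exactly those levels; any other level uses the exact
quantile). A cell is significant when the interval excludes zero.
Masks are intersected: a cell inside only one fit's support is
dropped. Back-transformation happens after the interval logic; the
displayed raw difference is the difference of back-transformed means.
The limits are pointwise — no familywise or false-discovery adjustment
across cells, matching standard GF practice.

Because the SEs ignore smoothing-parameter uncertainty and cells are
spatially correlated, the realized null per-cell significance rate is
only approximately nominal; the null-calibration check asserts the
mean rate over 200 identical-process cohort pairs lies in [2%, 10%]
at the 95% level rather than exactly 5%.

## Mixture (composition) models

Food and energy intake respond to diet composition, modeled with
Scheffe canonical polynomials (no intercept) on the energy-proportion
simplex: linear (3 coefficients), quadratic (6), special cubic (7),
fitted by ordinary least squares on cage-level data and selected by
small-sample-corrected AIC. Compositions below 5% of a component are
allowed (the design has no pure vertices); no pseudo-component
transformation is applied.

## Group statistics

Pooled-across-diet contrasts follow the study's conventions: per-group
Shapiro-Wilk (alpha = 0.05) gates Student's t (both groups normal)
versus Mann-Whitney (either non-normal — the conservative direction);
proportions use Fisher's exact test; everything is two-sided and
reported as mean +/- SEM. The Mann-Whitney p-value is exact (mid-rank
permutation enumeration) when the pooled sample is at most 20, and the
tie-corrected normal approximation beyond that.

Derived metrics: percent time per estrous stage; completed cycles,
defined as an ordered traversal P -> E -> D with M optional between E
and D and arbitrary repetition inside a visited stage (metestrus is
brief and often missed in daily smears); trapezoidal GTT AUC over the
full 0-90 min series. Below-LOD (left-censored) hormone values are
substituted either by LOD/sqrt(2) (default for steroids, LODs
0.05 ng/ml for DHT and 0.01 ng/ml for testosterone) or by the lowest
detected value (used for LH/FSH); the method is switchable per
analysis.

## The synthetic cohort generator

The generator is first-class code: it encodes, as explicit mean
functions plus noise, the qualitative structure the analysis is meant
to recover, calibrated so that pooled group means land on the
study-scale summaries (control vs PCOS corpora lutea 4.5 vs 0.5; body
weight 21.7 vs 23.5 g; adiponectin 16806 vs 11221 ng/ml; cholesterol
53.1 vs 61.5 mg/dL; fasting glucose 8.8 vs 9.2 mmol/L).

* **Design.** Ten diets, protein 5-60% of energy with the C:F ratio
  varied across protein levels, all at 16 kJ/g. The published
  composition table is not in the main text, so this design is a
  stand-in chosen to span the intake region densely around low-protein
  compositions, where the permissive window sits. Ten mice per diet
  per group by default, cages of 3, intake shared exactly within cage.
* **Intake rule.** Protein leverage: `food_g = 2.2 - 0.35*ln(x_p)`
  + Gaussian cage noise (SD 0.12 g), identical in both groups, giving
  daily energy intakes of roughly 38-52 kJ/day.
* **Corpora lutea.** Negative binomial (size 3). Control mean 4.5
  everywhere; PCOS mean `0.05 + 4.5 * w(C, F)` where `w` is a smooth
  plateau — the product of logistic edges (scale 1.5 kJ/day) at
  C in [20, 30] and F in [15, 25] kJ/day. The plateau is smooth rather
  than a hard box so the mean function is representable by a spline
  surface.
* **Estrous sequences.** 11-day, four-state Markov chains: a cycling
  kernel (ordered P->E->M->D traversal, mean cycle ~5 days) for
  controls and, with probability `w(C, F)`, for PCOS mice; otherwise an
  absorbing-diestrus kernel in which P->E never occurs, so completed
  cycles are impossible.
* **Metabolic outcomes.** Body weight rises linearly with total energy
  intake with a PCOS excess largest at jointly low C and F; adiponectin
  rises with C in controls only; cholesterol rises with F in PCOS only;
  fasting glucose is flat and elevated in PCOS; GTT curves share one
  excursion shape over the fasting baseline in both groups. Steroids
  and gonadotropins are lognormal with configurable below-LOD
  probability.
* **Options.** The third-diet attrition of the original design (3
  completers per group instead of 10) is reproduced by an optional
  dropout rule, off by default. `noise_scale=0` plus `cl_size=None`
  gives the deterministic limit in which continuous outcomes equal
  their mean functions exactly — the basis of the parameter-recovery
  tests.

**What passing tests do and do not show.** The generator has exact
cage sharing, no between-mouse intake variation within cage, no
longitudinal weight trajectories, no endocrine feedback, and noise
that is exactly Gaussian/negative-binomial/lognormal by construction.
Tests against it demonstrate that the estimation machinery recovers
known structure at study-scale sample sizes; they cannot demonstrate
robustness to real-data features such as measurement error in intake,
cage-level random effects, or model misspecification.

## Numerical choices and problem sizes

* Composition sums tolerate +/- 0.5 percentage points (diet-sheet
  rounding); simplex points are renormalized to sum exactly 1.
* Smoothing search: log10(lambda) in [-5, 6], tolerance 0.15;
  dispersion search: log10(alpha) in [-3, 1.5], tolerance 0.05.
* The null-calibration check uses 200 replicate cohort pairs at 10
  mice/diet; window recovery uses 50 replicates at 20 mice/diet —
  sizes at which the Monte-Carlo error of the reported rates is well
  below the decision margins they are checked against.
* All randomness derives from one root seed through
  `numpy.random.SeedSequence` spawning; reruns are byte-identical,
  and figure output (SVG) is hash-salted with the seed so rendered
  artifacts are reproducible too.

## Known limitations

* Pointwise CFLs understate joint uncertainty across cells; the
  procedure is a mapping tool, not a whole-surface test.
* GCV/UBRE can undersmooth in small samples; the basis cap (50 knots)
  bounds the damage but a REML criterion would be the natural next
  step.
* No cage random effects: cage-mates are treated as independent given
  their shared intake, as in the source analysis convention.
* The diet design is synthetic; analyses of a real cohort should load
  the actual design table and per-mouse CSV through the documented
  schemas.
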