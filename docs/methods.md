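# Methods

## The experimental design being modelled

The unit of observation is a homogenate of four male flies assayed for
three NADPH-regenerating enzyme activities (G6PD, IDH, MEN), triglyceride
and carbohydrate concentrations, soluble protein, and body weight. Samples
come from a factorial cross design: for each gene series (G6pd, Idh, Men),
activity-variant alleles give a full-activity and a reduced-activity
genotype class; each genotype is crossed into seven iso-third-chromosome
backgrounds, replicated in two bottles, and exposed to four environmental
conditions (control, paraquat-induced oxidative stress, starvation,
desiccation), with four samples per bottle per condition. The complete
layout is 3 × 7 × 2 × 4 × 2 × 4 = 1,344 samples.

Units: activities are stored in the assay-report convention, µmol NADP⁺
reduced · min⁻¹ · µg-protein⁻¹ × 10,000, which is 10 × the
nmol · min⁻¹ · µg⁻¹ rate. Elasticity computations convert to the nmol scale
before taking logarithms (a fixed factor of 0.1); because a log-log slope
is invariant to multiplicative rescaling, this affects reported
intercepts/baselines only, never ε.

## Generative model

All variation is multiplicative (log-normal): activities are strictly
positive and the analysis statistic is defined on ln-transformed values.
For a sample in gene series *g*, background *b*, genotype *q*, bottle *k*,
condition *c*, with E₁ the perturbed enzyme:

    ln E₁ = μ₁ + δ₁(c) + B_b + K_k + [q = reduced]·ln r_g + e₁
    ln v  = μ_v + δ_v(c) + B′_bv + ε(g, v, c)·(ln E₁ − μ₁ − δ₁(c)) + e_v

- r_g — genotype reduction ratio; defaults are the measured values 0.418
  (G6pd), 0.459 (Idh), 0.688 (Men).
- ε(g, v, c) — the true elasticity, injected as a within-condition log-log
  slope anchored at the condition-specific mean of ln E₁ so condition main
  effects never leak into slope estimates.
- δ(c) — condition main effects on the log scale, zero for control by
  construction.
- B_b ~ N(0, sd_background²) is shared by every sample of a (gene series,
  background) pair, making per-background slopes meaningful; the response
  background effects B′ are drawn independently of B by default, with an
  optional correlation parameter (the covariance structure of background
  heterogeneity is not identified by the design).
- K_k ~ N(0, sd_bottle²) per bottle of a cross enters E₁; responses receive
  bottle variation only through the ε coupling.
- Per-cell RNG streams are keyed by hashing the design labels together with
  the master seed, so deleting one cell never shifts the draws of another,
  and identical (config, seed) give bitwise-identical tables.

Defaults (log-scale SDs): sd_background = 0.08, sd_bottle = 0.03,
sd_residual = 0.08 for enzymes, 0.20 for triglyceride, 0.15 for
carbohydrate; weight ≈ N(3.4, 0.3²) mg per 4-fly sample and protein
≈ 1500 ± 120 mg/L with a mild linear coupling to weight. These are chosen
as realistic assay-scale variability for this kind of enzyme panel;
covariates are deliberately uncoupled from activities so that
covariate-adjusted and raw contrasts agree in expectation.

The calibrated default configuration reproduces the published qualitative
sign pattern of the interaction matrix (e.g. compensatory, negative
ε(G6pd→MEN) under every condition, strongest under oxidative stress; raised
carbohydrate in low-IDH flies under every condition; raised IDH in low-MEN
flies). Where a percent response is printed, the default magnitude is
back-computed as ε = ln(1 + Δ)/ln r; elsewhere magnitudes are plausible
placeholders, documented as package defaults rather than published
estimates.

What the generator does *not* emulate: plate-reader kinetics, assay
nonlinearity and detection limits, genotype-by-background interaction in
the reduction ratio, correlated residuals between the five responses, and
any mechanistic NADP/NADPH pool model. Passing tests therefore demonstrate
that the estimators recover the truth of this hierarchical log-linear
world, not that real fly data satisfy it.

## Standardization

Technical duplicates are averaged (a lone replicate passes through; zero
replicates propagate NaN and the sample is excluded downstream with a
count). Specific activity is raw rate / protein in the assayed aliquot,
re-expressed in the ×10,000 µmol convention. Percent change versus control
is computed over full-activity (wild-type) genotypes pooled across series
and backgrounds; raw condition means are the default, ANCOVA least-squares
means (at covariate grand means) are a flagged option — the two coincide
here because covariates are uncoupled from activities.

## Estimation and gating

The ANCOVA is an explicit least-squares full-versus-reduced F test: fit
response ~ intercept + covariates (+ factor dummies), test the factor on
the variation remaining after the covariates (type-II style marginal test;
with a single factor and no interactions this equals the usual type-III
test for two levels). Zero-variance covariates are dropped (they carry no
information and would otherwise be collinear with the intercept); a
covariate genuinely collinear with the factor raises a degenerate-model
error; a response with no residual variation returns F = 0, p = 1.
Adjusted means are model predictions at covariate grand means. The
implementation is validated against statsmodels `anova_lm` (type II) and an
independent explicit normal-equation oracle to 1e-8 relative tolerance.

Per-background slopes regress sample-level points of both genotypes pooled
(the two-group-means secant slope is available as an option; with only two
genotype classes both readings of "the slope of the plot" are defensible).
Non-positive measurements are excluded from log-scale computation rather
than offset-shifted — offsets distort slopes, and the measured quantities
are positive by construction; a background needs ≥ 2 usable samples per
genotype to contribute. ε is the arithmetic mean of the per-background
slopes, SE = SD/√n_b; the gate is the genotype ANCOVA on the condition
subset with protein and weight covariates applied to all five responses.
Bottle is not modelled in the ANCOVA (an optional fixed effect can be added
by passing it as a covariate); backgrounds are pooled in the gate.

Gate behaviour under clustering: because genotype is balanced within every
background, background effects cancel in the genotype contrast but remain
in the error mean square, so with background heterogeneity switched on the
pooled gate is *conservative* (fires at well below nominal α). The
nominal-level calibration study therefore runs the generator in its iid
regime (all ε = 0, background and bottle SDs = 0), where the empirical
false-positive rate sits within a few thousandths of α = 0.05.

## Cross-condition comparison

The reduced/full ratio is computed from genotype-pooled arithmetic means on
the measurement scale (bottles and samples pooled before the ratio), one
record per (background, condition). The one-way ANOVA of ratio on condition
uses the same least-squares path as the ANCOVA; the complete default layout
gives df 3, 24. Published analyses of this design sometimes print a
denominator df of 27 — the total df of a 28-observation layout — so results
carry a note that the model's own residual df is reported. Pooling to one
number per background deliberately discards within-genotype replication,
making the comparison conservative.

Tukey HSD p-values come from the studentized-range distribution computed by
direct numerical integration: the range CDF is an inner Gauss–Legendre
integral over the normal location (160 nodes on [−8.5, 8.5]) and the
studentization an outer Gauss–Legendre integral in the pooled-SD factor
over its essential support with the exact χ density folded into the weights
(96 nodes, tails truncated at the 1e-14 quantiles). Agreement with
published critical values (e.g. q(0.05; 4, 24) = 3.901) and with an
independent implementation is at ~1e-9 absolute, well inside the 1e-6
target; the vectorised evaluation makes 10,000-simulation calibration
studies cheap. Unequal group sizes use the Tukey–Kramer scale
√(s²/2·(1/nᵢ+1/nⱼ)); a zero pooled variance yields p = 0 for differing
means and p = 1 otherwise. The 2-group case reduces exactly to the
pooled-variance t test via q = |t|√2.

## Validation studies and problem sizes

The package ships its own simulation studies (`nadphnet.validation`):

- **Recovery/coverage** — truth values {−0.8, −0.3, 0, +0.3} assigned
  cyclically across all 48 matrix cells, residual SD 0.1; per-cell bias of
  the mean estimate and pooled coverage of ε ± 1.96·SE. With 7 backgrounds
  the interval's theoretical coverage is P(|t₆| < 1.96) ≈ 0.90, and the
  empirical value lands there. The test suite runs 200 replicates; the
  acceptance script 50.
- **Gate calibration** — iid null regime, 10,000 cells in the test suite,
  ~2,000 in the script.
- **Tukey FWER** — 4 groups × 7 replicates under the complete null, 10,000
  simulations in the suite, 2,000 in the script.
- **Ratio fidelity** — pooled reduction ratios versus their configured
  values, Monte-Carlo bound 3·sd_residual/√(per-genotype n).
- **Sign recovery** — the default sign-pattern configuration in a low-noise,
  larger-n regime (residual SDs halved, 8 samples per bottle per condition);
  a replicate passes when every gated cell with nonzero truth carries the
  true sign (gated zero-truth cells are type-I gate events and carry no
  sign truth).

These sizes keep the full test suite at a few minutes and the acceptance
script near one minute on a single CPU.

## Known limitations

- No mixed-effects/REML estimation: background and bottle enter only
  through the design structure, and the gate is conservative under
  background heterogeneity (see above).
- ε magnitudes in the default configuration are calibrated to printed
  percent responses where available and are otherwise defaults; they should
  not be quoted as published estimates.
- The ANCOVA assumes additive covariate effects on the measurement scale
  while the generator is log-linear; with the default mild noise this
  mismatch is negligible, but it is a real approximation for strongly
  skewed responses.
- No multiple-testing correction across the 48 matrix cells, by design;
  users scanning the matrix for discoveries should apply their own.
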