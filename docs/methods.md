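# Methods

## Model family and fitting

Each trait is modeled as a quadratic polynomial in mean daily
temperature (MDT, °C) and daily light integral (DLI, mol·m⁻²·d⁻¹):

    f(MDT, DLI) = y0 + a·MDT + b·DLI + c·MDT² + d·DLI² + e·MDT·DLI

Predictors are deliberately left raw (uncentered) so that fitted
coefficients are directly comparable to the published coefficient table;
the collinearity this induces is tolerable at the design sizes involved
(condition numbers around 10⁷ still leave agreement with a brute-force
normal-equations solve at the 10⁻⁹ level, which the test suite checks).

Fits are ordinary least squares on per-plant observations at the
*realized* (not set-point) treatment environments, via `statsmodels`.
Standard errors and p-values come from the standard OLS covariance.
R² is computed as 1 − SSE/SST for every model; the distinction between
r² (univariate) and R² (surface) in published tables is notational only.
When the response is constant, SST is degenerate (detected relative to
the response's scale, not as exact zero) and R² is reported as 0 with a
`DegenerateVarianceWarning`. The underlying experiment is a split plot
(temperature is a whole-plot factor); the package fits a single-error
OLS, matching how the reference coefficient tables were produced, and
consequently the reported standard errors do not include a whole-plot
variance component — a known limitation, not a bug.

## Term selection and replication pooling

The published per-trait models are reduced forms (e.g. branch number of
purple basil depends on MDT only), but no selection procedure was
published. The package's `select_terms` uses backward elimination from
the six-term model at α = 0.05 (default, configurable) under the
marginality constraint: a main effect is never removed while its
quadratic or the interaction survives, and the intercept is never
removed. Because several published models retain terms that are not
significant at 0.05 (the purple basil fresh-mass MDT quadratic among
them), the pipeline also accepts an explicit term mask (`terms:
[y0, a, c]` in the YAML config, `--terms y0,a,c` on the CLI) so a
pinned model form can be reproduced exactly.

Replications grown at different times are pooled when the
replication × treatment-cell interaction is not significant: a two-way
ANOVA F-test (`statsmodels` `anova_lm`, type II) at the same α. With
identical replicates the interaction sum of squares is zero and the
data pool trivially.

## Colorimetry

Hue angle is computed by the quadrant-aware piecewise arctangent (equal
to atan2(b\*, a\*) mod 360°, which a property test verifies to 10⁻⁹ °);
on the a\* = 0 axis the continuous limit (90°/270°) is used, and hue is
undefined at the achromatic point, where batch processing flags the row
rather than aborting. Chroma is √(a\*² + b\*²). Observed purple-basil
hues fall in [0°, 127°] ∪ [300°, 360°), so before modeling, hues above
a threshold (default 300°, configurable for other crops) have 360°
subtracted, making the purple→green arc continuous on (−60°, 300°].
Hue surfaces are fitted on this transformed scale; reports add 360° to
negative values for display. Note that a fitted hue surface may predict
values below −60° at design corners — polynomial extrapolation on a
circular quantity, one reason predictions outside the observed range
should not be over-read.

## Optimum-environment curves

MDT_opt(DLI) = −(a + e·DLI)/(2c) and DLI_opt(MDT) = −(b + e·MDT)/(2d)
zero the respective partial derivatives. (The correct interaction
coefficient here is e; cross-checking four independently published
optima confirms this resolution of an ambiguity in the printed
derivative equation, which shows b where e is meant.) The curvature
matrix decides whether the stationary structure is a maximum, minimum
or saddle; univariate-quadratic models get a one-axis optimum with no
joint classification. Every evaluated optimum is compared against the
species' experimental MDT/DLI range and flagged when it exits — e.g.
purple basil's fresh-mass optimum (≈37.3 °C from the published
coefficients) lies beyond the tested 35 °C and is reported as an
extrapolation throughout, never clipped or hidden.

Published optima are reproduced within ±0.25 °C (or mol·m⁻²·d⁻¹): the
slack absorbs the rounding of printed coefficients from which the
optima are recomputed.

## Synthetic study generator

The generator emulates the split-plot structure of the reference study:

| parameter | default | rationale |
| --- | --- | --- |
| MDT set points | 23, 26, 29, 32, 35 °C | the five greenhouse compartments |
| DLI targets | 14, 10, 7 mol·m⁻²·d⁻¹ | realized means of the 0/30/50 % shade levels |
| replications × plants | 2 × 10 | 300 observations per trait |
| environment noise sd | 0.8 °C, 2.0 mol·m⁻²·d⁻¹ | spread of realized vs set-point environments across replications |

Environmental noise is drawn once per treatment cell (all plants in a
cell share one realized MDT/DLI — temperature is a whole-plot factor);
realized DLI is floored at 0.5 mol·m⁻²·d⁻¹. Plant-level noise is
Gaussian around the surface mean. Masses and counts are truncated at
zero (with a `TruncationWarning`), counts rounded to integers —
a rounded truncated-Gaussian rather than a Poisson model, which is
sufficient for validating the fitting chain. F_v/F_m and leaf mass
fraction are clipped to [0, 1].

Per-trait residual standard deviations were never published, so they
are calibrated from each reference model's R²:
sd_res = sd_signal · √((1 − R²)/R²), with sd_signal the standard
deviation of surface means over the default design grid. Simulated
studies therefore match the published signal-to-noise ratio by
construction; recovery tests validate the pipeline under realistic
noise, not the study's exact uncertainties. Truncation at zero biases
low-mean cells slightly upward, which is why slope-recovery sits near
(but inside) the 2 % unbiasedness bound checked in the tests.

Color is generated by inverse construction: transformed hue, chroma and
L\* are drawn from their surfaces, then a\* = C·cos(h), b\* = C·sin(h),
so the colorimetry path recovers the generating hue and chroma exactly
in the noise-free case — a round trip real colorimeter data cannot
offer. Color is generated for all 10 plants per cell by default (the
real study measured color on 5); this keeps every trait at 300
observations and is configurable downward.

Randomness is hierarchical: one study seed spawns an independent
substream per trait × replication (CRC-keyed `SeedSequence`), so adding
a trait or replication never perturbs the draws of the others, and
identical (design, truth, seed) give bit-identical tables.

When the same species × trait has several published reduced models, the
generator truth uses the row with the most terms (ties to higher R²) —
the MDT-quadratic fresh-mass and DLI-quadratic DMC models for purple
basil, matching the models the reference narrative leans on.

## Problem sizes in the stochastic checks

The Monte-Carlo coefficient-coverage check uses 500 regenerated
study-scale datasets (300 observations each); the end-to-end
optimum-curve recovery averages 100 studies; the cell-mean convergence
check uses 10⁴ plants per cell. These sizes give comfortable margins on
the assertions (coverage ≥ 99 % at ±3 se; seed-averaged optimum curve
within ±0.5 °C of truth) while keeping the full suite around ten
seconds.

## Known limitations

* Single-error OLS on pooled observations; no split-plot/mixed-effects
  variance structure, no weighted regression, no cross-validation.
* The quadratic is a local model around the optimum: extrapolated
  optima (flagged) and hue predictions at design corners should not be
  treated as physiology.
* One corrected transcription in the shipped reference table: the sweet
  basil node-number MDT² coefficient is stored as −3.8×10⁻³ (the
  printed −3.8×10⁻¹ is inconsistent with every reported node count and
  with its own standard error of 2.1×10⁻³).
* Count traits are not modeled as counts; fractions are fitted on the
  [0, 1] scale without a link function, again matching the reference
  analysis.
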