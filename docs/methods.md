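# Methods

This note documents the statistical models behind `comboscreen`, the
defaults they ship with, the numerical choices that matter, and what the
bundled simulators do and do not emulate.

## Plate normalization

Raw metabolic-assay absorbances are normalized per plate to the
arithmetic mean of the no-drug control wells, so viability is a
dimensionless fraction with 1 = no drug effect. Normalization is
scale-invariant by construction. Replicate wells at the same dose pair
are averaged with the arithmetic mean. Viabilities above 1 — genuine
drug-induced stimulation of metabolic rate is observed in some resistant
lines — are retained rather than clipped; a configurable cap (default
2.0) guards against gross outliers only.

The canonical combination design is a 7×7 dose cross in which each axis
is {0} ∪ {six three-fold dilutions from the drug-specific top dose}
(trametinib from 0.03 µM, partner drugs from 1 µM). Embedding the
zero-dose row and column places the single-agent margins inside the
grid, which the Bliss analysis needs at matched doses; a
`grid_axes="all_nonzero"` switch produces margin-free grids for designs
that measure single agents on separate plates.

## Hill model and IC50 censoring

Single-agent curves are fitted with the four-parameter log-logistic
(Hill) model

    v(c) = e_inf + (e0 − e_inf) / (1 + (c / IC50)^h)

by least squares on the log10-dose axis. Parameters and bounds: log10
IC50 free within [min dose / 10³, max dose × 10³]; slope h ∈ [0.05, 10]
(log-parameterized); e0 ∈ [0.5, 1.5] because normalized data can sit
slightly off 1 at low dose; e_inf ∈ [0, 1]. Optimization is L-BFGS-B
(gradient-based) from a deterministic multi-start grid — five log-spaced
IC50 starts across the tested range crossed with slope starts
{0.5, 1, 2} — with objective tolerance 1e-8 and ≤ 5000 iterations, so
the fit is deterministic for a given curve. Optional seeded random
extra starts are available.

**Censoring.** Inhibition is judged against the no-drug control
(viability 1), not against the fitted e0. If the fitted curve's minimum
viability over the tested dose range stays above 0.5, the drug never
achieved 50% inhibition there and the fit is censored: the reported IC50
becomes the lower bound max_conc (the raw optimizer estimate is kept in
`ic50_fitted` for diagnostics). This inequality propagates through every
downstream combination-index use.

**AUC.** Potency is also summarized as the trapezoidal integral of
viability over log10 concentration divided by the log10 dose span, so a
no-effect curve scores exactly 1 for any dose range and complete kill
scores 0. AUC is computed from the observed points, not the fit.

## Gaussian-process combination surface

Combination dose-response surfaces in patient-derived lines are too
irregular for low-order parametric response surfaces, so the 49-point
grid is modelled with an exact GP: squared-exponential kernel with one
length-scale per axis plus independent Gaussian noise, on inputs
log10(dose + offset). The zero-dose offset defaults to one tenth of the
smallest nonzero dose (zero has no log coordinate); it is configurable.
The observed viabilities are centred/scaled internally, which makes a
constant grid an exact fixed point (posterior ≡ the constant) flagged as
degenerate via near-zero signal variance.

Hyperparameters maximize the exact log marginal likelihood with L-BFGS
from a deterministic grid of four kernel initializations (length-scales
start equal on both axes, which also preserves posterior symmetry on
symmetric data); the restart with the highest evidence wins, and
per-start evidences are recorded so a no-regression check is mechanical.
With 49 training points exact inference is cheap and the variational
evidence lower bound coincides with the marginal likelihood, so nothing
is lost by optimizing the exact objective.

Prediction is deliberately confined to the measured dose box
([0, top_A] × [0, top_B]); queries outside raise an error. The screen
licenses interpolation, not extrapolated synergy claims.

**Iso-effect contours.** The dose pairs achieving a target inhibition on
the posterior mean are traced along 50 rays from the origin of the dose
box to its far edges: a 33-point coarse scan finds the first upward
crossing, bisection refines it to 1e-3 in inhibition (tolerance and ray
count configurable). If the surface's maximum inhibition over the box —
evaluated on a dense 41×41 grid — is below the target, the contour is
reported as not reached and no combination indices are calculated at
that level.

## Synergy scoring

**Chou–Talalay combination index.** At effect level xx,
CI = C_A/IC_xx,A + C_B/IC_xx,B with the printed two-term (mutually
exclusive) form; the non-exclusive cross-term is not added. IC_xx values
come from inverting each agent's Hill fit (inhibition relative to
control). A censored agent contributes its bound max_conc, making the CI
a lower bound; a non-censored fit whose lower asymptote never reaches
the target level is handled the same conservative way. CI is exactly
linear under joint dose scaling. The optimal regimen is the contour
point with the smallest fully computed CI over the searched levels
(default {0.25, 0.5, 0.75}); lower-bound CIs are excluded from the
minimum, and ties break toward the smaller total concentration. CI can
be evaluated either on GP contour points (default) or directly on
observed grid cells.

**Bliss beta.** The Bliss-expected inhibition of an interior cell is
e_ij = 1 − (1 − a_i)(1 − b_j) from the margin inhibitions; beta is the
least-squares slope through the origin of observed versus expected
inhibition over interior cells with e_ij > 0. This estimator is the
simplest one consistent with the published calibration — exactly 1 on
noise-free Bliss-independent data, > 1 synergistic, < 1 antagonistic —
but other calibrated estimators exist and would differ in noisy detail;
treat cross-study beta comparisons accordingly. Beta is invariant to
transposing the grid.

**Concordance.** Panel-level agreement between the frameworks is the
Spearman rank correlation (average ranks on ties) of betas against
minimum CIs, paired by drug pair × cell line; synergy moves the two
scales in opposite directions, so concordance is negative.

## RPPA differential affinity

Only antibodies validated by the array core are analysed; "use with
caution" and other statuses are dropped up front. Per antibody, drug vs
vehicle within a stratum (a timepoint, optionally crossed with
sensitivity class) is tested with the empirical-Bayes moderated t:
pooled two-sample variances s²_g with d residual df are shrunk toward a
prior variance s²_0 with d₀ prior df,

    s̃²_g = (d₀ s²_0 + d s²_g) / (d₀ + d),
    t_g = Δmean_g / (s̃_g √(1/n₁ + 1/n₂)),  df = d + d₀,

where (d₀, s²_0) are estimated by moment matching the distribution of
log s²_g (digamma/trigamma identities, Newton trigamma inversion).
When the observed spread of log-variances is no wider than chi-square
sampling noise the prior df is infinite and all variances shrink to the
geometric mean of the observed variances — chosen over the
bias-corrected alternative so that exactly identical variances are a
fixed point (moderated t = ordinary t). Setting prior df to 0 disables
shrinkage and reproduces the ordinary equal-variance t exactly. The
finite-prior path agrees with the Bioconductor reference implementation
to machine precision (verified in the test suite by invoking it through
Rscript on a small simulated matrix).

P-values are two-sided from the t distribution with d + d₀ df (normal
when d₀ is infinite); FDR control is Benjamini–Hochberg step-up with
monotonicity enforcement, significance at FDR < 0.05. Cross-stratum
reporting intersects significant sets per direction of change (up/down),
mirroring the usual Venn summaries. Samples are treated as unpaired by
default; the pooled per-timepoint analysis and the
sensitivity-stratified analysis are both expressed through the `stratum`
argument.

## Xenograft summaries

Tumor volume uses the ellipsoid approximation V = L·W²/2 (mm³);
measurements with width > length are swapped with a warning. Group
trajectories are summarized as mean ± SD with per-day n over surviving
animals (no imputation for dropouts). Treatment effect is the percent
reduction of group-mean volume versus vehicle, tested with an
equal-variance Student's t (Welch optional); a zero difference with zero
pooled variance is reported as t = 0, p = 1 rather than NaN.

## Cohort classification

A line is sensitive when its IC50 is below 20% of the cohort median
IC50. The median is taken over uncensored fits only (censored bounds
would bias it upward) and censored lines are always resistant, since
their bound exceeds any threshold below max_conc. The rule is invariant
to record order and to uniform rescaling of IC50s.

## Synthetic data: what it emulates, and what it does not

All generators run off a single seeded PCG64 stream; the same seed
reproduces the same dataset bit-for-bit, and every generator returns its
ground truth alongside the data.

* Viability noise is additive Gaussian on the viability fraction
  (default sd 0.05, truncated at 0) — a reasonable stand-in for
  post-normalization absorbance noise. Defaults mirror the screen
  designs: 13×3-fold single-agent series from 10 µM; 7×7 combination
  grids with trametinib from 0.03 µM and partner from 1 µM; margin Hill
  parameters IC50 0.1 and 0.5 µM at slope 1.
* Combination surfaces are generated exactly under Bliss independence,
  exactly under Loewe additivity (per-cell bisection on the effect
  level, tolerance 1e-8, ≤ 200 iterations; requires margins with e0 = 1,
  e_inf = 0), or with inhibition = min(1, (1+s) × Bliss) applied to
  combination cells only — margins keep their single-agent values.
* RPPA matrices are Gaussian log2 values around antibody-specific
  baselines with planted mean shifts (defaults: 1000 antibodies, 50
  planted, 1 log2-unit shift, noise sd 0.25, 3 per arm) in designated
  strata of the drug × timepoint × sensitivity design.
* Growth curves are exponential (baseline 350 mm³, rate 0.0145/day) with
  a multiplicative treatment effect and lognormal caliper noise
  (default sd 0.1), emitted as (L, W) pairs with W = 0.8 L.

Not emulated: plate spatial artifacts (edge effects), passage-to-passage
drift, RPPA spot-level imaging and normalization, correlated antibody
modules, tumor-growth saturation, and animal dropout mechanisms. Tests
passing on these simulations therefore validate the estimators'
correctness and calibration under their stated models, not robustness to
those real-data pathologies.

## Problem sizes and tolerances used in the test suite

Property checks use the sizes a desk-scale study would: 100 simulated
curves for IC50 recovery (median relative error < 10% at noise sd 0.05),
50 replicates for GP length-scale recovery (median within a factor of 2)
and for Bliss-beta calibration (mean within [0.9, 1.1] at noise sd
0.05), 20 seeds for FDR calibration and planted-antibody power, and
single GP fits per contour oracle (sham CI within 0.05; closed-form
contour within 2% in dose). Exact contracts (BH step-up, CI linearity,
the ordinary-t limit, the sensitivity rule) are asserted to floating
precision.

## Known limitations

* The Bliss beta estimator is a design choice calibrated only at the
  additive point; its sampling behaviour under strong antagonism with
  capped inhibition is asymmetric.
* Censored CI lower bounds are excluded from regimen selection rather
  than propagated as interval arithmetic.
* The GP assumes homoscedastic noise; replicate-derived heteroscedastic
  weights are not modelled.
* The moderated t assumes independent antibodies when estimating the
  variance prior; correlated antibody families make the prior df
  optimistic.
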