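# comboscreen

Analysis toolkit for high-throughput drug-combination viability screens
on patient-derived tumor cells, with companion statistics for RPPA
proteomics and xenograft efficacy studies. It targets the standard
workflow of a functional precision-oncology screen — e.g. a MEK-inhibitor
(trametinib) combination screen on head-and-neck squamous-cell carcinoma
cultures — where the questions are: which lines respond, which drug
pairs are synergistic, at which doses, and what changes on the protein
level.

## What it computes

* **Plate model** — well-level parsing (CSV + YAML layout config),
  normalization to no-drug control wells, geometric dilution series, and
  assembly of 7×7 combination dose grids with embedded single-agent
  margins.
* **Dose-response** — four-parameter Hill fits
  `v(c) = e_inf + (e0 − e_inf)/(1 + (c/IC50)^h)` by deterministic
  multi-start gradient-based least squares; drugs never reaching 50%
  inhibition are censored as `IC50 ≥ max_conc`; normalized AUC over
  log10 dose (1 = no effect).
* **Combination surface** — an exact Gaussian process (RBF kernel on
  log-doses, evidence-maximized hyperparameters) interpolates the
  measured dose box; iso-effect contours are traced on the posterior
  mean and refused when the effect level is never reached.
* **Synergy** — Chou–Talalay combination index
  `CI = C_A/IC_xx,A + C_B/IC_xx,B` along iso-effect contours with
  censoring propagated as CI lower bounds; the minimum-CI dose pair is
  the optimal regimen; Bliss beta (origin-constrained slope of observed
  vs Bliss-expected inhibition, 1 = additive) scores the same grid from
  the Bliss-independence side; Spearman rank correlation summarizes
  concordance of the two frameworks across a panel.
* **RPPA differential affinity** — validated-antibody filtering,
  empirical-Bayes moderated t-tests (limma-style variance shrinkage,
  reimplemented and cross-checked against the Bioconductor original),
  Benjamini–Hochberg FDR, and direction-stratified set overlaps.
* **PDX summaries** — tumor volumes `V = L·W²/2`, group mean ± SD
  trajectories with per-day n, percent reduction vs vehicle, Student's
  t-tests.
* **Cohort** — sensitivity classification by the `<20% of median IC50`
  rule and AUC-ranked cohort tables.
* **Simulators** — seeded generators for every input above with ground
  truth attached (Hill plates, Bliss/Loewe/synergy-multiplier surfaces,
  planted RPPA matrices, exponential growth cohorts).

## Worked example

Score a simulated 7×7 combination screen carrying a +30% synergistic
interaction (`examples/combination_synergy.py`):

```python
import comboscreen as cs

spec = cs.GeneratorSpec(seed=3, noise_sd=0.03,
                        surface_mode="synergy", synergy_strength=0.3)
grid, truth = cs.gen_combination_grid(spec)

beta = cs.compute_bliss_beta(grid)
surface = cs.fit_gp_surface(grid)
fit_a = truth["hill_a"].as_fit(max_conc=grid.doses_a[-1])
fit_b = truth["hill_b"].as_fit(max_conc=grid.doses_b[-1])
results = cs.ci_over_grid(surface, fit_a, fit_b, effect_levels=(0.25, 0.5, 0.75))
regimen = cs.min_ci_regimen(results)
```

Output:

```
Bliss beta      : 1.204  (> 1 synergy, 1 additive, < 1 antagonism)
CI evaluations  : 130 contour points
optimal regimen : 0.0241 + 0.4359 uM at 75% inhibition, CI = 0.371
```

The beta above 1 says the observed inhibition exceeds the Bliss
expectation built from the grid's own single-agent margins; the minimum
CI below 1 says the same dose pair is dose-sparing in Loewe terms — the
combination achieves 75% inhibition using a fraction of the
iso-effective single-agent doses — and `(0.0241, 0.4359) µM` is the
recommended operating point within the measured dose box.

The other `examples/` scripts cover single-agent fitting and AUC
(`single_agent_fit.py`), cohort sensitivity calls
(`cohort_classification.py`), RPPA differential analysis
(`rppa_differential.py`), and xenograft growth comparisons
(`pdx_growth.py`). Each prints the numbers it computes and a one-line
reading of them.

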