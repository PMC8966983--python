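"""Fit a single-agent dose-response curve and score its potency.

Simulates one 13-point three-fold dilution plate (10 uM top dose) for a
drug with known IC50, normalizes to the no-drug control wells, fits the
Hill model, and reports IC50 (with censoring status) and normalized AUC.
"""

import comboscreen as cs

spec = cs.GeneratorSpec(
    seed=7, noise_sd=0.05, hill_params={"drug_a": cs.HillParams(ic50=0.02, slope=1.2)}
)
wells, truth = cs.gen_single_agent_plate(spec, drug="drug_a")
viability = cs.normalize_to_control(wells)
points = [(w.conc_a, viability[w]) for w in wells if not w.is_control]
curve = cs.DoseResponseCurve("drug_a", "line_10004", points)

fit = cs.fit_hill(curve)
auc = cs.compute_auc(curve)

print(f"true IC50      : {truth['hill'].ic50:.4f} uM")
print(f"fitted IC50    : {fit.ic50:.4f} uM (censored: {fit.censored})")
print(f"Hill slope     : {fit.hill_slope:.2f}")
print(f"normalized AUC : {auc.auc:.3f}   (1 = no drug effect, 0 = complete kill)")
# The fitted IC50 should sit within a few percent of the simulated truth;
# AUC well below 1 marks this line as a responder.
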