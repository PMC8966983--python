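"""Differential-affinity analysis of a simulated RPPA experiment.

Plants 50 drug-responsive antibodies (out of 1000) in the 72 h stratum
only, runs validated-antibody filtering and the moderated t-test per
timepoint, and summarizes timepoint overlap of significant antibodies.
"""

import comboscreen as cs

spec = cs.GeneratorSpec(seed=11)
matrix, truth = cs.gen_rppa_matrix(
    spec, planted_strata=[{"timepoint": "72h"}], n_caution=25
)
matrix = cs.filter_validated(matrix)
print(f"antibodies after validated-only filter: {matrix.n_antibodies}")

results = {
    tp: cs.moderated_t_test(matrix, stratum={"timepoint": tp}) for tp in ("24h", "72h")
}
for tp, res in results.items():
    print(
        f"{tp}: {int(res['significant'].sum()):3d} significant at FDR < 0.05 "
        f"(prior df = {res.attrs['prior_df']:.1f})"
    )

report = cs.set_comparison(results)
up = report["up"]
print(
    f"up-regulated: {len(up['shared'])} shared, "
    f"{len(up['only:24h'])} at 24h only, {len(up['only:72h'])} at 72h only"
)
planted_found = len(set(truth["planted"]) & up["only:72h"])
print(f"planted late responders recovered as 72h-only: {planted_found}/50")
# Antibodies planted only at the late timepoint should surface almost
# exclusively in the 72h-only set, with the 24h analysis near-empty.
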