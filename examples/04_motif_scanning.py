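"""PWM scanning with exact p-values and set-level enrichment.

Plants a sharp 8-bp motif in 90% of foreground sequences and 2% of
background sequences, scans both strands with exact dynamic-programming
null p-values, and ranks the planted PWM among decoys with the
lognormal-background group test.
"""

from regulome import (lognormal_enrichment_table, qvalue_filter, random_pwm,
                      scan_pwm, simulate_sequences_with_motifs)

pwm = random_pwm("PLANTED", width=8, sharpness=40, seed=11)
decoys = [random_pwm(f"DECOY_{i}", width=8, seed=100 + i) for i in range(5)]
fore, back, truth = simulate_sequences_with_motifs(
    n_fore=100, n_back=100, pwm=pwm, plant_rate_fore=0.9,
    plant_rate_back=0.02, seed=4)

hits = qvalue_filter(scan_pwm(fore, pwm, p_thresh=1e-3), q_max=0.05)
print(f"planted instances: {len(truth)}; significant hits: {len(hits)}")
print(hits.head(3).to_string(index=False))

table = lognormal_enrichment_table(fore, back, [pwm] + decoys)
print(table[["pwm_id", "p", "significant"]].to_string(index=False))

# Hit p-values are exact tail probabilities of the discretized
# log-odds score under the background model; the enrichment table
# should rank PLANTED first with p far below the 1e-3 cut-off while
# the decoys stay non-significant.
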