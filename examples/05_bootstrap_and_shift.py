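"""Knockdown fold-change shifts and bootstrap set statistics.

Classifies genes into knockdown-increased (iDEG) / decreased (dDEG) /
independent classes from paired contrast tables, then shows the two
bootstrap nulls: set-overlap against a uniform draw and sign
concordance against a relabeling null.
"""

import numpy as np

from regulome import (concordance_bootstrap, fc_shift_classes,
                      overlap_bootstrap, simulate_de_tables)

de_si, de_ctrl, truth = simulate_de_tables(shift_magnitude=0.5,
                                           noise_sd=0.05, seed=1)
restrict = de_si.loc[de_si["padj"] < 0.05, "gene"]
shift = fc_shift_classes(de_si, de_ctrl, restrict, shift_thresh=0.25)
print(shift["class"].value_counts().to_string())

universe = de_si["gene"].tolist()
idegs = shift.loc[shift["class"] == "iDEG", "gene_id"].tolist()
planted = truth.loc[truth["class"] == "iDEG", "gene_id"].tolist()
boot = overlap_bootstrap(planted, idegs, universe, n_iter=1000, seed=1)
print(f"overlap observed={boot.observed:.0f} null_mean={boot.null_mean:.1f} "
      f"p={boot.p_empirical:.4g}")

signs_a = {g: "up" for g in planted}
signs_b = dict(zip(de_si["gene"], np.where(de_si["log2fc"] > de_ctrl["log2fc"],
                                           "up", "down")))
conc = concordance_bootstrap(signs_a, signs_b, n_iter=10000, seed=1)
print(f"concordance observed={conc.observed:.2f} "
      f"null_mean={conc.null_mean:.2f} p={conc.p_empirical:.4g}")

# The planted iDEG set overlaps the recovered one far beyond the
# hypergeometric null mean, and its shift signs agree with the
# measured contrasts at a rate the relabeling null never reaches, so
# both empirical p-values sit at the resolution floor 1/(n_iter+1).
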