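"""Dual-criterion differential methylation on synthetic methylomes.

Simulates 500 regions (10-30 CpGs each, beta-distributed noise,
Poisson coverage) of which 50 carry a planted delta-beta of 0.4 in one
group, then runs the region test: binned chi-squared per group pair
plus Kruskal-Wallis across groups, both FDR-corrected, intersected.
"""

from regulome import region_diffmeth, simulate_methylomes

regions, tables, groups, truth = simulate_methylomes(
    n_regions=500, n_diff=50, delta_beta=0.4, coverage_mean=30, seed=1)
res = region_diffmeth(regions, tables, groups)

sig = res["significant"].to_numpy()
planted = truth["differential"].to_numpy()
power = sig[planted].mean()
fdp = (sig & ~planted).sum() / max(1, sig.sum())
print(f"regions flagged      : {int(sig.sum())} / {len(res)}")
print(f"sensitivity (planted): {power:.2f}")
print(f"false discovery prop : {fdp:.3f}")
print(res.loc[sig, ["name", "chi2_A_vs_B", "chi2_q_A_vs_B", "kw_q"]]
      .head(5).to_string(index=False))

# A delta-beta of 0.4 moves pooled beta-values across the 0.2/0.6 bin
# edges, so both criteria fire on essentially every planted region
# while the FDR intersection keeps false discoveries near zero.
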