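"""Differential DNA methylation: dual-criterion region test and
single-cytosine calls.

The region test declares a region differentially methylated only when
two independent criteria both survive FDR < 0.05 across regions:

1. for every pair of sample groups, a chi-squared test on the counts
   of pooled beta-values falling in the bins [0, 0.2), [0.2, 0.6),
   [0.6, 1.0];
2. a Kruskal-Wallis test on the raw beta-values across all groups at
   once.

Single-cytosine calls drop low-coverage records, average beta per
group per locus, and call a locus hyper-/hypomethylated when the group
mean difference reaches 0.15.  Note the deliberate asymmetry of the
0.2 boundary: the region-test binning puts beta = 0.2 in the middle
bin, whereas the three-level discretization used for summaries puts
0.2 in ``low`` — both conventions are kept exactly as defined, as two
distinct functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (DegenerateTableError, adjust_pvalues, chi2_independence,
                    kruskal_wallis)

__all__ = [
    "bin_beta_region",
    "discretize_beta",
    "region_diffmeth",
    "cytosine_diff",
    "category_enrichment",
    "motif_methylation_summary",
]

METH_COLUMNS = ["chrom", "pos", "strand", "context", "beta", "coverage"]

# region-test bins: [0, 0.2), [0.2, 0.6), [0.6, 1.0]
_REGION_BIN_EDGES = np.array([0.0, 0.2, 0.6, 1.0 + 1e-12])
REGION_BIN_LABELS = ["low", "medium", "high"]


def bin_beta_region(beta) -> np.ndarray:
    """Region-test binning: [0, 0.2) -> 0, [0.2, 0.6) -> 1, [0.6, 1] -> 2."""
    b = np.asarray(beta, dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("beta-values must lie in [0, 1]")
    return np.clip(np.digitize(b, [0.2, 0.6], right=False), 0, 2)


def discretize_beta(beta):
    """Summary discretization: low [0, 0.2], medium (0.2, 0.6], high (0.6, 1]."""
    b = np.asarray(beta, dtype=float)
    scalar = b.ndim == 0
    b = np.atleast_1d(b)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("beta-values must lie in [0, 1]")
    out = np.where(b <= 0.2, "low", np.where(b <= 0.6, "medium", "high"))
    return str(out[0]) if scalar else out


def _group_betas_in_region(tables: dict, groups: dict, chrom: str,
                           start: int, end: int, context: str,
                           min_cov: int, mode: str) -> dict[str, np.ndarray]:
    """Pooled beta observations per group for one region."""
    per_group: dict[str, list] = {}
    for sample, df in tables.items():
        grp = groups[sample]
        sub = df[(df["chrom"] == chrom) & (df["pos"] >= start)
                 & (df["pos"] < end) & (df["coverage"] >= min_cov)]
        if context is not None:
            sub = sub[sub["context"] == context]
        per_group.setdefault(grp, []).append(sub[["pos", "beta"]])
    out = {}
    for grp, parts in per_group.items():
        cat = pd.concat(parts, ignore_index=True)
        if mode == "pooled":
            out[grp] = cat["beta"].to_numpy(dtype=float)
        elif mode == "cytosine_mean":
            out[grp] = cat.groupby("pos")["beta"].mean().to_numpy()
        else:
            raise ValueError(f"unknown pooling mode {mode!r}")
    return out


def region_diffmeth(regions: pd.DataFrame, tables: dict, groups: dict,
                    context: str | None = "CpG", min_cov: int = 1,
                    alpha: float = 0.05, mode: str = "pooled") -> pd.DataFrame:
    """Dual-criterion differential methylation over regions.

    Parameters
    ----------
    regions : DataFrame with columns chrom, start, end (0-based
        half-open) and optionally name.
    tables : mapping sample id -> per-cytosine DataFrame with columns
        chrom, pos, strand, context, beta, coverage.
    groups : mapping sample id -> group label (>= 2 groups).
    context : cytosine context to keep (None = all).
    mode : 'pooled' pools every cytosine x sample observation per
        group; 'cytosine_mean' averages each cytosine across a group's
        samples first.

    Returns one row per region with the pairwise chi-squared p (and
    its per-pair FDR q across regions), the Kruskal-Wallis p/q, and
    ``significant`` = (min pairwise q < alpha) and (KW q < alpha).
    Regions with no covered cytosines in some group are flagged
    ``untestable`` and excluded from the FDR.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    pairs = [(a, b) for i, a in enumerate(group_names)
             for b in group_names[i + 1:]]

    recs = []
    for idx, reg in regions.reset_index(drop=True).iterrows():
        betas = _group_betas_in_region(
            tables, groups, reg["chrom"], int(reg["start"]), int(reg["end"]),
            context, min_cov, mode)
        rec = {
            "chrom": reg["chrom"], "start": int(reg["start"]),
            "end": int(reg["end"]),
            "name": reg.get("name", f"region_{idx}"),
        }
        if any(g not in betas or betas[g].size == 0 for g in group_names):
            rec["untestable"] = True
            recs.append(rec)
            continue
        rec["untestable"] = False
        for a, b in pairs:
            table = np.vstack([
                np.bincount(bin_beta_region(betas[a]), minlength=3),
                np.bincount(bin_beta_region(betas[b]), minlength=3),
            ])
            try:
                res = chi2_independence(table)
                stat, p = res.statistic, res.p
            except DegenerateTableError:
                # all observations in one bin for both groups: no evidence
                stat, p = 0.0, 1.0
            rec[f"chi2_{a}_vs_{b}"] = stat
            rec[f"chi2_p_{a}_vs_{b}"] = p
        kw = kruskal_wallis([betas[g] for g in group_names])
        rec["kw_stat"] = kw.statistic
        rec["kw_p"] = kw.p
        recs.append(rec)

    out = pd.DataFrame(recs)
    needed = ["kw_stat", "kw_p"] + [c for a, b in pairs
                                    for c in (f"chi2_{a}_vs_{b}",
                                              f"chi2_p_{a}_vs_{b}")]
    for col in needed:  # absent when every region was untestable
        if col not in out.columns:
            out[col] = np.nan
    testable = ~out["untestable"]
    for a, b in pairs:
        col = f"chi2_p_{a}_vs_{b}"
        out[f"chi2_q_{a}_vs_{b}"] = np.nan
        out.loc[testable, f"chi2_q_{a}_vs_{b}"] = adjust_pvalues(
            out.loc[testable, col].to_numpy(), method="bh")
    out["kw_q"] = np.nan
    out.loc[testable, "kw_q"] = adjust_pvalues(
        out.loc[testable, "kw_p"].to_numpy(), method="bh")
    qcols = [f"chi2_q_{a}_vs_{b}" for a, b in pairs]
    out["min_pair_q"] = out[qcols].min(axis=1)
    out["significant"] = testable & (out["min_pair_q"] < alpha) & (out["kw_q"] < alpha)
    return out


def cytosine_diff(group_a_tables, group_b_tables, min_cov: int = 7,
                  delta_beta: float = 0.15) -> pd.DataFrame:
    """Single-cytosine differential methylation between two groups.

    Records with coverage below ``min_cov`` are excluded; for each
    locus covered in at least one sample of each group the per-group
    mean beta is computed and delta = mean_B - mean_A classified as
    ``higher`` (delta >= delta_beta), ``lower`` (delta <= -delta_beta)
    or ``unchanged``.
    """

    def _pool(tables):
        kept = [t[t["coverage"] >= min_cov] for t in tables]
        cat = pd.concat(kept, ignore_index=True)
        return cat.groupby(["chrom", "pos"])["beta"].mean()

    mean_a = _pool(group_a_tables)
    mean_b = _pool(group_b_tables)
    both = mean_a.index.intersection(mean_b.index)
    a = mean_a.loc[both].to_numpy()
    b = mean_b.loc[both].to_numpy()
    delta = b - a
    cls = np.where(delta >= delta_beta, "higher",
                   np.where(delta <= -delta_beta, "lower", "unchanged"))
    out = pd.DataFrame({
        "chrom": [c for c, _ in both], "pos": [p for _, p in both],
        "mean_a": a, "mean_b": b, "delta": delta, "class": cls,
    })
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def category_enrichment(diff_categories, background_categories,
                        categories=None) -> dict:
    """Enrichment of differential cytosines across peak categories.

    ``diff_categories`` and ``background_categories`` are iterables of
    per-cytosine category labels (e.g. common / A_specific /
    B_specific).  Returns per-category percentages of each row, the
    log10 fold change of differential vs background percentage, and a
    chi-squared test on the 2 x k count table.  Categories with zero
    background are excluded.
    """
    diff = pd.Series(list(diff_categories))
    back = pd.Series(list(background_categories))
    if categories is None:
        categories = sorted(back.unique())
    back_counts = back.value_counts()
    kept = [c for c in categories if back_counts.get(c, 0) > 0]
    if len(kept) < len(list(categories)):
        import warnings
        warnings.warn("categories with zero background were excluded")
    d = np.array([int((diff == c).sum()) for c in kept])
    b = np.array([int(back_counts.get(c, 0)) for c in kept])
    pct_d = 100.0 * d / d.sum() if d.sum() else np.zeros(len(kept))
    pct_b = 100.0 * b / b.sum()
    with np.errstate(divide="ignore"):
        log10_fc = np.log10(np.where(pct_d > 0, pct_d, np.nan) / pct_b)
    test = chi2_independence(np.vstack([d, b]))
    return {
        "categories": kept,
        "pct_differential": pct_d,
        "pct_background": pct_b,
        "log10_fc": log10_fc,
        "chi2": test,
    }


def motif_methylation_summary(motif_hits: pd.DataFrame,
                              cytosines: pd.DataFrame) -> pd.DataFrame:
    """Mean methylation of cytosines under each TF's motifs.

    ``motif_hits`` carries columns tf, chrom, start, stop (0-based
    half-open intervals of motif occurrences); ``cytosines`` carries
    chrom, pos, beta (per-locus mean beta across samples).  A cytosine
    under several motifs of the *same* TF counts once for that TF; a
    cytosine under motifs of *different* TFs counts once per TF.
    """
    rows = []
    for tf, grp in motif_hits.groupby("tf", sort=True):
        seen: set[tuple] = set()
        for _, h in grp.iterrows():
            sub = cytosines[(cytosines["chrom"] == h["chrom"])
                            & (cytosines["pos"] >= h["start"])
                            & (cytosines["pos"] < h["stop"])]
            seen.update(zip(sub["chrom"], sub["pos"]))
        if not seen:
            rows.append({"tf": tf, "n_cytosines": 0, "mean_beta": np.nan,
                         "n_low": 0, "n_medium": 0, "n_high": 0})
            continue
        idx = pd.MultiIndex.from_tuples(sorted(seen), names=["chrom", "pos"])
        betas = cytosines.set_index(["chrom", "pos"]).loc[idx, "beta"].to_numpy()
        levels = discretize_beta(betas)
        rows.append({
            "tf": tf, "n_cytosines": len(betas),
            "mean_beta": float(np.mean(betas)),
            "n_low": int((levels == "low").sum()),
            "n_medium": int((levels == "medium").sum()),
            "n_high": int((levels == "high").sum()),
        })
    return pd.DataFrame(rows)
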