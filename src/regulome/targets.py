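"""TF target classification and knockdown fold-change statistics.

A regulator's putative targets (genes with a ChIP-seq peak in their
promoter) are classified as *activated* (expression positively
correlated with the regulator across a tumor cohort) or *repressed*
(negatively correlated), using a Pearson-|r| floor and a Bonferroni
significance limit.  Knockdown experiments enter in two ways: direct
intersection with differential-expression calls (primary targets), and
a fold-change *shift* between matched genotype contrasts run with and
without the knockdown, which splits genes into knockdown-increased
(iDEG), knockdown-decreased (dDEG) or knockdown-independent classes.
Empirical significance for set concordance/overlap comes from seeded
bootstrap nulls with the +1 / (n+1) p estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, pearson_with_p

__all__ = [
    "classify_targets",
    "primary_targets",
    "fc_shift_classes",
    "BootstrapResult",
    "concordance_bootstrap",
    "overlap_bootstrap",
    "variance_deciles",
    "correlate_with_signatures",
]

ACTIVATED = "activated"
REPRESSED = "repressed"
UNCLASSIFIED = "unclassified"


def classify_targets(target_genes, expr: pd.DataFrame, regulator: str,
                     r_thresh: float = 0.15,
                     alpha: float = 1e-4) -> pd.DataFrame:
    """Classify targets by expression correlation with the regulator.

    ``expr`` is a genes x samples matrix.  Each target gene is
    correlated (Pearson) with the regulator across samples; p-values
    are Bonferroni-corrected over the number of targets actually
    tested.  A gene is ``activated`` when r > r_thresh with adjusted
    p < alpha, ``repressed`` when r < -r_thresh with adjusted
    p < alpha, otherwise ``unclassified``.  Constant-expression targets
    are flagged and never tested.
    """
    if regulator not in expr.index:
        raise KeyError(f"regulator {regulator!r} absent from the matrix")
    reg = expr.loc[regulator].to_numpy(dtype=float)
    targets = [g for g in target_genes if g != regulator]
    missing = [g for g in targets if g not in expr.index]
    if missing:
        raise KeyError(f"targets absent from the matrix: {missing[:5]}...")
    rows = []
    for g in targets:
        y = expr.loc[g].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append({"gene_id": g, "r": np.nan, "p": np.nan,
                         "constant": True})
        else:
            r, p = pearson_with_p(reg, y)
            rows.append({"gene_id": g, "r": r, "p": p, "constant": False})
    out = pd.DataFrame(rows)
    tested = ~out["constant"]
    m = int(tested.sum())
    out["p_adj"] = np.nan
    if m:
        out.loc[tested, "p_adj"] = np.minimum(
            1.0, out.loc[tested, "p"].to_numpy() * m
        )
    cls = np.full(len(out), UNCLASSIFIED, dtype=object)
    sig = tested & (out["p_adj"] < alpha)
    cls[(sig & (out["r"] > r_thresh)).to_numpy()] = ACTIVATED
    cls[(sig & (out["r"] < -r_thresh)).to_numpy()] = REPRESSED
    out["class"] = cls
    return out


def primary_targets(chip_target_genes, de_table: pd.DataFrame,
                    padj_max: float = 0.05) -> dict[str, set]:
    """Intersect ChIP-bound genes with knockdown differential expression.

    Bound genes that go *up* after the knockdown (log2fc > 0,
    padj < padj_max) are the regulator's primary repressed targets;
    bound genes that go *down* are primary activated targets.
    """
    chip = set(chip_target_genes)
    de = de_table.set_index("gene") if "gene" in de_table.columns else de_table
    sig = de[(de["padj"] < padj_max) & de.index.isin(chip)]
    return {
        "repressed": set(sig.index[sig["log2fc"] > 0]),
        "activated": set(sig.index[sig["log2fc"] < 0]),
    }


def fc_shift_classes(de_si: pd.DataFrame, de_ctrl: pd.DataFrame,
                     restrict_to, shift_thresh: float = 0.25) -> pd.DataFrame:
    """Fold-change shift between knockdown and control contrasts.

    For each gene in ``restrict_to`` present in both tables,
    shift = log2fc(knockdown contrast) - log2fc(control contrast);
    shift > shift_thresh (strict) -> ``iDEG``, shift < -shift_thresh ->
    ``dDEG``, else ``independent``.  Genes missing from either table
    are dropped (count available via the ``dropped`` attribute on the
    returned frame's attrs).
    """
    si = de_si.set_index("gene") if "gene" in de_si.columns else de_si
    ct = de_ctrl.set_index("gene") if "gene" in de_ctrl.columns else de_ctrl
    genes = list(restrict_to)
    keep = [g for g in genes if g in si.index and g in ct.index]
    dropped = len(genes) - len(keep)
    shift = si.loc[keep, "log2fc"].to_numpy() - ct.loc[keep, "log2fc"].to_numpy()
    cls = np.where(shift > shift_thresh, "iDEG",
                   np.where(shift < -shift_thresh, "dDEG", "independent"))
    out = pd.DataFrame({"gene_id": keep, "shift": shift, "class": cls})
    out.attrs["dropped"] = dropped
    return out


@dataclass(frozen=True)
class BootstrapResult:
    observed: float
    null_samples: np.ndarray
    p_empirical: float
    n_iter: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_samples))


def _empirical_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + int((null >= observed).sum())) / (null.size + 1.0)


def concordance_bootstrap(signs_a: dict, signs_b: dict,
                          n_iter: int = 10000, seed: int = 1) -> BootstrapResult:
    """Sign-concordance of set A's genes in dataset B vs a sampling null.

    ``signs_a`` maps A's genes to 'up'/'down' (or +1/-1); ``signs_b``
    covers the measured universe.  The observed statistic is the
    fraction of A genes, restricted to those measured in B, whose signs
    agree.  Each null draw samples |A| genes without replacement from
    the universe and pairs A's sign multiset (fixed order) with the
    drawn genes' B signs.
    """
    a_genes = [g for g in signs_a if g in signs_b]
    if not a_genes:
        raise ValueError("no A genes measured in B")
    universe = np.array(sorted(signs_b))
    if len(a_genes) > universe.size:
        raise ValueError("|A| exceeds the measured universe")
    a_signs = np.array([signs_a[g] for g in a_genes])
    b_of_a = np.array([signs_b[g] for g in a_genes])
    observed = float((a_signs == b_of_a).mean())
    b_all = np.array([signs_b[g] for g in universe])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    k = len(a_genes)
    for i in range(n_iter):
        draw = rng.choice(universe.size, size=k, replace=False)
        null[i] = (a_signs == b_all[draw]).mean()
    return BootstrapResult(observed=observed, null_samples=null,
                           p_empirical=_empirical_p(observed, null),
                           n_iter=n_iter, seed=seed)


def overlap_bootstrap(query_set, reference_set, universe,
                      n_iter: int = 1000, seed: int = 1) -> BootstrapResult:
    """Overlap of two gene sets vs a uniform-draw null.

    The observed statistic is |query & reference|; each null draw takes
    |reference| genes uniformly without replacement from the universe
    and overlaps them with the query.  Empirical p is for enrichment.
    """
    uni = np.array(sorted(set(universe)))
    query = set(query_set) & set(uni)
    ref = set(reference_set) & set(uni)
    observed = float(len(query & ref))
    in_query = np.isin(uni, sorted(query))
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    k = len(ref)
    for i in range(n_iter):
        draw = rng.choice(uni.size, size=k, replace=False)
        null[i] = in_query[draw].sum()
    return BootstrapResult(observed=observed, null_samples=null,
                           p_empirical=_empirical_p(observed, null),
                           n_iter=n_iter, seed=seed)


def variance_deciles(expr: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Per-group decile boundaries of per-gene expression variance.

    ``groups`` maps sample (column) names to group labels.  For each
    group the sample variance (ddof=1) of every gene is computed and
    its nine interior decile boundaries (linear-interpolation
    quantiles) are returned as rows decile_1 .. decile_9.
    """
    out = {}
    labels = pd.Series(groups)
    for grp in sorted(labels.unique()):
        cols = labels.index[labels == grp]
        if len(cols) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        var = expr[list(cols)].var(axis=1, ddof=1).to_numpy()
        out[grp] = np.quantile(var, np.arange(1, 10) / 10.0, method="linear")
    return pd.DataFrame(out, index=[f"decile_{i}" for i in range(1, 10)])


def correlate_with_signatures(expr_of_genes: pd.DataFrame,
                              signature_scores: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each gene's expression with per-sample signature scores.

    ``expr_of_genes`` is genes x samples; ``signature_scores`` is
    samples x signatures.  Pearson r and p per (gene, signature) over
    the shared samples, BH adjustment across the whole matrix, and a
    significance mark at adjusted p < alpha.
    """
    shared = [s for s in expr_of_genes.columns if s in signature_scores.index]
    if not shared:
        raise ValueError("no shared samples between the two tables")
    rows = []
    for gene in expr_of_genes.index:
        x = expr_of_genes.loc[gene, shared].to_numpy(dtype=float)
        for sig_name in signature_scores.columns:
            y = signature_scores.loc[shared, sig_name].to_numpy(dtype=float)
            r, p = pearson_with_p(x, y)
            rows.append({"gene_id": gene, "signature": sig_name,
                         "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
    out["significant"] = out["q"] < alpha
    return out
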