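"""PWM motif scanning and motif-set statistics.

The scanner scores every offset of every sequence on both strands with
a log2-odds position weight matrix and converts scores to *exact* null
p-values: per-position scores are discretized to a fixed granularity
(1e-3 bits) and the full distribution of the window score under the
zero-order background model is obtained by dynamic programming
(convolution across positions), so the reported p equals the true tail
probability of the discretized score — the same number an exhaustive
enumeration of all 4^W words produces.

On top of the scanner sit the set-level statistics: BH q-value
filtering of hits, a lognormal-background group enrichment test on
per-sequence affinities, Fisher-exact group enrichment of motif
presence, the balanced-subsample ("n draws") procedure for unequal set
sizes, positional (central-window binomial) enrichment, hierarchical
clustering of peaks by their binary motif content, and a UPGMA
similarity tree of the PWMs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .stats import adjust_pvalues, fisher_exact_two_sided

__all__ = [
    "PWM",
    "pwm_from_counts",
    "gc_background",
    "ScoreDistribution",
    "score_distribution",
    "scan_pwm",
    "qvalue_filter",
    "sequence_affinity",
    "lognormal_set_enrichment",
    "lognormal_enrichment_table",
    "fisher_group_enrichment",
    "balanced_draw_enrichment",
    "MotifClustering",
    "cluster_peaks_by_motifs",
    "positional_enrichment",
    "pwm_similarity",
    "pwm_similarity_tree",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GRANULARITY = 1e-3  # bits per discretization unit of the exact-p DP

HIT_COLUMNS = ["pwm_id", "seq_id", "start", "stop", "strand", "score", "p"]


def gc_background(gc: float = 0.5) -> np.ndarray:
    """Strand-symmetric zero-order background from GC content."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    cg = gc / 2.0
    return np.array([at, cg, cg, at])


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities.

    ``probs`` has shape (4, W) with rows in A, C, G, T order; every
    column sums to 1.  Zero entries are representable (a raw count
    matrix normalized without pseudocount), but scanning and affinity
    scoring need finite log-odds and therefore require strictly
    positive entries — rebuild with a pseudocount first.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probs must have shape (4, W) with W >= 1")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if bg.shape != (4,) or (bg <= 0).any() or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a positive 4-vector summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2(p / background), shape (4, W); finite only when all
        probabilities are positive."""
        if (self.probs == 0).any():
            raise ValueError(
                f"PWM {self.id!r} contains zero probabilities; rebuild with "
                "a pseudocount for log-odds scoring")
        return np.log2(self.probs / self.background[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(
            id=self.id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )

    def with_background(self, background) -> "PWM":
        return PWM(id=self.id, probs=self.probs, background=background)

    def information_content(self) -> float:
        """Total information (bits) relative to the background."""
        return float((self.probs * self.log_odds()).sum())


def pwm_from_counts(pwm_id: str, counts, pseudocount: float = 0.01,
                    background=None) -> PWM:
    """Build a PWM from a 4 x W count (or probability) matrix.

    ``pseudocount`` is added per base before column normalization; a
    column of all zeros is an error when pseudocount is 0.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != 4:
        raise ValueError("counts must have shape (4, W)")
    if c.shape[1] < 1:
        raise ValueError("PWM width must be >= 1")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c + pseudocount
    sums = c.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("column of all zeros requires a positive pseudocount")
    probs = c / sums
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(id=pwm_id, probs=probs, background=bg)


# ---------------------------------------------------------------------------
# exact score null distribution


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the discretized window score under the
    zero-order background model.

    ``tail[i]`` is P(S >= min_score + i) where scores are integers in
    units of ``granularity`` bits.
    """

    min_score: int
    tail: np.ndarray
    granularity: float = GRANULARITY

    def pvalue(self, int_score: int) -> float:
        i = int_score - self.min_score
        if i < 0:
            return 1.0
        if i >= self.tail.size:
            return 0.0
        return float(self.tail[i])


def _int_scores(pwm: PWM, granularity: float = GRANULARITY) -> np.ndarray:
    return np.rint(pwm.log_odds() / granularity).astype(np.int64)


def score_distribution(pwm: PWM,
                       granularity: float = GRANULARITY) -> ScoreDistribution:
    """Exact null distribution of the total discretized score.

    Convolves the per-position score distributions under the PWM's
    background; exact up to the score discretization.
    """
    ints = _int_scores(pwm, granularity)
    bg = pwm.background
    min_total = int(ints.min(axis=0).sum())
    max_total = int(ints.max(axis=0).sum())
    size = max_total - min_total + 1
    dist = np.zeros(size)
    # running support: [cur_min, cur_min + cur_len)
    cur_min = 0
    cur = np.array([1.0])
    for j in range(pwm.width):
        col = ints[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(cur.size + (hi - lo))
        for b in range(4):
            off = int(col[b]) - lo
            new[off:off + cur.size] += bg[b] * cur
        cur = new
        cur_min += lo
    assert cur_min == min_total and cur.size == size
    dist = cur
    tail = np.minimum(1.0, np.cumsum(dist[::-1])[::-1])
    return ScoreDistribution(min_score=min_total, tail=tail,
                             granularity=granularity)


# ---------------------------------------------------------------------------
# scanning


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        code[arr == ord(base)] = idx
    return code


def _as_seq_dict(sequences) -> dict[str, str]:
    if isinstance(sequences, dict):
        return {str(k): str(v) for k, v in sequences.items()}
    out = {}
    for rec in sequences:  # Bio.SeqRecord or (id, seq) pairs
        if isinstance(rec, tuple):
            out[str(rec[0])] = str(rec[1])
        else:
            out[str(rec.id)] = str(rec.seq)
    return out


def scan_pwm(sequences, pwm: PWM, p_thresh: float = 1e-3,
             granularity: float = GRANULARITY) -> pd.DataFrame:
    """Scan sequences on both strands, keeping hits with exact p < p_thresh.

    Windows containing any non-ACGT character are skipped.  Reverse
    strand hits are scored with the reverse-complement matrix; their
    p-values come from that matrix's own exact null distribution (it
    coincides with the forward one whenever the background is
    strand-symmetric).  ``start``/``stop`` are 0-based half-open on the
    forward strand; ``score`` is in bits.
    """
    seqs = _as_seq_dict(sequences)
    W = pwm.width
    fwd_ints = _int_scores(pwm, granularity)
    fwd_null = score_distribution(pwm, granularity)
    rc = pwm.reverse_complement()
    rc_ints = _int_scores(rc, granularity)
    rc_null = score_distribution(rc, granularity)

    rows = []
    for seq_id, seq in seqs.items():
        code = _encode(seq)
        L = code.size
        if L < W:
            continue
        n_win = L - W + 1
        idx = np.arange(n_win)[:, None] + np.arange(W)[None, :]
        windows = code[idx]  # (n_win, W)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        wv = windows[valid]
        pos = np.arange(W)
        f_scores = fwd_ints[wv, pos].sum(axis=1)
        r_scores = rc_ints[wv, pos].sum(axis=1)
        offsets = np.nonzero(valid)[0]
        for strand, scores, null in (("+", f_scores, fwd_null),
                                     ("-", r_scores, rc_null)):
            for off, s in zip(offsets, scores):
                p = null.pvalue(int(s))
                if p < p_thresh:
                    rows.append(
                        (pwm.id, seq_id, int(off), int(off) + W, strand,
                         float(s) * granularity, p)
                    )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def qvalue_filter(hits: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """BH-adjust hit p-values over the whole batch; keep q < q_max."""
    if hits.empty:
        out = hits.copy()
        out["q"] = pd.Series(dtype=float)
        return out
    out = hits.copy()
    out["q"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
    return out[out["q"] < q_max].reset_index(drop=True)


# ---------------------------------------------------------------------------
# set-level enrichment


def sequence_affinity(seq: str, pwm: PWM) -> float:
    """Per-sequence motif affinity: log of the mean of 2^score over all
    valid positions on both strands (natural log)."""
    code = _encode(seq)
    W = pwm.width
    if code.size < W:
        raise ValueError("sequence shorter than the PWM")
    lods = [pwm.log_odds(), pwm.reverse_complement().log_odds()]
    scores = []
    n_win = code.size - W + 1
    idx = np.arange(n_win)[:, None] + np.arange(W)[None, :]
    windows = code[idx]
    valid = (windows >= 0).all(axis=1)
    wv = windows[valid]
    if wv.size == 0:
        raise ValueError("no valid (non-N) windows in sequence")
    pos = np.arange(W)
    for lo in lods:
        scores.append(lo[wv, pos].sum(axis=1))
    s = np.concatenate(scores) * math.log(2.0)  # nats
    return float(np.logaddexp.reduce(s) - math.log(s.size))


@dataclass(frozen=True)
class GroupEnrichment:
    pwm_id: str
    p: float
    foreground_mean: float
    background_mean: float
    background_sd: float
    n_foreground: int


def lognormal_set_enrichment(foreground_seqs, background_seqs, pwm: PWM,
                             p_thresh: float = 1e-3) -> GroupEnrichment:
    """Group enrichment of a motif in foreground vs background sequences.

    Affinities (log mean 2^score) are assumed normal across background
    sequences (lognormal on the affinity scale); the foreground group
    mean is tested against Normal(mu, sd^2 / n_foreground), upper tail.
    """
    fg = _as_seq_dict(foreground_seqs)
    bg = _as_seq_dict(background_seqs)
    if len(bg) < 30:
        raise ValueError("need >= 30 background sequences to fit the null")
    bg_aff = np.array([sequence_affinity(s, pwm) for s in bg.values()])
    mu, sd = float(bg_aff.mean()), float(bg_aff.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate background affinity variance")
    fg_aff = np.array([sequence_affinity(s, pwm) for s in fg.values()])
    stat = float(fg_aff.mean())
    z = (stat - mu) / (sd / math.sqrt(len(fg_aff)))
    p = float(sps.norm.sf(z))
    return GroupEnrichment(pwm_id=pwm.id, p=p, foreground_mean=stat,
                           background_mean=mu, background_sd=sd,
                           n_foreground=len(fg_aff))


def lognormal_enrichment_table(foreground_seqs, background_seqs, pwms,
                               p_thresh: float = 1e-3) -> pd.DataFrame:
    """Run the lognormal group test for every PWM; sorted by p."""
    rows = []
    for pwm in pwms:
        res = lognormal_set_enrichment(foreground_seqs, background_seqs, pwm,
                                       p_thresh)
        rows.append(
            {
                "pwm_id": res.pwm_id,
                "p": res.p,
                "foreground_mean": res.foreground_mean,
                "background_mean": res.background_mean,
                "background_sd": res.background_sd,
                "significant": res.p < p_thresh,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("p", kind="mergesort")
        .reset_index(drop=True)
    )


def fisher_group_enrichment(presence: pd.DataFrame,
                            group_labels) -> pd.DataFrame:
    """Per-motif Fisher exact test of presence between two groups.

    ``presence`` is a binary sequences x motifs table; ``group_labels``
    maps each sequence (row) to one of exactly two group names.  For
    every motif the 2x2 table (with/without motif x group) is tested
    two-sided; BH correction across motifs.
    """
    labels = pd.Series(group_labels)
    labels = labels.reindex(presence.index)
    if labels.isna().any():
        raise ValueError("every sequence needs a group label")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g0 = labels == groups[0]
    rows = []
    for motif in presence.columns:
        col = presence[motif].astype(bool)
        a = int((col & g0).sum())
        b = int((~col & g0).sum())
        c = int((col & ~g0).sum())
        d = int((~col & ~g0).sum())
        odds, p = fisher_exact_two_sided([[a, b], [c, d]])
        rows.append({"motif": motif, "odds_ratio": odds, "p": p,
                     "n_with_in_" + str(groups[0]): a,
                     "n_with_in_" + str(groups[1]): c})
    out = pd.DataFrame(rows)
    out["q"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
    return out


def balanced_draw_enrichment(large_set_seqs, small_set_size: int,
                             enrichment_fn, n_draws: int = 10,
                             seed: int = 1) -> list:
    """Balance unequal set sizes by repeated subsampling.

    Runs ``enrichment_fn`` (sequences -> iterable of significant motif
    ids) on the full large set and on ``n_draws`` uniform subsamples of
    ``small_set_size`` sequences; returns the motifs significant on the
    full set that are also significant in at least one draw (union over
    draws, intersected with the full-set result).
    """
    seqs = _as_seq_dict(large_set_seqs)
    ids = sorted(seqs)
    if small_set_size > len(ids):
        raise ValueError("small_set_size exceeds the sequence pool")
    rng = np.random.default_rng(seed)
    full = set(enrichment_fn(seqs))
    union: set = set()
    for _ in range(n_draws):
        chosen = rng.choice(ids, size=small_set_size, replace=False)
        union |= set(enrichment_fn({i: seqs[i] for i in chosen}))
    return sorted(full & union)


# ---------------------------------------------------------------------------
# clustering & positional statistics


@dataclass(frozen=True)
class MotifClustering:
    linkage: np.ndarray
    leaf_order: np.ndarray
    labels: list

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) in the original row order."""
        return fcluster(self.linkage, t=k, criterion="maxclust")


def cluster_peaks_by_motifs(matrix: pd.DataFrame) -> MotifClustering:
    """Hierarchically cluster peaks by their binary motif vectors.

    Euclidean distance between rows, complete linkage; scipy's
    deterministic ordering breaks ties by row index.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        return MotifClustering(
            linkage=np.empty((0, 4)),
            leaf_order=np.arange(X.shape[0]),
            labels=list(matrix.index),
        )
    Z = linkage(X, method="complete", metric="euclidean")
    return MotifClustering(linkage=Z, leaf_order=leaves_list(Z),
                           labels=list(matrix.index))


def positional_enrichment(hits: pd.DataFrame, seq_length: int, window: int,
                          n_pwms_tested: int,
                          evalue_max: float = 10.0) -> pd.DataFrame:
    """Central-window binomial enrichment per PWM.

    For each PWM, counts hits whose midpoint falls in the central
    ``window`` bp of the (fixed-length) sequences and tests the count
    against Binomial(n_hits, window / seq_length), upper tail; the
    E-value is p times the number of PWMs tested.
    """
    if window > seq_length:
        raise ValueError("window cannot exceed the sequence length")
    p0 = window / seq_length
    lo = (seq_length - window) / 2.0
    hi = (seq_length + window) / 2.0
    rows = []
    for pwm_id, grp in hits.groupby("pwm_id", sort=True):
        mid = (grp["start"].to_numpy() + grp["stop"].to_numpy()) / 2.0
        n = mid.size
        k = int(((mid >= lo) & (mid < hi)).sum())
        p = float(sps.binom.sf(k - 1, n, p0))
        e = p * n_pwms_tested
        rows.append({"pwm_id": pwm_id, "n_hits": n, "n_central": k,
                     "p": p, "evalue": e, "reported": e <= evalue_max})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PWM similarity tree


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    # Pearson correlation of two 4-vectors; 0 when either is constant
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_ungapped(p1: np.ndarray, p2: np.ndarray,
                   min_overlap: int) -> float:
    w1, w2 = p1.shape[1], p2.shape[1]
    best = -np.inf
    for shift in range(-(w2 - min_overlap), w1 - min_overlap + 1):
        s1, e1 = max(0, shift), min(w1, shift + w2)
        if e1 - s1 < min_overlap:
            continue
        cols1 = range(s1, e1)
        sims = [_column_corr(p1[:, j], p2[:, j - shift]) for j in cols1]
        best = max(best, float(np.mean(sims)))
    return best


def pwm_similarity(pwm_a: PWM, pwm_b: PWM, min_overlap: int = 4) -> float:
    """Best ungapped-alignment similarity of two PWMs.

    The similarity is the mean per-column Pearson correlation of base
    probabilities over the best-scoring overlap of at least
    ``min_overlap`` columns, considering both the given orientation and
    the reverse complement of the second matrix.
    """
    if pwm_a.width < min_overlap or pwm_b.width < min_overlap:
        raise ValueError(f"PWM width must be >= {min_overlap}")
    fwd = _best_ungapped(pwm_a.probs, pwm_b.probs, min_overlap)
    rev = _best_ungapped(pwm_a.probs, pwm_b.reverse_complement().probs,
                         min_overlap)
    return max(fwd, rev)


def pwm_similarity_tree(pwms, min_overlap: int = 4):
    """UPGMA tree over PWMs from ungapped-alignment similarities.

    Returns ``(tree, similarity)`` where ``tree`` is a scikit-bio
    TreeNode (serialize with ``str(tree)`` / ``tree.write``) and
    ``similarity`` a symmetric DataFrame of pairwise similarities.
    Distance is 1 - similarity, floored at 0.
    """
    pwms = list(pwms)
    if len(pwms) < 2:
        raise ValueError("need at least two PWMs")
    ids = [p.id for p in pwms]
    n = len(pwms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = pwm_similarity(pwms[i], pwms[j], min_overlap)
            sim[i, j] = sim[j, i] = s
    dist = np.maximum(0.0, 1.0 - sim)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, ids)
    return tree, pd.DataFrame(sim, index=ids, columns=ids)
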