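"""Synthetic inputs with planted, recoverable ground truth.

Every pipeline stage can be exercised without external data: replicate
ChIP-seq peak sets with coordinate jitter and a planted
common/A-specific/B-specific structure, grouped methylomes with
planted differentially methylated regions (beta-distributed noise,
Poisson coverage), an expression cohort in which designated targets
carry a planted Pearson correlation with a regulator gene, paired
differential-expression tables with planted fold-change shifts, and
sequences with motif instances planted at chosen rates.  All
generators are deterministic given their seed, and each returns the
truth alongside the data.

Default scales are deliberately desk-sized (hundreds of regions and
genes, not millions of cytosines) so that a complete pipeline run
finishes in minutes; effect sizes and thresholds follow the study
design the package implements (delta-beta 0.4 for planted regions,
target correlation 0.5, fold-change shift 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffmeth import METH_COLUMNS
from .motifs import PWM, pwm_from_counts
from .peaks import GenomicInterval, Peak

__all__ = [
    "simulate_peak_replicates",
    "simulate_methylomes",
    "simulate_expression_cohort",
    "simulate_de_tables",
    "simulate_sequences_with_motifs",
    "random_pwm",
]

BASES = "ACGT"


def simulate_peak_replicates(n_common: int, n_a: int, n_b: int,
                             genome: dict[str, int] | None = None,
                             jitter_sd: float = 20.0, seed: int = 1,
                             peak_length: int = 400,
                             spacing: int = 2000) -> tuple[dict, pd.DataFrame]:
    """Two conditions x two replicates of jittered peak calls.

    Base intervals of ``peak_length`` bp are placed non-overlapping,
    ``spacing`` bp apart; each replicate coordinate is the base
    coordinate plus rounded Gaussian jitter.  Common peaks appear in
    both conditions, specific peaks in one.

    Returns ``({"A": [rep1, rep2], "B": [rep1, rep2]}, truth)`` where
    truth lists every base peak with its planted category.
    """
    if min(n_common, n_a, n_b) < 0:
        raise ValueError("peak counts must be >= 0")
    if genome is None:
        genome = {"chr1": max(1, n_common + n_a + n_b) * spacing + spacing}
    n_total = n_common + n_a + n_b
    capacity = sum(max(0, (size - peak_length)) // spacing
                   for size in genome.values())
    if capacity < n_total:
        raise ValueError("genome too small to place the requested peaks")
    rng = np.random.default_rng(seed)
    slots = []
    for chrom in sorted(genome):
        n_slots = max(0, (genome[chrom] - peak_length)) // spacing
        slots.extend((chrom, i * spacing) for i in range(n_slots))
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    categories = (["common"] * n_common + ["A_specific"] * n_a
                  + ["B_specific"] * n_b)
    truth_rows = []
    base_peaks = []
    for k, (slot_idx, cat) in enumerate(zip(chosen, categories)):
        chrom, start = slots[slot_idx]
        base_peaks.append((chrom, start, start + peak_length, cat))
        truth_rows.append({"peak_id": f"peak_{k}", "chrom": chrom,
                           "start": start, "end": start + peak_length,
                           "category": cat})
    truth = pd.DataFrame(truth_rows)

    def _jitter(chrom, start, end):
        s = start + int(round(rng.normal(0, jitter_sd)))
        e = end + int(round(rng.normal(0, jitter_sd)))
        s = max(0, s)
        if e <= s:
            e = s + 1
        return Peak(interval=GenomicInterval(chrom, s, e),
                    summit=(s + e) // 2)

    out: dict[str, list[list[Peak]]] = {"A": [[], []], "B": [[], []]}
    for chrom, start, end, cat in base_peaks:
        conditions = {"common": ("A", "B"), "A_specific": ("A",),
                      "B_specific": ("B",)}[cat]
        for cond in conditions:
            for rep in (0, 1):
                out[cond][rep].append(_jitter(chrom, start, end))
    for cond in out:
        for rep in (0, 1):
            out[cond][rep].sort(key=lambda p: (p.chrom, p.start))
    return out, truth


def simulate_methylomes(n_regions: int = 500, n_diff: int = 50,
                        delta_beta: float = 0.4,
                        groups: dict[str, int] | None = None,
                        coverage_mean: float = 30.0,
                        concentration: float = 50.0,
                        cpgs_per_region: tuple[int, int] = (10, 30),
                        region_length: int = 1000, gap: int = 1000,
                        seed: int = 1):
    """Grouped methylomes with planted differential regions.

    Each region carries 10-30 CpGs; per cytosine x sample, beta ~
    Beta(mean * c, (1 - mean) * c) with concentration c and coverage ~
    Poisson(coverage_mean).  Baseline region means are uniform in
    [0.1, 0.5]; in the ``n_diff`` planted regions the *last* group's
    mean is shifted up by ``delta_beta``.

    Returns ``(regions, tables, group_map, truth)``: a region
    DataFrame, per-sample cytosine tables, the sample -> group map and
    the planted truth.
    """
    if groups is None:
        groups = {"A": 3, "B": 3}
    group_names = sorted(groups)
    if n_diff > n_regions:
        raise ValueError("n_diff cannot exceed n_regions")
    rng = np.random.default_rng(seed)
    base_means = rng.uniform(0.1, 0.5, size=n_regions)
    if delta_beta < 0 or (base_means.max() + delta_beta) > 1.0:
        raise ValueError("delta_beta pushes group means outside [0, 1]")
    diff_idx = np.sort(rng.choice(n_regions, size=n_diff, replace=False))
    is_diff = np.zeros(n_regions, dtype=bool)
    is_diff[diff_idx] = True

    starts = np.arange(n_regions) * (region_length + gap)
    regions = pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + region_length,
        "name": [f"region_{i}" for i in range(n_regions)],
    })
    n_cpg = rng.integers(cpgs_per_region[0], cpgs_per_region[1] + 1,
                         size=n_regions)
    cpg_pos = [np.sort(rng.choice(region_length, size=k, replace=False))
               + starts[i] for i, k in enumerate(n_cpg)]

    sample_group = {}
    tables: dict[str, pd.DataFrame] = {}
    for grp in group_names:
        for s in range(groups[grp]):
            sample_group[f"{grp}{s + 1}"] = grp

    shifted_group = group_names[-1]
    per_sample_rows: dict[str, list] = {s: [] for s in sample_group}
    for i in range(n_regions):
        for grp in group_names:
            mean = base_means[i]
            if is_diff[i] and grp == shifted_group:
                mean = mean + delta_beta
            a, b = mean * concentration, (1 - mean) * concentration
            for sample, g in sample_group.items():
                if g != grp:
                    continue
                betas = rng.beta(a, b, size=n_cpg[i])
                cov = rng.poisson(coverage_mean, size=n_cpg[i])
                for pos, beta, c in zip(cpg_pos[i], betas, cov):
                    per_sample_rows[sample].append(
                        ("chr1", int(pos), "+", "CpG", float(beta), int(c)))
    for sample, rows in per_sample_rows.items():
        tables[sample] = pd.DataFrame(rows, columns=METH_COLUMNS)

    truth = regions.copy()
    truth["differential"] = is_diff
    truth["base_mean"] = base_means
    truth["delta_beta"] = np.where(is_diff, delta_beta, 0.0)
    truth["shifted_group"] = np.where(is_diff, shifted_group, "")
    return regions, tables, sample_group, truth


def simulate_expression_cohort(n_samples: int = 100,
                               regulator: str = "REGULATOR",
                               n_activated: int = 50, n_repressed: int = 50,
                               n_null: int = 400, true_r: float = 0.5,
                               seed: int = 1):
    """Expression cohort with planted regulator-target correlations.

    The regulator is standard normal across samples; an activated
    target is ``r * regulator + sqrt(1 - r^2) * noise`` (repressed
    targets use ``-r``), nulls are independent noise.  Gene ids are
    assigned in shuffled order so they carry no class hints.

    Returns ``(expr, truth)``: genes x samples DataFrame (regulator
    included) and a gene -> planted class/true-r truth table.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if not abs(true_r) < 1:
        raise ValueError("|true_r| must be < 1")
    rng = np.random.default_rng(seed)
    n_genes = n_activated + n_repressed + n_null
    classes = (["activated"] * n_activated + ["repressed"] * n_repressed
               + ["null"] * n_null)
    rng.shuffle(classes)
    reg = rng.standard_normal(n_samples)
    rows = {regulator: reg}
    truth_rows = []
    width = len(str(n_genes))
    for i, cls in enumerate(classes):
        gene = f"G{i + 1:0{width}d}"
        noise = rng.standard_normal(n_samples)
        if cls == "activated":
            vals = true_r * reg + np.sqrt(1 - true_r ** 2) * noise
            r_planted = true_r
        elif cls == "repressed":
            vals = -true_r * reg + np.sqrt(1 - true_r ** 2) * noise
            r_planted = -true_r
        else:
            vals = noise
            r_planted = 0.0
        rows[gene] = vals
        truth_rows.append({"gene_id": gene, "class": cls,
                           "true_r": r_planted})
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return expr, pd.DataFrame(truth_rows)


def simulate_de_tables(n_genes: int = 1000, n_idegs: int = 100,
                       n_ddegs: int = 100, shift_magnitude: float = 0.5,
                       noise_sd: float = 0.05, seed: int = 1):
    """Paired contrast tables with planted log2 fold-change shifts.

    The control contrast draws log2fc ~ Normal(0, 1); the knockdown
    contrast adds +magnitude for planted iDEGs, -magnitude for planted
    dDEGs, plus Normal(0, noise_sd) noise.  Adjusted p-values for
    planted genes are assigned below 0.05 (differential-model fitting
    is out of scope); null genes draw padj uniformly.

    Returns ``(de_knockdown, de_control, truth)``.
    """
    if n_idegs + n_ddegs > n_genes:
        raise ValueError("planted classes exceed n_genes")
    rng = np.random.default_rng(seed)
    classes = np.array(["iDEG"] * n_idegs + ["dDEG"] * n_ddegs
                       + ["independent"] * (n_genes - n_idegs - n_ddegs))
    rng.shuffle(classes)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    fc_ctrl = rng.normal(0, 1, size=n_genes)
    shift = np.where(classes == "iDEG", shift_magnitude,
                     np.where(classes == "dDEG", -shift_magnitude, 0.0))
    fc_si = fc_ctrl + shift + rng.normal(0, noise_sd, size=n_genes)
    planted = classes != "independent"
    padj_si = np.where(planted, rng.uniform(1e-6, 0.049, size=n_genes),
                       rng.uniform(0, 1, size=n_genes))
    padj_ctrl = rng.uniform(0, 1, size=n_genes)
    de_si = pd.DataFrame({"gene": genes, "log2fc": fc_si, "padj": padj_si})
    de_ctrl = pd.DataFrame({"gene": genes, "log2fc": fc_ctrl,
                            "padj": padj_ctrl})
    truth = pd.DataFrame({"gene_id": genes, "class": classes,
                          "true_shift": shift})
    return de_si, de_ctrl, truth


def random_pwm(pwm_id: str, width: int = 8, sharpness: float = 10.0,
               seed: int = 1, background=None) -> PWM:
    """A random information-rich PWM (Dirichlet columns)."""
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(width):
        alpha = np.full(4, 0.2)
        alpha[rng.integers(4)] = sharpness
        cols.append(rng.dirichlet(alpha))
    return pwm_from_counts(pwm_id, np.array(cols).T, pseudocount=0.01,
                           background=background)


_COMPLEMENT = str.maketrans(BASES, "TGCA")


def simulate_sequences_with_motifs(n_fore: int, n_back: int, pwm: PWM,
                                   length: int = 200,
                                   plant_rate_fore: float = 0.8,
                                   plant_rate_back: float = 0.05,
                                   gc: float = 0.5, seed: int = 1):
    """FASTA-ready sequences with motif instances planted at set rates.

    Backgrounds are i.i.d. with the given GC content; with probability
    ``plant_rate`` a sequence receives one motif instance, sampled
    column-wise from the PWM, at a uniform offset on a uniform strand.

    Returns ``(foreground, background, truth)``: two id -> sequence
    dicts and a truth table of every planted (seq, offset, strand).
    """
    if not (0 <= plant_rate_fore <= 1 and 0 <= plant_rate_back <= 1):
        raise ValueError("plant rates must be in [0, 1]")
    if pwm.width >= length:
        raise ValueError("PWM width must be smaller than the sequence length")
    rng = np.random.default_rng(seed)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def _one(seq_id, rate, truth_rows):
        seq = "".join(rng.choice(list(BASES), size=length, p=base_p))
        if rng.random() < rate:
            inst = "".join(
                BASES[rng.choice(4, p=pwm.probs[:, j])]
                for j in range(pwm.width))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = inst.translate(_COMPLEMENT)[::-1]
            off = int(rng.integers(0, length - pwm.width + 1))
            seq = seq[:off] + inst + seq[off + pwm.width:]
            truth_rows.append({"seq_id": seq_id, "pwm_id": pwm.id,
                               "offset": off, "strand": strand})
        return seq

    truth_rows: list[dict] = []
    fore = {f"fg_{i:04d}": _one(f"fg_{i:04d}", plant_rate_fore, truth_rows)
            for i in range(n_fore)}
    back = {f"bg_{i:04d}": _one(f"bg_{i:04d}", plant_rate_back, truth_rows)
            for i in range(n_back)}
    return fore, back, pd.DataFrame(truth_rows,
                                    columns=["seq_id", "pwm_id", "offset",
                                             "strand"])
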