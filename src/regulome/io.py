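"""Readers and writers for the formats the pipeline touches.

BED3 / BED6 / narrowPeak peak files, six-column per-cytosine
methylation tables (chrom, pos, strand, context, beta, coverage),
plain-text PWM collections (HOCOMOCO-style ``>id`` blocks of counts or
probabilities), differential-expression tables and expression /
signature matrices.  All genomic records are 0-based half-open on
read and write; parse errors name the offending line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .diffmeth import METH_COLUMNS
from .motifs import PWM, pwm_from_counts
from .peaks import GenomicInterval, Peak, midpoint_summit

__all__ = [
    "read_peaks_bed",
    "write_peaks_bed",
    "read_methylation_table",
    "write_methylation_table",
    "read_pwms",
    "write_pwms",
    "read_de_table",
    "read_expression_matrix",
    "read_signature_scores",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    pass


def _parse_line(path, lineno, line, min_fields):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise ParseError(
            f"{path}:{lineno}: expected >= {min_fields} tab-separated "
            f"fields, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end <= start:
        raise ParseError(f"{path}:{lineno}: end ({end}) <= start ({start})")
    if start < 0:
        raise ParseError(f"{path}:{lineno}: negative start")
    return fields, start, end


def read_peaks_bed(path, dialect: str = "bed3") -> list[Peak]:
    """Read a peak file (0-based half-open BED coordinates).

    Dialects: ``bed3``, ``bed6`` (name/score/strand), ``narrowPeak``
    (10 columns; column 10 is the summit offset from the start, -1
    meaning unknown).  Without an explicit summit the interval
    midpoint is used.
    """
    min_fields = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[dialect]
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields, start, end = _parse_line(path, lineno, line, min_fields)
            chrom = fields[0]
            name = fields[3] if min_fields >= 6 else f"{chrom}:{start}-{end}"
            strand = fields[5] if min_fields >= 6 and fields[5] in "+-." else "."
            summit = midpoint_summit(start, end)
            if dialect == "narrowPeak":
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer summit offset") from exc
                if offset >= 0:
                    summit = start + offset
            peaks.append(Peak(interval=GenomicInterval(chrom, start, end, strand),
                              summit=summit, name=name))
    return peaks


def write_peaks_bed(peaks, path, dialect: str = "bed6") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "bed3":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            else:
                name = p.name or f"{p.chrom}:{p.start}-{p.end}"
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t"
                         f"{p.interval.strand}\n")


def read_methylation_table(path) -> pd.DataFrame:
    """Read a six-column per-cytosine methylation table.

    Columns: chrom, pos (0-based), strand, context (CpG/CHG/CHH),
    beta in [0, 1], coverage >= 0.  A header line is optional.
    Records are returned sorted by (chrom, pos).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=METH_COLUMNS, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=METH_COLUMNS)
    if len(df) and str(df.iloc[0]["pos"]) == "pos":  # header present
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=METH_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    df["beta"] = df["beta"].astype(float)
    df["coverage"] = df["coverage"].astype(int)
    bad_beta = df.index[(df["beta"] < 0) | (df["beta"] > 1)]
    if len(bad_beta):
        raise ParseError(
            f"{path}: beta outside [0, 1] at data row {bad_beta[0] + 1}")
    bad_cov = df.index[df["coverage"] < 0]
    if len(bad_cov):
        raise ParseError(
            f"{path}: negative coverage at data row {bad_cov[0] + 1}")
    bad_ctx = df.index[~df["context"].isin(["CpG", "CHG", "CHH"])]
    if len(bad_ctx):
        raise ParseError(
            f"{path}: unknown context at data row {bad_ctx[0] + 1}")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_methylation_table(df: pd.DataFrame, path) -> None:
    df[METH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_pwms(path, format: str = "counts", pseudocount: float = 0.01,
              background=None) -> list[PWM]:
    """Read a plain-text PWM collection.

    Each matrix starts with a ``>id`` header followed by numeric
    lines.  Orientation is inferred: W rows of 4 columns (positions as
    rows, HOCOMOCO-style, assumed for square 4x4 blocks) or 4 rows of
    W columns (bases as rows, A/C/G/T).  ``format='counts'`` applies
    the pseudocount before normalization; ``format='probabilities'``
    expects columns already summing to 1 (pseudocount still applied to
    guarantee finite log-odds).
    """
    if format not in ("counts", "probabilities"):
        raise ValueError(f"unknown PWM format {format!r}")
    blocks: list[tuple[str, list[list[float]]]] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = []
                blocks.append((line[1:].split()[0], current))
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: data before header")
                try:
                    current.append([float(x) for x in line.replace(",", " ").split()])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric entry") from exc
    pwms = []
    seen = set()
    for pwm_id, rows in blocks:
        if pwm_id in seen:
            raise ParseError(f"{path}: duplicate PWM id {pwm_id!r}")
        seen.add(pwm_id)
        m = np.array(rows, dtype=float)
        if m.ndim != 2 or m.size == 0:
            raise ParseError(f"{path}: matrix {pwm_id!r} is empty or ragged")
        if m.shape[1] == 4:       # positions as rows (incl. ambiguous 4x4)
            m = m.T
        elif m.shape[0] != 4:
            raise ParseError(
                f"{path}: matrix {pwm_id!r} has shape {m.shape}; need 4 rows "
                "or 4 columns")
        pwms.append(pwm_from_counts(pwm_id, m, pseudocount=pseudocount,
                                    background=background))
    return pwms


def write_pwms(pwms, path, digits: int = 6) -> None:
    """Write PWMs as probability matrices, positions as rows."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id}\n")
            for col in pwm.probs.T:
                fh.write("\t".join(f"{x:.{digits}f}" for x in col) + "\n")


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression table with columns gene, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    dups = df["gene"][df["gene"].duplicated()].unique()
    if len(dups):
        raise ParseError(f"{path}: duplicate gene ids: {list(dups)[:5]}")
    return df


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples matrix; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dups = df.index[df.index.duplicated()].unique()
    if len(dups):
        raise ParseError(f"{path}: duplicate gene ids: {list(dups)[:5]}")
    return df


def read_signature_scores(path) -> pd.DataFrame:
    """Samples x signatures score table; first column holds sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dups = df.index[df.index.duplicated()].unique()
    if len(dups):
        raise ParseError(f"{path}: duplicate sample ids: {list(dups)[:5]}")
    return df


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in seqs.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
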