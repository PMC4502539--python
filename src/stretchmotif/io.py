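"""Readers and writers for the external formats the pipeline touches.

Formats: BED3+, ENCODE narrowPeak (BED6+4), FASTA, bedGraph, MEME minimal
motif format, and TSV tables for SNPs, LD proxies, and TF expression.

Coordinate conventions are documented in :mod:`stretchmotif.intervals`:
everything is 0-based half-open internally. SNP catalogs that ship 1-based
positions should be converted with ``GenomeInterval.from_one_based_inclusive``
or by passing ``one_based=True`` to :func:`read_snp_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomeInterval, NarrowPeak

BASES = "ACGT"


class ParseError(ValueError):
    """A malformed record in an input file."""


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path, n_label_columns: int = 1
) -> list[tuple[GenomeInterval, tuple[str, ...]]]:
    """Read a BED3+ file, returning intervals with up to ``n_label_columns`` labels.

    Labels are the columns after the first three (commonly a chromatin-state
    name). Order of the file is preserved.
    """
    out: list[tuple[GenomeInterval, tuple[str, ...]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                iv = GenomeInterval(fields[0], start, end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            labels = tuple(fields[3 : 3 + n_label_columns])
            out.append((iv, labels))
    return out


def write_bed(
    path: str | Path,
    records: Iterable[tuple[GenomeInterval, Sequence[str]]] | Iterable[GenomeInterval],
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeInterval):
                iv, labels = rec, ()
            else:
                iv, labels = rec
            cols = [iv.chrom, str(iv.start), str(iv.end), *labels]
            fh.write("\t".join(cols) + "\n")


def read_narrowpeak(path: str | Path) -> list[NarrowPeak]:
    """Read a 10-column ENCODE narrowPeak file.

    Column 10 is the summit offset from the peak start; the ``-1`` sentinel
    (no summit called) falls back to the peak midpoint.
    """
    out: list[NarrowPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            try:
                iv = GenomeInterval(fields[0], int(fields[1]), int(fields[2]))
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if offset == -1:
                offset = iv.length // 2
            out.append(NarrowPeak(iv, offset, signal))
    return out


def write_narrowpeak(path: str | Path, peaks: Iterable[NarrowPeak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        ".",
                        "0",
                        ".",
                        f"{p.signal:g}",
                        "-1",
                        "-1",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    """Upper-case and map every non-ACGT character to N."""
    seq = seq.upper()
    table = str.maketrans({c: "N" for c in set(seq) - set(BASES)})
    return seq.translate(table)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into name -> sequence; sequences upper-cased, non-ACGT -> N."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA record {rec.id!r} in {path}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file into columns chrom/start/end/value."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(
    path: str | Path, records: Iterable[tuple[str, int, int, float]]
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

@dataclass
class MemeMotifRecord:
    """One motif from a MEME minimal format file."""

    name: str
    width: int
    matrix: np.ndarray  # width x 4 probabilities, columns A C G T
    nsites: int
    background: np.ndarray  # length-4 probabilities, A C G T

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.width < 1 or self.matrix.shape != (self.width, 4):
            raise ValueError(f"motif {self.name}: matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"motif {self.name}: matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-3):
            raise ValueError(f"motif {self.name}: background must sum to 1")


def read_meme_motifs(path: str | Path) -> list[MemeMotifRecord]:
    """Parse a MEME minimal format motif library.

    Probability rows must sum to 1 within 1e-3 and the alphabet must be DNA
    (ACGT). A missing "Background letter frequencies" block yields uniform
    0.25; a present one is attached to every motif in the file.
    """
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    out: list[MemeMotifRecord] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.upper().startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip().upper()
            if set(alpha) != set(BASES):
                raise ParseError(f"unsupported alphabet {alpha!r}; only ACGT supported")
            i += 1
        elif line.lower().startswith("background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {tokens[j].upper(): float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            if set(freq) != set(BASES):
                raise ParseError(f"{path}: background must list A C G T, got {sorted(freq)}")
            background = np.array([freq[b] for b in BASES])
        elif line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else f"motif_{len(out) + 1}"
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: MOTIF {name} has no probability matrix")
                i += 1
            if i >= n:
                raise ParseError(f"{path}: MOTIF {name} has no probability matrix")
            header = dict(
                zip(*(iter(lines[i].split(":", 1)[1].replace("=", " ").split()),) * 2)
            )
            width = int(header.get("w", 0))
            nsites = int(float(header.get("nsites", 20)))
            i += 1
            rows: list[list[float]] = []
            while i < n and len(rows) < width:
                stripped = lines[i].strip()
                if stripped:
                    rows.append([float(v) for v in stripped.split()])
                i += 1
            if len(rows) != width or any(len(r) != 4 for r in rows):
                raise ParseError(f"{path}: MOTIF {name}: expected {width} rows of 4 values")
            try:
                out.append(
                    MemeMotifRecord(
                        name=name, width=width, matrix=np.array(rows),
                        nsites=nsites, background=background,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
        else:
            i += 1
    # the shared background applies to every motif, including ones parsed
    # before the background block appeared
    for rec in out:
        rec.background = background
    return out


def write_meme_motifs(
    path: str | Path, records: Sequence[MemeMotifRecord]
) -> None:
    """Write motifs in MEME minimal format (single shared background)."""
    if not records:
        raise ValueError("no motifs to write")
    bg = records[0].background
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)),
        "",
    ]
    for rec in records:
        lines.append(f"MOTIF {rec.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {rec.width} "
            f"nsites= {rec.nsites} E= 0"
        )
        for row in rec.matrix:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# TSV tables: SNPs, LD proxies, expression
# ---------------------------------------------------------------------------

SNP_COLUMNS = ["rsid", "chrom", "pos", "trait", "pvalue"]
LD_COLUMNS = ["lead_rsid", "proxy_rsid", "chrom", "pos", "r2"]


def read_snp_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a GWAS catalog table (rsid, chrom, pos, trait, pvalue).

    Positions are 0-based unless ``one_based=True``. One rsid may appear under
    several traits; duplicate (rsid, trait) rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"SNP table {path} missing columns {sorted(missing)}")
    if df.duplicated(subset=["rsid", "trait"]).any():
        dup = df[df.duplicated(subset=["rsid", "trait"])]["rsid"].iloc[0]
        raise ParseError(f"duplicate SNP row for rsid {dup!r}")
    if one_based:
        df = df.assign(pos=df["pos"] - 1)
    return df


def read_ld_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read an LD proxy table (lead_rsid, proxy_rsid, chrom, pos, r2)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(LD_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"LD table {path} missing columns {sorted(missing)}")
    if one_based:
        df = df.assign(pos=df["pos"] - 1)
    return df


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene x cell RPKM table (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene row {dup!r} in expression table")
    return df.astype(float)


def write_expression_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene")
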