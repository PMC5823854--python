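"""Readers and writers for the on-disk formats used by the pipeline.

Formats: FASTA (genomes, amplicons), BED3/BED6 (peaks, motif placements),
MEME minimal motif format (PWMs), and tab-delimited tables for variant
pileups and read counts.  Round-trip (write then read) is the identity for
BED, variant tables and count tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import ALPHABET, GenomeSeq, Interval, PWM

_NON_ACGTN = re.compile("[^ACGTN]")


def read_fasta(path) -> list[GenomeSeq]:
    """Read a FASTA file into a list of :class:`GenomeSeq`.

    Lowercase letters are folded to uppercase and any character outside
    {A,C,G,T,N} is mapped to N.  Duplicate contig names and empty files
    are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        records.append(GenomeSeq(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[GenomeSeq], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.contig_name}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def read_meme_motifs(path, pseudocount: float = 1e-3) -> list[PWM]:
    """Parse PWMs from a MEME minimal motif file.

    Probabilities are regularized with the given pseudocount,
    (p + c) / (1 + 4c), then renormalized per position.  A probability row
    that does not sum to 1 within 0.01 *before* regularization is an
    error, as is an alphabet other than ACGT.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]

    alph = next((ln for ln in lines if ln.upper().startswith("ALPHABET")), None)
    if alph is not None and "".join(alph.split("=")[-1].split()) not in ("ACGT", "ACGU"):
        raise ValueError(f"unsupported alphabet line: {alph!r}")

    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith("MOTIF"):
            i += 1
            continue
        tokens = lines[i].split()
        motif_id = tokens[1] if len(tokens) > 1 else f"motif_{len(motifs) + 1}"
        tf_name = tokens[2] if len(tokens) > 2 else motif_id
        i += 1
        # skip to the letter-probability header
        while i < len(lines) and not lines[i].lstrip().startswith("letter-probability"):
            if lines[i].startswith("MOTIF"):
                raise ValueError(f"motif {motif_id!r} has no letter-probability matrix")
            i += 1
        if i == len(lines):
            raise ValueError(f"motif {motif_id!r} has no letter-probability matrix")
        i += 1
        rows = []
        while i < len(lines):
            stripped = lines[i].strip()
            parts = stripped.split()
            if not parts or not _is_number(parts[0]):
                break
            if len(parts) != 4:
                raise ValueError(
                    f"motif {motif_id!r}: expected 4 probabilities per row, "
                    f"got {len(parts)}"
                )
            row = [float(x) for x in parts]
            if abs(sum(row) - 1.0) > 0.01:
                raise ValueError(
                    f"motif {motif_id!r}: probability row sums to {sum(row):.4f}"
                )
            rows.append(row)
            i += 1
        if not rows:
            raise ValueError(f"motif {motif_id!r} has an empty matrix")
        motifs.append(
            PWM.from_probabilities(motif_id, np.array(rows), tf_name=tf_name,
                                   pseudocount=pseudocount)
        )
    if not motifs:
        raise ValueError(f"no MOTIF records in {path}")
    return motifs


def write_meme_motifs(pwms: Sequence[PWM], path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.tf_name or p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p)} "
                f"nsites= 100 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_bed(path) -> list[Interval]:
    """Read BED3+ into Interval objects (strand from column 6 when present)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(Interval(contig, start, end, strand))
    return out


def write_bed(intervals: Iterable[Interval], path, names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if iv.strand == "." and names is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


@dataclass(frozen=True)
class SiteRecord:
    """One row of a variant pileup table (positions are 1-based)."""

    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    zygosity: str | None = None

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"{self.contig}:{self.pos}: alt equals ref ({self.ref})")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"{self.contig}:{self.pos}: alt_reads {self.alt_reads} > depth {self.depth}"
            )
        if self.alt_reads < 0 or self.depth < 0:
            raise ValueError(f"{self.contig}:{self.pos}: negative counts")


_VARIANT_COLS = ["contig", "pos", "ref", "alt", "depth", "alt_reads"]


def read_variant_table(path) -> list[SiteRecord]:
    """Read a tab-delimited variant pileup table (1-based positions).

    Columns: contig, pos, ref, alt, depth, alt_reads and optionally
    zygosity.  ``alt == ref`` and ``alt_reads > depth`` are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in _VARIANT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} missing columns {missing}")
    has_zyg = "zygosity" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SiteRecord(
                contig=row.contig,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                depth=int(row.depth),
                alt_reads=int(row.alt_reads),
                zygosity=(None if not has_zyg or pd.isna(row.zygosity) else row.zygosity),
            )
        )
    return out


def write_variant_table(records: Iterable[SiteRecord], path) -> None:
    records = list(records)
    cols = dict(
        contig=[r.contig for r in records],
        pos=[r.pos for r in records],
        ref=[r.ref for r in records],
        alt=[r.alt for r in records],
        depth=[r.depth for r in records],
        alt_reads=[r.alt_reads for r in records],
    )
    if any(r.zygosity is not None for r in records):
        cols["zygosity"] = [r.zygosity for r in records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (first column = row key).  Counts must be
    non-negative integers and every sample column must have reads."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    if (df.sum(axis=0) <= 0).any():
        empty = df.columns[df.sum(axis=0) <= 0].tolist()
        raise ValueError(f"zero library size for samples {empty} in {path}")
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
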