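"""CRISPR deletion-allele scanning from amplicon ChIP sequencing.

Edited cells carry a spectrum of deletion alleles at the targeted locus.
Sequencing the amplicon from both ChIP input and IP material and
comparing each deletion allele's IP/Input ratio with the wild-type
allele's gives a per-deletion binding-retention estimate: reads are
globally aligned to the wild-type amplicon, kept when they are wild type
or carry a single deletion at >80% identity, tallied per deletion
interval, and normalized so the wild-type enrichment ratio is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .core import Interval

WT_KEY = "WT"

FULL = "full"
PARTIAL = "partial"
NONE = "none"


@dataclass(frozen=True)
class AlignmentResult:
    """A global read-vs-reference alignment.

    ``gap_events`` are deletions (gaps in the read spanning a reference
    interval, 0-based half-open); ``insertion_events`` are read bases
    absent from the reference, located by the reference position they
    precede.
    """

    aligned_read: str
    aligned_ref: str
    score: float
    percent_identity: float
    gap_events: tuple[tuple[int, int], ...]
    insertion_events: tuple[tuple[int, int], ...]  # (ref position, length)


def global_align(
    read: str,
    reference: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps
    are penalized like internal ones.  Percent identity counts identical
    columns over the full alignment length (gap columns included in the
    denominator).
    """
    read, reference = read.upper(), reference.upper()
    if not read or not reference:
        raise ValueError("empty sequence")
    for seq in (read, reference):
        if set(seq) - set("ACGTN"):
            raise ValueError("non-DNA characters in input")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(reference, read)[0]
    aligned_ref, aligned_read = str(alignment[0]), str(alignment[1])

    matches = sum(a == b for a, b in zip(aligned_ref, aligned_read))
    identity = 100.0 * matches / len(aligned_ref)

    deletions, insertions = [], []
    ref_pos = 0
    i = 0
    while i < len(aligned_ref):
        if aligned_read[i] == "-":
            start = ref_pos
            while i < len(aligned_ref) and aligned_read[i] == "-":
                ref_pos += 1
                i += 1
            deletions.append((start, ref_pos))
        elif aligned_ref[i] == "-":
            start = ref_pos
            length = 0
            while i < len(aligned_ref) and aligned_ref[i] == "-":
                length += 1
                i += 1
            insertions.append((start, length))
        else:
            ref_pos += 1
            i += 1
    return AlignmentResult(
        aligned_read=aligned_read,
        aligned_ref=aligned_ref,
        score=float(alignment.score),
        percent_identity=identity,
        gap_events=tuple(deletions),
        insertion_events=tuple(insertions),
    )


def classify_allele(
    alignment: AlignmentResult,
    min_identity: float = 80.0,
) -> tuple[str, tuple[int, int] | None]:
    """Classify an aligned read as wild type, single deletion, or discard.

    Reads at or below ``min_identity`` percent identity are discarded.
    Wild type means no gap events at all; a single-deletion allele has
    exactly one reference-gap event and no insertions.  Anything else
    (multiple deletions, insertions) is discarded.
    """
    if alignment.percent_identity <= min_identity:
        return "discard", None
    if not alignment.gap_events and not alignment.insertion_events:
        return "WT", None
    if len(alignment.gap_events) == 1 and not alignment.insertion_events:
        return "single_deletion", alignment.gap_events[0]
    return "discard", None


def tally_alleles(
    classified: dict[str, Iterable[tuple[str, tuple[int, int] | None]]],
) -> pd.DataFrame:
    """Count classified reads per deletion interval per library.

    ``classified`` maps library name -> iterable of classify_allele
    outputs.  Rows are keyed "start-end" (exact interval; off-by-one
    deletions are distinct alleles) plus a WT row that is always
    present; discarded reads are not counted.
    """
    counts: dict[str, dict[str, int]] = {}
    for lib, results in classified.items():
        col: dict[str, int] = {WT_KEY: 0}
        n = 0
        for kind, interval in results:
            n += 1
            if kind == "WT":
                col[WT_KEY] += 1
            elif kind == "single_deletion":
                key = f"{interval[0]}-{interval[1]}"
                col[key] = col.get(key, 0) + 1
        if n == 0:
            raise ValueError(f"library {lib!r} is empty")
        counts[lib] = col
    df = pd.DataFrame(counts).fillna(0).astype(int)
    return df.reindex([WT_KEY] + sorted(k for k in df.index if k != WT_KEY))


@dataclass(frozen=True)
class DeletionAllele:
    """A deletion allele with WT-normalized IP/Input enrichment."""

    interval: tuple[int, int] | None  # None for the wild-type allele
    input_counts: tuple[int, ...]
    ip_counts: tuple[int, ...]
    enrichment: float
    replicate_enrichments: tuple[float, ...] = ()
    low_coverage: bool = False
    motif_overlap: str = NONE

    @property
    def is_wt(self) -> bool:
        return self.interval is None

    @property
    def deletion_length(self) -> int:
        return 0 if self.interval is None else self.interval[1] - self.interval[0]


def compute_enrichment(
    tally: pd.DataFrame,
    replicates: Sequence[tuple[str, str]],
    min_input_count: int = 50,
) -> list[DeletionAllele]:
    """WT-normalized IP/Input enrichment per deletion allele.

    ``replicates`` pairs (input column, IP column).  Per replicate,
    enrichment(d) = (ip_d / ip_WT) / (input_d / input_WT), so the
    wild-type allele's ratio is 1 by construction; replicate ratios are
    averaged.  Alleles whose input count falls below ``min_input_count``
    in any replicate are flagged low-coverage (to be excluded from
    downstream statistics).
    """
    if WT_KEY not in tally.index:
        raise ValueError("wild-type allele missing from tally")
    for input_col, ip_col in replicates:
        if tally.loc[WT_KEY, input_col] <= 0 or tally.loc[WT_KEY, ip_col] <= 0:
            raise ValueError("wild-type allele needs positive input and IP counts")

    alleles = []
    for key in tally.index:
        interval = None if key == WT_KEY else tuple(int(x) for x in key.split("-"))
        rep_enr, inputs, ips = [], [], []
        for input_col, ip_col in replicates:
            inp = int(tally.loc[key, input_col])
            ip = int(tally.loc[key, ip_col])
            inputs.append(inp)
            ips.append(ip)
            if inp > 0:
                wt_ratio_ip = ip / tally.loc[WT_KEY, ip_col]
                wt_ratio_in = inp / tally.loc[WT_KEY, input_col]
                rep_enr.append(wt_ratio_ip / wt_ratio_in)
            else:
                rep_enr.append(np.nan)
        valid = [e for e in rep_enr if np.isfinite(e)]
        alleles.append(
            DeletionAllele(
                interval=interval,
                input_counts=tuple(inputs),
                ip_counts=tuple(ips),
                enrichment=float(np.mean(valid)) if valid else np.nan,
                replicate_enrichments=tuple(rep_enr),
                low_coverage=any(i < min_input_count for i in inputs),
            )
        )
    return alleles


def overlap_class(
    deletion: tuple[int, int] | None,
    motif: Interval | tuple[int, int],
) -> str:
    """Classify a deletion's overlap with a motif: full (motif entirely
    deleted), partial, or none.  The wild-type allele is 'none'."""
    m_start, m_end = (motif.start, motif.end) if isinstance(motif, Interval) else motif
    if m_start >= m_end:
        raise ValueError("empty motif interval")
    if deletion is None:
        return NONE
    d_start, d_end = deletion
    if d_start <= m_start and m_end <= d_end:
        return FULL
    if d_end <= m_start or m_end <= d_start:
        return NONE
    return PARTIAL


def annotate_overlap(
    alleles: Sequence[DeletionAllele],
    motif: Interval | tuple[int, int],
) -> list[DeletionAllele]:
    return [replace(a, motif_overlap=overlap_class(a.interval, motif)) for a in alleles]


def window_deletion_impact(
    alleles: Sequence[DeletionAllele],
    region: tuple[int, int],
    window: int = 2,
    step: int = 1,
    max_deletion_length: int = 2,
) -> pd.DataFrame:
    """Sliding-window impact of short deletions on binding retention.

    Alleles with deletions of 1..``max_deletion_length`` bp are assigned
    to every ``window``-bp window they intersect; per window the mean
    enrichment, its SEM, and a one-sided Wilcoxon test for enrichment
    below 1 are reported.  Low-coverage alleles are excluded.  Returns
    an empty table when no allele qualifies.
    """
    short = [
        a
        for a in alleles
        if not a.is_wt
        and not a.low_coverage
        and 1 <= a.deletion_length <= max_deletion_length
        and np.isfinite(a.enrichment)
    ]
    rows = []
    for w_start in range(region[0] - window + 1, region[1], step):
        w_end = w_start + window
        vals = np.array(
            [
                a.enrichment
                for a in short
                if a.interval[0] < w_end and w_start < a.interval[1]
            ]
        )
        if len(vals) == 0:
            continue
        if np.all(vals == 1.0):
            p = 1.0
        else:
            try:
                p = float(stats.wilcoxon(vals - 1.0, alternative="less").pvalue)
            except ValueError:
                p = 1.0
        rows.append(
            dict(
                window_start=w_start,
                window_end=w_end,
                n=len(vals),
                mean_enrichment=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                p_less_than_1=p,
            )
        )
    return pd.DataFrame(rows)


def scan_reads(
    reads_by_library: dict[str, Sequence[str]],
    reference: str,
    min_identity: float = 80.0,
    **align_kwargs,
) -> pd.DataFrame:
    """Align, classify and tally raw amplicon reads per library.

    Identical read sequences are aligned once and their classification
    reused, which makes deep libraries with few unique alleles cheap.
    """
    cache: dict[str, tuple[str, tuple[int, int] | None]] = {}

    def classify(seq: str):
        if seq not in cache:
            cache[seq] = classify_allele(
                global_align(seq, reference, **align_kwargs), min_identity
            )
        return cache[seq]

    classified = {
        lib: [classify(seq) for seq in reads]
        for lib, reads in reads_by_library.items()
    }
    return tally_alleles(classified)
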