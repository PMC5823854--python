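"""Zygosity calling from pileup counts and discriminatory-SNP detection.

The caller works from per-site (depth, variant-read) counts, assigns a
zygosity from read depth and variant read fraction, rescues ambiguous
calls inside homozygous-variant blocks, and pairs two cell lines into
*discriminatory SNPs* (discSNPs): sites where one line is homozygous for
a variant and the other is homozygous reference.  Only such homozygous-
divergent sites give an unambiguous allele assignment for downstream
allele-specific signal comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import Interval
from .io import SiteRecord

HOM_REF = "hom_ref"
HOM_VAR = "hom_var"
HET = "het"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ZygosityThresholds:
    """Depth and variant-read-fraction bands for zygosity calls.

    Sites at depth <= ``min_depth`` are ambiguous.  Above that, the
    variant read fraction is banded: >= ``hom_var_frac`` homozygous
    variant, <= ``hom_ref_frac`` homozygous reference, within
    [``het_lo``, ``het_hi``] heterozygous, anything else ambiguous.
    The defaults favour precision over recall.
    """

    min_depth: int = 5
    hom_var_frac: float = 0.9
    hom_ref_frac: float = 0.1
    het_lo: float = 0.35
    het_hi: float = 0.65


DEFAULT_THRESHOLDS = ZygosityThresholds()


@dataclass(frozen=True)
class VariantCall:
    """Per-site zygosity decision (1-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    zygosity: str

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.depth):
            raise ValueError(f"{self.contig}:{self.pos}: alt_reads outside [0, depth]")


@dataclass(frozen=True)
class DiscSNP:
    """A homozygous-divergent site between two cell lines."""

    contig: str
    pos: int  # 1-based
    base_line_a: str
    base_line_b: str
    isolated: bool = True
    containing_peaks: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.base_line_a == self.base_line_b:
            raise ValueError("discSNP alleles must differ between lines")


def call_zygosity(
    depth: int,
    alt_reads: int,
    thresholds: ZygosityThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Assign a zygosity from depth and variant read count."""
    if depth < 0:
        raise ValueError("negative depth")
    if alt_reads > depth:
        raise ValueError(f"alt_reads {alt_reads} > depth {depth}")
    if depth <= thresholds.min_depth:
        return AMBIGUOUS
    frac = alt_reads / depth
    if frac >= thresholds.hom_var_frac:
        return HOM_VAR
    if frac <= thresholds.hom_ref_frac:
        return HOM_REF
    if thresholds.het_lo <= frac <= thresholds.het_hi:
        return HET
    return AMBIGUOUS


def call_sites(
    sites: list[SiteRecord],
    thresholds: ZygosityThresholds = DEFAULT_THRESHOLDS,
) -> list[VariantCall]:
    """Call zygosity for every row of a pileup table."""
    return [
        VariantCall(
            contig=s.contig,
            pos=s.pos,
            ref=s.ref,
            alt=s.alt,
            depth=s.depth,
            alt_reads=s.alt_reads,
            zygosity=call_zygosity(s.depth, s.alt_reads, thresholds),
        )
        for s in sites
    ]


def smooth_zygosity_blocks(
    calls: list[VariantCall],
    min_calls: int = 10,
    min_frac: float = 0.9,
    max_gap: int = 50_000,
) -> list[VariantCall]:
    """Rescue ambiguous calls inside homozygous-variant blocks.

    Consecutive calls on the same contig separated by at most ``max_gap``
    bp are greedily merged into candidate blocks.  A block with at least
    ``min_calls`` calls of which at least ``min_frac`` are homozygous
    variant has its ambiguous members reassigned to homozygous variant.
    Non-ambiguous calls are never changed, so the operation is idempotent.
    Input must be sorted by (contig, pos).
    """
    for a, b in zip(calls, calls[1:]):
        if (a.contig, a.pos) > (b.contig, b.pos):
            raise ValueError("calls must be sorted by (contig, pos)")

    out = list(calls)
    block_start = 0
    for i in range(1, len(calls) + 1):
        boundary = i == len(calls) or (
            calls[i].contig != calls[i - 1].contig
            or calls[i].pos - calls[i - 1].pos > max_gap
        )
        if not boundary:
            continue
        block = calls[block_start:i]
        n_hom_var = sum(1 for c in block if c.zygosity == HOM_VAR)
        if len(block) >= min_calls and n_hom_var / len(block) >= min_frac:
            for j in range(block_start, i):
                if out[j].zygosity == AMBIGUOUS:
                    out[j] = replace(out[j], zygosity=HOM_VAR)
        block_start = i
    return out


def find_disc_snps(
    calls_a: list[VariantCall],
    calls_b: list[VariantCall],
    coverage_a: dict | None = None,
    coverage_b: dict | None = None,
    min_absent_depth: int = 6,
    isolation_bp: int = 1000,
    peaks: list[Interval] | None = None,
) -> list[DiscSNP]:
    """Pair two lines' calls into discriminatory SNPs.

    A discSNP is a site where one line is homozygous variant and the
    other homozygous reference; the variant line contributes the alt
    base and the reference line the ref base.  A site absent from one
    line's table counts as homozygous reference there only when that
    line's pileup coverage (``coverage_a``/``coverage_b``, keyed by
    (contig, pos)) is at least ``min_absent_depth`` reads; otherwise the
    site is skipped.  ``isolated`` is set iff no other discSNP lies
    within ``isolation_bp``.
    """
    index_a = {(c.contig, c.pos): c for c in calls_a}
    index_b = {(c.contig, c.pos): c for c in calls_b}

    def zygosity_at(key, index, coverage):
        call = index.get(key)
        if call is not None:
            return call.zygosity, call
        if coverage is not None and coverage.get(key, 0) >= min_absent_depth:
            return HOM_REF, None
        return None, None

    snps: list[DiscSNP] = []
    for key in sorted(set(index_a) | set(index_b)):
        za, ca = zygosity_at(key, index_a, coverage_a)
        zb, cb = zygosity_at(key, index_b, coverage_b)
        if za is None or zb is None:
            continue
        if za == HOM_VAR and zb == HOM_REF:
            base_a, base_b = ca.alt, (cb.ref if cb else ca.ref)
        elif za == HOM_REF and zb == HOM_VAR:
            base_a, base_b = (ca.ref if ca else cb.ref), cb.alt
        else:
            continue
        contig, pos = key
        containing = tuple(
            p for p in (peaks or []) if p.contig == contig and p.contains_pos(pos - 1)
        )
        snps.append(DiscSNP(contig, pos, base_a, base_b, containing_peaks=containing))

    # isolation: nearest other discSNP on the same contig > isolation_bp away
    out = []
    for i, s in enumerate(snps):
        isolated = True
        for j in (i - 1, i + 1):
            if 0 <= j < len(snps) and snps[j].contig == s.contig:
                if abs(snps[j].pos - s.pos) <= isolation_bp:
                    isolated = False
        out.append(replace(s, isolated=isolated))
    return out


def evaluate_calls(
    calls: list[VariantCall],
    truth: set,
    zygosity: str = HOM_VAR,
) -> tuple[float, float]:
    """Precision and recall of calls of a given zygosity class.

    ``truth`` is a set of (contig, pos, alt) triples.  Precision is
    reported as NaN when there are no positive calls.
    """
    if not truth:
        raise ValueError("empty truth set")
    positives = {(c.contig, c.pos, c.alt) for c in calls if c.zygosity == zygosity}
    tp = len(positives & truth)
    fp = len(positives - truth)
    fn = len(truth - positives)
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn)
    return precision, recall
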