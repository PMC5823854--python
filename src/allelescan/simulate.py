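"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
two phenotypically matched cell lines whose genomes differ only by
homozygous substitutions (discSNPs), TF peaks each anchored on a planted
motif instance, allele-resolved overdispersed read counts whose means
carry planted per-motif-position disruption effects, sequencing pileups
with per-base error, and CRISPR deletion-allele amplicon libraries with
IP/Input counts driven by a per-deletion binding-retention model.

Every function is a pure function of its configuration and seed, and all
truth quantities needed downstream (per-position effects, contextual
distance windows, per-allele retention) are returned machine-readably.

It deliberately does not model read-level artefacts (mappability,
fragment-length effects, GC bias) or heterozygous sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import ALPHABET, PWM, GenomeSeq, Interval
from .io import SiteRecord
from .motifs import MotifHit
from .predict import BOUND, UNBOUND, TrainingExample


@dataclass(frozen=True)
class NoiseModel:
    """Count-noise configuration for ChIP/DNase simulation.

    Counts are negative binomial with Var = mu + dispersion * mu^2
    (dispersion 0 gives the Poisson limit, useful for oracle checks).
    ``library_sizes`` maps sample name -> library size; means are scaled
    by library size relative to the mean library size.
    """

    dispersion: float = 0.2
    error_rate: float = 0.001
    library_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "ip_A": 1e6, "ip_B": 1e6, "input_A": 1e6, "input_B": 1e6,
        }
    )

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")


@dataclass(frozen=True)
class ContextConfig:
    """Contextual-motif planting: a second motif placed near the anchor.

    The context motif is planted in ``fraction`` of peaks at an
    edge-to-edge gap drawn uniformly from ``distance_range``; in
    ``snp_fraction`` of those peaks one line carries a SNP disrupting
    it, which multiplies that line's binding mean by ``effect`` — but
    only when the planted gap lies within ``active_range``.
    """

    pwm: PWM
    fraction: float = 0.5
    distance_range: tuple[int, int] = (0, 80)
    active_range: tuple[int, int] = (0, 40)
    effect: float = 0.5
    snp_fraction: float = 1.0


@dataclass
class SimulationTruth:
    """Ground truth emitted by :func:`simulate_genome_pair`."""

    reference: GenomeSeq
    line_a_seq: GenomeSeq
    line_b_seq: GenomeSeq
    planted_snps: list[tuple[int, str, str, bool]]  # (1-based pos, base A, base B, discriminatory)
    planted_motifs: list[tuple[str, Interval, float]]
    peaks: list[Interval]
    peak_truth: pd.DataFrame  # base_intensity, mean_a, mean_b per peak
    effect_truth: dict[int, float]  # 1-based motif position -> effect in [0, 1]
    context_truth: dict[str, tuple[float, tuple[int, int]]]
    snp_events: pd.DataFrame  # per disruption SNP: pos, peak, offset, disrupted line


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def _worst_base(pwm: PWM, offset0: int, exclude: int) -> int:
    """Lowest-probability base at a motif position, excluding one base."""
    probs = pwm.matrix[offset0].copy()
    probs[exclude] = np.inf
    return int(np.argmin(probs))


def simulate_genome_pair(
    length: int,
    n_peaks: int,
    n_snps: int,
    pwms: Sequence[PWM],
    context: ContextConfig | None = None,
    seed: int = 0,
    peak_width: int = 200,
    base_intensity: float = 500.0,
    intensity_sigma: float = 0.3,
    effect_by_offset: dict[int, float] | None = None,
    frac_in_motif: float = 0.5,
) -> SimulationTruth:
    """Generate a reference genome and two lines differing by planted SNPs.

    Peaks of ``peak_width`` bp are laid out with wide spacing (so SNPs in
    different peaks are >1 kb apart and isolated); each peak carries one
    planted anchor-motif instance (the consensus of ``pwms[0]``) at its
    summit.  ``frac_in_motif`` of the SNPs are placed inside anchor
    motifs at offsets cycling through ``effect_by_offset`` (1-based
    offset -> multiplicative binding effect); the rest are background
    substitutions between peaks.  The line carrying the disrupting base
    is chosen at random per SNP.
    """
    rng = np.random.default_rng(seed)
    anchor = pwms[0]
    if peak_width < len(anchor):
        raise ValueError("anchor motif longer than peak")
    if length < 10 * n_peaks * peak_width:
        raise ValueError("genome too short for requested peak count")
    effect_by_offset = dict(effect_by_offset or {2: 0.5})
    if any(not (1 <= o <= len(anchor)) for o in effect_by_offset):
        raise ValueError("effect offsets must lie inside the anchor motif")
    if any(not (0 <= f <= 1) for f in effect_by_offset.values()):
        raise ValueError("effects must be fractions in [0, 1]")

    ref = _random_seq(rng, length)
    contig = "chrS"
    spacing = length // max(n_peaks, 1)
    anchor_cons = anchor.consensus()
    anchor_idx = np.array([ALPHABET.index(b) for b in anchor_cons], dtype=np.int8)

    peaks, motifs = [], []
    anchor_iv: list[Interval] = []  # per-peak anchor placement
    context_iv: dict[int, Interval] = {}
    context_gap: dict[int, int | None] = {}
    for k in range(n_peaks):
        summit = spacing * k + spacing // 2
        start = summit - peak_width // 2
        peaks.append(Interval(contig, start, start + peak_width))
        m_start = summit - len(anchor) // 2
        ref[m_start : m_start + len(anchor)] = anchor_idx
        anchor_iv.append(Interval(contig, m_start, m_start + len(anchor), "+"))
        motifs.append(
            (anchor.motif_id, anchor_iv[-1],
             float(anchor.log_odds.max(axis=1).sum()))
        )
        context_gap[k] = None
        if context is not None and rng.random() < context.fraction:
            gap = int(rng.integers(context.distance_range[0], context.distance_range[1] + 1))
            c_start = m_start + len(anchor) + gap
            c_cons = context.pwm.consensus()
            if c_start + len(c_cons) <= start + peak_width:
                ref[c_start : c_start + len(c_cons)] = np.array(
                    [ALPHABET.index(b) for b in c_cons], dtype=np.int8
                )
                context_iv[k] = Interval(contig, c_start, c_start + len(c_cons), "+")
                motifs.append(
                    (context.pwm.motif_id, context_iv[k],
                     float(context.pwm.log_odds.max(axis=1).sum()))
                )
                context_gap[k] = gap

    line_a = ref.copy()
    line_b = ref.copy()
    snps: list[tuple[int, str, str, bool]] = []
    events = []
    log_mult_a = np.zeros(n_peaks)
    log_mult_b = np.zeros(n_peaks)

    n_motif_snps = int(round(frac_in_motif * n_snps))
    if n_motif_snps > n_peaks:
        raise ValueError("more motif SNPs requested than peaks available")
    offsets = sorted(effect_by_offset)
    target_peaks = rng.choice(n_peaks, size=n_motif_snps, replace=False)
    for j, k in enumerate(sorted(target_peaks)):
        offset = offsets[j % len(offsets)]
        pos0 = anchor_iv[k].start + offset - 1
        ref_base = int(ref[pos0])
        var_base = _worst_base(anchor, offset - 1, exclude=ref_base)
        disrupted = "A" if rng.random() < 0.5 else "B"
        (line_a if disrupted == "A" else line_b)[pos0] = var_base
        effect = effect_by_offset[offset]
        (log_mult_a if disrupted == "A" else log_mult_b)[k] += np.log(max(effect, 1e-12))
        snps.append(
            (pos0 + 1, ALPHABET[line_a[pos0]], ALPHABET[line_b[pos0]], True)
        )
        events.append(dict(pos=pos0 + 1, peak=k, offset=offset,
                           disrupted_line=disrupted, effect=effect,
                           kind="anchor"))

    # contextual-motif disruption SNPs
    if context is not None:
        for k, iv in sorted(context_iv.items()):
            if rng.random() >= context.snp_fraction:
                continue
            offset = len(context.pwm) // 2 + 1
            pos0 = iv.start + offset - 1
            ref_base = int(ref[pos0])
            var_base = _worst_base(context.pwm, offset - 1, exclude=ref_base)
            disrupted = "A" if rng.random() < 0.5 else "B"
            (line_a if disrupted == "A" else line_b)[pos0] = var_base
            gap = context_gap[k]
            active = (gap is not None
                      and context.active_range[0] <= gap <= context.active_range[1])
            if active:
                (log_mult_a if disrupted == "A" else log_mult_b)[k] += np.log(
                    max(context.effect, 1e-12)
                )
            events.append(dict(pos=pos0 + 1, peak=k, offset=offset,
                               disrupted_line=disrupted,
                               effect=context.effect if active else 1.0,
                               kind="context"))
            snps.append(
                (pos0 + 1, ALPHABET[line_a[pos0]], ALPHABET[line_b[pos0]], True)
            )

    # background SNPs between peaks: drawn from a >1-kb-spaced grid so
    # every planted SNP is isolated, then jittered within the grid cell
    n_background = n_snps - n_motif_snps
    if n_background > 0:
        pitch = 1100
        grid = np.arange(pitch // 2, length - pitch // 2, pitch)
        grid = grid + rng.integers(-40, 41, size=len(grid))
        peak_centers = np.array([(p.start + p.end) // 2 for p in peaks])
        if len(peak_centers):
            nearest = peak_centers[
                np.clip(
                    np.searchsorted(peak_centers, grid), 0, len(peak_centers) - 1
                )
            ]
            prev = peak_centers[
                np.clip(
                    np.searchsorted(peak_centers, grid) - 1, 0, len(peak_centers) - 1
                )
            ]
            clear = (np.abs(grid - nearest) > 1100) & (np.abs(grid - prev) > 1100)
            grid = grid[clear]
        if n_background > len(grid):
            raise ValueError("infeasible SNP density for genome length")
        chosen = np.sort(rng.choice(grid, size=n_background, replace=False))
        for pos0 in chosen.tolist():
            ref_base = int(ref[pos0])
            var_base = int((ref_base + 1 + rng.integers(0, 3)) % 4)
            disrupted = "A" if rng.random() < 0.5 else "B"
            (line_a if disrupted == "A" else line_b)[pos0] = var_base
            snps.append(
                (pos0 + 1, ALPHABET[line_a[pos0]], ALPHABET[line_b[pos0]], True)
            )

    base = base_intensity * np.exp(rng.normal(0.0, intensity_sigma, size=n_peaks))
    peak_truth = pd.DataFrame(
        dict(
            peak_id=[f"peak{k}" for k in range(n_peaks)],
            base_intensity=base,
            mean_a=base * np.exp(log_mult_a),
            mean_b=base * np.exp(log_mult_b),
        )
    ).set_index("peak_id")

    snps.sort()
    return SimulationTruth(
        reference=GenomeSeq(contig, _decode(ref)),
        line_a_seq=GenomeSeq(contig, _decode(line_a)),
        line_b_seq=GenomeSeq(contig, _decode(line_b)),
        planted_snps=snps,
        planted_motifs=motifs,
        peaks=peaks,
        peak_truth=peak_truth,
        effect_truth=effect_by_offset,
        context_truth=(
            {context.pwm.motif_id: (context.effect, context.active_range)}
            if context is not None
            else {}
        ),
        snp_events=pd.DataFrame(events),
    )


def simulate_pileups(
    truth: SimulationTruth,
    mean_depth: float = 30.0,
    error_rate: float = 0.003,
    seed: int = 0,
) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Sequencing pileups for both lines at every planted SNP position.

    Per site, depth ~ Poisson(mean_depth); at a line's homozygous-variant
    sites alt reads ~ Binomial(depth, 1 - e), at its homozygous-reference
    sites alt reads ~ Binomial(depth, e).
    """
    if mean_depth < 1:
        raise ValueError("mean depth must be >= 1")
    rng = np.random.default_rng(seed)
    ref_seq = truth.reference.sequence
    out_a: list[SiteRecord] = []
    out_b: list[SiteRecord] = []
    for pos, base_a, base_b, _ in truth.planted_snps:
        ref_base = ref_seq[pos - 1]
        alt_base = base_a if base_a != ref_base else base_b
        for line_base, out in ((base_a, out_a), (base_b, out_b)):
            depth = int(rng.poisson(mean_depth))
            p_alt = (1.0 - error_rate) if line_base == alt_base else error_rate
            alt_reads = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
            out.append(
                SiteRecord(
                    contig=truth.reference.contig_name,
                    pos=pos,
                    ref=ref_base,
                    alt=alt_base,
                    depth=depth,
                    alt_reads=alt_reads,
                )
            )
    return out_a, out_b


def simulate_chip_counts(
    truth: SimulationTruth,
    noise: NoiseModel | None = None,
    seed: int = 0,
    input_fraction: float = 0.05,
) -> pd.DataFrame:
    """Allele-resolved IP and input counts per peak.

    The input library sees only nonspecific background
    (``input_fraction`` x base intensity, effect-free); the IP library
    sees background plus the line's true binding mean, which already
    carries the planted multiplicative disruption effects.  Counts are
    negative binomial with the noise model's dispersion and are scaled by
    library size.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    libs = noise.library_sizes
    ref_lib = float(np.mean(list(libs.values())))
    background = input_fraction * truth.peak_truth["base_intensity"].to_numpy()

    def draw(mu: np.ndarray) -> np.ndarray:
        mu = np.maximum(mu, 1e-9)
        if noise.dispersion == 0:
            return rng.poisson(mu)
        n = 1.0 / noise.dispersion
        return rng.negative_binomial(n, n / (n + mu))

    means = {
        "ip_A": background + truth.peak_truth["mean_a"].to_numpy(),
        "ip_B": background + truth.peak_truth["mean_b"].to_numpy(),
        "input_A": background,
        "input_B": background,
    }
    data = {
        col: draw(mu * (libs[col] / ref_lib)) for col, mu in means.items()
    }
    return pd.DataFrame(data, index=truth.peak_truth.index)


def default_retention(motif: tuple[int, int]) -> Callable[[tuple[int, int]], float]:
    """Binding-retention model used by the deletion-library simulator:
    full motif deletion retains 5% of binding, partial 30%, and
    deletions missing the motif retain full binding."""

    def retention(deletion: tuple[int, int]) -> float:
        d_start, d_end = deletion
        m_start, m_end = motif
        if d_start <= m_start and m_end <= d_end:
            return 0.05
        if d_end <= m_start or m_end <= d_start:
            return 1.0
        return 0.3

    return retention


def simulate_deletion_library(
    locus_seq: str,
    motif: tuple[int, int],
    n_alleles: int = 100,
    mean_deletion_length: float = 26.0,
    retention: Callable[[tuple[int, int]], float] | None = None,
    library_sizes: dict[str, int] | None = None,
    seed: int = 0,
    wt_weight: float = 10.0,
    center_sd: float = 20.0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """CRISPR deletion-allele amplicon libraries with known retention.

    ``n_alleles`` distinct deletion intervals are drawn with lengths
    around ``mean_deletion_length`` bp centred near the motif; a
    wild-type allele is always present with relative abundance
    ``wt_weight``.  Input counts are multinomial over allele abundances;
    IP counts are multinomial with probabilities proportional to
    abundance x binding retention.  Reads are the amplicon with the
    deletion applied.  Returns (reads per library, truth table).
    """
    if retention is None:
        retention = default_retention(motif)
    library_sizes = library_sizes or {"input": 20000, "ip": 20000}
    rng = np.random.default_rng(seed)
    m_center = (motif[0] + motif[1]) // 2
    L = len(locus_seq)

    intervals: list[tuple[int, int]] = []
    sequences_seen = {locus_seq}
    guard = 0
    while len(intervals) < n_alleles:
        guard += 1
        if guard > 100 * n_alleles:
            raise ValueError("cannot place requested deletions inside amplicon")
        dlen = max(1, int(rng.poisson(mean_deletion_length)))
        center = int(round(rng.normal(m_center, center_sd)))
        start = center - dlen // 2
        end = start + dlen
        if start < 1 or end > L - 1:  # keep at least 1 bp of amplicon ends
            continue
        seq = locus_seq[:start] + locus_seq[end:]
        if (start, end) in intervals or seq in sequences_seen:
            continue
        intervals.append((start, end))
        sequences_seen.add(seq)

    alleles = [None] + intervals  # None = wild type
    weights = np.r_[wt_weight, rng.dirichlet(np.ones(n_alleles)) * n_alleles]
    abundance = weights / weights.sum()
    ret = np.array([1.0 if a is None else retention(a) for a in alleles])
    if np.any((ret < 0) | (ret > 1)):
        raise ValueError("retention values must lie in [0, 1]")

    input_counts = rng.multinomial(library_sizes["input"], abundance)
    ip_prob = abundance * ret
    ip_prob = ip_prob / ip_prob.sum()
    ip_counts = rng.multinomial(library_sizes["ip"], ip_prob)

    def allele_seq(a):
        return locus_seq if a is None else locus_seq[: a[0]] + locus_seq[a[1] :]

    reads = {
        "input": [allele_seq(a) for a, c in zip(alleles, input_counts) for _ in range(c)],
        "ip": [allele_seq(a) for a, c in zip(alleles, ip_counts) for _ in range(c)],
    }
    truth = pd.DataFrame(
        dict(
            allele=["WT"] + [f"{s}-{e}" for s, e in intervals],
            start=[np.nan] + [s for s, _ in intervals],
            end=[np.nan] + [e for _, e in intervals],
            abundance=abundance,
            retention=ret,
            input_count=input_counts,
            ip_count=ip_counts,
        )
    ).set_index("allele")
    return reads, truth


def simulate_binding_sites(
    anchor_pwm: PWM,
    context_pwm: PWM,
    n_sites: int = 4000,
    context_fraction: float = 0.5,
    anchor_coef: float = 0.5,
    context_coef: float = 1.5,
    intercept: float = -6.0,
    window_flank: int = 120,
    seed: int = 0,
) -> list[TrainingExample]:
    """Anchor-motif sites whose bound/unbound label depends on context.

    Each site is a random window with an anchor-motif instance sampled
    from the anchor PWM at its centre; ``context_fraction`` of sites
    additionally carry a context-motif consensus within 100 bp.  The
    label is Bernoulli with logit = intercept + anchor_coef *
    anchor_score + context_coef * [context planted]; setting
    ``context_coef=0`` (or both coefficients 0) removes the effect.
    Returns TrainingExamples ready for feature extraction.
    """
    rng = np.random.default_rng(seed)
    wa = len(anchor_pwm)
    examples = []
    for i in range(n_sites):
        win = _random_seq(rng, 2 * window_flank + wa)
        a_start = window_flank
        # sample an anchor instance from the PWM's own distribution
        for j in range(wa):
            win[a_start + j] = rng.choice(4, p=anchor_pwm.matrix[j])
        has_context = rng.random() < context_fraction
        if has_context:
            gap = int(rng.integers(5, 90))
            side = 1 if rng.random() < 0.5 else -1
            c_cons = context_pwm.consensus()
            c_start = (a_start + wa + gap) if side == 1 else (a_start - gap - len(c_cons))
            if 0 <= c_start and c_start + len(c_cons) <= len(win):
                win[c_start : c_start + len(c_cons)] = np.array(
                    [ALPHABET.index(b) for b in c_cons], dtype=np.int8
                )
        seq = _decode(win)
        anchor_score = float(
            anchor_pwm.log_odds[np.arange(wa), win[a_start : a_start + wa]].sum()
        )
        logit = intercept + anchor_coef * anchor_score + context_coef * has_context
        bound = rng.random() < 1.0 / (1.0 + np.exp(-logit))
        examples.append(
            TrainingExample(
                site=MotifHit(
                    anchor_pwm.motif_id,
                    Interval(f"site{i}", a_start, a_start + wa, "+"),
                    anchor_score,
                ),
                label=BOUND if bound else UNBOUND,
                anchor_score=anchor_score,
                sequence=seq,
                anchor_offset=a_start,
            )
        )
    return examples
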