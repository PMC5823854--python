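"""Allele-resolved signal normalization and motif-disruption impact statistics.

The central statistic is the *percent residual binding*: 100 times the
normalized ChIP (or accessibility) intensity on the allele carrying a
disrupted motif divided by the intensity on the intact allele.  Events
are grouped (by motif, motif position, variant base, distance bin or
peak class) and each group is tested against 100% with a one-sample
Wilcoxon signed-rank test, given a bootstrap confidence interval for its
median, and corrected for multiple testing with a maxT-style label
permutation: the observed p of each group is referred to the null
distribution of the smallest p across groups under label shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval
from .motifs import DisruptionEvent


# ---------------------------------------------------------------------------
# peaks and normalization

@dataclass(frozen=True)
class Peak:
    """A called peak with its summit (absolute position) and signal."""

    interval: Interval
    summit: int
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not self.interval.contains_pos(self.summit):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )


def merge_peaks(peak_sets: Sequence[Sequence[Peak]], flank: int = 100) -> list[Interval]:
    """Build consensus intervals from one or more peak sets.

    Every peak (any set; a peak present in a single set is kept) is
    re-centred to summit +/- ``flank``.  Overlapping consensus intervals
    are merged by keeping the interval of the higher-signal summit, so
    the output intervals are disjoint and all have width 2*flank.
    """
    centred = sorted(
        (
            (p.interval.contig, max(0, p.summit - flank), p.summit + flank, p.signal)
            for peaks in peak_sets
            for p in peaks
        ),
        key=lambda t: (t[0], t[1]),
    )
    out: list[tuple] = []
    for item in centred:
        if out and out[-1][0] == item[0] and item[1] < out[-1][2]:
            if item[3] > out[-1][3]:
                out[-1] = item
        else:
            out.append(item)
    return [Interval(c, s, e) for c, s, e, _ in out]


def normalize_chip(
    ip_counts,
    input_counts,
    lib_ip: float,
    lib_input: float,
    ref_size: float | None = None,
):
    """Input-subtracted, library-size-scaled ChIP intensity.

    Counts are scaled to a common reference library size (the mean of the
    two library sizes unless given), the scaled input is subtracted and
    the result floored at zero.
    """
    if lib_ip <= 0 or lib_input <= 0:
        raise ValueError("library sizes must be positive")
    if ref_size is None:
        ref_size = (lib_ip + lib_input) / 2.0
    ip = np.asarray(ip_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    return np.maximum(0.0, ip * (ref_size / lib_ip) - inp * (ref_size / lib_input))


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization across sample columns.

    Every column is mapped onto the mean sorted profile; tied values
    receive the mean of the quantile means at their (average) ranks.
    """
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples to quantile normalize")
    if (df.nunique(axis=0) <= 1).any():
        const = df.columns[df.nunique(axis=0) <= 1].tolist()
        raise ValueError(f"constant columns cannot be quantile normalized: {const}")
    values = df.to_numpy(dtype=float)
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    grid = np.arange(len(df), dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, sorted_means)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# percent residual binding and grouped statistics

def percent_residual(
    events: Sequence[DisruptionEvent],
    intensity_a: Sequence[float],
    intensity_b: Sequence[float],
    eps: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent residual intensity on each event's disrupted allele.

    ``intensity_a``/``intensity_b`` are the normalized intensities of the
    event's peak on lines A and B.  Returns (residuals, kept): events
    whose intact-allele intensity falls below ``eps`` (denominator too
    weak to quantify) or whose alleles tie in motif score are excluded.
    Residuals may exceed 100.
    """
    ia = np.asarray(intensity_a, dtype=float)
    ib = np.asarray(intensity_b, dtype=float)
    if len(ia) != len(events) or len(ib) != len(events):
        raise ValueError("intensity arrays must be parallel to events")
    residuals = np.full(len(events), np.nan)
    kept = np.zeros(len(events), dtype=bool)
    for i, e in enumerate(events):
        if e.disrupted_line == "A":
            disrupted, intact = ia[i], ib[i]
        elif e.disrupted_line == "B":
            disrupted, intact = ib[i], ia[i]
        else:
            continue
        if intact < eps:
            continue
        residuals[i] = 100.0 * disrupted / intact
        kept[i] = True
    return residuals[kept], kept


def _wilcoxon_vs(values: np.ndarray, null_value: float = 100.0) -> float:
    """One-sample two-sided Wilcoxon signed-rank p against a constant;
    a degenerate sample (all exactly at the null value) reports p = 1."""
    d = np.asarray(values, dtype=float) - null_value
    if np.all(d == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    except ValueError:
        return 1.0


def group_impact(
    residuals: Sequence[float],
    groups: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
    min_n: int = 5,
    null_value: float = 100.0,
) -> pd.DataFrame:
    """Per-group impact summary of percent residual intensities.

    For each group: n, median residual, bootstrap 95% CI of the median
    (percentiles of ``n_boot`` resampled medians) and a two-sided
    Wilcoxon signed-rank p against ``null_value``.  Groups smaller than
    ``min_n`` are suppressed.
    """
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    rows = []
    for g in pd.unique(groups):
        x = residuals[groups == g]
        if len(x) < min_n:
            continue
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        boot_medians = np.median(x[idx], axis=1)
        lo, hi = np.percentile(boot_medians, [2.5, 97.5])
        rows.append(
            dict(
                group=g,
                n=len(x),
                median=float(np.median(x)),
                ci_lo=float(lo),
                ci_hi=float(hi),
                wilcoxon_p=_wilcoxon_vs(x, null_value),
            )
        )
    return pd.DataFrame(rows)


def _signed_rank_p(d: np.ndarray) -> np.ndarray:
    """Vectorized one-sample signed-rank two-sided p (normal approximation
    with tie and zero corrections) for the last axis of ``d``.

    Used for the permutation machinery, where the same p must be computed
    for observed and for thousands of label-shuffled datasets.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[-1]
    absd = np.abs(d)
    r = stats.rankdata(absd, axis=-1)
    t_plus = np.where(d > 0, r, 0.0).sum(axis=-1)
    n0 = (d == 0).sum(axis=-1)  # zeros handled Pratt-style
    mu = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0

    s = np.sort(absd, axis=-1)
    if (s[..., 1:] == s[..., :-1]).any():
        flat = s.reshape(-1, n)
        adj = np.zeros(flat.shape[0])
        tied_rows = np.nonzero((flat[:, 1:] == flat[:, :-1]).any(axis=1))[0]
        for i in tied_rows:
            _, counts = np.unique(flat[i], return_counts=True)
            adj[i] = (counts.astype(float) ** 3 - counts).sum() / 48.0
        var = var - adj.reshape(var.shape) if np.ndim(var) else var - adj[0]
    var = np.maximum(var, 1e-12)
    z = (t_plus - mu) / np.sqrt(var)
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 0.0, 1.0)


def permutation_adjust(
    residuals: Sequence[float],
    groups: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
    null_value: float = 100.0,
) -> pd.DataFrame:
    """maxT permutation correction across groups of residuals.

    Group labels are shuffled over the pooled events (group sizes
    preserved); per permutation all group-wise signed-rank p-values are
    recomputed and the smallest is recorded.  Each group's q-value is
    (1 + #{null min-p <= observed p}) / (n_perm + 1), so q is monotone in
    the observed p and never exactly zero.
    """
    residuals = np.asarray(residuals, dtype=float)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups to permute")
    if len(residuals) < len(uniq):
        raise ValueError("fewer events than group labels")
    d = residuals - null_value
    sizes = [int((labels == g).sum()) for g in uniq]
    bounds = np.cumsum([0] + sizes)

    obs_p = np.array([_signed_rank_p(d[labels == g]) for g in uniq])

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(d))), axis=1)
    permuted = d[order]  # (n_perm, n)
    null_min_p = np.full(n_perm, np.inf)
    for k in range(len(uniq)):
        block = permuted[:, bounds[k] : bounds[k + 1]]
        null_min_p = np.minimum(null_min_p, _signed_rank_p(block))

    q = np.array([(1 + (null_min_p <= p).sum()) / (n_perm + 1) for p in obs_p])
    return pd.DataFrame(dict(group=uniq, p=obs_p, q=q))


# ---------------------------------------------------------------------------
# distance bins, peak classes, correlations, profiles

def distance_bins(
    distances: Sequence[float],
    start: int = 0,
    stop: int = 100,
    width: int = 10,
    step: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Overlapping sliding distance bins.

    Bins are [s, s+width) for s = start, start+step, ..., stop-step —
    with the defaults exactly 20 bins covering 0-100 bp, each event
    falling in up to two bins.  Distances are edge-to-edge gaps (0 when
    the intervals overlap).  Returns (bin table, membership matrix of
    shape (n_events, n_bins)).
    """
    distances = np.asarray(distances, dtype=float)
    if (distances < 0).any():
        raise ValueError("distances must be non-negative")
    starts = np.arange(start, stop, step)
    table = pd.DataFrame(
        dict(bin_id=np.arange(len(starts)), lo=starts, hi=starts + width)
    )
    member = (distances[:, None] >= starts[None, :]) & (
        distances[:, None] < (starts + width)[None, :]
    )
    return table, member


CONSTITUTIVE = "constitutive"
VARIABLE = "variable"
ERYTHROID_SPECIFIC = "erythroid_specific"
DIFFERENTIATION_INDUCED = "differentiation_induced"
OTHER = "other"


def classify_peaks(
    occupancy: pd.DataFrame,
    erythroid_tissues: Sequence[str],
    differentiation_pairs: Sequence[tuple[str, str]] = (),
    constitutive_frac: float = 0.6,
    variable_frac: float = 0.2,
) -> pd.DataFrame:
    """Classify peaks by tissue occupancy breadth.

    ``occupancy`` is a peaks x tissues boolean matrix.  A peak occupied
    in more than ``constitutive_frac`` of tissues is constitutive; in
    fewer than ``variable_frac``, variable.  Variable peaks occupied in
    every erythroid tissue and in no non-erythroid tissue are
    erythroid-specific; of those, peaks absent in the undifferentiated
    and present in the differentiated member of every differentiation
    pair are differentiation-induced.  The most specific class wins.
    """
    if occupancy.shape[1] < 5:
        raise ValueError("need at least 5 tissues")
    tissues = list(occupancy.columns)
    unknown = (set(erythroid_tissues) | {t for p in differentiation_pairs for t in p}) - set(tissues)
    if unknown:
        raise ValueError(f"unknown tissue ids: {sorted(unknown)}")
    occ = occupancy.astype(bool)
    non_erythroid = [t for t in tissues if t not in set(erythroid_tissues)]
    frac = occ.mean(axis=1)

    classes = []
    for peak in occ.index:
        row = occ.loc[peak]
        if frac[peak] > constitutive_frac:
            classes.append(CONSTITUTIVE)
            continue
        if frac[peak] >= variable_frac:
            classes.append(OTHER)
            continue
        cls = VARIABLE
        if all(row[t] for t in erythroid_tissues) and not any(
            row[t] for t in non_erythroid
        ):
            cls = ERYTHROID_SPECIFIC
            if differentiation_pairs and all(
                (not row[u]) and row[d] for u, d in differentiation_pairs
            ):
                cls = DIFFERENTIATION_INDUCED
        classes.append(cls)
    return pd.DataFrame(
        dict(occupancy_fraction=frac, peak_class=classes), index=occ.index
    )


def fisher_z_corr(
    x: Sequence[float],
    y: Sequence[float],
    other: tuple[Sequence[float], Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Pearson correlation with a Fisher-Z confidence interval.

    When a second (x, y) pair is supplied, the two correlations are
    compared with the z-difference test and the comparison p is included.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1, 1))
    half = zcrit / np.sqrt(n - 3)
    result = dict(r=r, n=n, ci_lo=float(np.tanh(z - half)), ci_hi=float(np.tanh(z + half)))
    if other is not None:
        x2, y2 = (np.asarray(v, dtype=float) for v in other)
        r2 = float(stats.pearsonr(x2, y2).statistic)
        z2 = np.arctanh(np.clip(r2, -1, 1))
        se = np.sqrt(1.0 / (n - 3) + 1.0 / (len(x2) - 3))
        result["comparison_p"] = float(
            np.clip(2 * stats.norm.sf(abs(z - z2) / se), 0.0, 1.0)
        )
        result["r_other"] = r2
    return result


def differential_binding_q(
    ip_a: Sequence[int],
    ip_b: Sequence[int],
    lib_a: float,
    lib_b: float,
) -> np.ndarray:
    """Per-peak differential-binding q between two alleles/lines.

    Two-sided binomial test of the line-A IP count against the expected
    library-size share lib_a / (lib_a + lib_b), BH-corrected across
    peaks.
    """
    ip_a = np.asarray(ip_a, dtype=int)
    ip_b = np.asarray(ip_b, dtype=int)
    p0 = lib_a / (lib_a + lib_b)
    pvals = np.ones(len(ip_a))
    for i, (a, b) in enumerate(zip(ip_a, ip_b)):
        total = int(a + b)
        if total > 0:
            pvals[i] = stats.binomtest(int(a), total, p0).pvalue
    return stats.false_discovery_control(pvals, method="bh")


def delta_vs_expression(
    delta_binding: Sequence[float],
    binding_q: Sequence[float],
    delta_expression: Sequence[float],
    tss_distance: Sequence[float] | None = None,
    fdr_grid: Sequence[float] = (1e-4, 1e-3, 1e-2, 0.05, 0.1, 1.0),
    distance_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Correlation of allele binding change with transcription change
    across differential-binding FDR cutoffs (and optional TSS-distance
    cutoffs), with Fisher-Z confidence intervals.  Points with fewer
    than 4 pairs are reported as NaN."""
    db = np.asarray(delta_binding, dtype=float)
    q = np.asarray(binding_q, dtype=float)
    de = np.asarray(delta_expression, dtype=float)
    dist = (
        np.zeros(len(db))
        if tss_distance is None
        else np.asarray(tss_distance, dtype=float)
    )
    d_grid = [np.inf] if distance_grid is None else list(distance_grid)
    rows = []
    for fdr in fdr_grid:
        for max_d in d_grid:
            mask = (q <= fdr) & (dist <= max_d)
            row = dict(fdr=fdr, max_distance=max_d, n=int(mask.sum()),
                       r=np.nan, ci_lo=np.nan, ci_hi=np.nan)
            if mask.sum() >= 4 and np.std(db[mask]) > 0 and np.std(de[mask]) > 0:
                res = fisher_z_corr(db[mask], de[mask])
                row.update(r=res["r"], ci_lo=res["ci_lo"], ci_hi=res["ci_hi"])
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_profile(
    tracks: dict[str, np.ndarray],
    anchors: Sequence[tuple[str, int, str]],
    flank: int = 400,
    summary: str = "median",
) -> np.ndarray:
    """Summary signal profile around a set of anchor positions.

    ``anchors`` are (contig, 0-based position, strand) triples; windows
    of flank bp either side are extracted (and reversed for minus-strand
    anchors) and summarized per offset.  Returns a vector of length
    2*flank + 1 indexed from -flank to +flank.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    windows = []
    for contig, pos, strand in anchors:
        track = np.asarray(tracks[contig], dtype=float)
        if pos - flank < 0 or pos + flank >= len(track):
            raise ValueError(f"anchor {contig}:{pos} window outside track bounds")
        win = track[pos - flank : pos + flank + 1]
        windows.append(win[::-1] if strand == "-" else win)
    stacked = np.vstack(windows)
    return np.median(stacked, axis=0) if summary == "median" else stacked.mean(axis=0)
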