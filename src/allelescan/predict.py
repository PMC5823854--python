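"""Contextual-motif logistic-regression prediction of TF binding sites.

Motif matches alone separate bound from unbound sites poorly; nearby
*contextual* motifs (other factors' sites within 100 bp of the anchor
motif) carry additional information.  This module builds bound/unbound
training sets (negatives composition-matched to positives), selects
contextual motifs by requiring them to beat column-shuffled versions of
their own PWM, fits cross-validated logistic regressions, and compares
models by ROC AUC with DeLong's paired test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .core import PWM, Interval
from .motifs import MotifHit, score_pwm

BOUND = "bound"
UNBOUND = "unbound"


@dataclass
class TrainingExample:
    """One anchor-motif site with its local sequence context.

    ``sequence`` is the window around the anchor used for contextual
    scanning; ``anchor_offset`` is the anchor hit's start within it.
    """

    site: MotifHit
    label: str
    anchor_score: float
    sequence: str
    anchor_offset: int
    context_scores: dict[str, float] = field(default_factory=dict)

    @property
    def anchor_len(self) -> int:
        return len(self.site.interval)


@dataclass
class ModelReport:
    """Cross-validated classifier performance for one model spec."""

    spec_id: str  # anchor_only | contextual | shuffled_control
    feature_names: list[str]
    labels: np.ndarray
    oof_scores: np.ndarray  # (n_runs, n_examples) out-of-fold probabilities
    aucs: list[float]
    rocs: list[tuple[np.ndarray, np.ndarray]]
    selected_motifs: list[str] = field(default_factory=list)

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def mean_scores(self) -> np.ndarray:
        """Per-example out-of-fold score averaged over CV runs (the paired
        score vector used for DeLong comparisons)."""
        return self.oof_scores.mean(axis=0)

    def summary(self) -> str:
        lines = [
            f"model: {self.spec_id}",
            f"features: {', '.join(self.feature_names)}",
            f"n examples: {len(self.labels)} "
            f"({int(self.labels.sum())} bound)",
            f"CV runs: {len(self.aucs)}",
            f"AUC median {self.median_auc:.4f} "
            f"(range {min(self.aucs):.4f}-{max(self.aucs):.4f})",
        ]
        if self.selected_motifs:
            lines.append(f"selected contextual motifs: {', '.join(self.selected_motifs)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# training-set construction

def composition_vector(seq: str) -> np.ndarray:
    """4 mono- + 16 di-nucleotide frequencies of a sequence window."""
    bases = "ACGT"
    idx = {b: i for i, b in enumerate(bases)}
    mono = np.zeros(4)
    di = np.zeros(16)
    clean = [c for c in seq.upper() if c in idx]
    for c in clean:
        mono[idx[c]] += 1
    for a, b in zip(clean, clean[1:]):
        di[idx[a] * 4 + idx[b]] += 1
    if mono.sum() > 0:
        mono /= mono.sum()
    if di.sum() > 0:
        di /= di.sum()
    return np.concatenate([mono, di])


def _hit_window(sequences: dict[str, str], hit: MotifHit, flank: int) -> tuple[str, int]:
    seq = sequences[hit.interval.contig]
    start = max(0, hit.interval.start - flank)
    end = min(len(seq), hit.interval.end + flank)
    return seq[start:end], hit.interval.start - start


def build_training_sets(
    hits: Sequence[MotifHit],
    peaks: Sequence[Interval],
    ip_window_counts: Sequence[float],
    input_window_counts: Sequence[float],
    lib_ip: float,
    lib_input: float,
    sequences: dict[str, str],
    disrupted_peaks: Sequence[Interval] = (),
    n_per_class: int | None = None,
    comp_flank: int = 100,
) -> list[TrainingExample]:
    """Build bound/unbound anchor-site training examples.

    Positives are anchor hits inside peaks.  Negative candidates are
    hits outside all peaks whose library-normalized IP read count in the
    400-bp window around the hit does not exceed the normalized input
    count; they are greedily matched 1:1 to positives by Euclidean
    distance in mono+di-nucleotide composition space (hit +/-
    ``comp_flank`` bp), without replacement.  Hits inside
    ``disrupted_peaks`` (peaks containing anchor-motif discSNP
    disruptions) are excluded from both sets.
    """
    if len(ip_window_counts) != len(hits) or len(input_window_counts) != len(hits):
        raise ValueError("window counts must be parallel to hits")

    def in_any(intervals, hit):
        return any(
            iv.contig == hit.interval.contig
            and iv.start < hit.interval.end
            and hit.interval.start < iv.end
            for iv in intervals
        )

    positives, candidates = [], []
    for i, h in enumerate(hits):
        if in_any(disrupted_peaks, h):
            continue
        if in_any(peaks, h):
            positives.append(h)
        elif ip_window_counts[i] / lib_ip <= input_window_counts[i] / lib_input:
            candidates.append(h)

    if n_per_class is not None:
        positives = positives[:n_per_class]
    if len(candidates) < len(positives):
        raise ValueError(
            f"only {len(candidates)} eligible negatives for "
            f"{len(positives)} positives"
        )

    pos_comp = np.array(
        [composition_vector(_hit_window(sequences, h, comp_flank)[0]) for h in positives]
    )
    cand_comp = np.array(
        [composition_vector(_hit_window(sequences, h, comp_flank)[0]) for h in candidates]
    )
    available = np.ones(len(candidates), dtype=bool)
    matched = []
    for i in range(len(positives)):
        dists = np.linalg.norm(cand_comp - pos_comp[i], axis=1)
        dists[~available] = np.inf
        j = int(np.argmin(dists))
        available[j] = False
        matched.append(candidates[j])

    examples = []
    for h, label in [(h, BOUND) for h in positives] + [(h, UNBOUND) for h in matched]:
        window, offset = _hit_window(sequences, h, comp_flank + 50)
        examples.append(
            TrainingExample(
                site=h,
                label=label,
                anchor_score=h.score,
                sequence=window,
                anchor_offset=offset,
            )
        )
    return examples


def extract_context_features(
    examples: Sequence[TrainingExample],
    context_pwms: Sequence[PWM],
    radius: int = 100,
    score_floor: float = 0.0,
) -> pd.DataFrame:
    """Best contextual-motif score within ``radius`` bp of each anchor.

    For every contextual PWM the feature is the maximum log-odds score
    among placements whose edge-to-edge distance to the anchor hit is at
    most ``radius``; 0 when no placement reaches ``score_floor``.  The
    returned frame also carries the anchor score and fills each
    example's ``context_scores``.
    """
    data = {"anchor_score": [e.anchor_score for e in examples]}
    for pwm in context_pwms:
        col = []
        for e in examples:
            anchor_iv = (e.anchor_offset, e.anchor_offset + e.anchor_len)
            best = 0.0
            if len(e.sequence) >= len(pwm):
                for hit in score_pwm(pwm, e.sequence, min_score=score_floor):
                    gap = max(
                        0,
                        max(hit.interval.start, anchor_iv[0])
                        - min(hit.interval.end, anchor_iv[1]),
                    )
                    if gap <= radius:
                        best = max(best, hit.score)
            e.context_scores[pwm.motif_id] = best
            col.append(best)
        data[pwm.motif_id] = col
    return pd.DataFrame(data)


def shuffle_pwm(pwm: PWM, seed: int | np.random.Generator = 0) -> PWM:
    """Column-wise (position-wise) shuffle of a PWM.

    Positions are permuted uniformly at random; each position's base
    distribution is untouched, so total information content is conserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(pwm))
    return PWM(
        motif_id=f"{pwm.motif_id}_shuffled",
        tf_name=pwm.tf_name,
        family=pwm.family,
        matrix=pwm.matrix[perm].copy(),
    )


# ---------------------------------------------------------------------------
# model fitting and comparison

def _fit_logistic(X_train, y_train, ridge: float | None = None) -> LogisticRegression:
    if ridge is None:
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    else:
        model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    model.fit(X_train, y_train)
    return model


def fit_predict_cv(
    features: pd.DataFrame,
    labels: Sequence,
    spec_id: str = "contextual",
    feature_columns: Sequence[str] | None = None,
    n_folds: int = 10,
    n_runs: int = 10,
    seed: int = 0,
    ridge: float | None = None,
) -> ModelReport:
    """Cross-validated logistic regression on the given feature columns.

    Each of ``n_runs`` runs re-draws a stratified ``n_folds``-fold split;
    out-of-fold predicted probabilities are pooled into one ROC per run.
    """
    cols = list(feature_columns) if feature_columns is not None else list(features.columns)
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray([1 if l in (1, True, BOUND) else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")

    oof = np.zeros((n_runs, len(y)))
    aucs, rocs = [], []
    for run in range(n_runs):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + run)
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("single-class training fold")
            model = _fit_logistic(X[train_idx], y[train_idx], ridge)
            oof[run, test_idx] = model.predict_proba(X[test_idx])[:, 1]
        aucs.append(float(roc_auc_score(y, oof[run])))
        fpr, tpr, _ = roc_curve(y, oof[run])
        rocs.append((fpr, tpr))
    return ModelReport(
        spec_id=spec_id,
        feature_names=cols,
        labels=y,
        oof_scores=oof,
        aucs=aucs,
        rocs=rocs,
    )


def select_context_motifs(
    positives: Sequence[TrainingExample],
    negative_pool: Sequence[TrainingExample],
    candidate_pwms: Sequence[PWM],
    n_shuffles: int = 100,
    n_runs: int = 10,
    seed: int = 0,
    radius: int = 100,
    score_floor: float = 0.0,
    win_threshold: float = 0.9,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Select contextual motifs that beat their own shuffles.

    Per candidate motif and per run (each run re-draws the negative set
    from the pool), an anchor+candidate logistic model is compared with
    anchor+shuffled-candidate models over ``n_shuffles`` column shuffles;
    a win is a higher cross-validated AUC.  Motifs winning more than
    ``win_threshold`` of all runs x shuffles are selected.
    """
    if len(candidate_pwms) < 2:
        raise ValueError("need at least 2 candidate motifs")
    if len(negative_pool) < len(positives):
        raise ValueError("negative pool smaller than positive set")
    rng = np.random.default_rng(seed)
    rows = []
    for pwm in candidate_pwms:
        wins = total = 0
        for run in range(n_runs):
            neg_idx = rng.choice(len(negative_pool), size=len(positives), replace=False)
            examples = list(positives) + [negative_pool[i] for i in neg_idx]
            y = [e.label for e in examples]
            feats = extract_context_features(examples, [pwm], radius, score_floor)
            auc_candidate = fit_predict_cv(
                feats, y, n_folds=n_folds, n_runs=1,
                seed=int(rng.integers(2**31)),
            ).median_auc
            for _ in range(n_shuffles):
                shuf = shuffle_pwm(pwm, rng)
                sfeats = extract_context_features(examples, [shuf], radius, score_floor)
                auc_shuffle = fit_predict_cv(
                    sfeats, y, n_folds=n_folds, n_runs=1,
                    seed=int(rng.integers(2**31)),
                ).median_auc
                wins += auc_candidate > auc_shuffle
                total += 1
        frac = wins / total
        rows.append(dict(motif_id=pwm.motif_id, win_fraction=frac,
                         selected=frac > win_threshold))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DeLong test and operating points

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (V10, V01) and AUC of one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = v10.mean()
    return v10, v01, auc


def compare_roc(report_a: ModelReport, report_b: ModelReport) -> float:
    """DeLong's paired test for two correlated ROC curves.

    Both reports must be built on the same example set; the per-example
    out-of-fold scores (averaged over CV runs) are compared.  Returns the
    two-sided p for equal AUCs.
    """
    if len(report_a.labels) != len(report_b.labels) or not np.array_equal(
        report_a.labels, report_b.labels
    ):
        raise ValueError("reports are not paired on the same examples")
    labels = report_a.labels
    sa, sb = report_a.mean_scores, report_b.mean_scores
    v10a, v01a, auc_a = _delong_components(sa, labels)
    v10b, v01b, auc_b = _delong_components(sb, labels)
    m, n = len(v10a), len(v01a)

    def cov(u, v):
        return np.cov(u, v, ddof=1)[0, 1] if len(u) > 1 else 0.0

    var = (
        (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m
        + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    )
    if var <= 0:
        return 1.0 if np.isclose(auc_a, auc_b) else 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(np.clip(2 * stats.norm.sf(abs(z)), 0.0, 1.0))


def sensitivity_at_fdr(
    scores: Sequence[float],
    labels: Sequence,
    fdr_target: float = 0.3,
) -> tuple[float, float]:
    """Best sensitivity achievable at an empirical FDR constraint.

    Scans unique score thresholds (prediction = score >= threshold) in
    descending order and returns (sensitivity, threshold) of the
    threshold maximizing sensitivity subject to FP/(FP+TP) <= target;
    (nan, nan) when no threshold qualifies.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (1, True, BOUND) else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # thresholds at the last occurrence of each unique score
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp, thr = tp[last], fp[last], s_sorted[last]
    fdr = fp / np.maximum(fp + tp, 1)
    sens = tp / y.sum()
    ok = fdr <= fdr_target
    if not ok.any():
        return float("nan"), float("nan")
    best_sens = sens[ok].max()
    best_thr = thr[ok & (sens == best_sens)].max()
    return float(best_sens), float(best_thr)
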