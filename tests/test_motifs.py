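import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allelescan as a
from allelescan.core import revcomp
from tests.conftest import make_uniform_pwm

BASES = "ACGT"


def naive_score(pwm: a.PWM, subseq: str) -> float:
    """Independent per-position log-odds sum (plain math, no numpy paths)."""
    total = 0.0
    for i, base in enumerate(subseq):
        total += math.log2(pwm.matrix[i, BASES.index(base)] / 0.25)
    return total


def brute_force_best_placement(snp_pos0, seq_a, seq_b, pwm, window=40):
    """Enumerate every placement x strand containing the SNP and return
    (score_max, diff_score) at the placement maximizing the better
    allele's score.  Fully independent of analyze_disc_snp internals."""
    half = window // 2
    lo = max(0, snp_pos0 - half)
    hi = min(len(seq_a), snp_pos0 + half)
    best = None
    w = len(pwm)
    for start in range(lo, hi - w + 1):
        if not (start <= snp_pos0 < start + w):
            continue
        sub_a, sub_b = seq_a[start : start + w], seq_b[start : start + w]
        if "N" in sub_a or "N" in sub_b:
            continue
        for strand in ("+", "-"):
            if strand == "+":
                sa, sb = naive_score(pwm, sub_a), naive_score(pwm, sub_b)
            else:
                sa, sb = naive_score(pwm, revcomp(sub_a)), naive_score(pwm, revcomp(sub_b))
            key = round(max(sa, sb), 9)  # same tie rule as the implementation
            if best is None or key > best[0]:
                best = (key, abs(sa - sb))
    return best


class TestScorePwm:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = make_uniform_pwm(length=4)
        hits = a.score_pwm(pwm, "ACGTACGT", min_score=-1)
        assert len(hits) == 10  # 5 placements x 2 strands
        assert all(h.score == pytest.approx(0.0) for h in hits)

    def test_two_column_hand_arithmetic(self):
        pwm = a.PWM.from_probabilities("m", [[1, 0, 0, 0], [0, 1, 0, 0]])
        expected = 2 * math.log2((1.001 / 1.004) / 0.25)
        (hit,) = [h for h in a.score_pwm(pwm, "AC", min_score=-100)
                  if h.interval.strand == "+"]
        assert hit.score == pytest.approx(expected)

    def test_reverse_strand_scores_reverse_complement(self, anchor_pwm):
        seq = "TTGATAAGTT"  # contains AGATAA start.. actually TTATCT rc
        fwd = a.score_pwm(anchor_pwm, seq, min_score=-100)
        rev = a.score_pwm(anchor_pwm, revcomp(seq), min_score=-100)
        assert sorted(round(h.score, 9) for h in fwd) == sorted(
            round(h.score, 9) for h in rev
        )

    def test_n_positions_skipped(self, anchor_pwm):
        hits = a.score_pwm(anchor_pwm, "AGANAA" + "AGATAA", min_score=-1000)
        assert all(
            "N" not in "AGANAAAGATAA"[h.interval.start : h.interval.end] for h in hits
        )

    def test_sequence_shorter_than_pwm_rejected(self, anchor_pwm):
        with pytest.raises(ValueError):
            a.score_pwm(anchor_pwm, "ACG")

    def test_scores_match_naive_arithmetic(self, anchor_pwm):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(BASES), 60))
        for h in a.score_pwm(anchor_pwm, seq, min_score=-1000):
            sub = seq[h.interval.start : h.interval.end]
            if h.interval.strand == "-":
                sub = revcomp(sub)
            assert h.score == pytest.approx(naive_score(anchor_pwm, sub))


class TestAnalyzeDiscSnp:
    @staticmethod
    def _random_case(rng, pwm):
        seq = "".join(rng.choice(list(BASES), 200))
        pos0 = int(rng.integers(20, 180))
        alt = rng.choice([b for b in BASES if b != seq[pos0]])
        seq_b = seq[:pos0] + alt + seq[pos0 + 1 :]
        return seq, seq_b, pos0

    def test_identical_alleles_give_zero_diff(self, anchor_pwm):
        seq = {"c": "A" * 30 + "AGATAA" + "C" * 30}
        snp = a.DiscSNP("c", 33, "T", "A")  # bases differ in record, seqs equal
        events = a.analyze_disc_snp(snp, seq, seq, [anchor_pwm])
        assert events and all(e.diff_score == pytest.approx(0.0) for e in events)
        assert all(e.disrupted_line is None for e in events)

    def test_consensus_destroying_snp_assigns_disrupted_line(self, anchor_pwm):
        base = "T" * 30 + "AGATAA" + "T" * 30
        broken = "T" * 30 + "AGCTAA" + "T" * 30  # A->C at motif position 3
        snp_pos = 33  # 1-based
        snp = a.DiscSNP("c", snp_pos, base[snp_pos - 1], broken[snp_pos - 1])
        events = a.analyze_disc_snp(snp, {"c": base}, {"c": broken}, [anchor_pwm])
        (e,) = events
        assert e.disrupted_line == "B"
        assert e.position_in_motif == 3
        assert e.intact_base == "A" and e.variant_base == "C"
        assert e.diff_score > 0

    def test_matches_brute_force_enumeration(self, anchor_pwm, context_pwm):
        rng = np.random.default_rng(42)
        for _ in range(60):
            seq_a, seq_b, pos0 = self._random_case(rng, anchor_pwm)
            for pwm in (anchor_pwm, context_pwm):
                events = a.analyze_disc_snp(
                    a.DiscSNP("c", pos0 + 1, seq_a[pos0], seq_b[pos0]),
                    {"c": seq_a},
                    {"c": seq_b},
                    [pwm],
                )
                expected = brute_force_best_placement(pos0, seq_a, seq_b, pwm)
                assert expected is not None
                (e,) = events
                assert e.score_max == pytest.approx(expected[0], abs=1e-9)
                assert e.diff_score == pytest.approx(expected[1], abs=1e-9)

    def test_strand_symmetry(self, anchor_pwm):
        rng = np.random.default_rng(7)
        seq_a, seq_b, pos0 = self._random_case(rng, anchor_pwm)
        (e,) = a.analyze_disc_snp(
            a.DiscSNP("c", pos0 + 1, seq_a[pos0], seq_b[pos0]),
            {"c": seq_a}, {"c": seq_b}, [anchor_pwm],
        )
        # reverse-complement the whole world; SNP lands at mirrored position
        ra, rb = revcomp(seq_a), revcomp(seq_b)
        rpos0 = len(seq_a) - 1 - pos0
        (er,) = a.analyze_disc_snp(
            a.DiscSNP("c", rpos0 + 1, ra[rpos0], rb[rpos0]),
            {"c": ra}, {"c": rb}, [anchor_pwm],
        )
        assert er.score_max == pytest.approx(e.score_max)
        assert er.diff_score == pytest.approx(e.diff_score)

    def test_window_clipped_at_contig_edge(self, anchor_pwm):
        seq_a = "AGATAA" + "T" * 10
        seq_b = "AGCTAA" + "T" * 10
        snp = a.DiscSNP("c", 3, "A", "C")
        events = a.analyze_disc_snp(snp, {"c": seq_a}, {"c": seq_b}, [anchor_pwm])
        assert events and events[0].placement.start >= 0


class TestCallDisruptions:
    def _event(self, score_a, score_b):
        return a.DisruptionEvent(
            disc_snp=a.DiscSNP("c", 10, "A", "G"),
            motif_id="m",
            placement=a.Interval("c", 5, 11, "+"),
            score_allele_a=score_a,
            score_allele_b=score_b,
            disrupted_line="B",
            position_in_motif=5,
            intact_base="A",
            variant_base="G",
        )

    @pytest.mark.parametrize(
        "score_a,score_b,called",
        [
            (8.0, 5.0, True),    # score_max 8.0, diff 3.0
            (7.4, 2.4, False),   # below score threshold
            (9.0, 6.6, False),   # diff 2.4 below disruption threshold
            (7.5, 5.0, True),    # thresholds inclusive
        ],
    )
    def test_default_thresholds(self, score_a, score_b, called):
        (out,) = a.call_disruptions([self._event(score_a, score_b)])
        assert out.is_called_disruption is called

    @given(
        t1=st.floats(0, 20), t2=st.floats(0, 10),
        d1=st.floats(0, 5), d2=st.floats(0, 5),
    )
    def test_monotone_in_thresholds(self, t1, t2, d1, d2):
        events = [self._event(9.0, 4.0), self._event(6.0, 5.5), self._event(12.0, 1.0)]
        loose = a.call_disruptions(events, a.ThresholdConfig(t1, t2))
        tight = a.call_disruptions(events, a.ThresholdConfig(t1 + d1, t2 + d2))
        for lo, hi in zip(loose, tight):
            assert not (hi.is_called_disruption and not lo.is_called_disruption)


class TestMergeMotifFamily:
    def _event(self, motif_id, score_a, score_b, pos=10):
        return a.DisruptionEvent(
            disc_snp=a.DiscSNP("c", pos, "A", "G"),
            motif_id=motif_id,
            placement=a.Interval("c", 5, 11, "+"),
            score_allele_a=score_a,
            score_allele_b=score_b,
            disrupted_line="B",
            position_in_motif=5,
            intact_base="A",
            variant_base="G",
        )

    FAMILY = {"Gata2": "GATA", "Gata4": "GATA", "Tal1": "EBOX"}

    def test_keeps_highest_scoring_family_member(self):
        events = [self._event("Gata2", 9.1, 4.0), self._event("Gata4", 8.0, 3.0)]
        (merged,) = a.merge_motif_family(events, self.FAMILY)
        assert merged.motif_id == "GATA"
        assert merged.score_max == pytest.approx(9.1)

    def test_single_member_family_is_identity_up_to_rename(self):
        events = [self._event("Tal1", 7.0, 3.0)]
        (merged,) = a.merge_motif_family(events, self.FAMILY)
        assert merged.motif_id == "EBOX"
        assert merged.score_allele_a == 7.0

    def test_tie_broken_lexicographically(self):
        events = [self._event("Gata4", 9.0, 4.0), self._event("Gata2", 9.0, 4.0)]
        (merged,) = a.merge_motif_family(events, self.FAMILY)
        assert merged.placement == events[1].placement  # Gata2 kept

    def test_unmapped_motif_rejected(self):
        with pytest.raises(ValueError, match="family map"):
            a.merge_motif_family([self._event("Zfp1", 5, 3)], self.FAMILY)


class TestOptimizeThresholds:
    def test_recovers_planted_diff_threshold(self, anchor_pwm):
        rng = np.random.default_rng(3)
        events, residuals = [], []
        for _ in range(400):
            diff = float(rng.uniform(0, 6))
            score_max = float(rng.uniform(6, 14))
            e = a.DisruptionEvent(
                disc_snp=a.DiscSNP("c", 10, "A", "G"),
                motif_id="m",
                placement=a.Interval("c", 5, 11, "+"),
                score_allele_a=score_max,
                score_allele_b=score_max - diff,
                disrupted_line="B",
                position_in_motif=3,
                intact_base="A",
                variant_base="G",
            )
            # only true disruptions (diff >= 2.5 on a real site) lose signal
            loss = 50.0 if (diff >= 2.5 and score_max >= 7.5) else 0.0
            residuals.append(100.0 - loss + rng.normal(0, 5))
            events.append(e)
        config, report = a.optimize_thresholds(events, residuals, n_runs=20, seed=0)
        assert report["converged"]
        assert config.diff_score_thres == pytest.approx(2.5, abs=1.0)

    def test_flat_objective_flags_non_converged(self):
        rng = np.random.default_rng(4)
        events = [
            a.DisruptionEvent(
                disc_snp=a.DiscSNP("c", 10, "A", "G"),
                motif_id="m",
                placement=a.Interval("c", 5, 11, "+"),
                score_allele_a=30.0,  # every threshold in the box calls everything
                score_allele_b=15.0,
                disrupted_line="B",
                position_in_motif=3,
                intact_base="A",
                variant_base="G",
            )
            for _ in range(150)
        ]
        residuals = [100.0] * 150
        config, report = a.optimize_thresholds(events, residuals, n_runs=5, seed=1)
        assert not report["converged"]
        assert 0 <= config.score_thres <= 20

    def test_deterministic_under_seed(self, anchor_pwm):
        rng = np.random.default_rng(5)
        events = [
            a.DisruptionEvent(
                disc_snp=a.DiscSNP("c", 10, "A", "G"),
                motif_id="m",
                placement=a.Interval("c", 5, 11, "+"),
                score_allele_a=float(rng.uniform(5, 15)),
                score_allele_b=float(rng.uniform(0, 10)),
                disrupted_line="B",
                position_in_motif=3,
                intact_base="A",
                variant_base="G",
            )
            for _ in range(120)
        ]
        residuals = list(rng.uniform(20, 110, size=120))
        c1, _ = a.optimize_thresholds(events, residuals, n_runs=5, seed=9)
        c2, _ = a.optimize_thresholds(events, residuals, n_runs=5, seed=9)
        assert c1 == c2

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            a.optimize_thresholds([], [])


class TestMotifEnrichment:
    def _peaks(self, seqs_dict, prefix, sequences):
        out = []
        for i, s in enumerate(sequences):
            name = f"{prefix}{i}"
            seqs_dict[name] = s
            out.append(a.Interval(name, 0, len(s)))
        return out

    def test_identical_sets_not_enriched(self, anchor_pwm):
        rng = np.random.default_rng(0)
        seqs = {}
        peaks = self._peaks(
            seqs, "p", ["".join(rng.choice(list(BASES), 80)) for _ in range(15)]
        )
        table = a.motif_enrichment(peaks, peaks, seqs, [anchor_pwm])
        row = table.iloc[0]
        assert row.fg_present == row.bg_present
        assert np.isnan(row.odds_ratio) or row.odds_ratio == pytest.approx(1.0)
        assert row.q > 0.9

    def test_planted_motif_detected(self, anchor_pwm, context_pwm):
        rng = np.random.default_rng(1)
        seqs = {}

        def random_peak(with_motif):
            s = "".join(rng.choice(list(BASES), 80))
            if with_motif:
                s = s[:30] + "AGATAA" + s[36:]
            return s

        fg = self._peaks(seqs, "f", [random_peak(rng.random() < 0.8) for _ in range(100)])
        bg = self._peaks(seqs, "b", [random_peak(rng.random() < 0.1) for _ in range(100)])
        table = a.motif_enrichment(fg, bg, seqs, [anchor_pwm, context_pwm]).set_index(
            "motif_id"
        )
        assert table.loc["GATA1", "q"] < 0.01
        assert table.loc["GATA1", "odds_ratio"] > 1

    def test_small_peak_sets_rejected(self, anchor_pwm):
        iv = [a.Interval("c", 0, 50)] * 5
        with pytest.raises(ValueError):
            a.motif_enrichment(iv, iv, {"c": "A" * 50}, [anchor_pwm])
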