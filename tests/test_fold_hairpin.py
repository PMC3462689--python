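from functools import lru_cache

import numpy as np
import pytest

from smallrna_forge._util import revcomp
from smallrna_forge.fold import MIN_LOOP, FoldResult, fold
from smallrna_forge.hairpin import (
    HairpinParams,
    amfe,
    detect_novel,
    evaluate_precursor,
    find_duplex,
    mature_spans_loop,
    mfei,
)
from smallrna_forge.io_formats import SeqRecord, UniqueTag
from smallrna_forge.simulate import generate_hairpin

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def nussinov_pair_count(seq: str) -> int:
    """Textbook recursive Nussinov maximum-pairing DP (independent oracle)."""

    @lru_cache(maxsize=None)
    def dp(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        best = dp(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                inner = dp(i + 1, k - 1) if k - 1 >= i + 1 else 0
                rest = dp(k + 1, j) if k + 1 <= j else 0
                best = max(best, inner + rest + 1)
        return best

    return dp(0, len(seq) - 1)


def _rng_seq(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


class TestFoldEngine:
    def test_unpairable_sequence(self):
        r = fold("A" * 12)
        assert r.structure == "." * 12 and r.mfe == 0.0 and r.n_pairs == 0

    def test_forced_nested_stem(self):
        r = fold("GGGGAAAACCCC")
        assert r.structure == "((((....))))"
        assert r.mfe < 0

    def test_perfect_inverted_repeat_pairs(self):
        rng = np.random.default_rng(4)
        stem = _rng_seq(rng, 30)
        seq = stem + "AAAAAA" + revcomp(stem)
        r = fold(seq)
        assert r.n_pairs >= 28
        assert r.n_pairs == nussinov_pair_count(seq)

    def test_pair_count_matches_textbook_dp(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            seq = _rng_seq(rng, int(rng.integers(10, 55)))
            assert fold(seq).n_pairs == nussinov_pair_count(seq)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        seq = _rng_seq(rng, 80)
        a, b = fold(seq), fold(seq)
        assert a.structure == b.structure and a.mfe == b.mfe

    def test_alphabet_violation(self):
        with pytest.raises(ValueError):
            fold("ACGX")

    def test_balanced_brackets(self):
        rng = np.random.default_rng(9)
        s = fold(_rng_seq(rng, 120)).structure
        depth = 0
        for c in s:
            depth += {"(": 1, ")": -1}.get(c, 0)
            assert depth >= 0
        assert depth == 0


class TestEnergyIndices:
    @pytest.mark.parametrize(
        "mfe_val,length,gc,exp_amfe,exp_mfei",
        [
            (-30.0, 100, 50.0, 30.0, 0.60),
            (-45.5, 91, 62.0, 50.0, 50.0 / 62.0),
            (0.0, 100, 50.0, 0.0, 0.0),
        ],
    )
    def test_closed_forms(self, mfe_val, length, gc, exp_amfe, exp_mfei):
        assert amfe(mfe_val, length) == pytest.approx(exp_amfe)
        assert mfei(mfe_val, length, gc) == pytest.approx(exp_mfei)

    def test_gc_zero_division_error(self):
        with pytest.raises(ZeroDivisionError):
            mfei(-30, 100, 0.0)

    def test_mfei_depends_only_on_mfe_length_gc(self):
        # invariance to sequence identity given the three arguments
        assert mfei(-42, 120, 55) == mfei(-42, 120, 55)
        assert mfei(-42, 120, 55) == pytest.approx((42 / 120 * 100) / 55)


class TestDuplex:
    def _planted(self, seed=0, **kw):
        rng = np.random.default_rng(seed)
        mature = "".join(
            "ACGU"[b] for b in rng.integers(0, 4, 21)
        )
        while not (0.38 <= (mature.count("G") + mature.count("C")) / 21 <= 0.7):
            mature = "".join("ACGU"[b] for b in rng.integers(0, 4, 21))
        pre, m_span, s_span = generate_hairpin(mature, rng=rng, **kw)
        return pre, m_span, s_span

    def test_star_recovered_at_construction_site(self):
        pre, m_span, s_span = self._planted(seed=2)
        d = find_duplex(fold(pre), m_span)
        assert d is not None
        assert d.star_span == s_span
        assert d.overhang3_mature == 2 and d.overhang3_star == 2

    def test_star_of_star_round_trip(self):
        pre, m_span, s_span = self._planted(seed=3)
        r = fold(pre)
        d = find_duplex(r, m_span)
        back = find_duplex(r, d.star_span)
        # the star's star is the mature, up to the reciprocal 2-nt overhangs
        assert abs(back.star_span[0] - m_span[0]) <= 2
        assert abs(back.star_span[1] - m_span[1]) <= 2

    def test_mature_on_loop_returns_none(self):
        rng = np.random.default_rng(6)
        stem = _rng_seq(rng, 25)
        seq = stem + "ACACAAAC" + revcomp(stem)
        r = fold(seq)
        centre = (len(seq) // 2 - 10, len(seq) // 2 + 10)
        assert mature_spans_loop(r, centre)
        assert find_duplex(r, centre) is None

    def test_mismatch_threshold(self):
        pre, m_span, _ = self._planted(seed=4)
        r = fold(pre)
        assert find_duplex(r, m_span, max_duplex_mismatch=4) is not None
        # an unstructured span has no duplex at all
        assert find_duplex(fold("A" * 60), (10, 30)) is None


class TestEvaluatePrecursor:
    def test_planted_hairpin_passes_all_criteria(self):
        rng = np.random.default_rng(11)
        mature = "UGACAGAAGAGAGUGAGCACA"
        pre, m_span, _ = generate_hairpin(mature, rng=rng)
        rep = evaluate_precursor(pre, mature=m_span)
        assert rep.passes and rep.failed_criteria == []
        assert rep.n_stems == 1 and rep.duplex is not None

    def test_mfe_threshold_recorded(self):
        rng = np.random.default_rng(12)
        pre, m_span, _ = generate_hairpin("UGACAGAAGAGAGUGAGCACA", rng=rng)
        rep = evaluate_precursor(pre, mature=m_span, params=HairpinParams(mfe_max=-500))
        assert "MFE" in rep.failed_criteria and not rep.passes

    def test_mfei_threshold_recorded(self):
        rng = np.random.default_rng(13)
        pre, m_span, _ = generate_hairpin("UGACAGAAGAGAGUGAGCACA", rng=rng)
        rep = evaluate_precursor(pre, mature=m_span, params=HairpinParams(mfei_min=50.0))
        assert "MFEI" in rep.failed_criteria

    def test_excess_planted_mismatches_fail_duplex(self):
        rng = np.random.default_rng(14)
        pre, m_span, _ = generate_hairpin(
            "UGACAGAAGAGAGUGAGCACA", stem_mismatches=5, rng=rng
        )
        rep = evaluate_precursor(
            pre, mature=m_span, params=HairpinParams(max_duplex_mismatch=4)
        )
        assert "duplex" in rep.failed_criteria or "mature_in_loop" in rep.failed_criteria

    def test_planted_recall_at_least_95_percent(self):
        rng = np.random.default_rng(15)
        n_pass = 0
        for _ in range(40):
            mature = _rng_seq(rng, 21)
            while not (0.38 <= (mature.count("G") + mature.count("C")) / 21 <= 0.7):
                mature = _rng_seq(rng, 21)
            pre, m_span, _ = generate_hairpin(mature, rng=rng)
            if evaluate_precursor(pre, mature=m_span).passes:
                n_pass += 1
        assert n_pass >= 38  # 95% of 40


class TestGenerateHairpin:
    def test_flank_zero_length_arithmetic(self):
        rng = np.random.default_rng(16)
        mature = "UGACAGAAGAGAGUGAGCACA"
        pre, _, _ = generate_hairpin(mature, loop_len=8, flank=0, rng=rng)
        assert len(pre) == 2 * (len(mature) + 2) + 8

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError):
            generate_hairpin("UGACAGAAGAGAGUGAGCACA", loop_len=2)

    def test_mature_length_bounds(self):
        with pytest.raises(ValueError):
            generate_hairpin("ACGU" * 8)  # 32 nt


class TestDetectNovel:
    def test_recovers_exactly_the_planted_matures(self, small_lib):
        from smallrna_forge.preprocess import run_cascade
        from smallrna_forge.annotate import ReferenceSet, build_index, classify_all

        tags, _ = run_cascade(small_lib.reads)
        refsets = [
            ReferenceSet("rRNA", small_lib.refs["rRNA"], "rRNA"),
            ReferenceSet("tRNA", small_lib.refs["tRNA"], "tRNA"),
            ReferenceSet("snRNA", small_lib.refs["snRNA"], "snRNA"),
            ReferenceSet("snoRNA", small_lib.refs["snoRNA"], "snoRNA"),
            ReferenceSet("repeat", small_lib.refs["repeat"], "repeat"),
            ReferenceSet(
                "known_miRNA", small_lib.refs["mature_mirna"], "known_miRNA_mature"
            ),
            ReferenceSet("exon", small_lib.refs["transcripts"], "exon"),
        ]
        recs = classify_all(tags, build_index(refsets))
        candidates = [
            r.tag for r in recs if r.category in ("exon_sense", "exon_antisense", "unannotated")
        ]
        calls = detect_novel(
            candidates,
            small_lib.refs["transcripts"],
            known_precursors=small_lib.refs["precursor_mirna"],
        )
        assert {c.mature.seq for c in calls} == {
            d["mature"] for d in small_lib.manifest.novel
        }

    def test_tag_inside_known_precursor_excluded(self):
        rng = np.random.default_rng(17)
        mature = "UGACAGAAGAGAGUGAGCACA"
        pre, _, _ = generate_hairpin(mature, rng=rng)
        transcript = SeqRecord("tx", "ACAC" * 20 + pre + "CACA" * 20)
        calls = detect_novel(
            [UniqueTag(mature, 5)],
            [transcript],
            known_precursors=[SeqRecord("known_pre", pre)],
        )
        assert calls == []
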