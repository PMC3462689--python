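import numpy as np
import pytest

from smallrna_forge._util import revcomp
from smallrna_forge.io_formats import SeqRecord
from smallrna_forge.simulate import make_target_site
from smallrna_forge.targets import (
    ScoringScheme,
    predict_targets,
    scan_transcript,
    score_site,
)

MIR = "UGACAGAAGAGAGUGAGCACA"  # 21 nt

#: scheme without the miRU sub-rules, for oracle comparisons
PLAIN = ScoringScheme(forbid_gap_at_cleavage=False, max_consecutive_mismatch=0)


def oracle_score(mirna, site, scheme=PLAIN):
    """Exhaustive enumeration over all <=1-gap antiparallel alignments,
    written independently of the implementation."""
    WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    GU = {("G", "U"), ("U", "G")}

    def pen(m_base, t_base, pos):
        p = 0.0 if (m_base, t_base) in WC else (
            scheme.gu_penalty if (m_base, t_base) in GU else scheme.mismatch_penalty
        )
        return p * (scheme.seed_multiplier if scheme.seed_start <= pos <= scheme.seed_end else 1.0)

    def gap_pen(pos):
        mult = scheme.seed_multiplier if scheme.seed_start <= pos <= scheme.seed_end else 1.0
        return scheme.gap_penalty * mult

    t = site[::-1]
    n = len(mirna)
    scores = []
    if len(t) == n:
        scores.append(sum(pen(mirna[i], t[i], i + 1) for i in range(n)))
    if len(t) == n + 1:
        for g in range(n + 1):
            gov = min(g + 1, n)
            if scheme.forbid_gap_at_cleavage and gov in (10, 11):
                continue
            s = gap_pen(gov)
            for i in range(n):
                s += pen(mirna[i], t[i] if i < g else t[i + 1], i + 1)
            scores.append(s)
    if len(t) == n - 1:
        for g in range(1, n + 1):
            if scheme.forbid_gap_at_cleavage and g in (10, 11):
                continue
            s = gap_pen(g)
            for i in range(n):
                if i == g - 1:
                    continue
                s += pen(mirna[i], t[i] if i < g - 1 else t[i - 1], i + 1)
            scores.append(s)
    return min(scores) if scores else float("inf")


def _rng_seq(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        score, states = score_site(MIR, revcomp(MIR))
        assert score == 0.0 and set(states) == {"WC"}

    def test_single_mismatch_outside_seed(self):
        site = list(revcomp(MIR))
        site[len(MIR) - 12] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[len(MIR) - 12]]
        assert score_site(MIR, "".join(site))[0] == 1.0

    def test_seed_gu_is_doubled(self):
        m = "UGAGAGAAGAGAGUGAGCACA"  # G at position 4
        site = list(revcomp(m))
        site[len(m) - 4] = "U"
        assert score_site(m, "".join(site))[0] == 1.0  # 0.5 x 2

    def test_seed_doubling_exactly_doubles_a_mismatch(self):
        mm = {"A": "C", "C": "A", "G": "A", "U": "C"}
        outside = list(revcomp(MIR))
        outside[len(MIR) - 12] = mm[outside[len(MIR) - 12]]
        inside = list(revcomp(MIR))
        inside[len(MIR) - 4] = mm[inside[len(MIR) - 4]]
        s_out = score_site(MIR, "".join(outside), PLAIN)[0]
        s_in = score_site(MIR, "".join(inside), PLAIN)[0]
        assert s_in == 2 * s_out == 2.0

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIR, "N" * 21)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(250):
            m = _rng_seq(rng, 21)
            kind = rng.integers(0, 4)
            if kind == 0:
                site = _rng_seq(rng, 21 + int(rng.integers(-1, 2)))
            else:  # near-complementary cases exercise the interesting region
                site = list(revcomp(m))
                for _k in range(int(rng.integers(0, 5))):
                    p = int(rng.integers(0, len(site)))
                    site[p] = "ACGU"[int(rng.integers(0, 4))]
                site = "".join(site)
                if kind == 3:
                    p = int(rng.integers(0, len(site)))
                    site = site[:p] + _rng_seq(rng, 1) + site[p:]
            got, _ = score_site(m, site, PLAIN)
            assert got == pytest.approx(oracle_score(m, site))

    def test_reported_score_equals_recomputed_penalty(self):
        rng = np.random.default_rng(22)
        scheme = ScoringScheme()
        for _ in range(50):
            m = _rng_seq(rng, 21)
            site = list(revcomp(m))
            for _k in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, 21))
                site[p] = "ACGU"[int(rng.integers(0, 4))]
            score, states = score_site(m, "".join(site), scheme)
            # recompute from the emitted column states
            total, pos = 0.0, 0
            for st in states:
                gov = min(pos + 1, 21) if st == "GAP" else pos + 1
                p = {"WC": 0.0, "GU": 0.5, "MM": 1.0, "GAP": 2.0}[st]
                if scheme.seed_start <= gov <= scheme.seed_end:
                    p *= 2
                total += p
                if st != "GAP":
                    pos += 1
            assert total == pytest.approx(score)


class TestScanTranscript:
    def test_planted_perfect_site(self):
        rng = np.random.default_rng(23)
        site = revcomp(MIR)
        tr = SeqRecord("t1", _rng_seq(rng, 200) + site + _rng_seq(rng, 150))
        hits = scan_transcript("m", MIR, tr)
        assert len(hits) == 1
        assert hits[0].site_span == (201, 221) and hits[0].score == 0.0

    def test_score_above_cutoff_not_reported(self):
        rng = np.random.default_rng(24)
        site = make_target_site(MIR, 4.5, rng)
        tr = SeqRecord("t1", _rng_seq(rng, 100) + site + _rng_seq(rng, 100))
        assert all(h.site_span != (101, 121) for h in scan_transcript("m", MIR, tr))

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(25)
        tr = SeqRecord(
            "t1",
            _rng_seq(rng, 80) + make_target_site(MIR, 2.0, rng) + _rng_seq(rng, 80)
            + make_target_site(MIR, 4.0, rng) + _rng_seq(rng, 60),
        )
        n_by_cutoff = [
            len(scan_transcript("m", MIR, tr, ScoringScheme(cutoff=c)))
            for c in (1.0, 2.0, 3.0, 4.0, 5.0)
        ]
        assert n_by_cutoff == sorted(n_by_cutoff)

    def test_planted_sites_recovered_with_exact_scores(self, small_lib):
        mat = {r.id: r.seq for r in small_lib.refs["mature_mirna"]}
        trs = {t.id: t for t in small_lib.refs["transcripts"]}
        for entry in small_lib.manifest.target_sites:
            if entry["score"] > 4.0:
                continue
            hits = scan_transcript(
                entry["mirna_id"], mat[entry["mirna_id"]], trs[entry["transcript_id"]]
            )
            assert any(
                h.site_span == tuple(entry["span"]) and h.score == entry["score"]
                for h in hits
            ), entry


class TestPredictTargets:
    def test_family_members_deduplicated_to_best_score(self):
        rng = np.random.default_rng(26)
        m2 = list(MIR)
        m2[12] = "A" if m2[12] != "A" else "C"
        m2 = "".join(m2)
        tr = SeqRecord("t1", _rng_seq(rng, 100) + revcomp(MIR) + _rng_seq(rng, 100))
        df = predict_targets(
            [("miR-x1", "MIRX", MIR), ("miR-x2", "MIRX", m2)], [tr]
        )
        assert len(df) == 1
        assert df.iloc[0]["score"] == 0.0 and df.iloc[0]["mirna_id"] == "miR-x1"

    def test_empty_db(self):
        assert predict_targets([("m", "F", MIR)], []).empty

    def test_manifest_family_counts(self, small_lib):
        mat = {r.id: r.seq for r in small_lib.refs["mature_mirna"]}
        wanted = {
            (e["mirna_id"], e["family"]) for e in small_lib.manifest.target_sites
        }
        mirnas = [(mid, fam, mat[mid]) for mid, fam in sorted(wanted)]
        df = predict_targets(mirnas, small_lib.refs["transcripts"])
        got = {
            (r.family, r.transcript_id): r.score for r in df.itertuples()
        }
        for e in small_lib.manifest.target_sites:
            if e["score"] <= 4.0:
                key = (e["family"], e["transcript_id"])
                assert key in got and got[key] <= e["score"]


class TestMakeTargetSite:
    @pytest.mark.parametrize("score", [0.0, 0.5, 2.0, 3.5, 4.5])
    def test_requested_scores_are_hit_exactly(self, score):
        rng = np.random.default_rng(int(score * 10) + 1)
        site = make_target_site(MIR, score, rng)
        assert score_site(MIR, site)[0] == score

    def test_off_lattice_request_rejected(self):
        with pytest.raises(ValueError):
            make_target_site(MIR, 1.3, np.random.default_rng(0))
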