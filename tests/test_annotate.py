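import numpy as np
import pytest

from smallrna_forge._util import revcomp
from smallrna_forge.annotate import (
    DEFAULT_PRECEDENCE,
    ReferenceSet,
    build_index,
    classify_all,
    classify_tag,
    length_profile,
    subtract_classes,
    summarize,
    summary_from_counts,
)
from smallrna_forge.io_formats import SeqRecord, UniqueTag

# Published category accounting used for the arithmetic checks
TABLE3_UNIQUE = {
    "rRNA": 90192, "tRNA": 18394, "snRNA": 2004, "snoRNA": 894,
    "repeat": 12017, "known_miRNA": 31979, "unannotated": 2672411,
}
TABLE3_REDUNDANT = {
    "rRNA": 2929163, "tRNA": 1611677, "snRNA": 6415, "snoRNA": 2428,
    "repeat": 736626, "known_miRNA": 1789329, "unannotated": 6907892,
}
TOTAL_UNIQUE = 2815874
TOTAL_CLEAN = 13246904


def _rng_seq(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def toy_index():
    rng = np.random.default_rng(3)
    rrna = SeqRecord("rrna1", _rng_seq(rng, 100))
    exon = SeqRecord("tx1", _rng_seq(rng, 200))
    mirna = SeqRecord("ath-miR156a", rrna.seq[9:31])  # shares rRNA content
    refs = [
        ReferenceSet("rRNA", [rrna], "rRNA"),
        ReferenceSet("known_miRNA", [mirna], "known_miRNA_mature"),
        ReferenceSet("exon", [exon], "exon"),
    ]
    return build_index(refs), rrna, exon


class TestSearchIndex:
    def test_plus_strand_hit(self, toy_index):
        index, rrna, _ = toy_index
        hits = index.hits(rrna.seq[9:31])
        assert hits["rRNA"] == ("rrna1", "+")

    def test_minus_strand_hit(self, toy_index):
        index, rrna, _ = toy_index
        hits = index.hits(revcomp(rrna.seq[9:31]))
        assert hits["rRNA"] == ("rrna1", "-")

    def test_absent_query_no_hit(self, toy_index):
        index, _, _ = toy_index
        assert index.hits("U" * 22) == {}


class TestClassify:
    def test_precedence_forces_rrna_over_mirna(self, toy_index):
        index, rrna, _ = toy_index
        rec = classify_tag(UniqueTag(rrna.seq[9:31], 5), index)
        assert rec.category == "rRNA"

    def test_exon_antisense_by_strand(self, toy_index):
        index, _, exon = toy_index
        rec = classify_tag(UniqueTag(revcomp(exon.seq[50:72]), 1), index)
        assert rec.category == "exon_antisense"
        assert rec.strand == "-"

    def test_unannotated_has_no_hit_id(self, toy_index):
        index, _, _ = toy_index
        rec = classify_tag(UniqueTag("U" * 22, 1), index)
        assert rec.category == "unannotated" and rec.hit_id is None

    def test_partition_property(self, study_annotation, study_tags_stats):
        tags, _ = study_tags_stats
        assert len(study_annotation) == len(tags)
        assert all(r.category for r in study_annotation)

    def test_matches_naive_scan_oracle(self, small_lib):
        """classify_tag must agree with a per-query scan of every reference."""
        from smallrna_forge.preprocess import run_cascade

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
        index = build_index(refsets)
        kind_cat = {
            "rRNA": "rRNA", "tRNA": "tRNA", "snRNA": "snRNA", "snoRNA": "snoRNA",
            "repeat": "repeat", "known_miRNA_mature": "known_miRNA",
        }
        for tag in tags[:300]:
            expected = "unannotated"
            for ref in refsets:  # refsets are in precedence order
                found = None
                for rec in ref.records:
                    if tag.seq in rec.seq:
                        found = "+"
                        break
                    if revcomp(tag.seq) in rec.seq:
                        found = "-"
                        break
                if found:
                    if ref.kind == "exon":
                        expected = "exon_sense" if found == "+" else "exon_antisense"
                    else:
                        expected = kind_cat[ref.kind]
                    break
            assert classify_tag(tag, index).category == expected

    def test_precedence_monotonicity(self, toy_index):
        """Moving a category earlier in precedence never decreases its count."""
        index, rrna, _ = toy_index
        tag = UniqueTag(rrna.seq[9:31], 5)
        late = tuple(c for c in DEFAULT_PRECEDENCE if c != "known_miRNA") + ("known_miRNA",)
        early = ("known_miRNA",) + tuple(c for c in DEFAULT_PRECEDENCE if c != "known_miRNA")
        assert classify_tag(tag, index, late).category == "rRNA"
        assert classify_tag(tag, index, early).category == "known_miRNA"


class TestSummary:
    def test_published_redundant_percentages(self):
        s = summary_from_counts(TABLE3_UNIQUE, TABLE3_REDUNDANT, TOTAL_UNIQUE, TOTAL_CLEAN)
        assert s.table.loc["rRNA", "redundant_pct"] == 22.11
        assert s.table.loc["tRNA", "redundant_pct"] == 12.17
        assert s.table.loc["unannotated", "unique_pct"] == 94.91

    def test_single_category_is_hundred_percent(self):
        recs = classify_all(
            [UniqueTag("A" * 9 + "C" * 9, 4)],
            build_index([ReferenceSet("rRNA", [SeqRecord("r", "A" * 9 + "C" * 9)], "rRNA")]),
        )
        s = summarize(recs, 4)
        assert s.table.loc["rRNA", "unique_pct"] == 100.0
        assert s.table.loc["rRNA", "redundant_pct"] == 100.0

    def test_subtraction_reproduces_published_total(self):
        s = summary_from_counts(TABLE3_UNIQUE, TABLE3_REDUNDANT, TOTAL_UNIQUE, TOTAL_CLEAN)
        assert subtract_classes(s, ["rRNA", "tRNA", "snRNA", "snoRNA"]) == 8697221

    def test_subtract_nothing_is_total_clean(self):
        s = summary_from_counts(TABLE3_UNIQUE, TABLE3_REDUNDANT, TOTAL_UNIQUE, TOTAL_CLEAN)
        assert subtract_classes(s, []) == TOTAL_CLEAN

    def test_subtract_unknown_class_errors(self):
        s = summary_from_counts(TABLE3_UNIQUE, TABLE3_REDUNDANT, TOTAL_UNIQUE, TOTAL_CLEAN)
        with pytest.raises(KeyError):
            subtract_classes(s, ["lncRNA"])

    def test_subtract_all_categories(self):
        s = summary_from_counts(TABLE3_UNIQUE, TABLE3_REDUNDANT, TOTAL_UNIQUE, TOTAL_CLEAN)
        left = subtract_classes(s, list(TABLE3_UNIQUE))
        assert left == TOTAL_CLEAN - sum(TABLE3_REDUNDANT.values())


class TestLengthProfile:
    def test_hand_countable(self):
        tags = [
            UniqueTag("A" * 21, 1), UniqueTag("C" * 21, 1), UniqueTag("G" * 21, 8),
            UniqueTag("U" * 24, 1),
        ]
        df = length_profile(tags)
        assert tuple(df.loc[21]) == (3, 10, 0.3)
        assert tuple(df.loc[24]) == (1, 1, 1.0)

    def test_empty(self):
        assert length_profile([]).empty

    def test_bimodal_lengths_dominate(self, study_tags_stats):
        tags, _ = study_tags_stats
        df = length_profile(tags)
        top2 = set(df["unique"].nlargest(2).index)
        assert top2 == {21, 24}
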