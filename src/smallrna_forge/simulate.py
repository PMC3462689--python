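"""Synthetic small-RNA study generator with a ground-truth manifest.

Everything the pipeline consumes can be generated here: an adapter-ligated
read population with a bimodal 21/24-nt insert length distribution and a
high singleton fraction, ncRNA/repeat reference sets, a transcriptome with
embedded foldable hairpin precursors and complementary target sites, known
mature miRNAs spiked at skewed abundances, RACE clone tables, and qPCR Ct
tables.  The manifest records every read's terminal fate and every planted
feature, so every expected pipeline output is determined by construction.

Reference sequences are random with planted shared substrings - they stand
in for real rRNA/tRNA/repeat collections and are labelled synthetic
throughout.  Determinism: a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import revcomp, to_dna, to_rna
from .io_formats import SeqRecord, UniqueTag, write_fasta, write_fastq
from .preprocess import (
    ADAPTER_NULL,
    INSERT_NULL,
    PreprocessParams,
    find_and_trim_adapter3,
    is_adapter5_contaminant,
    is_polyA,
)
from .targets import ScoringScheme, score_site

_DEFAULT_LENGTH_MIX = {
    18: 0.04, 19: 0.05, 20: 0.08, 21: 0.18, 22: 0.10, 23: 0.11,
    24: 0.22, 25: 0.08, 26: 0.06, 27: 0.04, 28: 0.02, 29: 0.01, 30: 0.01,
}

_DEFAULT_CLASS_MIX = {
    "rRNA": 0.05, "tRNA": 0.03, "snRNA": 0.005, "snoRNA": 0.005,
    "repeat": 0.05, "mRNA": 0.08, "random": 0.78,
}

_DEFAULT_CONTAMINATION = {
    "low_quality": 0.02,
    "adaptor3_null": 0.01,
    "insert_null": 0.005,
    "adaptor5_contaminant": 0.008,
    "polyA": 0.003,
    "small_insert": 0.05,
}

#: miRBase-style sources the spiked miRNAs are named after
_FAMILY_POOL = [156, 157, 159, 160, 162, 164, 165, 166, 167, 168,
                169, 171, 172, 319, 390, 394, 396, 398, 408, 858]
_SPECIES = ["ath", "ptc", "osa", "pta"]


@dataclass
class SimConfig:
    seed: int = 1
    n_reads: int = 10_000
    read_length: int = 50
    adapter3: str = "UCGUAUGCCGUCUUCUGCUUG"
    adapter5: str = "GUUCAGAGUUCUACAGUCCGACGAUC"
    length_mix: Dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_LENGTH_MIX))
    class_mix: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    contamination: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CONTAMINATION))
    singleton_fraction: float = 0.74
    n_known_mirnas: int = 30
    n_spiked_mirnas: int = 12
    spike_count_range: Tuple[int, int] = (30, 1000)
    n_novel_hairpins: int = 3
    novel_count: int = 17
    n_transcripts: int = 60
    transcript_len: int = 500
    target_site_scores: Tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.0, 2.5, 3.0, 3.0, 3.5, 4.0, 4.5
    )
    race_sites: int = 5
    race_clones_per_site: int = 10
    race_noise: float = 0.2

    def __post_init__(self) -> None:
        for name, mix in (("length_mix", self.length_mix), ("class_mix", self.class_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if not (0 < self.singleton_fraction < 1):
            raise ValueError("singleton_fraction must be in (0, 1)")
        if self.n_spiked_mirnas > self.n_known_mirnas:
            raise ValueError("cannot spike more miRNAs than the database holds")


@dataclass
class Manifest:
    """Ground truth for one generated library."""

    read_fates: Dict[str, int]
    total_clean: int
    n_unique: int
    n_singletons: int
    tag_classes: Dict[str, str]          # tag seq -> class label
    tag_counts: Dict[str, int]
    spiked: List[dict]                   # name, seq, count
    novel: List[dict]                    # mature, transcript_id, precursor/mature/star spans
    target_sites: List[dict]             # mirna_id, family, transcript_id, span, score
    race_clones: List[dict]              # clone_id, transcript_id, five_prime_pos, site info

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticLibrary:
    reads: List[SeqRecord]
    refs: Dict[str, List[SeqRecord]]     # rRNA/tRNA/snRNA/snoRNA/repeat/mature_mirna/precursor_mirna/transcripts
    manifest: Manifest
    config: SimConfig

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        paths["reads"] = outdir / "reads.fastq"
        write_fastq(self.reads, paths["reads"])
        for name, records in self.refs.items():
            p = outdir / f"{name}.fa"
            write_fasta(records, p)
            paths[name] = p
        paths["manifest"] = outdir / "manifest.json"
        self.manifest.to_json(paths["manifest"])
        return paths


# ---------------------------------------------------------------------------
# sequence sampling helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGU") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _rand_mirna(rng: np.random.Generator, n: int = 21, u5_bias: float = 0.79) -> str:
    """Random mature with moderate GC (0.38-0.70) and the 5'-terminal-U bias
    of AGO1-loaded plant miRNAs (~79% of conserved miRNAs start with U)."""
    while True:
        s = _rand_seq(rng, n)
        if rng.random() < u5_bias:
            s = "U" + s[1:]
        gc = (s.count("G") + s.count("C")) / n
        if 0.38 <= gc <= 0.70:
            return s


def _sample_length(rng: np.random.Generator, mix: Dict[int, float]) -> int:
    lengths = sorted(mix)
    probs = np.array([mix[k] for k in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------

def generate_hairpin(
    mature: str,
    stem_mismatches: int = 0,
    loop_len: int = 8,
    flank: int = 15,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    """Build a precursor around a mature; returns (seq, mature_span, star_span).

    Construction: 5' flank + e2 + mature + loop + revcomp(e2 + mature) + 3'
    flank, where e2 is 2 extra bases whose pairing encodes the 2-nt 3'
    overhangs of the excised duplex.  Flanks and loop are drawn from {A, C}
    so they cannot pair with each other, keeping the planted stem dominant.
    Spans are 1-based closed on the returned sequence; the star span is
    where duplex discovery should place the miRNA*.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if not (18 <= len(mature) <= 24):
        raise ValueError("mature length must be 18-24 nt")
    if loop_len < 3:
        raise ValueError("loop must be at least 3 nt")
    mature = to_rna(mature)
    e2 = _rand_seq(rng, 2)
    arm = e2 + mature
    star = list(revcomp(arm))
    if stem_mismatches:
        # avoid the 4 edge bases so the duplex ends stay anchored
        positions = rng.choice(
            np.arange(2, len(star) - 2), size=stem_mismatches, replace=False
        )
        for p in positions:
            current = star[p]
            star[p] = {"A": "C", "C": "A", "G": "A", "U": "C"}[current]
    star_seq = "".join(star)
    f5 = _rand_seq(rng, flank, "AC")
    f3 = _rand_seq(rng, flank, "AC")
    loop = _rand_seq(rng, loop_len, "AC")
    pre = f5 + arm + loop + star_seq + f3
    m5 = flank + 2 + 1
    mature_span = (m5, m5 + len(mature) - 1)
    star_start = flank + len(arm) + loop_len + 1
    # the called star: planted star minus the 2 bases pairing e2, plus the
    # 2-nt 3' overhang - net span [star_start + 2, star_end]
    star_span = (star_start + 2, star_start + len(arm) - 1)
    return pre, mature_span, star_span


# ---------------------------------------------------------------------------
# target site construction
# ---------------------------------------------------------------------------

def make_target_site(
    mirna: str,
    requested_score: float,
    rng: np.random.Generator,
    scheme: Optional[ScoringScheme] = None,
) -> str:
    """Mutate a perfect complementary site until it scores ``requested_score``.

    Mutations are placed outside the seed at non-adjacent positions:
    full-point steps as mismatches, a half-point step as one G:U wobble.
    The oracle scorer confirms the final penalty; an unreachable request
    raises.
    """
    scheme = scheme or ScoringScheme()
    m = to_rna(mirna)
    n = len(m)
    if requested_score * 2 != int(requested_score * 2) or requested_score < 0:
        raise ValueError("requested score must sit on the 0.5 lattice")
    n_mm = int(requested_score)
    n_gu = int(round((requested_score - n_mm) * 2))  # 0 or 1
    # candidate miRNA positions outside the seed, spaced >= 2 apart
    pool = [p for p in range(scheme.seed_end + 1, n + 1)]
    for _ in range(200):
        rng.shuffle(pool)
        chosen: List[int] = []
        for p in pool:
            if len(chosen) == n_mm + n_gu:
                break
            if all(abs(p - q) >= 2 for q in chosen):
                chosen.append(p)
        if len(chosen) < n_mm + n_gu:
            continue
        site = list(revcomp(m))  # site 5'->3'; miRNA pos p faces site[n-p]
        ok = True
        for idx, p in enumerate(chosen):
            si = n - p
            m_base = m[p - 1]
            if idx < n_gu:
                if m_base == "G":
                    site[si] = "U"
                elif m_base == "U":
                    site[si] = "G"
                else:
                    ok = False
                    break
            else:
                # mismatch: any base that neither WC- nor GU-pairs the miRNA base
                options = {
                    "A": "AGC", "C": "AC", "G": "GA", "U": "UC",
                }[m_base]
                site[si] = options[int(rng.integers(0, len(options)))]
        if not ok:
            continue
        site_seq = "".join(site)
        got, _ = score_site(m, site_seq, scheme)
        if got == requested_score:
            return site_seq
    raise ValueError(
        f"score {requested_score} unreachable for miRNA {mirna} under this scheme"
    )


# ---------------------------------------------------------------------------
# the library generator
# ---------------------------------------------------------------------------

def _substring_of(seq: str, groups: Sequence[List[SeqRecord]]) -> bool:
    rc = revcomp(seq)
    for group in groups:
        for rec in group:
            r = to_rna(rec.seq)
            if seq in r or rc in r:
                return True
    return False


def generate_library(config: Optional[SimConfig] = None) -> SyntheticLibrary:
    """Generate reads, references and the ground-truth manifest."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    pp = PreprocessParams(adapter3=config.adapter3, adapter5=config.adapter5)
    _pad = "ACACACACACACACACACACACACACACAC"

    def _clean_insert(seq: str) -> bool:
        """Would this insert deterministically reach the clean fate?"""
        if "N" in seq:
            return False
        rec = SeqRecord("probe", seq)
        if is_polyA(rec, pp) or is_adapter5_contaminant(rec, pp):
            return False
        read = SeqRecord("probe", (seq + pp.adapter3 + _pad)[: config.read_length])
        ins = find_and_trim_adapter3(read, pp)
        return ins not in (ADAPTER_NULL, INSERT_NULL) and to_rna(ins.seq) == seq

    def _clean_mirna(n: int = 21) -> str:
        while True:
            s = _rand_mirna(rng, n)
            if _clean_insert(s):
                return s

    # --- reference sets (synthetic stand-ins, random content) ---------------
    refs: Dict[str, List[SeqRecord]] = {
        "rRNA": [SeqRecord(f"rRNA_{i+1}", _rand_seq(rng, 1000)) for i in range(3)],
        "tRNA": [SeqRecord(f"tRNA_{i+1}", _rand_seq(rng, 75)) for i in range(10)],
        "snRNA": [SeqRecord(f"snRNA_{i+1}", _rand_seq(rng, 150)) for i in range(4)],
        "snoRNA": [SeqRecord(f"snoRNA_{i+1}", _rand_seq(rng, 120)) for i in range(4)],
        "repeat": [SeqRecord(f"repeat_{i+1}", _rand_seq(rng, 400)) for i in range(5)],
    }

    # --- known mature miRNA database ----------------------------------------
    matures: List[SeqRecord] = []
    for i in range(config.n_known_mirnas):
        fam = _FAMILY_POOL[i % len(_FAMILY_POOL)]
        sp = _SPECIES[i % len(_SPECIES)]
        letter = chr(ord("a") + i // len(_FAMILY_POOL))
        matures.append(SeqRecord(f"{sp}-miR{fam}{letter}", _clean_mirna()))
    refs["mature_mirna"] = matures

    # known precursors for a few database entries (hairpins around matures)
    precursors: List[SeqRecord] = []
    for rec in matures[: 4]:
        pre, _, _ = generate_hairpin(rec.seq, rng=rng)
        precursors.append(SeqRecord(f"{rec.id}_pre", pre))
    refs["precursor_mirna"] = precursors

    # --- transcriptome with planted features --------------------------------
    transcripts: List[SeqRecord] = []
    novel_manifest: List[dict] = []
    hairpin_transcript_ids = set()
    novel_matures: List[str] = []
    for i in range(config.n_novel_hairpins):
        mature = _clean_mirna()
        pre, m_span, s_span = generate_hairpin(mature, rng=rng)
        insert_at = int(rng.integers(80, 150))
        body = _rand_seq(rng, config.transcript_len - len(pre))
        seq = body[:insert_at] + pre + body[insert_at:]
        tid = f"unigene{i+1:04d}"
        transcripts.append(SeqRecord(tid, seq))
        hairpin_transcript_ids.add(tid)
        novel_matures.append(mature)
        novel_manifest.append(
            {
                "mature": mature,
                "transcript_id": tid,
                "precursor_span": [insert_at + 1, insert_at + len(pre)],
                "mature_span": [insert_at + m_span[0], insert_at + m_span[1]],
                "star_span": [insert_at + s_span[0], insert_at + s_span[1]],
            }
        )

    # spiked miRNA selection (targets are planted for these)
    spike_records = matures[: config.n_spiked_mirnas]
    scheme = ScoringScheme()
    target_manifest: List[dict] = []
    t_index = config.n_novel_hairpins
    for j, score in enumerate(config.target_site_scores):
        src = spike_records[j % len(spike_records)]
        site = make_target_site(src.seq, score, rng, scheme)
        insert_at = int(rng.integers(150, 300))
        body = _rand_seq(rng, config.transcript_len - len(site))
        seq = body[:insert_at] + site + body[insert_at:]
        tid = f"unigene{t_index + j + 1:04d}"
        transcripts.append(SeqRecord(tid, seq))
        target_manifest.append(
            {
                "mirna_id": src.id,
                "family": f"MIR{''.join(c for c in src.id.split('miR')[1] if c.isdigit())}",
                "transcript_id": tid,
                "span": [insert_at + 1, insert_at + len(site)],
                "score": score,
            }
        )
    n_plain = config.n_transcripts - len(transcripts)
    for k in range(max(0, n_plain)):
        transcripts.append(
            SeqRecord(
                f"unigene{len(transcripts) + 1:04d}",
                _rand_seq(rng, config.transcript_len),
            )
        )
    refs["transcripts"] = transcripts
    plain_transcripts = [
        t for t in transcripts if t.id not in hairpin_transcript_ids
    ]

    # --- RACE clones over the first few planted sites -----------------------
    race_manifest: List[dict] = []
    cid = 0
    for entry in target_manifest[: config.race_sites]:
        s, e = entry["span"]
        canon = e - 10 + 1
        for _ in range(config.race_clones_per_site):
            cid += 1
            if rng.random() < config.race_noise:
                delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                pos = canon + delta
            else:
                pos = canon
            race_manifest.append(
                {
                    "clone_id": f"clone{cid:03d}",
                    "transcript_id": entry["transcript_id"],
                    "five_prime_pos": pos,
                    "mirna_id": entry["mirna_id"],
                    "site_span": entry["span"],
                }
            )

    # --- tag pool ------------------------------------------------------------
    contam_counts = {
        k: int(round(v * config.n_reads)) for k, v in config.contamination.items()
    }
    n_clean = config.n_reads - sum(contam_counts.values())

    lo, hi = config.spike_count_range
    spike_counts = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=len(spike_records))
    ).astype(int)
    spike_counts = np.maximum(spike_counts, 2)
    spiked_manifest = [
        {"name": rec.id, "seq": to_rna(rec.seq), "count": int(c)}
        for rec, c in zip(spike_records, spike_counts)
    ]
    planted_multi = [(to_rna(r.seq), int(c)) for r, c in zip(spike_records, spike_counts)]
    planted_multi += [(m, config.novel_count) for m in novel_matures]

    R = n_clean - sum(c for _, c in planted_multi)
    if R <= 0:
        raise ValueError("library too small for the requested spike-in mass")
    f = config.singleton_fraction
    mu_est = 2.0 + float(np.exp(0.5 + 0.8 ** 2 / 2))
    U_tot = int(R / (f + (1 - f) * mu_est)) + len(planted_multi)
    n_single = int(round(f * U_tot))
    n_multi_rest = U_tot - n_single - len(planted_multi)
    if n_multi_rest < 0:
        raise ValueError("infeasible singleton fraction for this spike-in mass")
    multi_counts = (2 + np.floor(rng.lognormal(0.5, 0.8, n_multi_rest))).astype(int)
    resid = R - n_single - int(multi_counts.sum())
    # absorb the residual while keeping every multi count >= 2
    while resid != 0 and len(multi_counts):
        if resid > 0:
            multi_counts[int(np.argmax(multi_counts))] += resid
            resid = 0
        else:
            k = int(np.argmax(multi_counts))
            take = min(multi_counts[k] - 2, -resid)
            multi_counts[k] -= take
            resid += take
            if take == 0:
                break
    if resid != 0:
        raise ValueError("could not balance read counts; adjust configuration")

    # sample tag sequences per class, with cross-fate guards
    class_names = list(config.class_mix)
    class_probs = np.array([config.class_mix[c] for c in class_names])
    class_probs = class_probs / class_probs.sum()

    taken = {to_rna(r.seq) for r in matures} | set(novel_matures)
    tag_classes: Dict[str, str] = {}
    tag_counts: Dict[str, int] = {}
    for rec, c in zip(spike_records, spike_counts):
        tag_classes[to_rna(rec.seq)] = "known_miRNA"
        tag_counts[to_rna(rec.seq)] = int(c)
    for m in novel_matures:
        tag_classes[m] = "novel_miRNA"
        tag_counts[m] = config.novel_count

    higher_than = {
        "rRNA": [],
        "tRNA": [refs["rRNA"]],
        "snRNA": [refs["rRNA"], refs["tRNA"]],
        "snoRNA": [refs["rRNA"], refs["tRNA"], refs["snRNA"]],
        "repeat": [refs["rRNA"], refs["tRNA"], refs["snRNA"], refs["snoRNA"]],
        "mRNA": [refs["rRNA"], refs["tRNA"], refs["snRNA"], refs["snoRNA"],
                 refs["repeat"], refs["mature_mirna"]],
        "random": [refs["rRNA"], refs["tRNA"], refs["snRNA"], refs["snoRNA"],
                   refs["repeat"], refs["mature_mirna"], refs["transcripts"],
                   refs["precursor_mirna"]],
    }

    def _sample_tag(cls: str) -> str:
        for _ in range(500):
            length = _sample_length(rng, config.length_mix)
            if cls == "random":
                seq = _rand_seq(rng, length)
            elif cls == "mRNA":
                rec = plain_transcripts[int(rng.integers(0, len(plain_transcripts)))]
                start = int(rng.integers(0, len(rec.seq) - length + 1))
                seq = to_rna(rec.seq[start : start + length])
            else:
                group = refs[cls]
                rec = group[int(rng.integers(0, len(group)))]
                if len(rec.seq) < length:
                    continue
                start = int(rng.integers(0, len(rec.seq) - length + 1))
                seq = to_rna(rec.seq[start : start + length])
            if seq in taken or not _clean_insert(seq):
                continue
            if _substring_of(seq, higher_than[cls]):
                continue
            return seq
        raise RuntimeError(f"failed to sample a {cls} tag")

    all_counts = [c for _, c in planted_multi] + list(multi_counts) + [1] * n_single
    n_rest = n_multi_rest + n_single
    rest_classes = [
        class_names[i] for i in rng.choice(len(class_names), size=n_rest, p=class_probs)
    ]
    for cls, count in zip(rest_classes, all_counts[len(planted_multi):]):
        seq = _sample_tag(cls)
        taken.add(seq)
        tag_classes[seq] = cls
        tag_counts[seq] = int(count)

    # --- emit reads -----------------------------------------------------------
    reads: List[SeqRecord] = []

    def _qual(n: int, low: bool = False) -> List[int]:
        if low:
            return [int(q) for q in rng.integers(8, 18, n)]
        return [int(q) for q in rng.integers(30, 41, n)]

    def _read_from_insert(seq: str) -> str:
        return to_dna((seq + pp.adapter3 + _pad))[: config.read_length]

    for seq, count in tag_counts.items():
        for _ in range(count):
            reads.append(SeqRecord("x", _read_from_insert(seq), _qual(config.read_length)))

    # contaminated populations
    for _ in range(contam_counts["low_quality"]):
        seq = _read_from_insert(_rand_seq(rng, 22))
        if rng.random() < 0.5:
            reads.append(SeqRecord("x", seq, _qual(config.read_length, low=True)))
        else:
            k = int(rng.integers(0, len(seq)))
            reads.append(
                SeqRecord("x", seq[:k] + "N" + seq[k + 1 :], _qual(config.read_length))
            )
    for _ in range(contam_counts["adaptor3_null"]):
        while True:
            seq = _rand_seq(rng, config.read_length)
            probe = SeqRecord("x", seq, None)
            if find_and_trim_adapter3(probe, pp) is ADAPTER_NULL:
                break
        reads.append(SeqRecord("x", to_dna(seq), _qual(config.read_length)))
    for _ in range(contam_counts["insert_null"]):
        seq = to_dna(pp.adapter3 + _rand_seq(rng, config.read_length))[: config.read_length]
        reads.append(SeqRecord("x", seq, _qual(config.read_length)))
    for _ in range(contam_counts["adaptor5_contaminant"]):
        while True:
            tail = _rand_seq(rng, 10)
            ins = pp.adapter5[-12:] + tail
            rec = SeqRecord("x", ins)
            read = SeqRecord("x", (ins + pp.adapter3 + _pad)[: config.read_length])
            got = find_and_trim_adapter3(read, pp)
            if (
                got not in (ADAPTER_NULL, INSERT_NULL)
                and to_rna(got.seq) == ins
                and is_adapter5_contaminant(rec, pp)
            ):
                break
        reads.append(SeqRecord("x", to_dna(read.seq), _qual(config.read_length)))
    for _ in range(contam_counts["polyA"]):
        while True:
            n_a = int(rng.integers(18, 25))
            ins = list("A" * n_a)
            for p in rng.choice(n_a, size=2, replace=False):
                ins[int(p)] = "C"
            ins = "".join(ins)
            rec = SeqRecord("x", ins)
            read = SeqRecord("x", (ins + pp.adapter3 + _pad)[: config.read_length])
            got = find_and_trim_adapter3(read, pp)
            if (
                got not in (ADAPTER_NULL, INSERT_NULL)
                and to_rna(got.seq) == ins
                and is_polyA(rec, pp)
                and not is_adapter5_contaminant(rec, pp)
            ):
                break
        reads.append(SeqRecord("x", to_dna(read.seq), _qual(config.read_length)))
    for _ in range(contam_counts["small_insert"]):
        while True:
            ins = _rand_seq(rng, int(rng.integers(10, 18)))
            rec = SeqRecord("x", ins)
            read = SeqRecord("x", (ins + pp.adapter3 + _pad)[: config.read_length])
            got = find_and_trim_adapter3(read, pp)
            if (
                got not in (ADAPTER_NULL, INSERT_NULL)
                and to_rna(got.seq) == ins
                and not is_polyA(rec, pp)
                and not is_adapter5_contaminant(rec, pp)
            ):
                break
        reads.append(SeqRecord("x", to_dna(read.seq), _qual(config.read_length)))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    for i, r in enumerate(reads):
        r.id = f"read{i+1:06d}"

    n_singletons = sum(1 for c in tag_counts.values() if c == 1)
    fates = dict(contam_counts)
    fates["total_raw"] = len(reads)
    fates["high_quality"] = len(reads) - contam_counts["low_quality"]
    manifest = Manifest(
        read_fates=fates,
        total_clean=n_clean,
        n_unique=len(tag_counts),
        n_singletons=n_singletons,
        tag_classes=tag_classes,
        tag_counts=tag_counts,
        spiked=spiked_manifest,
        novel=novel_manifest,
        target_sites=target_manifest,
        race_clones=race_manifest,
    )
    return SyntheticLibrary(reads=reads, refs=refs, manifest=manifest, config=config)


# ---------------------------------------------------------------------------
# qPCR table generator
# ---------------------------------------------------------------------------

def generate_ct_table(
    seed: int = 1,
    contrast_log2: float = 8.2,
    noise_sd: float = 0.05,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Triplicate Ct table encoding a strong seed/leaf expression contrast.

    The focal miRNA's dCt is ``contrast_log2`` cycles lower in seeds than
    in leaves (2^8.2 ~ 294-fold), with small replicate noise on every
    measurement; a second miRNA shows the opposite, milder pattern.
    """
    rng = np.random.default_rng(seed)
    samples = {"seeds": 0.0, "seedlings": 4.0, "leaves": contrast_log2, "stems": 7.5}
    rows = []
    for sample, shift in samples.items():
        for rep in range(1, n_reps + 1):
            rows.append(("ref_5.8S", sample, rep, 18.0 + rng.normal(0, noise_sd)))
            rows.append(("cln-miR157a", sample, rep, 20.0 + shift + rng.normal(0, noise_sd)))
            rows.append(
                ("cln-miR164a", sample, rep,
                 24.0 - shift / 3.0 + rng.normal(0, noise_sd))
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate", "ct"])
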