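"""End-to-end orchestration: reads -> tags -> annotation -> miRNA calls -> targets.

The pipeline is a pure function of (inputs, configuration, seed): re-running
with an identical configuration produces identical outputs.  Stage order
follows the discovery narrative - cleanup, hierarchical annotation,
conserved calling against the known-miRNA database, novel calling on the
remaining transcript-mapped tags, then target prediction for everything
called.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    DEFAULT_PRECEDENCE,
    ReferenceSet,
    build_index,
    classify_all,
    length_profile,
    summarize,
)
from .conserved import HomologyParams, MatureDb, identify_conserved
from .hairpin import HairpinParams, detect_novel
from .io_formats import Gff3Feature, read_fasta, read_fastq, write_gff3, write_tags
from .preprocess import PreprocessParams, run_cascade
from .targets import ScoringScheme, predict_targets

#: reference categories accepted in PipelineConfig.references, in precedence order
_REF_KINDS = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat": "repeat",
}


@dataclass
class PipelineConfig:
    reads_fastq: str
    references: Dict[str, str]           # category -> FASTA (rRNA/tRNA/snRNA/snoRNA/repeat)
    mature_mirna_fasta: str
    transcriptome_fasta: str
    precursor_mirna_fasta: Optional[str] = None
    output_dir: str = "smallrna_out"
    seed: int = 0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    homology: HomologyParams = field(default_factory=HomologyParams)
    hairpin: HairpinParams = field(default_factory=HairpinParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    precedence: tuple = DEFAULT_PRECEDENCE

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("preprocess", PreprocessParams),
            ("homology", HomologyParams),
            ("hairpin", HairpinParams),
            ("scoring", ScoringScheme),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.reads_fastq, self.mature_mirna_fasta, self.transcriptome_fasta]
        paths += list(self.references.values())
        if self.precursor_mirna_fasta:
            paths.append(self.precursor_mirna_fasta)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        unknown = set(self.references) - set(_REF_KINDS)
        if unknown:
            raise ValueError(f"unknown reference categories: {sorted(unknown)}")


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- preprocess ---------------------------------------------------------
    reads = read_fastq(config.reads_fastq)
    tags, stats = _stage("preprocess")(lambda: run_cascade(reads, config.preprocess))
    paths["tags"] = out / "tags.tsv"
    write_tags(tags, paths["tags"])
    paths["stats"] = out / "stats.json"
    with open(paths["stats"], "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1, sort_keys=True)

    # --- annotate -----------------------------------------------------------
    matures = list(read_fasta(config.mature_mirna_fasta))
    transcripts = list(read_fasta(config.transcriptome_fasta))
    refsets = [
        ReferenceSet(cat, list(read_fasta(p)), _REF_KINDS[cat])
        for cat, p in config.references.items()
    ]
    refsets.append(ReferenceSet("known_miRNA", matures, "known_miRNA_mature"))
    refsets.append(ReferenceSet("exon", transcripts, "exon"))
    index = _stage("annotate")(lambda: build_index(refsets))
    records = classify_all(tags, index, config.precedence)
    summary = summarize(records, stats.total_clean)
    paths["annotations"] = out / "annotations.tsv"
    pd.DataFrame(
        [
            {
                "seq": r.tag.seq,
                "count": r.tag.count,
                "category": r.category,
                "hit_id": r.hit_id or "",
                "strand": r.strand or "",
            }
            for r in records
        ]
    ).to_csv(paths["annotations"], sep="\t", index=False)
    paths["summary"] = out / "summary.tsv"
    summary.table.to_csv(paths["summary"], sep="\t")
    paths["length_profile"] = out / "length_profile.tsv"
    length_profile(tags).to_csv(paths["length_profile"], sep="\t")

    # --- conserved miRNAs ---------------------------------------------------
    db = MatureDb(matures)
    structural = {"rRNA", "tRNA", "snRNA", "snoRNA", "repeat"}
    kept = [r for r in records if r.category not in structural]
    conserved = _stage("conserved")(
        lambda: identify_conserved(
            [r.tag for r in kept],
            db,
            config.homology,
            transcripts=transcripts,
            hairpin_params=config.hairpin,
        )
    )
    paths["conserved"] = out / "conserved.tsv"
    pd.DataFrame(
        [
            {
                "name": c.name,
                "seq": c.mature.seq,
                "count": c.mature.count,
                "family": c.family,
                "source_hit": c.source_hit,
                "mismatches": c.mismatches,
                "five_prime_U": c.has_5prime_U,
                "precursor_id": c.precursor_id or "",
            }
            for c in conserved
        ]
    ).to_csv(paths["conserved"], sep="\t", index=False)

    # --- novel miRNAs -------------------------------------------------------
    known_pre = (
        list(read_fasta(config.precursor_mirna_fasta))
        if config.precursor_mirna_fasta
        else []
    )
    conserved_seqs = {c.mature.seq for c in conserved}
    novel_input = [
        r.tag
        for r in kept
        if r.category != "known_miRNA" and r.tag.seq not in conserved_seqs
    ]
    novel = _stage("novel")(
        lambda: detect_novel(novel_input, transcripts, known_pre, config.hairpin)
    )
    paths["novel"] = out / "novel.tsv"
    pd.DataFrame(
        [
            {
                "seq": n.mature.seq,
                "count": n.mature.count,
                "transcript_id": n.transcript_id,
                "strand": n.strand,
                "precursor_start": n.precursor_span[0],
                "precursor_end": n.precursor_span[1],
                "mfe": round(n.report.fold.mfe, 2),
                "amfe": round(n.report.amfe, 2),
                "mfei": round(n.report.mfei, 3),
                "gc_percent": round(n.report.gc_percent, 2),
            }
            for n in novel
        ]
    ).to_csv(paths["novel"], sep="\t", index=False)
    paths["novel_gff"] = out / "novel.gff3"
    write_gff3(
        [
            Gff3Feature(
                seqid=n.transcript_id,
                type="miRNA_primary_transcript",
                start=n.precursor_span[0],
                end=n.precursor_span[1],
                strand=n.strand,
                attributes={"ID": f"novel_{i+1}", "mature": n.mature.seq},
            )
            for i, n in enumerate(novel)
        ],
        paths["novel_gff"],
    )

    # --- target prediction --------------------------------------------------
    mirna_list = [(c.name, c.family, c.mature.seq) for c in conserved]
    mirna_list += [
        (f"novel_{i+1}", f"MIRn{i+1}", n.mature.seq) for i, n in enumerate(novel)
    ]
    target_df = _stage("targets")(
        lambda: predict_targets(mirna_list, transcripts, config.scoring)
    )
    paths["targets"] = out / "targets.tsv"
    target_df.to_csv(paths["targets"], sep="\t", index=False)
    paths["targets_gff"] = out / "target_sites.gff3"
    write_gff3(
        [
            Gff3Feature(
                seqid=row.transcript_id,
                type="target_site",
                start=int(row.start),
                end=int(row.end),
                score=float(row.score),
                attributes={"mirna": row.mirna_id, "family": row.family},
            )
            for row in target_df.itertuples()
        ],
        paths["targets_gff"],
    )

    # --- run log ------------------------------------------------------------
    paths["run_log"] = out / "run_log.yaml"
    log = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "preprocess": asdict(config.preprocess),
            "homology": asdict(config.homology),
            "hairpin": asdict(config.hairpin),
            "scoring": asdict(config.scoring),
            "precedence": list(config.precedence),
        },
        "inputs": {
            "reads": str(config.reads_fastq),
            "references": {k: str(v) for k, v in config.references.items()},
            "mature_mirna": str(config.mature_mirna_fasta),
            "transcriptome": str(config.transcriptome_fasta),
        },
        "counts": {
            "clean_tags": len(tags),
            "conserved": len(conserved),
            "novel": len(novel),
            "target_rows": int(len(target_df)),
        },
    }
    with open(paths["run_log"], "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return paths
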