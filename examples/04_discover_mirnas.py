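"""Identify conserved and novel miRNAs among clean tags.

Conserved: mismatch-bounded homology (<= 2 mismatches, small end shifts)
to known mature miRNAs; non-identical hits additionally need a
hairpin-passing precursor.  Novel: a transcript-mapped tag whose flanking
window folds into a single stem-loop with MFE <= -30 kcal/mol,
MFEI >= 0.60, and a miRNA/miRNA* duplex with 2-nt 3' overhangs.
"""

from smallrna_forge import (
    MatureDb, ReferenceSet, SimConfig, build_index, classify_all,
    detect_novel, family_census, five_prime_u_fraction, generate_library,
    identify_conserved, run_cascade,
)

lib = generate_library(SimConfig(seed=1, n_reads=5000, spike_count_range=(20, 400)))
tags, stats = run_cascade(lib.reads)

refsets = [
    ReferenceSet(k, lib.refs[k], k)
    for k in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")
]
refsets.append(ReferenceSet("known_miRNA", lib.refs["mature_mirna"], "known_miRNA_mature"))
refsets.append(ReferenceSet("exon", lib.refs["transcripts"], "exon"))
records = classify_all(tags, build_index(refsets))

db = MatureDb(lib.refs["mature_mirna"])
conserved = identify_conserved(tags, db, transcripts=lib.refs["transcripts"])
count_u, _, pct_u = five_prime_u_fraction(conserved)
print(f"conserved miRNAs: {len(conserved)}; {count_u} ({pct_u}%) start with 5' U "
      "(the AGO1-loading signature)")
print(family_census(conserved))

candidates = [r.tag for r in records
              if r.category in ("exon_sense", "exon_antisense", "unannotated")]
novel = detect_novel(candidates, lib.refs["transcripts"],
                     known_precursors=lib.refs["precursor_mirna"])
print(f"\nnovel miRNAs: {len(novel)}")
for n in novel:
    r = n.report
    print(f"  {n.mature.seq} on {n.transcript_id}: MFE {r.fold.mfe:.1f} kcal/mol, "
          f"MFEI {r.mfei:.2f}, duplex mismatches {r.duplex.n_mismatch_in_duplex}")
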