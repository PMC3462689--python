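# Methods

`smallrna_forge` re-implements, as a tested library, the analysis chain used
in deep-sequencing surveys of plant small RNAs — the kind of study that takes
a single adapter-ligated sRNA library from a non-model species (here modelled
on a conifer) through read cleanup, annotation, miRNA discovery, target
prediction and validation-oriented downstream statistics. This note records
the models, the parameters that matter, and the choices made where the
procedure was genuinely open.

## Read cleanup and accounting

Raw reads are assigned exactly one terminal fate, in a fixed cascade order:

1. **low quality** — mean Phred below `min_mean_qual` (default 20) or any N.
   "Low quality" is rarely defined precisely in study reports; this is the
   standard parameterised reading.
2. **3' adapter null** — no adapter match. Matching is seed-and-extend: a
   candidate is the full adapter internally or an adapter prefix reaching the
   read's 3' end, with overlap ≥ 6 nt and mismatch rate ≤ 0.1; the best match
   minimises mismatch rate, then maximises overlap, then is leftmost.
3. **insert null** — adapter at position 0.
4. **5' adapter contaminant** — the insert begins with a suffix of the 5'
   adapter (same overlap/mismatch rule).
5. **poly(A)** — A fraction ≥ 0.8.
6. **length** — inserts outside 18–30 nt.

Clean inserts collapse into unique tags with counts. Conservation laws
(`total_raw = Σ discards + total_clean`; `Σ tag counts = total_clean`) are
asserted as properties. Percentages are reported as a share of raw reads,
rounded half-up to two decimals — the printing convention of the library
statistics tables this accounting mirrors.

## Hierarchical annotation

Annotation is exact-match only: a tag is assigned the first category in a
configurable precedence order (default rRNA > tRNA > snRNA > snoRNA > repeat
> known miRNA > exon > intron, each checked on both strands) for which it is
a perfect full-length substring of a reference sequence. Whether historical
pipelines resolved multi-category hits by precedence or multi-counted them is
ambiguous; we enforce the partition property (every tag exactly one category)
and expose the order. Sense/antisense is decided by the matching strand for
exon/intron sets.

## Conserved miRNA identification

BLASTN with a small E-value threshold is unstable for 18–26 nt queries, so
homology is an exact mismatch-bounded search: over every database entry and
every end shift `s` (|s| ≤ 2), mismatches = Hamming distance on the overlap
plus unaligned query bases; the best hit minimises mismatches with ties going
to database order. "Fewer than 3 mismatches" is `max_mismatch = 2`. Identical
tags are accepted outright; homologous (non-identical) hits must have a
hairpin-passing precursor in the transcriptome (`require_precursor`,
default on). Families follow miRBase nomenclature — the numeric core of the
source name (miR156a → MIR156) — with an optional merge map for families some
studies count jointly (e.g. MIR156/157); the default keeps them distinct.

## The fold engine

The built-in engine is deliberately self-contained rather than a
thermodynamic partition-function folder:

- **Structure**: Nussinov-style dynamic programming over Watson-Crick and G:U
  pairs with a minimum hairpin loop of 3. Two matrices are filled (free, and
  outer-pair-forced) and each pair scores 1 plus an epsilon bonus (ε = 1/4n)
  per stacked continuation. Since the total bonus is below 1, any optimal
  structure carries the exact Nussinov-maximal pair count — the property the
  test suite checks against an independent textbook recursion — while the
  traceback prefers long contiguous helices, which is what makes embedded
  stems recoverable.
- **Energy**: the traced structure is scored with an approximate
  nearest-neighbour stacking table (kcal/mol); only stacked pairs contribute,
  so MFE ≤ 0 always. These energies are engine-relative: they track the
  familiar ordering (GC-rich stacks strongest) but are not Turner-accurate,
  which is why every MFE threshold is a named, configurable parameter rather
  than a constant.
- An adapter around the `RNAfold` executable satisfies the same interface
  when that binary is available; nothing in the package or its tests requires
  it.

## Hairpin criteria and novel miRNA calling

A candidate precursor passes when all hold:

- MFE ≤ −30 kcal/mol (`mfe_max`; engine-relative, see above);
- MFEI ≥ 0.60, with MFEI = AMFE / GC% and AMFE = |MFE|/length × 100, GC% on
  the 0–100 scale — the standard index separating plant pre-miRNAs (≈0.6–1.2)
  from mRNA fragments and other RNAs;
- a single terminal loop within the duplex-enclosed region
  (`require_single_stem`);
- with a mature supplied: the mature must not fold back on itself (terminal
  loop overlap), and a miRNA/miRNA* duplex must exist.

**Duplex model.** The star is read off the pairing table with the 2-nt 3'
offset on both strands (the Dicer signature): for mature `[m5, m3]` on
pairing diagonal `D` (`pos + partner = D`), the star is
`[D−(m3−2), D−m5+2]`. Three quality requirements apply: at most
`max_duplex_mismatch` (default 4) mature bases off the duplex; all pairs on a
single diagonal (substitution mismatches only — asymmetric bulges are
rejected); and a contiguous helix of ≥ `min_duplex_run` (default 8) bp.
The last two are this package's additions: a maximum-pairing fold has no loop
penalties, so without them chance fragmented complementarity in transcript
windows passes at a rate of roughly one per few hundred mapped tags.
Real Dicer substrates satisfy both easily; heavily bulged duplexes are the
one biological corner this model deliberately excludes.

**Novel calling.** Each transcript-mapped tag (18–25 nt, ncRNA/repeat classes
removed upstream, known-precursor matches excluded as conserved) is evaluated
in four excision windows around its hit — (20 up, 160 down), (160, 20),
(30, 80), (80, 30), capped at 300 nt. The wide windows follow the common
two-arrangement excision convention; the narrow pair exists because a
maximum-pairing fold of a long window can trade an embedded stem against
long-range context pairs. A tag is called novel if any window passes.

## Target prediction

miRU/psRNATarget-style penalty scoring: the miRNA is aligned antiparallel to
a transcript window; each duplex column costs 0 (Watson-Crick), 0.5 (G:U), 1
(mismatch) or 2 (gap), doubled at miRNA positions 2–7 (the seed); at most one
gap, by default not opposite positions 10–11 and with ≤ 2 consecutive
mismatches (both sub-rules configurable, and disabled in oracle comparisons);
sites with penalty ≤ 4.0 are putative targets. All penalties live on a 0.5
lattice, matching the half-point scores such tables print. The transcript
scan is vectorised per gap pattern and confirmed by the exact scorer;
overlapping hits reduce to local score minima ≥ 5 nt apart. Family tables
deduplicate per (family, transcript), keeping the best score. Which exact
server variant produced any particular published table cannot be pinned down;
this scheme reproduces the value lattice, not a specific server.

## RACE cleavage mapping

Slicer cleavage leaves the 5' end of the 3' fragment opposite the boundary
between miRNA positions 10 and 11; both "position 10" and "position 11"
phrasings appear in the literature, so the boundary is standardised as offset
10. In-site clone ends are expressed in miRNA coordinates (a bijection with
transcript coordinates over the site span); outside ends are reported as nt
upstream/downstream of the canonical position. A site is *canonical* if
offset 10 holds a strict plurality of clones, *shifted(k)* for another strict
modal offset, *dispersed* on ties — thresholds documented here, not inherited
from any publication's qualitative figures.

## Expression quantification

Pure comparative-Ct: replicates averaged on the Ct scale, ΔCt against the
reference gene per sample, ΔΔCt against the calibrator sample, fold = 2^−ΔΔCt
(no efficiency correction). The calibrator's fold change is exactly 1 and all
folds are invariant to adding a constant to every Ct — both asserted as
properties. SEM bars propagate each target replicate through the ΔΔCt chain
against mean reference values.

## The synthetic-data generator

The generator emulates the statistical structure of a deeply sequenced plant
sRNA library, with every choice fixed once:

- 10,000 reads of 50 nt by default (the analysis scale for tests and the
  acceptance run; the real library's ~15.7M reads only change runtimes, not
  logic);
- insert lengths bimodal at 24 nt (22% of unique mass) and 21 nt (18%);
- singleton fraction targeted at 0.74 of unique tags; remaining multi-copy
  counts from a discretised log-normal (≥ 2), residual mass absorbed by the
  largest tag;
- 12 spiked known miRNAs at log-uniform counts 30–1000 — the published
  extremes (10^4–10^5 copies) scaled to library size with the skew preserved;
  matures have GC 0.38–0.70 and a 79% 5'-terminal-U bias;
- 3 novel hairpin precursors embedded in transcripts, each mature at 17
  copies (the read count reported for the one novel miRNA such a survey
  found);
- contamination rates: low quality 2%, adapter-null 1%, insert-null 0.5%,
  5'-contaminant 0.8%, poly(A) 0.3%, short inserts 5%;
- 12 planted target sites with requested penalties on the 0.5 lattice
  (0–4.5), built by mutating perfect complements and confirmed by the scorer;
  RACE clones over the first 5 sites, 10 per site with 20% positional noise;
- reference ncRNA/repeat sets are random sequences with planted shared
  substrings — synthetic stand-ins, not real Rfam/RepeatMasker content.

Manifest exactness is guaranteed *by construction*: every candidate insert is
screened with the preprocess predicates themselves (no accidental adapter
seeds, 5'-adapter prefixes or poly(A) calls), and class-labelled tags are
checked against all higher-precedence reference sets. Hairpin constructions
use {A,C} flanks and loops (which cannot pair each other) so the planted stem
dominates the fold.

**What passing tests do and do not show.** The generator matches the study's
*statistical* structure, not its sequence content: real libraries have
sequencing-error isomiRs, expression-correlated length classes, genuinely
homologous (not random) ncRNA families, and thermodynamically structured
transcripts. Exact manifest recovery therefore validates the bookkeeping,
thresholds and geometry of the pipeline — it does not certify discovery
performance on real tissue data, where the simplified fold energies and
exact-match annotation would be the first things to revisit.

## Numerical conventions

- Percentages print half-up (Decimal-based) at 2 decimals; integer statistics
  (singleton %, 5'U %) round half-up to whole percent.
- Coordinates are 1-based closed everywhere; strand is "+"/"−"; RNA alphabet
  (U) internally, with T→U at ingest boundaries.
- Sorting tie-breaks: tags by descending count then lexicographic sequence;
  homology ties by database order; alignment ties by fewer gaps, then
  leftmost gap; scan clusters keep the leftmost minimum.
- Degenerate inputs: empty tag lists make ratio statistics an error rather
  than NaN; GC% of 0 raises on MFEI; unpairable sequences fold to MFE 0 with
  an all-dot structure.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full chain on the
10,000-read default library, oracle equivalences at 10³ tags × 10³ database
entries (homology), 10³ random pairs (target scoring) and ≤ 60 nt sequences
(folding), and the accounting arithmetic at the published scale (15.7M reads)
— counts are exact integers, so scale there is free.

## Known limitations

- The fold engine over-pairs relative to thermodynamic folders; its MFE scale
  is internally consistent but not comparable to Mfold/ViennaRNA values, and
  pseudoknots are out of scope.
- Annotation has no mismatch tolerance by design; SNP-bearing fragments land
  in "unannotated".
- The duplex model rejects asymmetric bulges; a real miRNA with a bulged
  duplex would need `min_duplex_run`/diagonal handling relaxed.
- Target prediction models cleavage-style complementarity only; no
  translational-inhibition or conservation scoring.
- qPCR assumes perfect doubling per cycle (no efficiency calibration).
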