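# Methods

## Scope and data model

`txrefine` revises an existing exon-structured annotation against
expression evidence; it does not assemble transcriptomes de novo and it
does not align reads.  Its inputs are the artefacts an upstream aligner
produces anyway: per-sample, per-strand base coverage and a table of
junction-spanning read counts.  Consuming these text formats instead of
BAM keeps every decision re-checkable — each `RevisionEvent` names the
exact reads/depths that justified it — and keeps the method testable
without alignment machinery.  A junction record is assumed to count
reads whose alignment gap matches the intron exactly with a few bases
anchored on each side; the library trusts the counts it is given.

All in-memory coordinates are 0-based half-open on the forward genomic
axis.  GTF I/O converts to/from the format's 1-based closed convention;
BED and bedGraph are native.  Transcripts with exons on multiple
chromosomes or strands are rejected outright rather than repaired.

## Revision rules and their parameters

All thresholds live in `RefinementConfig`; the defaults below are the
rule set the package is tested under.

| parameter | default | role |
|---|---|---|
| `min_junction_reads` | 2 reads | minimum support for a new splice, a new-exon link, or a chain join |
| `allowed_pairs` | GT–AG, GC–AG, AT–AC | canonical splice dinucleotides, transcription sense |
| `exon_len_ratio` | [0.80, 1.20] | band for revised/annotated flanking-exon length |
| `utr_depth_threshold` | 15 reads/base | coverage floor for the UTR walk |
| `utr_min_low_samples` | 2 samples | samples that must fall below the floor at a stop |
| `utr_min_extension` | 100 bp | extensions shorter than this are discarded |
| `island_min_depth` | 5 reads/base (pooled) | coverage island floor |
| `island_min_length` | 50 bp | minimum island length |
| `new_exon_max_overlap` | 0.30 | max fraction of a new exon overlapping annotated exons |
| `min_new_transcript_exons` | 2 exons | minimum chain length for a new transcript |

Read thresholds are evaluated on counts pooled across samples; the
junction table keeps per-sample counts, so per-sample minima could be
layered on, but the default semantics is pooled support.

Points where the rule set was genuinely open, and the choices made:

* **Boundary-revision tie-break.**  When several candidate introns pass
  all four rules for one unsupported annotated intron, the winner is the
  one with most reads, then the smallest total boundary shift, then the
  leftmost.  At most one event is emitted per annotated intron.
* **UTR stopping rule, clause (ii).**  "Runs of identical coverage" is
  operationalised as: the maximal constant-depth run containing the
  candidate stop, merged with one adjacent constant run on each side,
  averaged per sample.  This reading lets the walk ride over short dips
  (a 3-base gap inside deep coverage does not stop it) while a genuine
  drop-off — where the run containing the stop is long and low — does.
  The run search is windowed to ±2 kb around the walk, which bounds work
  per position and only truncates runs longer than 2 kb of perfectly
  constant depth, which real coverage does not produce.
* **UTR walk clamping.**  The walk halts at the nearest same-strand
  annotated transcript boundary, preventing gene fusion through a
  neighbour's expression; opposite-strand genes do not block, because
  the evidence is strand-specific.
* **Island calling.**  Intact putative exons are defined internally as
  maximal runs of pooled depth ≥ `island_min_depth` spanning
  ≥ `island_min_length`, rather than delegating to an external
  assembler; this keeps the stage deterministic, dependency-free and
  unit-testable.  The overlap fraction in the < 30 % rule is taken over
  the *new exon's* length (after snapping its ends to the linking
  junctions' inner coordinates).
* **"Intergenic"** for new transcripts means no overlap with any
  annotated transcript span — introns included — on *either* strand,
  the conservative reading.
* **Stage order.**  Junction → UTR → new exon → new transcript, each
  applied to the models as revised by the previous stage.  Within a
  stage events are independent by construction (one per intron, per
  transcript end, per island), so application order inside a stage does
  not matter.
* **Gene clustering** of new transcripts is single-linkage: two
  transcripts join one gene if they share a splice junction or ≥ 1 base
  of same-strand exonic overlap.  This is a deliberately simplified
  stand-in for full EST-cluster building; it is exact for the
  non-overlapping loci the benchmark generates.

## Reading-frame audit

For a boundary revision, the exonic-length delta is Δ = (old intron
length − new intron length); the revision is frame-shifting iff both
flanking exons overlap annotated CDS and Δ mod 3 ≠ 0.  Companion
("double mistake") detection is purely arithmetic: two events on one
transcript pair up iff their summed deltas are ≡ 0 mod 3.  No distance
bound is applied within a transcript, and no cross-species homology is
consulted — the longest-ORF scan (`scan_orf`, exhaustive over the three
frames of the spliced sense sequence) is the implemented proxy for
"still encodes a protein".  Transcripts lacking CDS annotation are
excluded from frame accounting (reported with `coding_coding=False`)
rather than guessed at.

## Evaluation statistics

* **Splice PFMs** over donor window [−3, +6) and acceptor window
  [−13, +3) in transcription sense (negative = exonic); information
  content per offset is 2 − H bits without small-sample correction.
  The windows cover the 9-mer donor and polypyrimidine/AG acceptor
  consensus; both are configurable.
* **Poly(A) profile**: fraction of transcripts whose sense hexamer at
  each offset in [−60, +10) from the 3' end equals AATAAA (DNA sense of
  AAUAAA); the negative control anchors the identical window at the 5'
  start.
* **Coverage categories** around each revised junction label every base
  in the disputed window by old/new exonic status, normalise pooled
  depth by the window maximum, and compare the two disputed categories
  (exonic-only-in-new vs exonic-only-in-old) with a two-sided
  Mann–Whitney test — exact null when both groups are < 20 and tie-free,
  tie-corrected normal approximation otherwise.
* **Conservation profiles** average a per-base score track per offset
  around donors and acceptors, exon side negative.
* **Distance histograms** bin signed, transcription-sense distances from
  peak midpoints (e.g. promoter-mark summits) to the nearest transcript
  5' end within ±5 kb in 100-bp bins.
* **Summary accounting** counts a feature as evidence-covered at ≥ 1
  read, reports per-category event/transcript counts, and percentages at
  one decimal over the annotated transcript total, counting multiply
  revised transcripts once.

## The synthetic benchmark

`SimConfig` defaults define the study conditions: 2 chromosomes ×
500 kb, 50 genes of 3–7 exons (exons 150–300 bp, introns 90–400 bp,
intergenic gaps 2–4 kb), 3 samples, exonic depth Poisson(30) per sample.
Every intron is canonical (5 % GC–AG); every transcript carries an
intact ORF confined to internal exons — terminal exons stay untranslated
so UTR corruption never cuts coding sequence — and an AATAAA planted at
a triangular-random offset in [−40, −15] of the 3' end (real poly(A)
signals cluster 15–30 nt upstream of cleavage).  A conservation track is
high (0.85) over exons, low (0.10) elsewhere, ±0.05 noise.

Intronic/intergenic background depth defaults to zero, modelling
poly(A)-selected, uniquely mapped data whose background is negligible
beside a 30× exonic mean.  This choice makes the UTR stopping position
and island boundaries exact, so planted errors are recoverable at exact
coordinates and recovery scoring is sharp; `noise_depth` raises the
background for robustness exploration.

The corrupter plants, on disjoint transcripts: 8 boundary shifts of
4–24 bp (each frame-shifting; half arranged as two frame-restoring pairs
whose deltas cancel mod 3), 5 × 5'-UTR and 10 × 3'-UTR truncations of
110–200 bp, 5 internal-exon deletions and 5 whole-transcript deletions.
Corrupted splice sites are verified non-canonical, and shifted exons
stay inside the 80–120 % band so every plant is recoverable by rule.
Seven decoys each violate exactly one rule (1-read support, supported
old junction, non-canonical candidate, length-band violation, 80-bp UTR
truncation, one-sided new-exon link, junctionless intergenic island) and
are flagged unsatisfiable; the evidence generator applies their read
overrides from the ledger.  Everything is a pure function of the seed.

What passing proves, and does not: recovery is exact under clean,
strand-resolved evidence on non-overlapping loci.  Real data add
multi-isoform loci, overlapping genes, fluctuating background and
library-specific coverage artefacts; the benchmark shows the *rules* are
implemented correctly, not that the thresholds are optimal for any
particular dataset.  Desk-scale sizes (1 Mb, 50 genes, 3 samples) were
chosen so the whole simulate-corrupt-refine-audit loop runs in about a
second; all stages are linear in genome size and stream per chromosome.

## Numerical and degenerate-input notes

* Length-band checks use exact arithmetic on integer lengths
  (`0.8·old ≤ new ≤ 1.2·old`), so the 80 %/120 % edges are inclusive.
* PFM columns are renormalised per offset; junctions shorter than a
  window are skipped and counted in `n_skipped`.
* Windows that would leave the chromosome (profiles, PFMs, hexamer
  scans) skip that anchor rather than truncating it.
* Empty inputs return empty structures: no junction events without
  evidence junctions, `n_anchors = 0` profiles for empty model sets, an
  undefined rank-sum p-value when a disputed category is empty.
* All writers are deterministic byte-for-byte given the same inputs;
  run manifests digest inputs and configuration (timestamps excluded).

## Known limitations

Single-isoform refinement only: alternative isoforms at one locus are
revised independently and may disagree.  CDS intervals are clipped to
revised exons, not re-predicted, after boundary changes.  Annotation
merging, antisense pairing, expression quantification and read mapping
are out of scope.
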