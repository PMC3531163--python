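"""Genomic intervals, transcript models and file I/O.

Single home for coordinate conventions: everything in memory is 0-based,
half-open ``[start, end)`` on the forward genomic axis, with strand carried
alongside.  GTF input/output converts to and from the format's 1-based
closed coordinates; BED and bedGraph are natively 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from intervaltree import IntervalTree

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: canonical splice dinucleotide pairs in transcription sense
CANONICAL_PAIRS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (``N`` preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


class ModelError(ValueError):
    """A transcript model violating structural invariants."""


class GtfParseError(ValueError):
    """Malformed GTF input; message names the offending line number."""


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class SpliceSiteKey:
    """One intron: ``[intron_start, intron_end)`` plus strand.

    The donor is the 5' end of the intron in transcription sense (left end
    on '+', right end on '-'); the acceptor the 3' end.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.intron_end - self.intron_start < 4:
            raise ModelError(
                f"intron {self.chrom}:{self.intron_start}-{self.intron_end} "
                "shorter than 4 bases"
            )

    def __len__(self) -> int:
        return self.intron_end - self.intron_start


class GenomeSequence:
    """Uppercase DNA for one chromosome with strand-aware lookup."""

    def __init__(self, chrom: str, sequence: str):
        self.chrom = chrom
        self.sequence = sequence.upper()
        self.length = len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        if start < 0 or end > self.length:
            raise IndexError(
                f"{self.chrom}:{start}-{end} outside [0,{self.length})"
            )
        seq = self.sequence[start:end]
        return revcomp(seq) if strand == "-" else seq


class Genome:
    """A set of chromosomes; from FASTA (via pyfaidx) or in-memory dict."""

    def __init__(self, chroms: Dict[str, str]):
        self.chroms: Dict[str, GenomeSequence] = {
            name: GenomeSequence(name, seq) for name, seq in chroms.items()
        }

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(path, as_raw=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def __getitem__(self, chrom: str) -> GenomeSequence:
        return self.chroms[chrom]

    def lengths(self) -> Dict[str, int]:
        return {c: g.length for c, g in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        return self.chroms[chrom].fetch(start, end, strand)

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.chroms):
                fh.write(f">{name}\n")
                seq = self.chroms[name].sequence
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript with optional CDS.

    ``exons`` are sorted by start, non-overlapping, separated by introns of
    at least one base; ``cds`` intervals are each contained in an exon.
    ``frame`` is the frame offset of the first coding base in transcription
    sense (0/1/2), ``attributes`` opaque extra GTF attribute text.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)
    frame: int = 0
    attributes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.transcript_id}: bad strand")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ModelError(
                    f"{self.transcript_id}: exon on wrong chrom/strand"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ModelError(
                    f"{self.transcript_id}: overlapping/abutting exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        self.cds = sorted(self.cds, key=lambda c: c.start)
        for c in self.cds:
            if not any(c.start >= e.start and c.end <= e.end for e in self.exons):
                raise ModelError(
                    f"{self.transcript_id}: CDS {c.start}-{c.end} "
                    "not contained in an exon"
                )

    # -- derived geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_sequence(self, genome: Genome) -> str:
        seq = "".join(
            genome.fetch(self.chrom, e.start, e.end) for e in self.exons
        )
        return revcomp(seq) if self.strand == "-" else seq

    def copy(self) -> "TranscriptModel":
        return dataclasses.replace(
            self, exons=list(self.exons), cds=list(self.cds)
        )

    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript 3' terminus.

        On '+' this is the exclusive span end; on '-' the inclusive span
        start (the boundary coordinate in half-open convention).
        """
        return self.end if self.strand == "+" else self.start

    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end


def introns_of(transcript: TranscriptModel) -> List[SpliceSiteKey]:
    """Introns between consecutive exons, in genomic order."""
    return [
        SpliceSiteKey(transcript.chrom, a.end, b.start, transcript.strand)
        for a, b in zip(transcript.exons, transcript.exons[1:])
    ]


class GeneModelSet:
    """Transcripts indexed by id with per-chrom overlap queries."""

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel] = (),
        provenance: str = "putative",
    ):
        self.transcripts: Dict[str, TranscriptModel] = {}
        self.provenance = provenance
        self._trees: Optional[Dict[str, IntervalTree]] = None
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ModelError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        self._trees = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def _index(self) -> Dict[str, IntervalTree]:
        if self._trees is None:
            trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
            for t in self.transcripts.values():
                trees[t.chrom].addi(t.start, t.end, t.transcript_id)
            self._trees = dict(trees)
        return self._trees

    def overlapping(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> List[TranscriptModel]:
        """Transcripts whose span intersects ``[start, end)``."""
        tree = self._index().get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))

    def sorted_transcripts(self) -> List[TranscriptModel]:
        return sorted(
            self.transcripts.values(),
            key=lambda t: (t.chrom, t.start, t.transcript_id),
        )

    def copy(self, provenance: Optional[str] = None) -> "GeneModelSet":
        return GeneModelSet(
            (t.copy() for t in self.sorted_transcripts()),
            provenance=provenance or self.provenance,
        )


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect: exon and CDS features, gene_id/transcript_id)
# ---------------------------------------------------------------------------

def _parse_attributes(text: str, lineno: int) -> Tuple[str, str, str]:
    gene_id = transcript_id = None
    extras: List[str] = []
    for item in text.strip().rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        parts = item.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: bad attribute {item!r}")
        key, val = parts
        val = val.strip().strip('"')
        if key == "gene_id":
            gene_id = val
        elif key == "transcript_id":
            transcript_id = val
        else:
            extras.append(item if item.endswith('"') else item)
    if gene_id is None or transcript_id is None:
        raise GtfParseError(
            f"line {lineno}: missing gene_id/transcript_id attribute"
        )
    return gene_id, transcript_id, "; ".join(extras)


def read_gtf(path_or_handle) -> GeneModelSet:
    """Read exon/CDS features from an Ensembl-style GTF.

    1-based closed GTF coordinates become 0-based half-open.  Transcripts
    with exons on multiple chromosomes or strands, or with overlapping
    exons, are rejected with a :class:`ModelError`.
    """
    if isinstance(path_or_handle, (str,)):
        fh = open(path_or_handle)
        close = True
    else:
        fh, close = path_or_handle, False
    exons: Dict[str, List[Interval]] = defaultdict(list)
    cds: Dict[str, List[Interval]] = defaultdict(list)
    frames: Dict[str, Tuple[int, int]] = {}  # tid -> (coord, frame) of 5'-most CDS
    meta: Dict[str, Tuple[str, str, str, str]] = {}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, frame_s, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1
                end = int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates")
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            gene_id, tid, extra = _parse_attributes(attrs, lineno)
            try:
                iv = Interval(chrom, start, end, strand)
            except ModelError as exc:
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            prev = meta.get(tid)
            if prev is None:
                meta[tid] = (gene_id, chrom, strand, extra)
            elif prev[1] != chrom or prev[2] != strand:
                raise ModelError(
                    f"transcript {tid}: features on multiple chroms/strands"
                )
            if feature == "exon":
                exons[tid].append(iv)
            else:
                cds[tid].append(iv)
                if frame_s in ("0", "1", "2"):
                    key = start if strand == "+" else -end
                    if tid not in frames or key < frames[tid][0]:
                        frames[tid] = (key, int(frame_s))
    finally:
        if close:
            fh.close()

    models = GeneModelSet()
    for tid in exons:
        gene_id, chrom, strand, extra = meta[tid]
        models.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                cds=cds.get(tid, []),
                frame=frames.get(tid, (0, 0))[1],
                attributes=extra,
            )
        )
    return models


def write_gtf(models: GeneModelSet, path_or_handle) -> None:
    """Write exon/CDS lines, deterministically ordered.

    Transcripts ordered by (chrom, start, transcript_id); exon lines in
    ascending genomic order regardless of strand (standard GTF layout).
    """
    if isinstance(path_or_handle, str):
        fh = open(path_or_handle, "w")
        close = True
    else:
        fh, close = path_or_handle, False
    try:
        for t in models.sorted_transcripts():
            attr = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.attributes:
                attr += " " + t.attributes + ";"
            for ex in t.exons:
                fh.write(
                    f"{t.chrom}\ttxrefine\texon\t{ex.start + 1}\t{ex.end}\t."
                    f"\t{t.strand}\t.\t{attr}\n"
                )
            frame = _cds_frames(t)
            for c, fr in zip(t.cds, frame):
                fh.write(
                    f"{t.chrom}\ttxrefine\tCDS\t{c.start + 1}\t{c.end}\t."
                    f"\t{t.strand}\t{fr}\t{attr}\n"
                )
    finally:
        if close:
            fh.close()


def _cds_frames(t: TranscriptModel) -> List[int]:
    """Per-CDS-interval frame column in genomic order."""
    pieces = t.cds if t.strand == "+" else list(reversed(t.cds))
    out: List[int] = []
    fr = t.frame
    for c in pieces:
        out.append(fr)
        fr = (3 - ((len(c) - fr) % 3)) % 3
    if t.strand == "-":
        out = list(reversed(out))
    return out


def gtf_string(models: GeneModelSet) -> str:
    buf = io.StringIO()
    write_gtf(models, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> List[Interval]:
    """BED6 (or BED3; strand defaults to '+') intervals."""
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "+"
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n"
            )
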