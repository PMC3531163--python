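"""Evidence-driven revision of putative gene models.

Four procedures, run in a fixed order on progressively revised models:

1. exon/intron boundary (junction) revision — an annotated intron with no
   junction-spanning reads is replaced by an evidenced intron when the new
   splice is read-supported, canonically spliced, stays inside the two
   flanking exons, and leaves both revised exons within a length band of
   the annotated ones;
2. UTR extension — transcript ends walk outward while base coverage stays
   high, with a run-averaged stopping rule and a minimum extension length;
3. new internal exons — coverage islands inside a transcript, linked to
   annotated exon boundaries by junction reads on both sides and mostly
   non-overlapping with annotated exons;
4. new intergenic transcripts — chains of coverage islands connected by
   junction reads, wholly outside annotated loci, then clustered into
   genes by shared junctions or same-strand exon overlap.

Every accepted change is a :class:`RevisionEvent`, independently
re-checkable against the evidence it cites.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CANONICAL_PAIRS,
    GeneModelSet,
    Genome,
    Interval,
    SpliceSiteKey,
    TranscriptModel,
    introns_of,
)
from .evidence import (
    CoverageTrack,
    EvidenceBundle,
    JunctionTable,
    is_canonical,
    pooled_depth,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefinementConfig:
    """Every numeric threshold of the refinement procedures.

    Defaults follow the published rule set: two junction-spanning reads to
    accept a new splice and none supporting the old one; GT-AG/GC-AG/AT-AC
    dinucleotides; revised exons within 80-120% of the annotated length;
    UTR walk stops where depth drops below 15 in at least two samples (and
    the run-averaged depth is below 15 in every sample), with extensions
    under 100 bp discarded; a new exon may overlap annotated exons by less
    than 30% of its length; a new transcript needs at least two exons.
    The island caller replaces an external assembler with explicit pooled
    depth/length thresholds.
    """

    min_junction_reads: int = 2
    allowed_pairs: frozenset = CANONICAL_PAIRS
    exon_len_ratio: Tuple[float, float] = (0.80, 1.20)
    utr_depth_threshold: float = 15.0
    utr_min_low_samples: int = 2
    utr_min_extension: int = 100
    island_min_depth: float = 5.0
    island_min_length: int = 50
    new_exon_max_overlap: float = 0.30
    min_new_transcript_exons: int = 2
    #: external-assembler parameters recorded for provenance, not interpreted
    legacy_assembler_params: str = "-o -F 0.4 -j 0.45 -m 220 -p 4"

    def __post_init__(self) -> None:
        if self.min_junction_reads < 1 or self.utr_min_low_samples < 1:
            raise ValueError("count thresholds must be >= 1")
        lo, hi = self.exon_len_ratio
        if not (lo <= 1.0 <= hi):
            raise ValueError("exon_len_ratio interval must contain 1")
        if not (0 < self.new_exon_max_overlap <= 1):
            raise ValueError("new_exon_max_overlap must be in (0, 1]")

    def to_dict(self) -> Dict[str, object]:
        return {
            "min_junction_reads": self.min_junction_reads,
            "allowed_pairs": sorted(
                f"{d}-{a}" for d, a in self.allowed_pairs
            ),
            "exon_len_ratio": list(self.exon_len_ratio),
            "utr_depth_threshold": self.utr_depth_threshold,
            "utr_min_low_samples": self.utr_min_low_samples,
            "utr_min_extension": self.utr_min_extension,
            "island_min_depth": self.island_min_depth,
            "island_min_length": self.island_min_length,
            "new_exon_max_overlap": self.new_exon_max_overlap,
            "min_new_transcript_exons": self.min_new_transcript_exons,
        }


EVENT_TYPES = ("junction", "utr5", "utr3", "new_exon", "new_transcript")


@dataclass
class RevisionEvent:
    """One refinement, coordinate-anchored with its supporting evidence.

    ``old_start``/``old_end`` and ``new_start``/``new_end`` are the revised
    feature's coordinates before and after: the intron for junction events,
    the terminal exon for UTR events, the inserted exon for new exons and
    the transcript span for new transcripts (old coordinates are None).
    """

    event_type: str
    transcript_id: Optional[str]
    chrom: str
    strand: str
    old_start: Optional[int]
    old_end: Optional[int]
    new_start: int
    new_end: int
    support_reads: int = 0
    support_samples: int = 0
    detail: str = ""
    event_id: str = ""
    #: exon chain for new_transcript events
    exons: Optional[Tuple[Tuple[int, int], ...]] = None

    TSV_COLUMNS = (
        "event_id",
        "event_type",
        "transcript_id",
        "chrom",
        "strand",
        "old_start",
        "old_end",
        "new_start",
        "new_end",
        "support_reads",
        "support_samples",
        "detail",
    )

    def tsv_row(self) -> str:
        def fmt(v):
            return "." if v is None or v == "" else str(v)

        detail = self.detail
        if self.exons:
            chain = ",".join(f"{s}-{e}" for s, e in self.exons)
            detail = (detail + ";" if detail else "") + f"exons={chain}"
        return "\t".join(
            [
                fmt(self.event_id),
                self.event_type,
                fmt(self.transcript_id),
                self.chrom,
                self.strand,
                fmt(self.old_start),
                fmt(self.old_end),
                str(self.new_start),
                str(self.new_end),
                str(self.support_reads),
                str(self.support_samples),
                fmt(detail),
            ]
        )


def write_events_tsv(events: Sequence[RevisionEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RevisionEvent.TSV_COLUMNS) + "\n")
        for ev in events:
            fh.write(ev.tsv_row() + "\n")


def read_events_tsv(path: str) -> List[RevisionEvent]:
    events: List[RevisionEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RevisionEvent.TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected events header {header!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != len(RevisionEvent.TSV_COLUMNS):
                continue
            detail = "" if f[11] == "." else f[11]
            exons = None
            parts = detail.split(";")
            chain_parts = [p for p in parts if p.startswith("exons=")]
            if chain_parts:
                detail = ";".join(p for p in parts if not p.startswith("exons="))
                exons = tuple(
                    tuple(int(x) for x in part.split("-"))
                    for part in chain_parts[0][len("exons="):].split(",")
                )
            events.append(
                RevisionEvent(
                    event_id=f[0],
                    event_type=f[1],
                    transcript_id=None if f[2] == "." else f[2],
                    chrom=f[3],
                    strand=f[4],
                    old_start=None if f[5] == "." else int(f[5]),
                    old_end=None if f[6] == "." else int(f[6]),
                    new_start=int(f[7]),
                    new_end=int(f[8]),
                    support_reads=int(f[9]),
                    support_samples=int(f[10]),
                    detail=detail,
                    exons=exons,
                )
            )
    return events


# ---------------------------------------------------------------------------
# 1. junction revision
# ---------------------------------------------------------------------------

def _ratio_ok(new_len: int, old_len: int, band: Tuple[float, float]) -> bool:
    lo, hi = band
    # integer-exact comparison: lo <= new/old <= hi
    return lo * old_len <= new_len <= hi * old_len


def propose_junction_revisions(
    models: GeneModelSet,
    junctions: JunctionTable,
    genome: Genome,
    config: RefinementConfig,
) -> List[RevisionEvent]:
    """One revision event per unsupported annotated intron, if any
    evidenced intron passes all four acceptance rules.

    Rules, per candidate intron C replacing annotated intron A between
    exons L and R: (a) reads across C >= ``min_junction_reads`` while A has
    zero reads; (b) C's dinucleotides are in ``allowed_pairs``; (c) C lies
    within ``[L.start, R.end)``; (d) both revised exon lengths are within
    ``exon_len_ratio`` of the annotated ones.  Ties: most reads, then
    smallest total boundary shift, then leftmost.
    """
    events: List[RevisionEvent] = []
    for t in models.sorted_transcripts():
        for old in introns_of(t):
            total_old, _ = junctions.support(old)
            if total_old > 0:
                continue
            idx = next(
                i
                for i, ex in enumerate(t.exons)
                if ex.end == old.intron_start
            )
            left, right = t.exons[idx], t.exons[idx + 1]
            best = None
            for cand in junctions.contained_in(
                t.chrom, left.start, right.end, t.strand
            ):
                if cand == old:
                    continue
                reads, samples = junctions.support(cand)
                if reads < config.min_junction_reads:
                    continue
                if not is_canonical(genome, cand, config.allowed_pairs):
                    continue
                if cand.intron_start <= left.start or cand.intron_end >= right.end:
                    continue  # a flanking exon would vanish
                new_left = cand.intron_start - left.start
                new_right = right.end - cand.intron_end
                if not _ratio_ok(new_left, len(left), config.exon_len_ratio):
                    continue
                if not _ratio_ok(new_right, len(right), config.exon_len_ratio):
                    continue
                shift = abs(cand.intron_start - old.intron_start) + abs(
                    cand.intron_end - old.intron_end
                )
                score = (-reads, shift, cand.intron_start, cand.intron_end)
                if best is None or score < best[0]:
                    best = (score, cand, reads, samples)
            if best is None:
                continue
            _, cand, reads, samples = best
            events.append(
                RevisionEvent(
                    event_type="junction",
                    transcript_id=t.transcript_id,
                    chrom=t.chrom,
                    strand=t.strand,
                    old_start=old.intron_start,
                    old_end=old.intron_end,
                    new_start=cand.intron_start,
                    new_end=cand.intron_end,
                    support_reads=reads,
                    support_samples=samples,
                    detail=f"intron_index={idx}",
                )
            )
    return events


def apply_junction_revisions(
    models: GeneModelSet, events: Sequence[RevisionEvent]
) -> GeneModelSet:
    """Move flanking exon boundaries to the revised intron ends.

    Exon counts are unchanged; CDS intervals are re-clipped to the revised
    exons.  Two events on the same annotated intron are an error.
    """
    revised = models.copy(provenance="revised")
    seen = set()
    for ev in events:
        if ev.event_type != "junction":
            continue
        key = (ev.transcript_id, ev.old_start, ev.old_end)
        if key in seen:
            raise ValueError(f"conflicting events on intron {key}")
        seen.add(key)
        t = revised[ev.transcript_id]
        exons = list(t.exons)
        idx = next(
            i for i, ex in enumerate(exons) if ex.end == ev.old_start
        )
        exons[idx] = replace(exons[idx], end=ev.new_start)
        exons[idx + 1] = replace(exons[idx + 1], start=ev.new_end)
        t.exons = exons
        t.cds = _clip_cds(t.cds, exons)
        t.validate()
    return revised


def _clip_cds(cds: List[Interval], exons: List[Interval]) -> List[Interval]:
    out: List[Interval] = []
    for c in cds:
        for e in exons:
            s, t_ = max(c.start, e.start), min(c.end, e.end)
            if s < t_:
                out.append(replace(c, start=s, end=t_))
    return out


# ---------------------------------------------------------------------------
# 2. UTR extension
# ---------------------------------------------------------------------------

def _run_mean_below(
    arr: np.ndarray, pos: int, threshold: float
) -> bool:
    """Mean depth over the constant run containing ``pos`` merged with one
    adjacent constant run on each side, compared against ``threshold``."""
    n = len(arr)
    v = arr[pos]
    lo = pos
    while lo > 0 and arr[lo - 1] == v:
        lo -= 1
    hi = pos
    while hi + 1 < n and arr[hi + 1] == v:
        hi += 1
    # extend by one neighbouring run per side
    if lo > 0:
        w = arr[lo - 1]
        lo2 = lo - 1
        while lo2 > 0 and arr[lo2 - 1] == w:
            lo2 -= 1
        lo = lo2
    if hi + 1 < n:
        w = arr[hi + 1]
        hi2 = hi + 1
        while hi2 + 1 < n and arr[hi2 + 1] == w:
            hi2 += 1
        hi = hi2
    return float(arr[lo : hi + 1].mean()) < threshold


def extend_utr(
    transcript: TranscriptModel,
    coverage_tracks: Sequence[CoverageTrack],
    models: GeneModelSet,
    config: RefinementConfig,
    side: str,
) -> Optional[RevisionEvent]:
    """Walk one transcript end outward along the coverage and extend it.

    ``side`` is ``"5"`` or ``"3"`` (transcription sense).  A genomic
    position p is a *stop* iff (i) its depth is below
    ``utr_depth_threshold`` in at least ``utr_min_low_samples`` samples,
    and (ii) in every sample the mean over the maximal constant-depth run
    containing p, merged with one adjacent run on each side, is below the
    threshold.  The new end is the base before the first stop.  The walk
    is clamped at the nearest same-strand annotated transcript boundary
    and at the chromosome end; extensions shorter than
    ``utr_min_extension`` are discarded.
    """
    if side not in ("5", "3"):
        raise ValueError("side must be '5' or '3'")
    if len(coverage_tracks) < config.utr_min_low_samples:
        raise ValueError(
            f"{len(coverage_tracks)} coverage samples available but "
            f"utr_min_low_samples={config.utr_min_low_samples}"
        )
    outward_right = (transcript.strand == "+") == (side == "3")
    chrom_len = len(coverage_tracks[0].depth[transcript.chrom])

    if outward_right:
        origin = transcript.end  # first candidate base
        limit = chrom_len
        for other in models.overlapping(
            transcript.chrom, origin, chrom_len, transcript.strand
        ):
            if other.transcript_id != transcript.transcript_id and other.start >= origin:
                limit = min(limit, other.start)
    else:
        origin = transcript.start - 1  # first candidate base, walking left
        limit = -1
        for other in models.overlapping(
            transcript.chrom, 0, transcript.start, transcript.strand
        ):
            if other.transcript_id != transcript.transcript_id and other.end <= transcript.start:
                limit = max(limit, other.end - 1)

    step = 1 if outward_right else -1
    windows = None  # lazily fetched per-sample arrays around the walk
    pos = origin
    new_boundary = None
    while (pos < limit) if outward_right else (pos > limit):
        depths = [tr.at(transcript.chrom, pos) for tr in coverage_tracks]
        n_low = sum(d < config.utr_depth_threshold for d in depths)
        if n_low >= config.utr_min_low_samples:
            lo = min(origin, pos) - 2000
            hi = max(origin, pos) + 2000
            lo = max(lo, 0)
            hi = min(hi, chrom_len)
            if all(
                _run_mean_below(
                    tr.window(transcript.chrom, lo, hi),
                    pos - lo,
                    config.utr_depth_threshold,
                )
                for tr in coverage_tracks
            ):
                new_boundary = pos  # first stop
                break
        pos += step
    if new_boundary is None:
        new_boundary = limit if outward_right else limit  # clamped at limit
        # pos ran to the clamp; the new end sits at the clamp boundary
        new_boundary = pos

    if outward_right:
        extension = new_boundary - transcript.end  # new end (exclusive)
        new_start, new_end = transcript.exons[-1].start, new_boundary
        old_start, old_end = (
            transcript.exons[-1].start,
            transcript.exons[-1].end,
        )
    else:
        extension = transcript.start - (new_boundary + 1)
        new_start, new_end = new_boundary + 1, transcript.exons[0].end
        old_start, old_end = (
            transcript.exons[0].start,
            transcript.exons[0].end,
        )
    if extension < config.utr_min_extension:
        return None
    event_type = "utr5" if side == "5" else "utr3"
    # depth statistics over the extension, per sample
    if outward_right:
        ext_lo, ext_hi = old_end, new_end
    else:
        ext_lo, ext_hi = new_start, old_start
    means = [
        float(tr.window(transcript.chrom, ext_lo, ext_hi).mean())
        for tr in coverage_tracks
    ]
    return RevisionEvent(
        event_type=event_type,
        transcript_id=transcript.transcript_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        old_start=old_start,
        old_end=old_end,
        new_start=new_start,
        new_end=new_end,
        support_reads=int(round(sum(means))),
        support_samples=sum(m >= config.utr_depth_threshold for m in means),
        detail=f"extension={extension}",
    )


def apply_utr_events(
    models: GeneModelSet, events: Sequence[RevisionEvent]
) -> GeneModelSet:
    revised = models.copy(provenance="revised")
    for ev in events:
        if ev.event_type not in ("utr5", "utr3"):
            continue
        t = revised[ev.transcript_id]
        exons = list(t.exons)
        if ev.old_start == exons[-1].start and ev.new_end != exons[-1].end:
            exons[-1] = replace(exons[-1], end=ev.new_end)
        if ev.old_end == exons[0].end and ev.new_start != exons[0].start:
            exons[0] = replace(exons[0], start=ev.new_start)
        t.exons = exons
        t.validate()
    return revised


# ---------------------------------------------------------------------------
# 3. coverage islands and new exons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageIsland:
    """Maximal run of above-threshold pooled depth on one strand."""

    interval: Interval
    mean_depth: Tuple[float, ...]  # per sample
    boundary_basis: str = "coverage"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def __len__(self) -> int:
        return len(self.interval)


def call_coverage_islands(
    coverage_tracks: Sequence[CoverageTrack],
    strand: str,
    config: RefinementConfig,
) -> List[CoverageIsland]:
    """Maximal runs where pooled depth >= ``island_min_depth`` and length
    >= ``island_min_length``; islands on one strand never overlap."""
    if not coverage_tracks:
        return []
    islands: List[CoverageIsland] = []
    chroms = sorted(coverage_tracks[0].depth)
    for chrom in chroms:
        pooled = pooled_depth(
            coverage_tracks, chrom, 0, len(coverage_tracks[0].depth[chrom])
        )
        above = pooled >= config.island_min_depth
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = list(edges[~above[edges]] + 1) if len(edges) else []
        ends = list(edges[above[edges]] + 1) if len(edges) else []
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [len(above)]
        for s, e in zip(starts, ends):
            if e - s < config.island_min_length:
                continue
            means = tuple(
                float(tr.window(chrom, s, e).mean()) for tr in coverage_tracks
            )
            islands.append(
                CoverageIsland(Interval(chrom, int(s), int(e), strand), means)
            )
    return islands


def _exon_boundaries(t: TranscriptModel) -> Tuple[set, set]:
    """(exon end coordinates, exon start coordinates)."""
    return {e.end for e in t.exons}, {e.start for e in t.exons}


def find_new_exons(
    models: GeneModelSet,
    islands: Sequence[CoverageIsland],
    junctions: JunctionTable,
    genome: Genome,
    config: RefinementConfig,
) -> List[RevisionEvent]:
    """Islands inside a transcript, junction-linked to it on both ends.

    Acceptance: the island lies inside the transcript span; a canonical
    junction with >= ``min_junction_reads`` reads connects each island end
    to an annotated exon boundary of the transcript; the snapped exon
    (between the linking junctions' inner ends) overlaps all annotated
    exons by less than ``new_exon_max_overlap`` of its length.
    """
    events: List[RevisionEvent] = []
    all_exons_by_chrom: Dict[Tuple[str, str], List[Interval]] = {}
    for t in models:
        all_exons_by_chrom.setdefault((t.chrom, t.strand), []).extend(t.exons)

    for island in sorted(islands, key=lambda i: (i.chrom, i.start)):
        hosts = [
            t
            for t in models.overlapping(
                island.chrom, island.start, island.end, island.interval.strand
            )
            if t.start <= island.start and island.end <= t.end
        ]
        for t in hosts:
            ends, starts = _exon_boundaries(t)
            left = _best_link(
                junctions, genome, config, island, t, ends, side="left"
            )
            right = _best_link(
                junctions, genome, config, island, t, starts, side="right"
            )
            if left is None or right is None:
                continue
            lj, l_reads, l_samp = left
            rj, r_reads, r_samp = right
            if lj.intron_end >= rj.intron_start:
                continue
            new_exon = Interval(
                island.chrom, lj.intron_end, rj.intron_start,
                island.interval.strand,
            )
            overlap = sum(
                new_exon.overlap_len(e)
                for e in all_exons_by_chrom.get(
                    (island.chrom, island.interval.strand), []
                )
            )
            if overlap >= config.new_exon_max_overlap * len(new_exon):
                continue
            events.append(
                RevisionEvent(
                    event_type="new_exon",
                    transcript_id=t.transcript_id,
                    chrom=island.chrom,
                    strand=island.interval.strand,
                    old_start=None,
                    old_end=None,
                    new_start=new_exon.start,
                    new_end=new_exon.end,
                    support_reads=l_reads + r_reads,
                    support_samples=max(l_samp, r_samp),
                    detail=(
                        f"island={island.start}-{island.end};"
                        f"left_junction={lj.intron_start}-{lj.intron_end};"
                        f"right_junction={rj.intron_start}-{rj.intron_end}"
                    ),
                )
            )
    return events


def _best_link(
    junctions: JunctionTable,
    genome: Genome,
    config: RefinementConfig,
    island: CoverageIsland,
    t: TranscriptModel,
    boundaries: set,
    side: str,
) -> Optional[Tuple[SpliceSiteKey, int, int]]:
    """Strongest canonical junction tying one island end to an annotated
    exon boundary of ``t`` (``side='left'``: junction lands on the island's
    left end from an exon end; ``'right'``: leaves the right end to an
    exon start)."""
    best = None
    # widen by one base: a linking junction may abut the island exactly
    for j in junctions.in_region(
        island.chrom, island.start - 1, island.end + 1, island.interval.strand
    ):
        reads, samples = junctions.support(j)
        if reads < config.min_junction_reads:
            continue
        if side == "left":
            if not (island.start <= j.intron_end < island.end):
                continue
            if j.intron_start not in boundaries:
                continue
        else:
            if not (island.start < j.intron_start <= island.end):
                continue
            if j.intron_end not in boundaries:
                continue
        if not is_canonical(genome, j, config.allowed_pairs):
            continue
        score = (-reads, j.intron_start, j.intron_end)
        if best is None or score < best[0]:
            best = (score, j, reads, samples)
    return None if best is None else best[1:]


def apply_new_exons(
    models: GeneModelSet, events: Sequence[RevisionEvent]
) -> GeneModelSet:
    revised = models.copy(provenance="revised")
    for ev in events:
        if ev.event_type != "new_exon":
            continue
        t = revised[ev.transcript_id]
        t.exons = list(t.exons) + [
            Interval(ev.chrom, ev.new_start, ev.new_end, ev.strand)
        ]
        t.validate()
    return revised


# ---------------------------------------------------------------------------
# 4. new transcripts
# ---------------------------------------------------------------------------

def assemble_new_transcripts(
    islands: Sequence[CoverageIsland],
    junctions: JunctionTable,
    models: GeneModelSet,
    genome: Genome,
    config: RefinementConfig,
) -> List[RevisionEvent]:
    """Chains of islands joined by canonical junction reads, wholly
    intergenic (no overlap with any annotated transcript span on either
    strand), with at least ``min_new_transcript_exons`` exons.  Exon ends
    are snapped to the connecting junctions."""
    events: List[RevisionEvent] = []
    by_strand: Dict[Tuple[str, str], List[CoverageIsland]] = {}
    for isl in islands:
        by_strand.setdefault((isl.chrom, isl.interval.strand), []).append(isl)

    counter = itertools.count(1)
    for (chrom, strand), group in sorted(by_strand.items()):
        group = sorted(group, key=lambda i: i.start)
        links: Dict[int, Tuple[int, SpliceSiteKey, int, int]] = {}
        for i, a in enumerate(group):
            best = None
            for j in junctions.in_region(chrom, a.start, a.end + 1, strand):
                if not (a.start < j.intron_start <= a.end):
                    continue
                reads, samples = junctions.support(j)
                if reads < config.min_junction_reads:
                    continue
                if not is_canonical(genome, j, config.allowed_pairs):
                    continue
                target = None
                for k in range(i + 1, len(group)):
                    b = group[k]
                    if b.start <= j.intron_end < b.end:
                        target = k
                        break
                if target is None:
                    continue
                score = (-reads, j.intron_start)
                if best is None or score < best[0]:
                    best = (score, target, j, reads, samples)
            if best is not None:
                links[i] = best[1:]
        # walk maximal chains
        has_incoming = {tgt for tgt, *_ in links.values()}
        for i in range(len(group)):
            if i in has_incoming or i not in links:
                continue
            chain = [i]
            joins: List[Tuple[SpliceSiteKey, int, int]] = []
            cur = i
            while cur in links:
                tgt, j, reads, samples = links[cur]
                joins.append((j, reads, samples))
                chain.append(tgt)
                cur = tgt
            if len(chain) < config.min_new_transcript_exons:
                continue
            exons: List[Tuple[int, int]] = []
            for pos, idx in enumerate(chain):
                isl = group[idx]
                s = isl.start if pos == 0 else joins[pos - 1][0].intron_end
                e = (
                    isl.end
                    if pos == len(chain) - 1
                    else joins[pos][0].intron_start
                )
                if s >= e:
                    exons = []
                    break
                exons.append((s, e))
            if not exons:
                continue
            span_s, span_e = exons[0][0], exons[-1][1]
            if models.overlapping(chrom, span_s, span_e, strand=None):
                continue  # not intergenic
            total_reads = sum(r for _, r, _ in joins)
            events.append(
                RevisionEvent(
                    event_type="new_transcript",
                    transcript_id=f"NOVT{next(counter):05d}",
                    chrom=chrom,
                    strand=strand,
                    old_start=None,
                    old_end=None,
                    new_start=span_s,
                    new_end=span_e,
                    support_reads=total_reads,
                    support_samples=max((s for *_, s in joins), default=0),
                    detail=f"n_exons={len(exons)}",
                    exons=tuple(exons),
                )
            )
    return events


def cluster_new_transcripts(
    new_transcripts: Sequence[TranscriptModel],
) -> Dict[str, str]:
    """Single-linkage gene clusters: transcripts sharing a splice junction
    or >=1 base of same-strand exonic overlap join one cluster.  Returns
    transcript_id -> gene_id, deterministic."""
    ts = sorted(new_transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    parent = list(range(len(ts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    junction_sets = [set(introns_of(t)) for t in ts]
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            a, b = ts[i], ts[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if b.start >= a.end:
                break  # sorted by start; no further overlap on this chrom
            linked = bool(junction_sets[i] & junction_sets[j]) or any(
                ea.overlap_len(eb) > 0 for ea in a.exons for eb in b.exons
            )
            if linked:
                union(i, j)
    roots: Dict[int, str] = {}
    assignment: Dict[str, str] = {}
    counter = itertools.count(1)
    for i, t in enumerate(ts):
        r = find(i)
        if r not in roots:
            roots[r] = f"NOVG{next(counter):05d}"
        assignment[t.transcript_id] = roots[r]
    return assignment


def events_to_transcripts(
    events: Sequence[RevisionEvent],
) -> List[TranscriptModel]:
    """Materialise new_transcript events as transcript models."""
    out = []
    for ev in events:
        if ev.event_type != "new_transcript" or not ev.exons:
            continue
        out.append(
            TranscriptModel(
                transcript_id=ev.transcript_id,
                gene_id=ev.transcript_id,  # provisional; clustering assigns
                chrom=ev.chrom,
                strand=ev.strand,
                exons=[
                    Interval(ev.chrom, s, e, ev.strand) for s, e in ev.exons
                ],
            )
        )
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    models: GeneModelSet
    events: List[RevisionEvent]

    def events_of(self, *types: str) -> List[RevisionEvent]:
        return [e for e in self.events if e.event_type in types]

    def transcripts_affected(self) -> int:
        """Distinct previously annotated transcripts with >=1 revision
        (new transcripts excluded; multiply revised counted once)."""
        return len(
            {
                e.transcript_id
                for e in self.events
                if e.event_type != "new_transcript" and e.transcript_id
            }
        )


def refine(
    models: GeneModelSet,
    evidence: EvidenceBundle,
    genome: Genome,
    config: Optional[RefinementConfig] = None,
) -> RefinementResult:
    """Run the four refinement procedures in order on progressively
    revised models and return the revised set plus the event ledger."""
    config = config or RefinementConfig()
    ledger: List[RevisionEvent] = []
    counter = itertools.count(1)

    jev = propose_junction_revisions(models, evidence.junctions, genome, config)
    for ev in jev:
        ev.event_id = f"E{next(counter):05d}"
    ledger.extend(jev)
    current = apply_junction_revisions(models, jev)
    logger.info("junction stage: %d events", len(jev))

    uev: List[RevisionEvent] = []
    for t in current.sorted_transcripts():
        tracks = evidence.tracks(t.strand)
        if len(tracks) < config.utr_min_low_samples:
            continue
        for side in ("5", "3"):
            ev = extend_utr(t, tracks, current, config, side)
            if ev is not None:
                ev.event_id = f"E{next(counter):05d}"
                uev.append(ev)
    ledger.extend(uev)
    current = apply_utr_events(current, uev)
    logger.info("UTR stage: %d events", len(uev))

    nev: List[RevisionEvent] = []
    islands_by_strand = {
        strand: call_coverage_islands(evidence.tracks(strand), strand, config)
        for strand in ("+", "-")
    }
    for strand in ("+", "-"):
        nev.extend(
            find_new_exons(
                current, islands_by_strand[strand], evidence.junctions,
                genome, config,
            )
        )
    for ev in nev:
        ev.event_id = f"E{next(counter):05d}"
    ledger.extend(nev)
    current = apply_new_exons(current, nev)
    logger.info("new-exon stage: %d events", len(nev))

    tev: List[RevisionEvent] = []
    for strand in ("+", "-"):
        tev.extend(
            assemble_new_transcripts(
                islands_by_strand[strand], evidence.junctions, current,
                genome, config,
            )
        )
    tev.sort(key=lambda e: (e.chrom, e.new_start, e.strand))
    for i, ev in enumerate(tev, start=1):
        ev.event_id = f"E{next(counter):05d}"
        ev.transcript_id = f"NOVT{i:05d}"
    new_models = events_to_transcripts(tev)
    gene_ids = cluster_new_transcripts(new_models)
    for t in new_models:
        t.gene_id = gene_ids[t.transcript_id]
        current.add(t)
    ledger.extend(tev)
    logger.info("new-transcript stage: %d events", len(tev))

    current.provenance = "revised"
    return RefinementResult(models=current, events=ledger)
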