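"""Reading-frame impact of junction revisions.

A boundary revision between coding exons changes the spliced exonic
length by a signed delta; a delta that is not a multiple of three shifts
the annotated reading frame.  Two such errors on one transcript whose
deltas cancel modulo three ("double mistakes") leave a spuriously intact
ORF, which is why frame-shifting mis-annotations can hide from
ORF-integrity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .core import Genome, TranscriptModel
from .refinement import RevisionEvent

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class OrfReport:
    """Frame effect of one junction revision on one transcript."""

    transcript_id: str
    event_id: str
    coding_coding: bool
    exonic_length_delta: int
    frameshift: bool
    companion_event_ids: List[str] = field(default_factory=list)


@dataclass
class OrfScan:
    """Longest ATG-to-stop ORF of a spliced transcript."""

    transcript_id: str
    start: int  # 0-based offset in the spliced sense sequence
    stop: int  # exclusive end (after the stop codon), 0 if none
    length_codons: int
    intact: bool


def event_delta(event: RevisionEvent) -> int:
    """Signed exonic-length change: old intron length minus new."""
    if event.old_start is None or event.old_end is None:
        raise ValueError("event has no old coordinates")
    return (event.old_end - event.old_start) - (event.new_end - event.new_start)


def classify_frame_effect(
    transcript: TranscriptModel, event: RevisionEvent
) -> OrfReport:
    """Decide whether a junction revision sits between coding exons and
    whether its exonic-length delta shifts the frame.

    ``coding_coding`` holds when both exons flanking the revised intron
    overlap a CDS interval; transcripts without CDS (or events flanked by
    a non-coding exon) report ``frameshift=False``.
    """
    if event.event_type != "junction":
        raise ValueError("frame classification applies to junction events")
    if event.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"event for {event.transcript_id} applied to "
            f"{transcript.transcript_id}"
        )
    idx = next(
        (
            i
            for i, ex in enumerate(transcript.exons)
            if ex.end == event.old_start
        ),
        None,
    )
    if idx is None:
        raise ValueError("event does not match an intron of this transcript")
    left, right = transcript.exons[idx], transcript.exons[idx + 1]
    coding_coding = bool(transcript.cds) and all(
        any(ex.overlap_len(c) > 0 for c in transcript.cds)
        for ex in (left, right)
    )
    delta = event_delta(event)
    frameshift = coding_coding and (delta % 3 != 0)
    return OrfReport(
        transcript_id=transcript.transcript_id,
        event_id=event.event_id,
        coding_coding=coding_coding,
        exonic_length_delta=delta,
        frameshift=frameshift,
    )


def find_companion_anomalies(
    transcript: TranscriptModel, events: Sequence[RevisionEvent]
) -> List[OrfReport]:
    """Frame reports with frame-restoring companions filled in.

    For each frame-shifting event, the companions are the other events on
    the same transcript whose delta cancels it modulo three (pairwise sum
    divisible by 3).  An empty companion list marks an unpaired
    frame-shift.  The pairing is symmetric.
    """
    reports = [classify_frame_effect(transcript, ev) for ev in events]
    for i, r in enumerate(reports):
        if not r.frameshift:
            continue
        for j, other in enumerate(reports):
            if i == j:
                continue
            if (r.exonic_length_delta + other.exonic_length_delta) % 3 == 0:
                r.companion_event_ids.append(other.event_id)
    return reports


def scan_orf(transcript: TranscriptModel, genome: Genome) -> OrfScan:
    """Longest ATG..stop ORF across the three frames of the spliced
    sense-strand sequence.  ``length_codons`` includes the stop codon;
    ``intact`` requires an ATG start and an in-frame stop."""
    seq = transcript.spliced_sequence(genome)
    best = (0, 0, 0)  # (codons, start, stop)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                codons = (pos + 3 - start) // 3
                if codons > best[0]:
                    best = (codons, start, pos + 3)
                start = None
    codons, start, stop = best
    return OrfScan(
        transcript_id=transcript.transcript_id,
        start=start,
        stop=stop,
        length_codons=codons,
        intact=codons >= 2,
    )


def orf_audit(
    models, events: Sequence[RevisionEvent]
) -> List[OrfReport]:
    """Frame reports for every junction event, companions resolved
    per transcript."""
    by_tid = {}
    for ev in events:
        if ev.event_type == "junction" and ev.transcript_id in models:
            by_tid.setdefault(ev.transcript_id, []).append(ev)
    reports: List[OrfReport] = []
    for tid in sorted(by_tid):
        reports.extend(find_companion_anomalies(models[tid], by_tid[tid]))
    return reports


def write_orf_report_tsv(reports: Sequence[OrfReport], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tevent_id\tcoding_coding\tdelta\tframeshift"
            "\tcompanion_ids\n"
        )
        for r in reports:
            companions = ",".join(r.companion_event_ids) or "."
            fh.write(
                f"{r.transcript_id}\t{r.event_id}\t{int(r.coding_coding)}"
                f"\t{r.exonic_length_delta}\t{int(r.frameshift)}\t{companions}\n"
            )
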