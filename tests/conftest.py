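"""Shared fixtures: hand-built micro-fixtures and one session-scoped
synthetic benchmark run reused by the integration tests."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from txrefine import (
    GeneModelSet,
    Genome,
    Interval,
    SpliceSiteKey,
    TranscriptModel,
    refine,
)
from txrefine.evidence import CoverageTrack, EvidenceBundle, JunctionTable
from txrefine.simulate import SimConfig, simulate_bundle


def make_transcript(
    tid: str,
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    cds: Sequence[Tuple[int, int]] = (),
    gene_id: Optional[str] = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or tid.split(".")[0],
        chrom=chrom,
        strand=strand,
        exons=[Interval(chrom, s, e, strand) for s, e in exons],
        cds=[Interval(chrom, s, e, strand) for s, e in cds],
    )


def make_genome(length: int = 5000, seed: int = 11, chrom: str = "chr1",
                plant: Dict[int, str] = None) -> Genome:
    """Random genome with optional sequence plants {position: text}."""
    rng = np.random.default_rng(seed)
    seq = bytearray(
        rng.choice(np.frombuffer(b"ACGT", dtype="S1"), length).tobytes()
    )
    for pos, text in (plant or {}).items():
        seq[pos : pos + len(text)] = text.encode()
    return Genome({chrom: seq.decode()})


def make_tracks(
    arrays: Sequence[np.ndarray],
    strand: str = "+",
    chrom: str = "chr1",
) -> List[CoverageTrack]:
    tracks = []
    for i, arr in enumerate(arrays):
        tr = CoverageTrack(f"S{i + 1}", strand, {chrom: len(arr)})
        tr.depth[chrom][:] = arr
        tracks.append(tr)
    return tracks


def make_junctions(
    records: Sequence[Tuple[int, int, str, int]],
    chrom: str = "chr1",
) -> JunctionTable:
    """records: (intron_start, intron_end, strand, total_reads) — reads
    split over two pseudo-samples."""
    table = JunctionTable()
    for s, e, strand, total in records:
        key = SpliceSiteKey(chrom, s, e, strand)
        if total <= 1:
            table.add(key, "S1", total)
        else:
            table.add(key, "S1", total - 1)
            table.add(key, "S2", 1)
    return table


@pytest.fixture(scope="session")
def sim():
    """Default synthetic benchmark: genome, truth, corrupted, evidence."""
    return simulate_bundle(SimConfig(seed=0))


@pytest.fixture(scope="session")
def refined(sim):
    """Refinement of the corrupted annotation against the evidence."""
    return refine(sim.corrupted, sim.evidence, sim.genome)
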