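"""Deterministic synthetic genomes, gene models, planted annotation
errors and matching expression evidence.

The generator emulates the evidence regime of a strand-specific,
poly(A)-selected RNA-Seq survey over multiple tissues: per-sample,
per-strand base coverage that is Poisson around a high mean on true
exonic bases and at a (default zero) background elsewhere, and
junction-spanning read counts for every true intron.  Gene structures are
planted with canonical splice dinucleotides (GT-AG with a GC-AG
minority), an intact ORF confined to internal exons, and an AATAAA
poly(A) signal 15-40 bases upstream of each 3' end.

``corrupt_annotation`` then injects the classic annotation error
taxonomy — shifted exon/intron boundaries (optionally in frame-restoring
pairs), truncated UTRs, deleted exons and deleted whole transcripts —
plus below-threshold decoys, and records every injection in a
:class:`PlantLedger` so a refinement run can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GeneModelSet,
    Genome,
    Interval,
    SpliceSiteKey,
    TranscriptModel,
    introns_of,
    revcomp,
)
from .evidence import CoverageTrack, EvidenceBundle, JunctionTable, is_canonical
from .refinement import RefinementConfig, RevisionEvent

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults model a desk-scale version of a multi-tissue survey: a 1 Mb
    genome in two chromosomes, 50 multi-exon genes, three samples, deep
    exonic coverage well above the UTR depth threshold, and negligible
    intronic/intergenic background (poly(A)-selected, uniquely mapped
    tags).  Plant counts give every refinement category at least five
    recoverable errors plus one decoy per acceptance rule.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 50
    exons_per_gene: Tuple[int, int] = (3, 7)
    exon_length: Tuple[int, int] = (150, 300)
    intron_length: Tuple[int, int] = (90, 400)
    intergenic_gap: Tuple[int, int] = (2000, 4000)
    n_samples: int = 3
    exonic_depth_mean: float = 30.0
    noise_depth: float = 0.0
    junction_read_range: Tuple[int, int] = (3, 12)
    gc_ag_fraction: float = 0.05
    polya_offset_range: Tuple[int, int] = (-40, -15)
    exon_conservation: float = 0.85
    intron_conservation: float = 0.10
    conservation_noise: float = 0.05
    n_junction_plants: int = 8
    frame_pair_fraction: float = 0.5
    n_utr5_plants: int = 5
    n_utr3_plants: int = 10
    n_new_exon_plants: int = 5
    n_new_transcript_plants: int = 5
    include_decoys: bool = True
    boundary_shift_range: Tuple[int, int] = (4, 24)
    utr_truncation_range: Tuple[int, int] = (110, 200)

    def __post_init__(self) -> None:
        cfg = RefinementConfig()
        if self.exonic_depth_mean <= cfg.utr_depth_threshold + 5:
            raise ValueError(
                "exonic depth mean must clear the UTR depth threshold "
                "with margin"
            )
        if self.junction_read_range[0] < cfg.min_junction_reads:
            raise ValueError("supported junctions must carry enough reads")
        for lo, hi in (
            self.exons_per_gene,
            self.exon_length,
            self.intron_length,
            self.intergenic_gap,
            self.junction_read_range,
            self.boundary_shift_range,
            self.utr_truncation_range,
        ):
            if lo > hi:
                raise ValueError("empty range in SimConfig")


@dataclass
class PlantEntry:
    """One injected annotation error and the event expected to fix it."""

    category: str  # junction | utr5 | utr3 | new_exon | new_transcript
    transcript_id: Optional[str]
    chrom: str
    strand: str
    satisfiable: bool
    rule: str = "plant"  # or the decoy rule name
    #: expected event coordinates on recovery (None where inapplicable)
    expected_old: Optional[Tuple[int, int]] = None
    expected_new: Optional[Tuple[int, int]] = None
    expected_exons: Optional[Tuple[Tuple[int, int], ...]] = None
    #: frame delta for junction plants (old intron len - new intron len)
    delta: Optional[int] = None
    pair_id: Optional[int] = None
    evidence_directives: Dict[str, list] = field(default_factory=dict)


@dataclass
class PlantLedger:
    entries: List[PlantEntry] = field(default_factory=list)

    def satisfiable(self) -> List[PlantEntry]:
        return [e for e in self.entries if e.satisfiable]

    def decoys(self) -> List[PlantEntry]:
        return [e for e in self.entries if not e.satisfiable]

    def to_tsv(self, path: str) -> None:
        cols = (
            "category\ttranscript_id\tchrom\tstrand\tsatisfiable\trule"
            "\texpected_old\texpected_new\texpected_exons\tdelta\tpair_id"
        )
        with open(path, "w") as fh:
            fh.write(cols + "\n")
            for e in self.entries:

                def fmt(v):
                    return "." if v is None else str(v)

                exons = (
                    ",".join(f"{s}-{t}" for s, t in e.expected_exons)
                    if e.expected_exons
                    else "."
                )
                fh.write(
                    f"{e.category}\t{fmt(e.transcript_id)}\t{e.chrom}"
                    f"\t{e.strand}\t{int(e.satisfiable)}\t{e.rule}"
                    f"\t{fmt(e.expected_old)}\t{fmt(e.expected_new)}"
                    f"\t{exons}\t{fmt(e.delta)}\t{fmt(e.pair_id)}\n"
                )


# ---------------------------------------------------------------------------
# genome + true models
# ---------------------------------------------------------------------------

def _paint(seq: bytearray, start: int, text: str) -> None:
    seq[start : start + len(text)] = text.encode()


def _spliced_to_genomic(t: TranscriptModel, offset: int) -> int:
    """Genomic coordinate of a transcription-sense spliced offset."""
    if t.strand == "+":
        for ex in t.exons:
            if offset < len(ex):
                return ex.start + offset
            offset -= len(ex)
    else:
        for ex in reversed(t.exons):
            if offset < len(ex):
                return ex.end - 1 - offset
            offset -= len(ex)
    raise IndexError("spliced offset outside transcript")


def _paint_sense(
    seq: bytearray, t: TranscriptModel, spliced_offset: int, text: str
) -> None:
    """Write ``text`` at a transcription-sense spliced position."""
    for i, ch in enumerate(text):
        g = _spliced_to_genomic(t, spliced_offset + i)
        seq[g : g + 1] = (ch if t.strand == "+" else revcomp(ch)).encode()


def simulate_genome_and_models(
    config: SimConfig,
) -> Tuple[Genome, GeneModelSet, CoverageTrack]:
    """Random genome, true gene models and a conservation score track.

    Deterministic in ``config.seed``.  Every intron is canonical (GC-AG
    with probability ``gc_ag_fraction``, else GT-AG); every transcript
    carries an intact ORF confined to its internal exons and an AATAAA
    hexamer upstream of its 3' end.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    raw: Dict[str, bytearray] = {
        name: bytearray(
            rng.choice(np.frombuffer(b"ACGT", dtype="S1"), config.chrom_length)
            .tobytes()
        )
        for name in chrom_names
    }

    transcripts: List[TranscriptModel] = []
    gene_no = itertools.count(1)
    for chrom in chrom_names:
        cursor = int(rng.integers(*config.intergenic_gap))
        genes_here = config.n_genes // config.n_chroms + (
            config.n_genes % config.n_chroms if chrom == chrom_names[-1] else 0
        )
        for _ in range(genes_here):
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(
                config.exon_length[0], config.exon_length[1] + 1, n_exons
            )
            intron_lens = rng.integers(
                config.intron_length[0], config.intron_length[1] + 1,
                n_exons - 1,
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + config.intergenic_gap[1] >= config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons: List[Interval] = []
            pos = cursor
            for i, el in enumerate(exon_lens):
                exons.append(Interval(chrom, pos, pos + int(el), strand))
                pos += int(el)
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            gid = f"G{next(gene_no):04d}"
            t = TranscriptModel(
                transcript_id=f"{gid}.T1",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
            _plant_gene_sequence(raw[chrom], t, config, rng)
            transcripts.append(t)
            cursor = pos + int(rng.integers(*config.intergenic_gap))

    genome = Genome({c: raw[c].decode() for c in chrom_names})
    models = GeneModelSet(transcripts, provenance="truth")
    conservation = _conservation_track(models, config, rng)
    return genome, models, conservation


def _plant_gene_sequence(
    seq: bytearray, t: TranscriptModel, config: SimConfig, rng
) -> None:
    # canonical splice dinucleotides, transcription sense
    for key in introns_of(t):
        donor = "GC" if rng.random() < config.gc_ag_fraction else "GT"
        acceptor = "AG"
        if t.strand == "+":
            _paint(seq, key.intron_start, donor)
            _paint(seq, key.intron_end - 2, acceptor)
        else:
            _paint(seq, key.intron_end - 2, revcomp(donor))
            _paint(seq, key.intron_start, revcomp(acceptor))
    # intact ORF confined to internal exons (terminal exons stay UTR so
    # UTR truncations never cut coding sequence)
    first_len = len(t.exons[0] if t.strand == "+" else t.exons[-1])
    last_len = len(t.exons[-1] if t.strand == "+" else t.exons[0])
    spliced_len = t.spliced_length()
    cds_start = first_len + 30
    cds_end = spliced_len - last_len - 30
    n_codons = (cds_end - cds_start) // 3
    if n_codons >= 4:
        _paint_sense(seq, t, cds_start, "ATG")
        for c in range(1, n_codons - 1):
            codon = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
            _paint_sense(seq, t, cds_start + 3 * c, codon)
        stop = STOP_CODONS[int(rng.integers(3))]
        _paint_sense(seq, t, cds_start + 3 * (n_codons - 1), stop)
        t.cds = _cds_intervals(t, cds_start, cds_start + 3 * n_codons)
    # poly(A) signal upstream of the 3' end (triangular, peaked near -25:
    # real signals cluster 15-30 nt upstream of the cleavage site)
    lo, hi = config.polya_offset_range
    offset = int(round(rng.triangular(lo, -25, hi)))
    offset = max(lo, min(hi, offset))
    _paint_sense(seq, t, spliced_len + offset, "AATAAA")


def _cds_intervals(
    t: TranscriptModel, spliced_start: int, spliced_end: int
) -> List[Interval]:
    """Genomic CDS intervals for a spliced coding span."""
    out: List[Interval] = []
    consumed = 0
    exon_iter = t.exons if t.strand == "+" else list(reversed(t.exons))
    for ex in exon_iter:
        lo = max(spliced_start, consumed)
        hi = min(spliced_end, consumed + len(ex))
        if lo < hi:
            if t.strand == "+":
                out.append(
                    Interval(t.chrom, ex.start + (lo - consumed),
                             ex.start + (hi - consumed), t.strand)
                )
            else:
                out.append(
                    Interval(t.chrom, ex.end - (hi - consumed),
                             ex.end - (lo - consumed), t.strand)
                )
        consumed += len(ex)
    return sorted(out, key=lambda c: c.start)


def _conservation_track(
    models: GeneModelSet, config: SimConfig, rng
) -> CoverageTrack:
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    track = CoverageTrack("conservation", ".", sizes, dtype=np.float64)
    for chrom, arr in track.depth.items():
        arr += config.intron_conservation
        arr += rng.uniform(-config.conservation_noise,
                           config.conservation_noise, len(arr))
    for t in models:
        for ex in t.exons:
            track.depth[t.chrom][ex.start : ex.end] = (
                config.exon_conservation
                + rng.uniform(-config.conservation_noise,
                              config.conservation_noise, len(ex))
            )
    for arr in track.depth.values():
        np.clip(arr, 0.0, 1.0, out=arr)
    return track


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

class CapacityError(RuntimeError):
    pass


def corrupt_annotation(
    true_models: GeneModelSet,
    config: SimConfig,
    genome: Optional[Genome] = None,
) -> Tuple[GeneModelSet, PlantLedger]:
    """Inject the error taxonomy into a copy of the true models.

    Each planted error uses a distinct transcript (frame-restoring pairs
    place two boundary shifts on one transcript).  Shifted boundaries are
    kept within the 80-120% exon-length band and land on non-canonical
    dinucleotides; decoys each violate exactly one acceptance rule and
    are flagged unsatisfiable.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    corrupted = true_models.copy(provenance="putative")
    ledger = PlantLedger()
    order = sorted(true_models.transcripts)
    pool = [order[i] for i in rng.permutation(len(order))]

    def take(min_exons: int = 1) -> TranscriptModel:
        for i, tid in enumerate(pool):
            if len(true_models[tid].exons) >= min_exons:
                pool.pop(i)
                return true_models[tid]
        raise CapacityError("not enough transcripts to host requested plants")

    pair_counter = itertools.count(1)
    n_pairs = int(round(config.n_junction_plants * config.frame_pair_fraction / 2))
    n_singles = config.n_junction_plants - 2 * n_pairs

    for _ in range(n_pairs):
        # two shifts on one transcript touching disjoint exons
        t = take(min_exons=6)
        hi = len(t.exons) - 2
        i1 = int(rng.integers(1, hi - 2))
        i2 = int(rng.integers(i1 + 2, hi))
        d1 = _frameshift_delta(rng)
        d2 = _paired_delta(rng, d1)
        pid = next(pair_counter)
        for idx, delta in zip((i1, i2), (d1, d2)):
            _plant_boundary_shift(
                corrupted, ledger, t, idx, delta, config, genome, rng,
                pair_id=pid,
            )
    for _ in range(n_singles):
        t = take(min_exons=4)
        idx = int(rng.integers(1, len(t.exons) - 2))
        _plant_boundary_shift(
            corrupted, ledger, t, idx, _frameshift_delta(rng), config,
            genome, rng,
        )

    for side, count in (("5", config.n_utr5_plants), ("3", config.n_utr3_plants)):
        for _ in range(count):
            t = take(min_exons=3)
            _plant_utr_truncation(corrupted, ledger, t, side, config, rng)

    for _ in range(config.n_new_exon_plants):
        t = take(min_exons=3)
        _plant_exon_deletion(corrupted, ledger, t, rng)

    for _ in range(config.n_new_transcript_plants):
        t = take(min_exons=2)
        _plant_transcript_deletion(corrupted, ledger, t)

    if config.include_decoys:
        _plant_decoys(corrupted, ledger, take, config, genome, rng)

    return corrupted, ledger


def _frameshift_delta(rng) -> int:
    mag = int(rng.integers(4, 25))
    while mag % 3 == 0:
        mag = int(rng.integers(4, 25))
    return mag if rng.random() < 0.5 else -mag


def _paired_delta(rng, d1: int) -> int:
    while True:
        d2 = _frameshift_delta(rng)
        if (d1 + d2) % 3 == 0:
            return d2


def _plant_boundary_shift(
    corrupted: GeneModelSet,
    ledger: PlantLedger,
    t: TranscriptModel,
    intron_idx: int,
    delta: int,
    config: SimConfig,
    genome: Optional[Genome],
    rng,
    pair_id: Optional[int] = None,
    satisfiable: bool = True,
    rule: str = "plant",
    force_ratio_violation: bool = False,
) -> Optional[PlantEntry]:
    """Shift one end of one intron; delta = corrupted minus true intron
    exonic change (old intron length - new intron length on recovery)."""
    ct = corrupted[t.transcript_id]
    true_intron = introns_of(t)[intron_idx]
    left, right = ct.exons[intron_idx], ct.exons[intron_idx + 1]
    candidates = []
    # delta = corrupted_len - true_len: shift end by +delta, or start by -delta
    for which in ("end", "start"):
        if which == "end":
            new_s, new_e = true_intron.intron_start, true_intron.intron_end + delta
            moved_exon_old, moved_exon_new = len(right), len(right) - delta
        else:
            new_s, new_e = true_intron.intron_start - delta, true_intron.intron_end
            moved_exon_old, moved_exon_new = len(left), len(left) - delta
        if new_e - new_s < 4 or moved_exon_new < 30:
            continue
        lo_r, hi_r = RefinementConfig().exon_len_ratio
        ratio_ok = (
            lo_r * moved_exon_new <= moved_exon_old <= hi_r * moved_exon_new
        )
        if force_ratio_violation == ratio_ok:
            continue
        candidates.append((which, new_s, new_e))
    if len(candidates) > 1 and rng.random() < 0.5:
        candidates.reverse()
    for which, new_s, new_e in candidates:
        key = SpliceSiteKey(t.chrom, new_s, new_e, t.strand)
        if genome is not None and is_canonical(genome, key):
            continue  # corrupted site must look non-canonical
        exons = list(ct.exons)
        if which == "end":
            exons[intron_idx + 1] = replace(exons[intron_idx + 1], start=new_e)
        else:
            exons[intron_idx] = replace(exons[intron_idx], end=new_s)
        ct.exons = exons
        ct.cds = _reclip(ct.cds, exons)
        ct.validate()
        entry = PlantEntry(
            category="junction",
            transcript_id=t.transcript_id,
            chrom=t.chrom,
            strand=t.strand,
            satisfiable=satisfiable,
            rule=rule,
            expected_old=(new_s, new_e),
            expected_new=(true_intron.intron_start, true_intron.intron_end),
            delta=delta,
            pair_id=pair_id,
        )
        ledger.entries.append(entry)
        return entry
    raise CapacityError(
        f"could not place boundary shift on {t.transcript_id} intron "
        f"{intron_idx} (delta={delta})"
    )


def _reclip(cds: List[Interval], exons: List[Interval]) -> List[Interval]:
    out = []
    for c in cds:
        for e in exons:
            s, t_ = max(c.start, e.start), min(c.end, e.end)
            if s < t_:
                out.append(replace(c, start=s, end=t_))
    return out


def _plant_utr_truncation(
    corrupted: GeneModelSet,
    ledger: PlantLedger,
    t: TranscriptModel,
    side: str,
    config: SimConfig,
    rng,
    truncation: Optional[int] = None,
    satisfiable: bool = True,
    rule: str = "plant",
) -> None:
    ct = corrupted[t.transcript_id]
    outward_right = (t.strand == "+") == (side == "3")
    exon = ct.exons[-1] if outward_right else ct.exons[0]
    max_t = len(exon) - 40
    if truncation is None:
        lo, hi = config.utr_truncation_range
        truncation = int(rng.integers(lo, min(hi, max_t) + 1))
    exons = list(ct.exons)
    if outward_right:
        exons[-1] = replace(exons[-1], end=exon.end - truncation)
        expected_old = (exons[-1].start, exons[-1].end)
        expected_new = (exon.start, exon.end)
    else:
        exons[0] = replace(exons[0], start=exon.start + truncation)
        expected_old = (exons[0].start, exons[0].end)
        expected_new = (exon.start, exon.end)
    ct.exons = exons
    ct.cds = _reclip(ct.cds, exons)
    ct.validate()
    ledger.entries.append(
        PlantEntry(
            category="utr5" if side == "5" else "utr3",
            transcript_id=t.transcript_id,
            chrom=t.chrom,
            strand=t.strand,
            satisfiable=satisfiable,
            rule=rule,
            expected_old=expected_old,
            expected_new=expected_new,
            delta=truncation,
        )
    )


def _plant_exon_deletion(
    corrupted: GeneModelSet,
    ledger: PlantLedger,
    t: TranscriptModel,
    rng,
    satisfiable: bool = True,
    rule: str = "plant",
) -> PlantEntry:
    ct = corrupted[t.transcript_id]
    idx = int(rng.integers(1, len(ct.exons) - 1))
    gone = ct.exons[idx]
    exons = [e for i, e in enumerate(ct.exons) if i != idx]
    ct.exons = exons
    ct.cds = _reclip(ct.cds, exons)
    ct.validate()
    entry = PlantEntry(
        category="new_exon",
        transcript_id=t.transcript_id,
        chrom=t.chrom,
        strand=t.strand,
        satisfiable=satisfiable,
        rule=rule,
        expected_new=(gone.start, gone.end),
        # the two true junctions that must link the recovered exon
        evidence_directives={},
        delta=None,
    )
    entry.evidence_directives["flanking_junctions"] = [
        (t.chrom, t.exons[idx - 1].end, gone.start, t.strand),
        (t.chrom, gone.end, t.exons[idx + 1].start, t.strand),
    ]
    ledger.entries.append(entry)
    return entry


def _plant_transcript_deletion(
    corrupted: GeneModelSet, ledger: PlantLedger, t: TranscriptModel
) -> None:
    del corrupted.transcripts[t.transcript_id]
    corrupted._trees = None
    ledger.entries.append(
        PlantEntry(
            category="new_transcript",
            transcript_id=None,
            chrom=t.chrom,
            strand=t.strand,
            satisfiable=True,
            expected_new=(t.start, t.end),
            expected_exons=tuple((e.start, e.end) for e in t.exons),
        )
    )


def _plant_decoys(
    corrupted: GeneModelSet,
    ledger: PlantLedger,
    take,
    config: SimConfig,
    genome: Optional[Genome],
    rng,
) -> None:
    # (1) new-splice support below two reads
    t = take(min_exons=4)
    e = _plant_boundary_shift(
        corrupted, ledger, t, int(rng.integers(1, len(t.exons) - 2)),
        _frameshift_delta(rng), config, genome, rng,
        satisfiable=False, rule="decoy_low_reads",
    )
    e.evidence_directives["set_junction_reads"] = [
        ((e.chrom, e.expected_new[0], e.expected_new[1], e.strand), 1)
    ]
    # (2) old splicing model still has supporting tags
    t = take(min_exons=4)
    e = _plant_boundary_shift(
        corrupted, ledger, t, int(rng.integers(1, len(t.exons) - 2)),
        _frameshift_delta(rng), config, genome, rng,
        satisfiable=False, rule="decoy_old_supported",
    )
    e.evidence_directives["add_junction"] = [
        ((e.chrom, e.expected_old[0], e.expected_old[1], e.strand), 2)
    ]
    # (3) only candidate junction is non-canonical
    t = take(min_exons=4)
    e = _plant_boundary_shift(
        corrupted, ledger, t, int(rng.integers(1, len(t.exons) - 2)),
        _frameshift_delta(rng), config, genome, rng,
        satisfiable=False, rule="decoy_noncanonical",
    )
    e.evidence_directives["set_junction_reads"] = [
        ((e.chrom, e.expected_new[0], e.expected_new[1], e.strand), 0)
    ]
    fake = _noncanonical_fake_junction(e, genome, rng)
    e.evidence_directives["add_junction"] = [(fake, 3)]
    # (4) revised exon outside the 80-120% length band
    t = take(min_exons=4)
    idx = int(rng.integers(1, len(t.exons) - 2))
    big = _ratio_breaking_delta(t, idx, rng)
    _plant_boundary_shift(
        corrupted, ledger, t, idx, big, config, genome, rng,
        satisfiable=False, rule="decoy_ratio",
        force_ratio_violation=True,
    )
    # (5) UTR extension shorter than the 100 bp minimum
    t = take(min_exons=3)
    _plant_utr_truncation(
        corrupted, ledger, t, "3", config, rng, truncation=80,
        satisfiable=False, rule="decoy_short_extension",
    )
    # (6) new exon linked on one side only
    t = take(min_exons=3)
    e = _plant_exon_deletion(
        corrupted, ledger, t, rng, satisfiable=False, rule="decoy_one_link"
    )
    right = e.evidence_directives["flanking_junctions"][1]
    e.evidence_directives["set_junction_reads"] = [(right, 0)]
    # (7) intergenic island with no connecting junction
    blob = _reserve_intergenic(corrupted, config, rng)
    ledger.entries.append(
        PlantEntry(
            category="new_transcript",
            transcript_id=None,
            chrom=blob.chrom,
            strand=blob.strand,
            satisfiable=False,
            rule="decoy_single_island",
            expected_new=(blob.start, blob.end),
            evidence_directives={
                "add_coverage": [
                    (blob.chrom, blob.start, blob.end, blob.strand)
                ]
            },
        )
    )


def _ratio_breaking_delta(t: TranscriptModel, idx: int, rng) -> int:
    # shrink the moved exon below 80% of its corrupted length:
    # |delta| > exon_len / 5 suffices (delta negative shifts keep
    # moved_exon_new = len - delta > len)
    left_len = len(t.exons[idx])
    right_len = len(t.exons[idx + 1])
    d = max(left_len, right_len) // 4 + 6
    while d % 3 == 0:
        d += 1
    return d


def _noncanonical_fake_junction(
    entry: PlantEntry, genome: Optional[Genome], rng
) -> Tuple[str, int, int, str]:
    s, e = entry.expected_new
    for shift in (2, 1, 3, 5, 6, 7):
        if (s + shift, e) == entry.expected_old:
            continue
        key = SpliceSiteKey(entry.chrom, s + shift, e, entry.strand)
        if genome is None or not is_canonical(genome, key):
            return (entry.chrom, s + shift, e, entry.strand)
    raise CapacityError("no non-canonical fake junction found")


def _reserve_intergenic(
    models: GeneModelSet, config: SimConfig, rng
) -> Interval:
    """A 300-base intergenic interval at least 1 kb from any transcript."""
    chrom = "chr1"
    spans = sorted(
        (t.start, t.end) for t in models if t.chrom == chrom
    )
    prev_end = 0
    for s, e in spans + [(config.chrom_length, config.chrom_length)]:
        if s - prev_end >= 2600:
            start = prev_end + 1000
            return Interval(chrom, start, start + 300,
                            "+" if rng.random() < 0.5 else "-")
        prev_end = max(prev_end, e)
    raise CapacityError("no intergenic room for decoy island")


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def simulate_evidence(
    true_models: GeneModelSet,
    config: SimConfig,
    conservation: Optional[CoverageTrack] = None,
    ledger: Optional[PlantLedger] = None,
) -> EvidenceBundle:
    """Coverage tracks and a junction table reflecting the TRUE models.

    Per-sample exonic depth is Poisson(``exonic_depth_mean``); intronic
    and intergenic background is Poisson(``noise_depth``) (zero depth when
    the rate is zero).  Every true junction receives a read total drawn
    from ``junction_read_range`` split across samples.  Ledger decoy
    directives (read overrides, extra junctions, extra coverage) are
    applied last.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 2_000_029)
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    coverage: Dict[str, List[CoverageTrack]] = {
        strand: [CoverageTrack(s, strand, sizes) for s in samples]
        for strand in ("+", "-")
    }
    if config.noise_depth > 0:
        for strand in ("+", "-"):
            for tr in coverage[strand]:
                for chrom in sizes:
                    tr.depth[chrom] += rng.poisson(
                        config.noise_depth, sizes[chrom]
                    )
    for t in true_models.sorted_transcripts():
        for tr in coverage[t.strand]:
            for ex in t.exons:
                tr.depth[t.chrom][ex.start : ex.end] += rng.poisson(
                    config.exonic_depth_mean, len(ex)
                )

    junctions = JunctionTable()
    lo, hi = config.junction_read_range
    for t in true_models.sorted_transcripts():
        for key in introns_of(t):
            if key in junctions:
                continue
            total = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(total, [1 / len(samples)] * len(samples))
            for s, c in zip(samples, counts):
                if c > 0:
                    junctions.add(key, s, int(c))

    if ledger is not None:
        _apply_directives(coverage, junctions, ledger, samples, config, rng)

    return EvidenceBundle(
        coverage=coverage, junctions=junctions, conservation=conservation
    )


def _apply_directives(
    coverage, junctions: JunctionTable, ledger: PlantLedger, samples,
    config: SimConfig, rng,
) -> None:
    for entry in ledger.entries:
        d = entry.evidence_directives
        for key_t, total in d.get("set_junction_reads", []):
            key = SpliceSiteKey(*key_t)
            junctions.remove(key)
            if total > 0:
                junctions.add(key, samples[0], total)
        for key_t, total in d.get("add_junction", []):
            key = SpliceSiteKey(*key_t)
            junctions.remove(key)
            junctions.add(key, samples[0], total)
        for chrom, start, end, strand in d.get("add_coverage", []):
            for tr in coverage[strand]:
                tr.depth[chrom][start:end] += rng.poisson(
                    config.exonic_depth_mean, end - start
                )


# ---------------------------------------------------------------------------
# one-call bundle + recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    genome: Genome
    truth: GeneModelSet
    corrupted: GeneModelSet
    ledger: PlantLedger
    evidence: EvidenceBundle


def simulate_bundle(config: Optional[SimConfig] = None) -> SimBundle:
    """Genome, truth, corrupted annotation, plant ledger and evidence."""
    config = config or SimConfig()
    genome, truth, conservation = simulate_genome_and_models(config)
    corrupted, ledger = corrupt_annotation(truth, config, genome=genome)
    evidence = simulate_evidence(
        truth, config, conservation=conservation, ledger=ledger
    )
    return SimBundle(config, genome, truth, corrupted, ledger, evidence)


@dataclass
class RecoveryScore:
    n_satisfiable: int
    n_recovered: int
    n_decoys: int
    n_decoys_reported: int
    n_off_ledger: int
    missing: List[PlantEntry] = field(default_factory=list)
    off_ledger_events: List[RevisionEvent] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        if self.n_satisfiable == 0:
            return 1.0
        return self.n_recovered / self.n_satisfiable


def _event_matches(entry: PlantEntry, ev: RevisionEvent) -> bool:
    if ev.event_type != entry.category or ev.chrom != entry.chrom:
        return False
    if ev.strand != entry.strand:
        return False
    if entry.category == "new_transcript":
        return ev.exons == entry.expected_exons
    if ev.transcript_id != entry.transcript_id:
        return False
    if entry.category == "junction":
        return (
            (ev.old_start, ev.old_end) == entry.expected_old
            and (ev.new_start, ev.new_end) == entry.expected_new
        )
    # utr5/utr3/new_exon: exact new coordinates
    return (ev.new_start, ev.new_end) == entry.expected_new


def score_recovery(
    events: Sequence[RevisionEvent], ledger: PlantLedger
) -> RecoveryScore:
    """Match refinement events against the plant ledger, exactly."""
    satisfiable = ledger.satisfiable()
    decoys = ledger.decoys()
    matched_events = set()
    n_recovered = 0
    missing: List[PlantEntry] = []
    for entry in satisfiable:
        hit = next(
            (
                i
                for i, ev in enumerate(events)
                if i not in matched_events and _event_matches(entry, ev)
            ),
            None,
        )
        if hit is None:
            missing.append(entry)
        else:
            matched_events.add(hit)
            n_recovered += 1
    n_decoys_reported = 0
    for entry in decoys:
        if any(
            i not in matched_events and _event_matches(entry, ev)
            for i, ev in enumerate(events)
        ):
            n_decoys_reported += 1
    off = [
        ev for i, ev in enumerate(events) if i not in matched_events
    ]
    return RecoveryScore(
        n_satisfiable=len(satisfiable),
        n_recovered=n_recovered,
        n_decoys=len(decoys),
        n_decoys_reported=n_decoys_reported,
        n_off_ledger=len(off),
        missing=missing,
        off_ledger_events=off,
    )
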