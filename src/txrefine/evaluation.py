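"""Validation statistics for gene-model revisions.

Quality of revisions is judged by signals that do not depend on the
annotation being checked: read coverage should be high over exons and low
over introns, cross-species conservation steps at true exon borders,
splice junctions carry donor/acceptor motifs, a poly(A) signal (AATAAA in
DNA sense) sits shortly upstream of true 3' ends, and promoter marks
cluster at true 5' ends.  Each statistic is computed per anchor and
aggregated into positional profiles, frequency matrices or distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import GeneModelSet, Genome, Interval, introns_of
from .evidence import CoverageTrack, EvidenceBundle, JunctionTable, pooled_depth
from .refinement import RevisionEvent

BASES = ("A", "C", "G", "T")


@dataclass
class PositionalProfile:
    """Per-offset statistic around an anchor (exon side negative)."""

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int

    def value_at(self, offset: int) -> float:
        idx = int(np.flatnonzero(self.offsets == offset)[0])
        return float(self.values[idx])

    def peak(self) -> Tuple[int, float]:
        """(offset, value) of the maximum."""
        if self.n_anchors == 0 or not len(self.values):
            return (0, 0.0)
        i = int(np.argmax(self.values))
        return (int(self.offsets[i]), float(self.values[i]))


@dataclass
class PositionFrequencyMatrix:
    """Base frequencies per offset around a splice site.

    ``freqs`` has shape (n_offsets, 4) in A,C,G,T order; columns sum to 1
    where any sequence contributed.  Information content per offset is
    ``2 - H`` bits (no small-sample correction).
    """

    offsets: np.ndarray
    freqs: np.ndarray
    n_sites: int
    n_skipped: int = 0

    def information_content(self) -> np.ndarray:
        ic = np.zeros(len(self.offsets))
        for i, row in enumerate(self.freqs):
            if row.sum() <= 0:
                continue
            h = -sum(p * math.log2(p) for p in row if p > 0)
            ic[i] = 2.0 - h
        return ic

    def ic_at(self, offset: int) -> float:
        idx = int(np.flatnonzero(self.offsets == offset)[0])
        return float(self.information_content()[idx])


def percentage(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, as printed in summary tables."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# coverage around revised junctions
# ---------------------------------------------------------------------------

@dataclass
class CoverageCategories:
    """Window-max-normalised depths in the four junction categories.

    ``exon``: exonic under both old and new models; ``intron``: intronic
    under both; ``revised_exon``: exonic only under the revised model;
    ``revised_intron``: intronic only under the revised model (i.e. bases
    the old model called exonic).
    """

    exon: np.ndarray
    intron: np.ndarray
    revised_exon: np.ndarray
    revised_intron: np.ndarray
    statistic: Optional[float] = None
    p_value: Optional[float] = None


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null below 20 per group when
    tie-free, else the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return (float("nan"), float("nan"))
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) < 20 and len(y) < 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue))


def boundary_coverage_categories(
    old_models: GeneModelSet,
    new_models: GeneModelSet,
    events: Sequence[RevisionEvent],
    coverage: Dict[str, Sequence[CoverageTrack]],
    flank: int = 50,
) -> CoverageCategories:
    """Per-base normalised depth around each revised junction, split by
    old/new exonic status, plus a rank-sum comparison of the two disputed
    categories (revised-exon vs revised-intron)."""
    cats: Dict[str, List[float]] = {
        "exon": [],
        "intron": [],
        "revised_exon": [],
        "revised_intron": [],
    }
    for ev in events:
        if ev.event_type != "junction":
            continue
        t_old = old_models[ev.transcript_id]
        t_new = new_models[ev.transcript_id]
        lo = min(ev.old_start, ev.new_start) - flank
        hi = max(ev.old_end, ev.new_end) + flank
        lo = max(lo, 0)
        tracks = coverage.get(ev.strand, [])
        if not tracks:
            continue
        hi = min(hi, len(tracks[0].depth[ev.chrom]))
        depth = pooled_depth(tracks, ev.chrom, lo, hi)
        dmax = depth.max()
        norm = depth / dmax if dmax > 0 else depth
        old_exonic = _exonic_mask(t_old, lo, hi)
        new_exonic = _exonic_mask(t_new, lo, hi)
        for i in range(hi - lo):
            o, n = old_exonic[i], new_exonic[i]
            if o and n:
                cats["exon"].append(norm[i])
            elif not o and not n:
                cats["intron"].append(norm[i])
            elif n:
                cats["revised_exon"].append(norm[i])
            else:
                cats["revised_intron"].append(norm[i])
    out = CoverageCategories(
        exon=np.array(cats["exon"]),
        intron=np.array(cats["intron"]),
        revised_exon=np.array(cats["revised_exon"]),
        revised_intron=np.array(cats["revised_intron"]),
    )
    if len(out.revised_exon) and len(out.revised_intron):
        out.statistic, out.p_value = rank_sum_test(
            out.revised_exon, out.revised_intron
        )
    return out


def _exonic_mask(t, lo: int, hi: int) -> np.ndarray:
    mask = np.zeros(hi - lo, dtype=bool)
    for ex in t.exons:
        s, e = max(ex.start, lo), min(ex.end, hi)
        if s < e:
            mask[s - lo : e - lo] = True
    return mask


# ---------------------------------------------------------------------------
# conservation around junctions
# ---------------------------------------------------------------------------

def conservation_junction_profile(
    models: GeneModelSet,
    score_track: CoverageTrack,
    half_window: int = 50,
) -> Tuple[PositionalProfile, PositionalProfile]:
    """Mean conservation per offset around donor and acceptor sites.

    Offsets run over ``[-half_window, +half_window)`` in transcription
    sense with the exon side negative and the first intronic base at 0.
    Junctions too close to a chromosome edge are skipped.
    """
    offsets = np.arange(-half_window, half_window)
    sums = {"donor": np.zeros(2 * half_window), "acceptor": np.zeros(2 * half_window)}
    counts = {"donor": 0, "acceptor": 0}
    for t in models:
        chrom_arr = score_track.depth.get(t.chrom)
        if chrom_arr is None:
            continue
        for key in introns_of(t):
            for site in ("donor", "acceptor"):
                vals = _site_window(chrom_arr, key, site, half_window)
                if vals is None:
                    continue
                sums[site] += vals
                counts[site] += 1
    profiles = []
    for site in ("donor", "acceptor"):
        n = counts[site]
        profiles.append(
            PositionalProfile(
                offsets=offsets.copy(),
                values=sums[site] / n if n else np.zeros_like(sums[site]),
                n_anchors=n,
            )
        )
    return profiles[0], profiles[1]


def _site_window(
    chrom_arr: np.ndarray, key, site: str, half_window: int
) -> Optional[np.ndarray]:
    """Score values for offsets [-hw, hw) at one splice site, sense
    orientation; None if out of bounds."""
    if key.strand == "+":
        anchor = key.intron_start if site == "donor" else key.intron_end
        # offset o -> genomic anchor + o (donor); for the acceptor, offset 0
        # is the first exonic base after the intron, exon side positive:
        # we keep intron side negative for the acceptor instead.
        if site == "donor":
            lo, hi = anchor - half_window, anchor + half_window
            if lo < 0 or hi > len(chrom_arr):
                return None
            return chrom_arr[lo:hi].astype(float)
        lo, hi = anchor - half_window, anchor + half_window
        if lo < 0 or hi > len(chrom_arr):
            return None
        return chrom_arr[lo:hi][::-1].astype(float)
    # minus strand: mirror
    anchor = key.intron_end if site == "donor" else key.intron_start
    lo, hi = anchor - half_window, anchor + half_window
    if lo < 0 or hi > len(chrom_arr):
        return None
    vals = chrom_arr[lo:hi].astype(float)
    return vals[::-1] if site == "donor" else vals


# ---------------------------------------------------------------------------
# splice-site PFMs
# ---------------------------------------------------------------------------

def pfm_from_junctions(
    keys: Iterable,
    genome: Genome,
    donor_window: Tuple[int, int] = (-3, 6),
    acceptor_window: Tuple[int, int] = (-13, 3),
) -> Tuple[PositionFrequencyMatrix, PositionFrequencyMatrix]:
    """Donor and acceptor base-frequency matrices for a set of introns.

    Offsets are transcription-sense positions relative to the splice site:
    for the donor, 0 is the first intronic base (exon side negative); for
    the acceptor, -1 is the last intronic base and 0 the first exonic base
    of the next exon.  Introns shorter than the windows are skipped and
    counted."""
    d_lo, d_hi = donor_window
    a_lo, a_hi = acceptor_window
    d_counts = np.zeros((d_hi - d_lo, 4))
    a_counts = np.zeros((a_hi - a_lo, 4))
    n_sites = 0
    n_skipped = 0
    base_idx = {b: i for i, b in enumerate(BASES)}
    for key in keys:
        if len(key) < max(d_hi, -a_lo):
            n_skipped += 1
            continue
        try:
            d_seq, a_seq = _junction_sequences(
                genome, key, donor_window, acceptor_window
            )
        except IndexError:
            n_skipped += 1
            continue
        n_sites += 1
        for i, b in enumerate(d_seq):
            if b in base_idx:
                d_counts[i, base_idx[b]] += 1
        for i, b in enumerate(a_seq):
            if b in base_idx:
                a_counts[i, base_idx[b]] += 1

    def finish(counts, lo, hi):
        totals = counts.sum(axis=1, keepdims=True)
        freqs = np.divide(
            counts, totals, out=np.zeros_like(counts), where=totals > 0
        )
        return PositionFrequencyMatrix(
            offsets=np.arange(lo, hi),
            freqs=freqs,
            n_sites=n_sites,
            n_skipped=n_skipped,
        )

    return finish(d_counts, d_lo, d_hi), finish(a_counts, a_lo, a_hi)


def _junction_sequences(
    genome: Genome,
    key,
    donor_window: Tuple[int, int],
    acceptor_window: Tuple[int, int],
) -> Tuple[str, str]:
    """Transcription-sense donor/acceptor window sequences for one intron."""
    d_lo, d_hi = donor_window
    a_lo, a_hi = acceptor_window
    chrom = genome[key.chrom]
    if key.strand == "+":
        d_seq = chrom.fetch(key.intron_start + d_lo, key.intron_start + d_hi)
        a_seq = chrom.fetch(key.intron_end + a_lo, key.intron_end + a_hi)
    else:
        d_seq = chrom.fetch(key.intron_end - d_hi, key.intron_end - d_lo, "-")
        a_seq = chrom.fetch(key.intron_start - a_hi, key.intron_start - a_lo, "-")
    return d_seq, a_seq


def splice_pfm(
    models: GeneModelSet,
    genome: Genome,
    donor_window: Tuple[int, int] = (-3, 6),
    acceptor_window: Tuple[int, int] = (-13, 3),
) -> Tuple[PositionFrequencyMatrix, PositionFrequencyMatrix]:
    """PFMs over every intron of every transcript in a model set."""
    keys = [k for t in models for k in introns_of(t)]
    return pfm_from_junctions(keys, genome, donor_window, acceptor_window)


# ---------------------------------------------------------------------------
# poly(A)-signal hexamer profile
# ---------------------------------------------------------------------------

def hexamer_end_profile(
    models: GeneModelSet,
    genome: Genome,
    motif: str = "AATAAA",
    window: Tuple[int, int] = (-60, 10),
    anchor: str = "3",
) -> PositionalProfile:
    """Fraction of transcripts whose sense-strand hexamer at each offset
    from the transcript end equals ``motif``.

    Offset -1 is the last transcribed base for the 3' anchor; for the 5'
    anchor (the negative control) offset 0 is the first transcribed base.
    Transcripts whose window leaves the chromosome are skipped.
    """
    lo, hi = window
    k = len(motif)
    offsets = np.arange(lo, hi)
    hits = np.zeros(len(offsets))
    n = 0
    for t in models.sorted_transcripts():
        chrom = genome[t.chrom]
        seq = _end_window_sequence(chrom, t, lo, hi + k, anchor)
        if seq is None:
            continue
        n += 1
        for i in range(len(offsets)):
            if seq[i : i + k] == motif:
                hits[i] += 1
    return PositionalProfile(
        offsets=offsets,
        values=hits / n if n else hits,
        n_anchors=n,
    )


def _end_window_sequence(chrom, t, lo: int, hi: int, anchor: str) -> Optional[str]:
    """Sense-strand sequence covering offsets [lo, hi) from an end anchor."""
    if anchor == "3":
        if t.strand == "+":
            g_lo, g_hi = t.end + lo, t.end + hi
            if g_lo < 0 or g_hi > chrom.length:
                return None
            return chrom.fetch(g_lo, g_hi)
        g_lo, g_hi = t.start - hi, t.start - lo
        if g_lo < 0 or g_hi > chrom.length:
            return None
        return chrom.fetch(g_lo, g_hi, "-")
    # 5' anchor
    if t.strand == "+":
        g_lo, g_hi = t.start + lo, t.start + hi
        if g_lo < 0 or g_hi > chrom.length:
            return None
        return chrom.fetch(g_lo, g_hi)
    g_lo, g_hi = t.end - hi, t.end - lo
    if g_lo < 0 or g_hi > chrom.length:
        return None
    return chrom.fetch(g_lo, g_hi, "-")


def hexamer_profiles_with_control(
    models: GeneModelSet,
    genome: Genome,
    motif: str = "AATAAA",
    window: Tuple[int, int] = (-60, 10),
) -> Tuple[PositionalProfile, PositionalProfile]:
    """(3'-end profile, 5'-start negative control)."""
    return (
        hexamer_end_profile(models, genome, motif, window, anchor="3"),
        hexamer_end_profile(models, genome, motif, window, anchor="5"),
    )


# ---------------------------------------------------------------------------
# peak-to-end distance histogram
# ---------------------------------------------------------------------------

def end_distance_profile(
    peaks: Sequence[Interval],
    models: GeneModelSet,
    side: str = "5",
    window: int = 5000,
    bin_size: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of signed distances from peak midpoints to the nearest
    transcript 5' end within ``±window``.

    Distance is transcription-sense signed (downstream of the end is
    positive).  Returns (bin_edges, counts) with ``bin_size`` bins.
    """
    if side != "5":
        raise ValueError("only 5'-end profiles are defined")
    ends: Dict[str, List[Tuple[int, str]]] = {}
    for t in models:
        ends.setdefault(t.chrom, []).append((t.five_prime_end(), t.strand))
    dists: List[float] = []
    for pk in peaks:
        mid = (pk.start + pk.end) // 2
        best = None
        for pos, strand in ends.get(pk.chrom, []):
            signed = (mid - pos) if strand == "+" else (pos - mid)
            if abs(signed) <= window and (
                best is None or abs(signed) < abs(best)
            ):
                best = signed
        if best is not None:
            dists.append(best)
    edges = np.arange(-window, window + bin_size, bin_size)
    counts, _ = np.histogram(dists, bins=edges)
    return edges, counts


# ---------------------------------------------------------------------------
# summary accounting
# ---------------------------------------------------------------------------

@dataclass
class SummaryTable:
    """Evidence-coverage and refinement-accounting summary.

    ``coverage`` rows: (total, covered, percentage) for exons, junctions
    and transcripts.  ``refinement`` rows: (events, transcripts,
    percentage-of-all-transcripts) per category plus a deduplicated total.
    """

    coverage: Dict[str, Tuple[int, int, float]]
    refinement: Dict[str, Tuple[int, int, float]]
    total_transcripts: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "total_transcripts": self.total_transcripts,
            "coverage": {
                k: {"total": t, "covered": c, "percentage": p}
                for k, (t, c, p) in self.coverage.items()
            },
            "refinement": {
                k: {"events": e, "transcripts": n, "percentage": p}
                for k, (e, n, p) in self.refinement.items()
            },
        }


_CATEGORY_ORDER = ("junction", "utr5", "utr3", "new_exon")


def summary_report(
    models: GeneModelSet,
    evidence: Optional[EvidenceBundle],
    ledger: Sequence[RevisionEvent],
) -> SummaryTable:
    """Coverage statistics (a feature counts as covered with >=1 read) and
    per-category refinement accounting with one-decimal percentages;
    transcripts with several revisions are counted once in the total."""
    n_tx = len(models)
    coverage: Dict[str, Tuple[int, int, float]] = {}
    if evidence is not None:
        ex_total = ex_cov = 0
        jn_total = jn_cov = 0
        tx_cov = 0
        for t in models:
            tracks = evidence.tracks(t.strand)
            t_covered = False
            for ex in t.exons:
                ex_total += 1
                d = pooled_depth(tracks, t.chrom, ex.start, ex.end) if tracks else None
                if d is not None and (d >= 1).any():
                    ex_cov += 1
                    t_covered = True
            for key in introns_of(t):
                jn_total += 1
                if evidence.junctions.support(key)[0] >= 1:
                    jn_cov += 1
            if t_covered:
                tx_cov += 1
        coverage = {
            "exons": (ex_total, ex_cov, percentage(ex_cov, ex_total)),
            "junctions": (jn_total, jn_cov, percentage(jn_cov, jn_total)),
            "transcripts": (n_tx, tx_cov, percentage(tx_cov, n_tx)),
        }
    refinement: Dict[str, Tuple[int, int, float]] = {}
    all_tids = set()
    total_events = 0
    for cat in _CATEGORY_ORDER:
        evs = [e for e in ledger if e.event_type == cat]
        tids = {e.transcript_id for e in evs if e.transcript_id}
        refinement[cat] = (len(evs), len(tids), percentage(len(tids), n_tx))
        all_tids |= tids
        total_events += len(evs)
    refinement["total"] = (
        total_events,
        len(all_tids),
        percentage(len(all_tids), n_tx),
    )
    n_new = sum(1 for e in ledger if e.event_type == "new_transcript")
    refinement["new_transcript"] = (n_new, n_new, percentage(0, 0))
    return SummaryTable(
        coverage=coverage, refinement=refinement, total_transcripts=n_tx
    )
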