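"""Expression evidence: strand-specific base coverage and junction reads.

Coverage arrives as one bedGraph per sample x strand; junction-spanning
read counts as a TSV (chrom, intron_start, intron_end, strand, sample,
read_count).  The genomic splice dinucleotides of any intron are read
directly from the genome, reported in transcription sense.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import CANONICAL_PAIRS, Genome, SpliceSiteKey


class BedGraphError(ValueError):
    pass


class CoverageTrack:
    """Per-sample, per-strand read depth for every base of every chrom.

    Bases not covered by any bedGraph interval have depth 0.  Values are
    held as float arrays so the same container serves integer read depth
    and fractional score tracks (conservation).
    """

    def __init__(
        self,
        sample_id: str,
        strand: str,
        chrom_sizes: Dict[str, int],
        dtype=np.float64,
    ):
        self.sample_id = sample_id
        self.strand = strand
        self.depth: Dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=dtype) for c, n in chrom_sizes.items()
        }

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depth[chrom]

    def at(self, chrom: str, pos: int) -> float:
        return float(self.depth[chrom][pos])

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.depth[chrom][start:end]

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        self.depth[chrom][start:end] += value

    def to_bedgraph(self, path: str) -> None:
        """Write non-zero runs as bedGraph lines (deterministic)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.depth):
                arr = self.depth[chrom]
                if not len(arr):
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v == 0:
                        continue
                    if float(v).is_integer():
                        fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")
                    else:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def load_bedgraph(
    path: str,
    sample_id: str,
    strand: str,
    chrom_sizes: Dict[str, int],
    dtype=np.float64,
) -> CoverageTrack:
    """Dense coverage from a bedGraph file; overlapping intervals rejected."""
    track = CoverageTrack(sample_id, strand, chrom_sizes, dtype=dtype)
    last_end: Dict[str, int] = defaultdict(int)
    seen_unsorted: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedGraphError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, s, e, v = fields
            start, end = int(s), int(e)
            if chrom not in track.depth:
                raise BedGraphError(f"{path}:{lineno}: unknown chrom {chrom}")
            if end > len(track.depth[chrom]) or start < 0 or start >= end:
                raise BedGraphError(
                    f"{path}:{lineno}: interval {start}-{end} out of bounds"
                )
            seen_unsorted[chrom].append((start, end))
            track.depth[chrom][start:end] = float(v)
    # overlap check (intervals may arrive unsorted)
    for chrom, ivs in seen_unsorted.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise BedGraphError(
                    f"{path}: overlapping intervals on {chrom}: "
                    f"{s1}-{e1} and {s2}-{e2}"
                )
    return track


def pooled_depth(
    tracks: Sequence[CoverageTrack], chrom: str, start: int, end: int
) -> np.ndarray:
    """Summed depth over tracks for ``[start, end)``."""
    out = np.zeros(end - start, dtype=np.float64)
    for t in tracks:
        out += t.window(chrom, start, end)
    return out


# ---------------------------------------------------------------------------
# Junction evidence
# ---------------------------------------------------------------------------

JUNCTION_COLUMNS = (
    "chrom",
    "intron_start",
    "intron_end",
    "strand",
    "sample",
    "read_count",
)


class JunctionTable:
    """Per-sample read counts for observed introns, indexed two ways."""

    def __init__(self) -> None:
        self._by_key: Dict[SpliceSiteKey, Dict[str, int]] = {}
        self._by_chrom_strand: Dict[Tuple[str, str], List[SpliceSiteKey]] = {}
        self._sorted = True

    def add(self, key: SpliceSiteKey, sample: str, read_count: int) -> None:
        if read_count < 1:
            raise ValueError("read_count must be >= 1")
        per = self._by_key.get(key)
        if per is None:
            per = self._by_key[key] = {}
            self._by_chrom_strand.setdefault(
                (key.chrom, key.strand), []
            ).append(key)
            self._sorted = False
        if sample in per:
            raise ValueError(f"duplicate (junction, sample) record: {key}, {sample}")
        per[sample] = read_count

    def remove(self, key: SpliceSiteKey) -> None:
        if key in self._by_key:
            del self._by_key[key]
            lst = self._by_chrom_strand[(key.chrom, key.strand)]
            lst.remove(key)

    def keys(self) -> List[SpliceSiteKey]:
        return list(self._by_key)

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: SpliceSiteKey) -> bool:
        return key in self._by_key

    def samples_for(self, key: SpliceSiteKey) -> Dict[str, int]:
        return dict(self._by_key.get(key, {}))

    def support(self, key: SpliceSiteKey) -> Tuple[int, int]:
        """(total reads summed over samples, number of samples with reads)."""
        per = self._by_key.get(key)
        if not per:
            return (0, 0)
        return (sum(per.values()), len(per))

    def in_region(
        self, chrom: str, start: int, end: int, strand: str
    ) -> List[SpliceSiteKey]:
        """Junctions intersecting ``[start, end)`` on one strand."""
        self._ensure_sorted()
        keys = self._by_chrom_strand.get((chrom, strand), [])
        return [
            k for k in keys if k.intron_start < end and start < k.intron_end
        ]

    def contained_in(
        self, chrom: str, start: int, end: int, strand: str
    ) -> List[SpliceSiteKey]:
        """Junctions fully inside ``[start, end)`` on one strand."""
        self._ensure_sorted()
        keys = self._by_chrom_strand.get((chrom, strand), [])
        return [
            k for k in keys if k.intron_start >= start and k.intron_end <= end
        ]

    def _ensure_sorted(self) -> None:
        if not self._sorted:
            for lst in self._by_chrom_strand.values():
                lst.sort()
            self._sorted = True

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(JUNCTION_COLUMNS) + "\n")
            for key in sorted(self._by_key):
                for sample in sorted(self._by_key[key]):
                    fh.write(
                        f"{key.chrom}\t{key.intron_start}\t{key.intron_end}"
                        f"\t{key.strand}\t{sample}\t{self._by_key[key][sample]}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "JunctionTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != JUNCTION_COLUMNS:
                raise ValueError(
                    f"{path}: bad header {header!r}; "
                    f"expected {list(JUNCTION_COLUMNS)}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                chrom, s, e, strand, sample, n = line.split("\t")
                table.add(
                    SpliceSiteKey(chrom, int(s), int(e), strand),
                    sample,
                    int(n),
                )
        return table


def junction_support(
    table: JunctionTable, key: SpliceSiteKey
) -> Tuple[int, int]:
    """Total reads and distinct supporting samples for one intron."""
    return table.support(key)


# ---------------------------------------------------------------------------
# Splice dinucleotides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DinucleotidePair:
    """Intron-terminal 2-mers in transcription sense."""

    donor2: str
    acceptor2: str

    @property
    def canonical(self) -> bool:
        return (self.donor2, self.acceptor2) in CANONICAL_PAIRS


def splice_dinucleotides(genome: Genome, key: SpliceSiteKey) -> DinucleotidePair:
    """Donor/acceptor dinucleotides of one intron, transcription sense.

    On '+' the donor is the first two intronic bases and the acceptor the
    last two; on '-' the roles swap ends and both are reverse-complemented.
    """
    chrom = genome[key.chrom]
    left = chrom.fetch(key.intron_start, key.intron_start + 2)
    right = chrom.fetch(key.intron_end - 2, key.intron_end)
    if key.strand == "+":
        return DinucleotidePair(left, right)
    return DinucleotidePair(
        chrom.fetch(key.intron_end - 2, key.intron_end, "-"),
        chrom.fetch(key.intron_start, key.intron_start + 2, "-"),
    )


def is_canonical(
    genome: Genome,
    key: SpliceSiteKey,
    allowed_pairs: Iterable[Tuple[str, str]] = CANONICAL_PAIRS,
) -> bool:
    pair = splice_dinucleotides(genome, key)
    return (pair.donor2, pair.acceptor2) in set(allowed_pairs)


@dataclass
class EvidenceBundle:
    """Everything the refiner consumes, keyed by strand."""

    coverage: Dict[str, List[CoverageTrack]]  # strand -> tracks (one/sample)
    junctions: JunctionTable
    conservation: Optional[CoverageTrack] = None

    def tracks(self, strand: str) -> List[CoverageTrack]:
        return self.coverage.get(strand, [])

    def n_samples(self) -> int:
        return max((len(v) for v in self.coverage.values()), default=0)
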