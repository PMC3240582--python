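"""Core genomic data models shared across the pipeline.

Coordinates are 0-based half-open throughout the in-memory API; the GFF3
writer converts to 1-based closed and the BED writer keeps 0-based half-open.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

#: Lengths (bp) of the six euchromatic chromosome arms of the D. melanogaster
#: BDGP release 5 assembly. Used for genome-scale window arithmetic.
BDGP5_EUCHROMATIC_ARMS: Dict[str, int] = {
    "X": 22_422_827,
    "2L": 23_011_544,
    "2R": 21_146_708,
    "3L": 24_543_557,
    "3R": 27_905_053,
    "4": 1_351_857,
}

DEFAULT_BIN_SIZE = 50


def n_bins(length: int, bin_size: int = DEFAULT_BIN_SIZE) -> int:
    """Number of fixed-width windows tiling a chromosome; the final partial
    window counts."""
    if length < 0:
        raise ValueError("chromosome length must be non-negative")
    return math.ceil(length / bin_size)


def count_windows(layout: Dict[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> int:
    """Total fixed-width window count over a genome layout (per-chromosome
    tiling, final partial window counted per chromosome)."""
    return sum(n_bins(length, bin_size) for length in layout.values())


@dataclass(frozen=True)
class Transcript:
    """One annotated transcript: genomic span, exons, and optional CDS."""

    tx_id: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...]
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.tx_id}: start must be < end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.tx_id}: exon ({s},{e}) outside span")


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts on a fixed strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Tuple[Transcript, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: at least one transcript required")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1

    def tss_positions(self) -> Tuple[int, ...]:
        """Distinct transcription start sites (genomic position of the first
        transcribed base), in stable transcript order."""
        seen = []
        for t in self.transcripts:
            p = t.start if self.strand == "+" else t.end - 1
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    def txend_positions(self) -> Tuple[int, ...]:
        seen = []
        for t in self.transcripts:
            p = t.end - 1 if self.strand == "+" else t.start
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    def midpoints(self) -> Tuple[int, ...]:
        seen = []
        for t in self.transcripts:
            p = (t.start + t.end) // 2
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    @property
    def tss(self) -> int:
        """TSS of the first transcript (primary annotation)."""
        return self.tss_positions()[0]


@dataclass(frozen=True)
class TransposonCopy:
    """A genomic copy of a transposon family."""

    family: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappedTag:
    """One sequenced tag and its best-tier genomic matching site(s).

    ``sites`` holds (chrom, five_prime_pos, strand) triples; for a
    minus-strand site the 5' position is the rightmost genomic base of the
    match. All sites share the minimal mismatch count.
    """

    read_id: str
    sites: Tuple[Tuple[str, int, str], ...]
    mismatches: int

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def unique(self) -> bool:
        return self.k == 1


@dataclass
class MappingStats:
    total_reads: int = 0
    dropped_ambiguous: int = 0
    rounds: list = field(default_factory=list)  # (allowance, cumulative mapped fraction)
    final_allowance: int = 0
    unique_count: int = 0
    multiple_count: int = 0

    @property
    def mapped_count(self) -> int:
        return self.unique_count + self.multiple_count

    @property
    def mapped_fraction(self) -> float:
        kept = self.total_reads - self.dropped_ambiguous
        return self.mapped_count / kept if kept else 0.0

    @property
    def multiple_fraction(self) -> float:
        return self.multiple_count / self.mapped_count if self.mapped_count else 0.0

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "dropped_ambiguous": self.dropped_ambiguous,
            "rounds": [{"allowance": a, "mapped_fraction": f} for a, f in self.rounds],
            "final_allowance": self.final_allowance,
            "unique_count": self.unique_count,
            "multiple_count": self.multiple_count,
            "mapped_fraction": self.mapped_fraction,
            "multiple_fraction": self.multiple_fraction,
        }
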