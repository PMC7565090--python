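"""Core genomic data structures shared across the pipeline.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the 1-based inclusive convention on the way through :mod:`lncreg.gtf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence."""

    seqname: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seqname}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any shared base, ignoring strand."""
        return (
            self.seqname == other.seqname
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqname == other.seqname
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """Strand-aware exon chain on one sequence.

    Exons are stored sorted by start and must not overlap each other;
    introns are the gaps between consecutive exons.
    """

    id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        seqnames = {e.seqname for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqnames) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id} mixes seqnames or strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id} has overlapping exons")

    @property
    def seqname(self) -> str:
        return self.exons[0].seqname

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seqname, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced transcript length in nucleotides."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.seqname, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment hit with Karlin-Altschul significance."""

    query_id: str
    target_id: str
    score: float
    evalue: float
    identity: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    frame: Optional[int] = None  # blastx-style frame (+1..+3 / -1..-3) or None


def index_by_seqname(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    """Group transcripts by seqname, sorted by (start, id) for determinism."""
    index: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        index.setdefault(t.seqname, []).append(t)
    for seq in index:
        index[seq].sort(key=lambda t: (t.start, t.id))
    return index
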