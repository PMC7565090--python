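"""Open reading frame scanning and six-frame translation.

An ORF here is a complete ATG-to-stop span: its length counts the start
codon and excludes the stop, matching the getorf-style "between a START
and a STOP codon" definition used by the length filter. Both strands are
scanned. ``N`` never matches a start or stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

START = "ATG"
STOPS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """A single open reading frame on a transcript sequence.

    ``start``/``end`` are 0-based half-open on the given strand's sequence;
    ``length`` excludes the stop codon. ``complete`` is False for an
    ATG-to-sequence-end run with no in-frame stop.
    """

    strand: str
    frame: int
    start: int
    end: int
    complete: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_frame(seq: str, frame: int) -> list[tuple[int, int, bool]]:
    """(start, end, complete) for maximal ORFs in one forward frame."""
    orfs = []
    open_start: Optional[int] = None
    i = frame
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if open_start is None:
            if codon == START:
                open_start = i
        elif codon in STOPS:
            orfs.append((open_start, i, True))
            open_start = None
        i += 3
    if open_start is not None:
        orfs.append((open_start, i, False))
    return orfs


def find_orfs(seq: str, both_strands: bool = True) -> list[Orf]:
    """All maximal ORFs (earliest ATG per stop) over the scanned frames."""
    seq = seq.upper()
    out: list[Orf] = []
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        for frame in range(3):
            for start, end, complete in _scan_frame(s, frame):
                out.append(Orf(strand, frame, start, end, complete))
    return out


def max_orf_length(seq: str, both_strands: bool = True) -> int:
    """Length (nt) of the longest complete ATG-to-stop ORF; 0 if none."""
    if not seq:
        return 0
    complete = [o.length for o in find_orfs(seq, both_strands) if o.complete]
    return max(complete, default=0)


def best_orf(seq: str, both_strands: bool = True) -> Optional[Orf]:
    """Longest ORF, preferring complete ones; ties go to the earliest.

    Used by the coding-potential features: if no complete ORF exists the
    longest open (start-without-stop) run is reported with
    ``complete=False``.
    """
    orfs = find_orfs(seq, both_strands)
    if not orfs:
        return None
    return max(
        orfs,
        key=lambda o: (o.complete, o.length, -o.start, o.strand == "+"),
    )


def orf_peptide(seq: str, orf: Orf) -> str:
    """Translate an ORF (stop codon excluded) to its peptide."""
    s = seq.upper() if orf.strand == "+" else reverse_complement(seq)
    sub = s[orf.start : orf.end]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


def six_frame_translate(seq: str) -> list[str]:
    """Translate the three forward and three reverse frames.

    Stops render as ``*``; trailing partial codons are dropped. Order:
    frames +1, +2, +3, -1, -2, -3.
    """
    seq = seq.upper()
    rc = reverse_complement(seq)
    peptides = []
    for s in (seq, rc):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            peptides.append(str(Seq(sub).translate()))
    return peptides
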