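"""Positional classification of novel transcripts against a reference.

Each assembled transcript gets a cuffcompare-style class code describing
its geometric relation to the closest reference transcript:

====  =========================================================
``=``  complete match of intron chain
``c``  contained in a reference transcript, junctions matching
``j``  shares at least one splice junction (novel isoform)
``o``  generic exonic overlap, same strand, no shared junction
``i``  falls entirely within a reference intron
``x``  exonic overlap with a reference on the opposite strand
``s``  an intron overlaps a reference intron, opposite strand
``u``  intergenic (none of the above)
====  =========================================================

When several codes apply against different reference transcripts the
most specific one wins; the precedence is ``= > c > j > o > i > x > s > u``,
mirroring the published ordering from most- to least-specific match.
Unstranded (``.``) novel transcripts never receive the strand-requiring
codes ``x``/``s`` and are treated as matching either strand for ``j``/``o``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import GenomicInterval, TranscriptModel, index_by_seqname

logger = logging.getLogger(__name__)

#: Most-specific-first ordering used to resolve multiple candidate codes.
PRECEDENCE = ("=", "c", "j", "o", "i", "x", "s", "u")
_RANK = {code: i for i, code in enumerate(PRECEDENCE)}


@dataclass(frozen=True)
class ClassCode:
    code: str
    ref_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.code not in PRECEDENCE:
            raise ValueError(f"unknown class code {self.code!r}")
        if (self.code == "u") != (self.ref_id is None):
            raise ValueError("ref_id must be None exactly for code 'u'")


def splice_junctions(t: TranscriptModel) -> set[tuple[str, int, int, str]]:
    """Intron coordinates of a transcript as (seqname, start, end, strand)."""
    return {(i.seqname, i.start, i.end, i.strand) for i in t.introns()}


def _strand_compatible(novel: TranscriptModel, ref: TranscriptModel) -> bool:
    """'.' on either side matches both strands."""
    return "." in (novel.strand, ref.strand) or novel.strand == ref.strand


def _junctions_ignoring_strand(t: TranscriptModel) -> set[tuple[str, int, int]]:
    return {(i.seqname, i.start, i.end) for i in t.introns()}


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def _is_equal(t: TranscriptModel, r: TranscriptModel) -> bool:
    if not _strand_compatible(t, r):
        return False
    if t.n_exons == 1 and r.n_exons == 1:
        e, f = t.exons[0], r.exons[0]
        return e.start == f.start and e.end == f.end
    if t.n_exons == 1 or r.n_exons == 1:
        return False
    return _junctions_ignoring_strand(t) == _junctions_ignoring_strand(r)


def _is_contained(t: TranscriptModel, r: TranscriptModel) -> bool:
    """t's chain contained in r's with matching internal junctions (proper)."""
    if not _strand_compatible(t, r) or _is_equal(t, r):
        return False
    if not r.span.contains(t.span):
        return False
    if t.n_exons == 1:
        return any(e.contains(t.exons[0]) for e in r.exons)
    tj = sorted(_junctions_ignoring_strand(t))
    rj = sorted(_junctions_ignoring_strand(r))
    if not set(tj) <= set(rj):
        return False
    # junction chain must be a contiguous run of the reference chain
    k = rj.index(tj[0])
    if rj[k : k + len(tj)] != tj:
        return False
    # terminal exons must stay inside the flanking reference exons
    first_ref = r.exons[k]
    last_ref = r.exons[k + len(tj)]
    return first_ref.contains(t.exons[0]) and last_ref.contains(t.exons[-1])


def _shares_junction(t: TranscriptModel, r: TranscriptModel) -> bool:
    if not _strand_compatible(t, r):
        return False
    return bool(_junctions_ignoring_strand(t) & _junctions_ignoring_strand(r))


def _within_intron(t: TranscriptModel, r: TranscriptModel) -> bool:
    return any(i.contains(t.span) for i in r.introns())


def _opposite_strand(t: TranscriptModel, r: TranscriptModel) -> bool:
    return (
        t.strand != "."
        and r.strand != "."
        and t.strand != r.strand
        and t.seqname == r.seqname
    )


def _intron_overlap(t: TranscriptModel, r: TranscriptModel) -> bool:
    return any(it.overlaps(ir) for it in t.introns() for ir in r.introns())


def _code_against(t: TranscriptModel, r: TranscriptModel) -> Optional[str]:
    """Most specific code of t relative to a single reference transcript."""
    if _is_equal(t, r):
        return "="
    if _is_contained(t, r):
        return "c"
    if _shares_junction(t, r):
        return "j"
    exonic = _exonic_overlap(t, r)
    if exonic and _strand_compatible(t, r):
        return "o"
    if _within_intron(t, r):
        return "i"
    if exonic and _opposite_strand(t, r):
        return "x"
    if not exonic and _opposite_strand(t, r) and _intron_overlap(t, r):
        return "s"
    return None


def classify_transcript(
    t: TranscriptModel,
    reference: Sequence[TranscriptModel] | dict[str, list[TranscriptModel]],
) -> ClassCode:
    """Class code of a novel transcript relative to a reference annotation."""
    index = (
        reference
        if isinstance(reference, dict)
        else index_by_seqname(reference)
    )
    candidates = index.get(t.seqname)
    if not candidates:
        logger.debug("seqname %s of %s absent from reference; classified 'u'", t.seqname, t.id)
        return ClassCode("u", None)
    best: Optional[tuple[int, str, str]] = None
    for r in candidates:
        code = _code_against(t, r)
        if code is None:
            continue
        key = (_RANK[code], r.id)
        if best is None or key < (best[0], best[2]):
            best = (_RANK[code], code, r.id)
        if best[0] == 0:
            break
    if best is None:
        return ClassCode("u", None)
    return ClassCode(best[1], best[2])


def classify_catalogue(
    novels: Iterable[TranscriptModel],
    reference: Sequence[TranscriptModel] | dict[str, list[TranscriptModel]],
) -> pd.DataFrame:
    """Classify every novel transcript; returns columns (id, class_code, ref_id)."""
    index = (
        reference
        if isinstance(reference, dict)
        else index_by_seqname(reference)
    )
    rows = []
    for t in novels:
        cc = classify_transcript(t, index)
        rows.append({"id": t.id, "class_code": cc.code, "ref_id": cc.ref_id})
    return pd.DataFrame(rows, columns=["id", "class_code", "ref_id"])


def class_summary(table: pd.DataFrame) -> pd.Series:
    """Count transcripts per class code, in precedence order."""
    counts = table["class_code"].value_counts()
    return counts.reindex([c for c in PRECEDENCE if c in counts.index])
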