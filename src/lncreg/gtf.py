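"""Minimal GTF reader/writer for exon-level transcript annotations.

Only `exon` features are considered. Attributes `transcript_id` and
`gene_id` are required; `class_code` is carried through when present.
GTF coordinates are 1-based inclusive; in memory everything is 0-based
half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Union

from .models import GenomicInterval, TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: Union[str, Path]) -> list[TranscriptModel]:
    """Read exon rows of a GTF file into transcript models."""
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            seqname, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attributes = _parse_attributes(attrs)
            try:
                tid = attributes["transcript_id"]
                gid = attributes["gene_id"]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing {exc} attribute") from None
            iv = GenomicInterval(seqname, int(start) - 1, int(end), strand)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                gene_of[tid] = gid
            exons[tid].append(iv)
    return [TranscriptModel(tid, gene_of[tid], exons[tid]) for tid in order]


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: Union[str, Path],
    source: str = "lncreg",
    class_codes: dict[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
                if class_codes and t.id in class_codes:
                    attrs += f' class_code "{class_codes[t.id]}";'
                fh.write(
                    "\t".join(
                        [
                            t.seqname,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
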