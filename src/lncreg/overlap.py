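"""QTL interval overlap and external-catalogue homology annotation.

QTL overlap is strand-agnostic and counts any shared base between the
lncRNA locus span and the QTL interval (half-open intersection).
Catalogue homology reuses the nucleotide local aligner against an
external lncRNA catalogue (NONCODE-style FASTA), keeping hits with
E < 1e-6; many novel lncRNA may match the same catalogue entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .align import NucleotideHomologySearch
from .models import GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class QtlRecord:
    interval: GenomicInterval
    qtl_id: str
    trait: str

    def __post_init__(self) -> None:
        if not self.trait:
            raise ValueError("trait name must be non-empty")


def read_qtl_bed(path: Union[str, Path]) -> list[QtlRecord]:
    """BED-like TSV: seqname, start, end, qtl_id, trait (0-based half-open)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            seqname, start, end, qtl_id, trait = fields[:5]
            try:
                iv = GenomicInterval(seqname, int(start), int(end))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed interval ({exc})") from None
            records.append(QtlRecord(iv, qtl_id, trait))
    return records


def write_qtl_bed(records: Sequence[QtlRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.seqname}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.qtl_id}\t{r.trait}\n"
            )


def qtl_overlap(
    lncrna_loci: Sequence[TranscriptModel],
    qtl: Sequence[QtlRecord],
) -> pd.DataFrame:
    """One row per (lncRNA, QTL) pair sharing at least one base.

    Returns columns (lncrna, qtl_id, trait), sorted for determinism.
    """
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(qtl):
        trees.setdefault(rec.interval.seqname, IntervalTree()).addi(
            rec.interval.start, rec.interval.end, i
        )
    rows = []
    for t in lncrna_loci:
        tree = trees.get(t.seqname)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(t.start, t.end), key=lambda h: h.data):
            rec = qtl[hit.data]
            rows.append({"lncrna": t.id, "qtl_id": rec.qtl_id, "trait": rec.trait})
    return (
        pd.DataFrame(rows, columns=["lncrna", "qtl_id", "trait"])
        .sort_values(["lncrna", "qtl_id"])
        .reset_index(drop=True)
    )


def trait_summary(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Per-trait counts of distinct lncRNA and distinct QTL."""
    return (
        overlaps.groupby("trait")
        .agg(n_lncrna=("lncrna", "nunique"), n_qtl=("qtl_id", "nunique"))
        .reset_index()
    )


def catalogue_homology(
    lncrna_seqs: dict[str, str],
    catalogue_seqs: Sequence[tuple[str, str]],
    max_evalue: float = 1e-6,
) -> pd.DataFrame:
    """Significant nucleotide homology of each lncRNA to a catalogue.

    Returns columns (lncrna, catalogue_id, score, evalue, identity); the
    best hit per (lncRNA, catalogue entry) pair is reported, many-to-one
    matches allowed.
    """
    search = NucleotideHomologySearch(catalogue_seqs) if catalogue_seqs else None
    rows = []
    if search is not None:
        for lnc_id in sorted(lncrna_seqs):
            for hit in search.hits(lnc_id, lncrna_seqs[lnc_id], max_evalue):
                rows.append(
                    {
                        "lncrna": lnc_id,
                        "catalogue_id": hit.target_id,
                        "score": hit.score,
                        "evalue": hit.evalue,
                        "identity": hit.identity,
                    }
                )
    return pd.DataFrame(
        rows, columns=["lncrna", "catalogue_id", "score", "evalue", "identity"]
    )
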