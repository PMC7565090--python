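"""The lncRNA identification filter cascade.

Candidate novel transcripts pass, in order: (1) minimum spliced length of
200 nt; (2) no complete ORF longer than 300 nt; (3) no significant
protein homology (blastx-style screen, E < 1e-6); (4) a noncoding call
from the coding-potential classifier; and finally the multi-exon
requirement. Survivors of all stages are the lncRNA catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .align import ProteinHomologySearch
from .coding import CodingModel, coding_call, coding_features, load_coding_model
from .models import TranscriptModel
from .orf import max_orf_length

STAGES = ("length", "orf", "homology", "coding_potential", "multi_exon")


@dataclass(frozen=True)
class FilterConfig:
    min_length_nt: int = 200
    max_orf_nt: int = 300
    homology_evalue: float = 1e-6
    coding_prob_threshold: float = 0.5
    require_multi_exon: bool = True
    orf_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_length_nt <= 0 or self.max_orf_nt <= 0 or self.homology_evalue <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.coding_prob_threshold < 1.0):
            raise ValueError("coding_prob_threshold must be in (0, 1)")


@dataclass
class FilterReport:
    """Per-stage tallies plus each transcript's first failing stage."""

    stage_input: dict[str, int] = field(default_factory=dict)
    stage_excluded: dict[str, int] = field(default_factory=dict)
    first_failure: dict[str, str] = field(default_factory=dict)

    def stage_surviving(self, stage: str) -> int:
        return self.stage_input[stage] - self.stage_excluded[stage]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s,
                "input": self.stage_input[s],
                "excluded": self.stage_excluded[s],
                "surviving": self.stage_surviving(s),
            }
            for s in STAGES
            if s in self.stage_input
        ]
        return pd.DataFrame(rows, columns=["stage", "input", "excluded", "surviving"])


def run_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    seqs: Mapping[str, str],
    protein_db: Sequence[tuple[str, str]],
    cfg: FilterConfig = FilterConfig(),
    coding_model: Optional[CodingModel] = None,
) -> tuple[list[str], FilterReport]:
    """Apply the filter stages in order; returns surviving IDs and tallies."""
    missing = [t.id for t in transcripts if t.id not in seqs]
    if missing:
        raise KeyError(f"transcripts missing sequences: {missing}")
    if coding_model is None:
        coding_model = load_coding_model()
    homology = ProteinHomologySearch(protein_db) if protein_db else None

    report = FilterReport()
    by_id = {t.id: t for t in transcripts}
    alive = [t.id for t in transcripts]

    def run_stage(stage: str, fails) -> None:
        nonlocal alive
        report.stage_input[stage] = len(alive)
        survivors = []
        excluded = 0
        for tid in alive:
            if fails(tid):
                report.first_failure[tid] = stage
                excluded += 1
            else:
                survivors.append(tid)
        report.stage_excluded[stage] = excluded
        alive = survivors

    run_stage("length", lambda tid: len(seqs[tid]) < cfg.min_length_nt)
    run_stage(
        "orf",
        lambda tid: max_orf_length(seqs[tid], both_strands=cfg.orf_both_strands)
        > cfg.max_orf_nt,
    )
    run_stage(
        "homology",
        lambda tid: (
            homology is not None
            and (hit := homology.best_hit(tid, seqs[tid])) is not None
            and hit.evalue < cfg.homology_evalue
        ),
    )
    run_stage(
        "coding_potential",
        lambda tid: coding_call(
            coding_features(seqs[tid], both_strands=cfg.orf_both_strands),
            coding_model,
            cfg.coding_prob_threshold,
        )
        == "coding",
    )
    if cfg.require_multi_exon:
        run_stage("multi_exon", lambda tid: by_id[tid].n_exons < 2)
    return alive, report
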