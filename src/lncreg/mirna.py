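"""miRNA precursor and sponge-site analysis of lncRNA.

Two candidate roles are screened. *Precursor*: nucleotide homology of the
lncRNA to known miRNA hairpin precursors (E < 1e-6, via the shared local
aligner). *Sponge*: miRanda-style two-stage site scan — a complementarity
local alignment between the miRNA (5'->3') and the lncRNA read 3'->5'
(Watson-Crick pairs score `match`, G:U wobbles score `wobble`, with the
miRNA seed, positions 2-8, scaled up), followed by a two-state
nearest-neighbor duplex free energy on high-scoring alignments. A site
is reported only if score > 160 and energy < -20 kcal/mol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import NucleotideHomologySearch
from .models import AlignmentHit

_NEG = -1e18


def _load_turner() -> tuple[dict[str, float], float]:
    d = json.loads(
        resources.files("lncreg").joinpath("data/turner_stacks.json").read_text()
    )
    return d["stacks"], float(d["duplex_init"])


TURNER_STACKS, DUPLEX_INIT = _load_turner()

#: Free-energy penalty for each run of unpaired/mismatched columns that
#: interrupts a helix (a flat two-state stand-in for interior-loop terms).
LOOP_BREAK_PENALTY = 4.0

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def is_paired(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _WOBBLE


@dataclass(frozen=True)
class NtScoring:
    """Complementarity scoring for the miRNA-site local alignment."""

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2  # 1-based miRNA positions scaled by seed_scale
    seed_end: int = 8
    seed_scale: float = 4.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class BindingSite:
    lncrna_id: str
    mirna_id: str
    lnc_start: int  # 0-based half-open on the lncRNA, 5'->3'
    lnc_end: int
    score: float
    energy: float
    #: alignment columns as (mirna_base, lnc_base) with '-' for gaps,
    #: miRNA 5'->3', lncRNA 3'->5'
    columns: tuple[tuple[str, str], ...] = field(default=(), compare=False)


def _pair_score_matrix(mir: str, scoring: NtScoring) -> np.ndarray:
    """Score of miRNA base i against each RNA letter AUCG+N."""
    letters = "ACGUN"
    mat = np.full((len(mir), len(letters)), scoring.mismatch)
    for i, a in enumerate(mir):
        scale = (
            scoring.seed_scale
            if scoring.seed_start <= i + 1 <= scoring.seed_end
            else 1.0
        )
        for j, b in enumerate(letters):
            if (a, b) in _WC:
                s = scoring.match
            elif (a, b) in _WOBBLE:
                s = scoring.wobble
            else:
                s = scoring.mismatch
            mat[i, j] = s * scale if s > 0 else s
    return mat


def _smith_waterman_rc(
    mir: str, rev_target: str, scoring: NtScoring, col_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine-gap local DP of the miRNA against the reversed target.

    Returns the three DP layers (match, gap-in-target, gap-in-miRNA) with
    shape (len(mir)+1, len(rev_target)+1). Masked target columns score
    -inf so already-claimed sites cannot be re-used.
    """
    letters = {c: i for i, c in enumerate("ACGUN")}
    smat = _pair_score_matrix(mir, scoring)
    tidx = np.array([letters.get(c, 4) for c in rev_target])
    m, n = len(mir), len(rev_target)
    M = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), _NEG)  # gap consumes miRNA base
    Iy = np.full((m + 1, n + 1), _NEG)  # gap consumes target base
    go, ge = scoring.gap_open, scoring.gap_extend
    j_arange = np.arange(1, n + 1, dtype=float)
    for i in range(1, m + 1):
        sub = smat[i - 1, tidx]
        sub = np.where(col_mask, _NEG, sub)
        diag = np.maximum.reduce([M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1]])
        M[i, 1:] = np.maximum(0.0, diag + sub)
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + go, Ix[i - 1, 1:] + ge)
        # running-max scan for the within-row gap layer
        g = np.maximum.accumulate(M[i, :-1] + go - ge * (j_arange - 1))
        Iy[i, 1:] = g + ge * (j_arange - 1)
    return M, Ix, Iy


def _traceback(
    M: np.ndarray,
    Ix: np.ndarray,
    Iy: np.ndarray,
    mir: str,
    rev_target: str,
    scoring: NtScoring,
    i: int,
    j: int,
) -> tuple[int, int, list[tuple[str, str]]]:
    """Recover the local alignment ending at M[i, j]."""
    cols: list[tuple[str, str]] = []
    layer = "M"
    go, ge = scoring.gap_open, scoring.gap_extend
    while i > 0 and j > 0:
        if layer == "M":
            if M[i, j] <= 0:
                break
            cols.append((mir[i - 1], rev_target[j - 1]))
            diag = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            layer = ("M", "Ix", "Iy")[int(np.argmax(diag))]
            i, j = i - 1, j - 1
            if max(diag) <= 0:
                break
        elif layer == "Ix":
            cols.append((mir[i - 1], "-"))
            layer = "M" if Ix[i, j] == M[i - 1, j] + go else "Ix"
            i -= 1
        else:
            cols.append(("-", rev_target[j - 1]))
            layer = "M" if abs(Iy[i, j] - (M[i, j - 1] + go)) < 1e-9 else "Iy"
            j -= 1
    cols.reverse()
    return i, j, cols


def duplex_energy(columns: Sequence[tuple[str, str]]) -> float:
    """Two-state nearest-neighbor free energy of an aligned miRNA:site duplex.

    Consecutive paired columns contribute the Turner stack term; every
    interruption (mismatch or gap) between helices costs a flat loop
    penalty; one duplex initiation is added if any pair forms. Returns
    0.0 when nothing pairs.
    """
    paired = [
        (a, b) if ("-" not in (a, b) and is_paired(_rna(a), _rna(b))) else None
        for a, b in ((_rna(a), _rna(b)) for a, b in columns)
    ]
    if not any(p is not None for p in paired):
        return 0.0
    energy = DUPLEX_INIT
    in_helix = False
    seen_pair = False
    pending_break = False
    prev_pair: Optional[tuple[str, str]] = None
    for p in paired:
        if p is None:
            if seen_pair:
                pending_break = True
            prev_pair = None
            continue
        if prev_pair is not None:
            energy += TURNER_STACKS[f"{prev_pair[0]}{prev_pair[1]}/{p[0]}{p[1]}"]
        elif seen_pair and pending_break:
            energy += LOOP_BREAK_PENALTY
        pending_break = False
        seen_pair = True
        prev_pair = p
    return energy


def scan_sites(
    mirna_seq: str,
    lncrna_seq: str,
    scoring: NtScoring = NtScoring(),
    min_score: float = 160.0,
    mirna_id: str = "miRNA",
    lncrna_id: str = "lncRNA",
) -> list[BindingSite]:
    """Non-overlapping high-score candidate sites of a miRNA on a lncRNA.

    Sites are extracted greedily by score (ties to the leftmost lncRNA
    coordinate); each claimed site masks its lncRNA span before rescanning.
    Energy is attached but NOT thresholded here; see
    :func:`filter_sites` / :func:`sponge_profile`.
    """
    mir = _rna(mirna_seq)
    lnc = _rna(lncrna_seq)
    if not (2 <= len(mir) <= len(lnc)):
        return []
    rev = lnc[::-1]
    n = len(lnc)
    mask = np.zeros(n, dtype=bool)
    sites: list[BindingSite] = []
    while True:
        # the DP walks the reversed sequence, so flip the claimed-site mask
        M, Ix, Iy = _smith_waterman_rc(mir, rev, scoring, mask[::-1])
        best = float(M.max())
        if best <= min_score:
            break
        # ties: highest score, then leftmost on the lncRNA (= rightmost j in rev)
        ii, jj = np.nonzero(M == best)
        order = np.lexsort((ii, -jj))
        i, j = int(ii[order[0]]), int(jj[order[0]])
        _, j0, cols = _traceback(M, Ix, Iy, mir, rev, scoring, i, j)
        # rev[j0:j] maps to lnc[n-j : n-j0]
        start, end = n - j, n - j0
        sites.append(
            BindingSite(
                lncrna_id=lncrna_id,
                mirna_id=mirna_id,
                lnc_start=start,
                lnc_end=end,
                score=best,
                energy=duplex_energy(cols),
                columns=tuple(cols),
            )
        )
        mask[start:end] = True
    sites.sort(key=lambda s: (s.lnc_start, -s.score))
    return sites


def filter_sites(
    sites: Sequence[BindingSite],
    min_score: float = 160.0,
    max_energy: float = -20.0,
) -> list[BindingSite]:
    """Keep sites passing both the score and free-energy thresholds."""
    return [s for s in sites if s.score > min_score and s.energy < max_energy]


def precursor_match(
    lncrna_id: str,
    lncrna_seq: str,
    precursor_db: Sequence[tuple[str, str]],
    max_evalue: float = 1e-6,
) -> list[AlignmentHit]:
    """Significant homology of a lncRNA to miRNA precursor hairpins."""
    if not precursor_db:
        return []
    search = NucleotideHomologySearch(precursor_db)
    return search.hits(lncrna_id, lncrna_seq.upper().replace("U", "T"), max_evalue)


def sponge_profile(
    lncrna_seqs: dict[str, str],
    mirna_db: Sequence[tuple[str, str]],
    scoring: NtScoring = NtScoring(),
    min_score: float = 160.0,
    max_energy: float = -20.0,
) -> pd.DataFrame:
    """Site table over all lncRNA x miRNA pairs, both thresholds applied.

    Returns columns (lncrna, mirna, start, end, score, energy); lncRNA
    with no surviving site are absent.
    """
    rows = []
    for lnc_id in sorted(lncrna_seqs):
        for mir_id, mir_seq in mirna_db:
            for s in filter_sites(
                scan_sites(
                    mir_seq,
                    lncrna_seqs[lnc_id],
                    scoring,
                    min_score,
                    mirna_id=mir_id,
                    lncrna_id=lnc_id,
                ),
                min_score,
                max_energy,
            ):
                rows.append(
                    {
                        "lncrna": lnc_id,
                        "mirna": mir_id,
                        "start": s.lnc_start,
                        "end": s.lnc_end,
                        "score": s.score,
                        "energy": s.energy,
                    }
                )
    return pd.DataFrame(
        rows, columns=["lncrna", "mirna", "start", "end", "score", "energy"]
    )


def sponge_counts(profile: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(distinct miRNA per lncRNA, distinct lncRNA per miRNA)."""
    per_lnc = profile.groupby("lncrna")["mirna"].nunique()
    per_mir = profile.groupby("mirna")["lncrna"].nunique()
    return per_lnc, per_mir
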