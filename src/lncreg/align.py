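"""Smith-Waterman local alignment with Karlin-Altschul significance.

Two aligners back the pipeline's homology screens: a blastx-like protein
aligner (six translated frames vs a peptide database, BLOSUM62, affine
gaps 11/1) and a blastn-like nucleotide aligner (match +2 / mismatch -3,
affine gaps 5/2, both strands). Significance follows the Karlin-Altschul
form E = K*m*n*exp(-lambda*S), with lambda solved from

    sum_ij p_i p_j exp(lambda * s_ij) = 1

under the database residue frequencies, and K fixed at 0.13 — an
ungapped-style calibration applied to gapped scores, chosen for
determinism rather than exact BLAST numerics.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .models import AlignmentHit
from .orf import reverse_complement, six_frame_translate

KARLIN_K = 0.13

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NT_ALPHABET = "ACGTN"


def solve_lambda(
    matrix: substitution_matrices.Array,
    freqs: dict[str, float],
) -> float:
    """Karlin-Altschul lambda for a scoring matrix and residue frequencies.

    Requires a negative expected score and at least one positive score,
    otherwise no positive root exists.
    """
    letters = [a for a in freqs if freqs[a] > 0]
    p = np.array([freqs[a] for a in letters])
    p = p / p.sum()
    s = np.array([[matrix[a, b] for b in letters] for a in letters], dtype=float)
    expected = float(p @ s @ p)
    if expected >= 0 or s.max() <= 0:
        raise ValueError("scoring system must have negative expectation and a positive score")

    def f(lam: float) -> float:
        return float(p @ np.exp(lam * s) @ p) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 64:
            raise RuntimeError("failed to bracket lambda")
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


def _db_frequencies(seqs: Iterable[str], alphabet: set[str]) -> dict[str, float]:
    counts: Counter[str] = Counter()
    for s in seqs:
        counts.update(c for c in s.upper() if c in alphabet)
    total = sum(counts.values())
    if total == 0:
        return {a: 1.0 / len(alphabet) for a in sorted(alphabet)}
    return {a: counts[a] / total for a in sorted(alphabet)}


def _nucleotide_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_NT_ALPHABET, dims=2)
    for a in _NT_ALPHABET:
        for b in _NT_ALPHABET:
            # N is worst-case: always scores as a mismatch
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


def _make_aligner(
    matrix: substitution_matrices.Array, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length L costs gap_open + L*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_details(alignment) -> tuple[float, int, int, int, int]:
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    qblocks, tblocks = alignment.aligned[0], alignment.aligned[1]
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    return identity, qs, qe, ts, te


class ProteinHomologySearch:
    """blastx-style screen of nucleotide queries against a peptide database."""

    def __init__(
        self,
        protein_db: Sequence[tuple[str, str]],
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
        k: float = KARLIN_K,
    ):
        self.db = [(name, seq.upper()) for name, seq in protein_db]
        self.k = k
        self.matrix = substitution_matrices.load("BLOSUM62")
        self.aligner = _make_aligner(self.matrix, gap_open, gap_extend)
        self.db_length = sum(len(s) for _, s in self.db)
        if self.db:
            freqs = _db_frequencies((s for _, s in self.db), _PROTEIN_ALPHABET)
            self.lam = solve_lambda(self.matrix, freqs)

    def evalue(self, score: float, query_len: int) -> float:
        return self.k * query_len * self.db_length * np.exp(-self.lam * score)

    def best_hit(self, query_id: str, nt_seq: str) -> Optional[AlignmentHit]:
        """Minimum-E hit of any translated frame against any db peptide."""
        if not self.db or len(nt_seq) < 3:
            return None
        frames = six_frame_translate(nt_seq)
        frame_labels = [1, 2, 3, -1, -2, -3]
        best: Optional[tuple[float, float, int, str, str]] = None
        for frame, pep in zip(frame_labels, frames):
            if not pep:
                continue
            for name, target in self.db:
                score = self.aligner.score(pep, target)
                if score <= 0:
                    continue
                e = self.evalue(score, len(pep))
                key = (e, -score, frame, name)
                if best is None or key < (best[0], -best[1], best[2], best[3]):
                    best = (e, score, frame, name, pep)
        if best is None:
            return None
        e, score, frame, name, pep = best
        target = dict(self.db)[name]
        alignment = self.aligner.align(pep, target)[0]
        identity, qs, qe, ts, te = _alignment_details(alignment)
        return AlignmentHit(
            query_id=query_id,
            target_id=name,
            score=score,
            evalue=e,
            identity=identity,
            query_start=qs,
            query_end=qe,
            target_start=ts,
            target_end=te,
            frame=frame,
        )


class NucleotideHomologySearch:
    """blastn-style screen of nucleotide queries against a nucleotide database."""

    def __init__(
        self,
        db: Sequence[tuple[str, str]],
        match: float = 2.0,
        mismatch: float = -3.0,
        gap_open: float = 5.0,
        gap_extend: float = 2.0,
        k: float = KARLIN_K,
    ):
        self.db = [(name, seq.upper().replace("U", "T")) for name, seq in db]
        self.k = k
        self.matrix = _nucleotide_matrix(match, mismatch)
        self.aligner = _make_aligner(self.matrix, gap_open, gap_extend)
        self.db_length = sum(len(s) for _, s in self.db)
        if self.db:
            freqs = {a: 0.25 for a in "ACGT"}
            freqs["N"] = 0.0
            self.lam = solve_lambda(self.matrix, freqs)

    def evalue(self, score: float, query_len: int) -> float:
        return self.k * query_len * self.db_length * np.exp(-self.lam * score)

    def hits(
        self, query_id: str, seq: str, max_evalue: float = 1e-6
    ) -> list[AlignmentHit]:
        """Best significant hit per database entry, either strand, sorted by E."""
        if not self.db or not seq:
            return []
        seq = seq.upper().replace("U", "T")
        strands = {1: seq, -1: reverse_complement(seq)}
        out = []
        for name, target in self.db:
            best = None
            for strand, q in strands.items():
                score = self.aligner.score(q, target)
                if best is None or score > best[0]:
                    best = (score, strand, q)
            score, strand, q = best
            if score <= 0:
                continue
            e = self.evalue(score, len(seq))
            if e >= max_evalue:
                continue
            alignment = self.aligner.align(q, target)[0]
            identity, qs, qe, ts, te = _alignment_details(alignment)
            out.append(
                AlignmentHit(
                    query_id=query_id,
                    target_id=name,
                    score=score,
                    evalue=e,
                    identity=identity,
                    query_start=qs,
                    query_end=qe,
                    target_start=ts,
                    target_end=te,
                    frame=strand,
                )
            )
        out.sort(key=lambda h: (h.evalue, h.target_id))
        return out

    def best_hit(
        self, query_id: str, seq: str, max_evalue: float = 1e-6
    ) -> Optional[AlignmentHit]:
        hits = self.hits(query_id, seq, max_evalue)
        return hits[0] if hits else None
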