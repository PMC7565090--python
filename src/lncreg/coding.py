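"""Coding-potential features and classifier for the lncRNA filter.

The feature set mirrors the one CPC2 popularised — Fickett TESTCODE
score, ORF length, ORF integrity and the isoelectric point of the ORF
peptide (plus ORF coverage) — combined here by a logistic model fit once
on synthetic labelled data (mRNA-like long-ORF positives vs shuffled
negatives) and shipped as a versioned constant file. The filter is a
backstop after length/ORF/homology screening, so feature fidelity
matters more than the exact decision boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .orf import best_orf, orf_peptide

# ---------------------------------------------------------------------------
# Fickett TESTCODE (position and composition lookup tables from the
# published method, as used by downstream coding-potential tools)
# ---------------------------------------------------------------------------

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.42, 0.29, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, edges: list[float], probs: list[float]) -> float:
    for edge, prob in zip(edges, probs):
        if value >= edge:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic over the whole transcript sequence."""
    seq = seq.upper().replace("U", "T")
    usable = [c for c in seq if c in "ACGT"]
    if not usable:
        return 0.0
    score = 0.0
    n = len(usable)
    for base in "ACGT":
        counts = [0, 0, 0]
        for i, c in enumerate(usable):
            if c == base:
                counts[i % 3] += 1
        position_param = max(counts) / (min(counts) + 1)
        content = sum(counts) / n
        score += _lookup(position_param, _POSITION_EDGES, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_EDGES, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Isoelectric point via Henderson-Hasselbalch net charge
# ---------------------------------------------------------------------------

PKA_POSITIVE = {"Nterm": 9.69, "K": 10.53, "R": 12.48, "H": 6.00}
PKA_NEGATIVE = {"Cterm": 2.34, "D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07}


def net_charge(peptide: str, ph: float) -> float:
    """Net charge of a peptide at a given pH (Henderson-Hasselbalch)."""
    peptide = peptide.upper()
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in peptide:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(peptide: str) -> float:
    """pH at which the net charge crosses zero; 7.0 for an empty peptide."""
    if not peptide:
        return 7.0
    return float(brentq(lambda ph: net_charge(peptide, ph), 0.0, 14.0, xtol=1e-9))


# ---------------------------------------------------------------------------
# Feature extraction and the logistic coding call
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("fickett", "orf_len_nt", "orf_coverage", "orf_integrity", "pI")


@dataclass(frozen=True)
class CodingFeatures:
    fickett: float
    orf_len_nt: int
    orf_integrity: int  # +1 if the best ORF has both start and stop, else -1
    orf_coverage: float
    pI: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.fickett, self.orf_len_nt, self.orf_coverage, self.orf_integrity, self.pI],
            dtype=float,
        )


def coding_features(seq: str, both_strands: bool = True) -> CodingFeatures:
    """CPC2-style features of a transcript sequence."""
    seq = seq.upper().replace("U", "T")
    orf = best_orf(seq, both_strands=both_strands)
    if orf is None or (not orf.complete and orf.length < 3):
        return CodingFeatures(fickett_score(seq), 0, -1, 0.0, 7.0)
    peptide = orf_peptide(seq, orf).rstrip("*")
    return CodingFeatures(
        fickett=fickett_score(seq),
        orf_len_nt=orf.length,
        orf_integrity=1 if orf.complete else -1,
        orf_coverage=orf.length / len(seq) if seq else 0.0,
        pI=isoelectric_point(peptide),
    )


@dataclass
class CodingModel:
    """Standardized-feature logistic model for the coding/noncoding call."""

    means: np.ndarray
    scales: np.ndarray
    weights: np.ndarray
    intercept: float
    version: str = "1"

    def predict_proba(self, f: CodingFeatures) -> float:
        x = (f.as_vector() - self.means) / self.scales
        z = float(x @ self.weights + self.intercept)
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "features": list(FEATURE_NAMES),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodingModel":
        return cls(
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            version=str(d.get("version", "?")),
        )


def load_coding_model() -> CodingModel:
    """Load the packaged coding model constants."""
    text = resources.files("lncreg").joinpath("data/coding_model.json").read_text()
    return CodingModel.from_dict(json.loads(text))


def coding_call(
    features: CodingFeatures,
    model: Optional[CodingModel] = None,
    threshold: float = 0.5,
) -> str:
    """'coding' iff the model probability reaches the threshold."""
    if model is None:
        model = load_coding_model()
    return "coding" if model.predict_proba(features) >= threshold else "noncoding"


# ---------------------------------------------------------------------------
# One-time model fitting on synthetic labelled data
# ---------------------------------------------------------------------------

def _logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-3, n_iter: int = 50
) -> tuple[np.ndarray, float]:
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(n_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-8, None)
        z = eta + (y - mu) / w
        A = Xd.T @ (w[:, None] * Xd) + ridge * np.eye(Xd.shape[1])
        beta_new = np.linalg.solve(A, Xd.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta[1:], float(beta[0])


def fit_coding_model(n_per_class: int = 400, seed: int = 20200825) -> CodingModel:
    """Refit the logistic model on synthetic mRNA-like vs shuffled sequences.

    Positives carry a long clean ORF flanked by UTR-like sequence;
    negatives are per-sequence shuffles of the positives, which destroys
    the reading frame but preserves composition.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    stops = {"TAA", "TAG", "TGA"}
    rows, labels = [], []
    for _ in range(n_per_class):
        n_codons = int(rng.integers(100, 400))
        codons = ["ATG"]
        while len(codons) < n_codons:
            c = "".join(rng.choice(bases, 3))
            if c not in stops:
                codons.append(c)
        codons.append(rng.choice(sorted(stops)))
        utr5 = "".join(rng.choice(bases, int(rng.integers(10, 150))))
        utr3 = "".join(rng.choice(bases, int(rng.integers(10, 300))))
        pos_seq = utr5 + "".join(codons) + utr3
        neg = np.array(list(pos_seq))
        rng.shuffle(neg)
        for seq, label in ((pos_seq, 1), ("".join(neg), 0)):
            rows.append(coding_features(seq).as_vector())
            labels.append(label)
    X = np.asarray(rows)
    y = np.asarray(labels, dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    weights, intercept = _logistic_irls((X - means) / scales, y)
    return CodingModel(means=means, scales=scales, weights=weights, intercept=intercept)
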