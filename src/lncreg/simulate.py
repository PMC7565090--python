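"""Synthetic-data generator for the whole pipeline.

Emulates the study design the pipeline targets — five tissues from two
divergent feed-efficiency groups of ~9 animals each — with full ground
truth: novel transcripts planted so each receives a known class code,
transcript sequences with exactly controlled maximal ORF lengths,
negative-binomial counts with planted differential expression and
differentially wired regulator lncRNA, miRNA databases with planted
sponge sites and precursors, QTL intervals overlapping a known subset
of loci, and gene sets containing the planted regulator targets.

Every output is a pure function of the master seed: each component
draws from its own `default_rng([seed, component_id])` stream so stages
can be regenerated independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import GROUPS, CountMatrix
from .models import GenomicInterval, TranscriptModel
from .orf import max_orf_length, reverse_complement
from .overlap import QtlRecord

TISSUES = ("adrenal", "hypothalamus", "liver", "muscle", "pituitary")

DEFAULT_CLASS_MIX = {
    "j": 0.38,
    "u": 0.23,
    "o": 0.12,
    "i": 0.10,
    "x": 0.07,
    "c": 0.05,
    "=": 0.03,
    "s": 0.02,
}

_FORBIDDEN = ("ATG", "CAT")  # no start codon on either strand
_STOPS = ("TAA", "TAG", "TGA")

# rng stream ids per component
_STREAM_ANNOT = 1
_STREAM_SEQ = 2
_STREAM_QTL = 3
_STREAM_GMT = 4
_STREAM_MIRNA = 5
_STREAM_PROTEIN = 6
_STREAM_COUNTS = 100  # + tissue index


@dataclass
class SimulationConfig:
    seed: int = 0
    n_ref_genes: int = 30
    n_novel: int = 60
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_samples_per_group: int = 9
    nb_dispersion: float = 0.08
    n_de: int = 8
    de_log2fc: float = 2.0
    n_regulators: int = 3
    regulator_targets: int = 10
    wiring_r_high: float = 0.9
    wiring_r_low: float = 0.0
    #: group shift of wired target mRNA (the panel emulates FE-relevant
    #: mRNA, which differ between groups by construction of the panel)
    target_log2fc: float = 0.8
    orf_spec: dict[str, int] = field(default_factory=dict)
    n_tissue_specific: int = 6
    n_mrna: int = 120
    n_mirna: int = 12
    tissues: tuple[str, ...] = TISSUES
    bio_sd: float = 0.7  # log2-scale biological variability per sample
    #: amplitude of the shared regulatory program on wired rows; larger
    #: than bio_sd so the nominal wiring correlation survives counting noise
    wiring_sd: float = 1.2

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        unknown = set(self.class_mix) - set("=cjioux" + "s")
        if unknown:
            raise ValueError(f"unknown class codes in class_mix: {unknown}")
        if self.n_de + self.n_regulators > self.n_novel:
            raise ValueError("n_de + n_regulators must not exceed n_novel")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        for r in (self.wiring_r_high, self.wiring_r_low):
            if not -1.0 <= r <= 1.0:
                raise ValueError("wiring correlations must be in [-1, 1]")


@dataclass
class GroundTruth:
    true_class: dict[str, str] = field(default_factory=dict)
    true_de: set[str] = field(default_factory=set)
    true_regulators: set[str] = field(default_factory=set)
    regulator_targets: dict[str, list[str]] = field(default_factory=dict)
    planted_qtl_overlaps: set[str] = field(default_factory=set)
    true_sponges: dict[str, set[str]] = field(default_factory=dict)
    true_precursors: set[str] = field(default_factory=set)
    #: transcript -> tissues in which it is expressed (absent = all tissues)
    tissue_profile: dict[str, set[str]] = field(default_factory=dict)
    #: lncRNA with a diverged copy planted in the external catalogue
    true_catalogue_matches: set[str] = field(default_factory=set)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _apportion(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n transcripts over classes."""
    items = sorted(mix.items())
    floors = {c: int(np.floor(p * n)) for c, p in items}
    remainder = n - sum(floors.values())
    fracs = sorted(items, key=lambda cp: (-(cp[1] * n - np.floor(cp[1] * n)), cp[0]))
    for c, _ in fracs[:remainder]:
        floors[c] += 1
    return floors


def _make_reference(cfg: SimulationConfig, rng: np.random.Generator) -> list[TranscriptModel]:
    refs = []
    for g in range(cfg.n_ref_genes):
        chrom = f"chr{g % 5 + 1}"
        slot = g // 5
        start = 10_000 + slot * 60_000
        n_ex = int(rng.integers(3, 7))
        lens = rng.integers(120, 301, n_ex)
        gaps = rng.integers(400, 1501, n_ex - 1)
        strand = "+" if g % 2 == 0 else "-"
        exons = []
        pos = start
        for i in range(n_ex):
            exons.append(GenomicInterval(chrom, pos, pos + int(lens[i]), strand))
            pos += int(lens[i])
            if i < n_ex - 1:
                pos += int(gaps[i])
        refs.append(TranscriptModel(f"REF_T{g:04d}", f"REF_G{g:04d}", exons))
    return refs


def _plant_novel(
    code: str, host: TranscriptModel, k: int, shift: int
) -> list[GenomicInterval]:
    """Exon chain satisfying one class code's geometry relative to the host."""
    ex = host.exons
    strand = host.strand
    flip = "-" if strand == "+" else "+"
    chrom = host.seqname
    intron0 = GenomicInterval(chrom, ex[0].end, ex[1].start)
    intron1 = GenomicInterval(chrom, ex[1].end, ex[2].start)
    if code == "=":
        return list(ex)
    if code == "c":
        return list(ex[1:])
    if code == "j":
        third = GenomicInterval(chrom, ex[2].start + 40 + shift, ex[2].end, strand)
        return [ex[0], ex[1], third]
    if code == "o":
        return [GenomicInterval(chrom, ex[0].start - 150 - shift, ex[0].start + 100, strand)]
    if code == "i":
        s = intron0.start + 30 + shift
        return [GenomicInterval(chrom, s, s + 250, strand)]
    if code == "x":
        return [GenomicInterval(chrom, ex[0].start - 60 - shift, ex[0].end + 60, flip)]
    if code == "s":
        e1 = GenomicInterval(chrom, intron0.end - 140 - shift, intron0.end - 20 - shift, flip)
        e2 = GenomicInterval(chrom, intron1.start + 20 + shift, intron1.start + 140 + shift, flip)
        return [e1, e2]
    raise ValueError(f"cannot plant class {code!r}")


def generate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptModel], list[TranscriptModel], GroundTruth]:
    """Reference annotation plus novel transcripts with known class codes."""
    rng = _rng(cfg.seed, _STREAM_ANNOT)
    reference = _make_reference(cfg, rng)
    truth = GroundTruth()
    novels: list[TranscriptModel] = []
    if cfg.n_novel == 0:
        return reference, novels, truth
    counts = _apportion(cfg.class_mix, cfg.n_novel)
    idx = 0
    u_slot = 0
    host_use: dict[tuple[str, int], int] = {}
    for code in sorted(counts):
        for _ in range(counts[code]):
            tid = f"TCONS_{idx + 1:08d}"
            gid = f"XLOC_{idx + 1:06d}"
            if code == "u":
                chrom = f"chr{u_slot % 5 + 1}"
                start = 10_000 + (2000 + u_slot // 5) * 60_000
                exons = [
                    GenomicInterval(chrom, start, start + 200, "+"),
                    GenomicInterval(chrom, start + 700, start + 900, "+"),
                ]
                u_slot += 1
            else:
                host_i = idx % cfg.n_ref_genes
                host = reference[host_i]
                use = host_use.get((code, host_i), 0)
                host_use[(code, host_i)] = use + 1
                exons = _plant_novel(code, host, idx, 7 * use)
            novels.append(TranscriptModel(tid, gid, exons))
            truth.true_class[tid] = code
            idx += 1
    return reference, novels, truth


# ---------------------------------------------------------------------------
# Sequences with controlled ORF content
# ---------------------------------------------------------------------------

def _safe_random_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence containing no ATG on either strand (no ATG/CAT)."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) < n:
        c = bases[int(rng.integers(4))]
        out.append(c)
        if len(out) >= 3 and "".join(out[-3:]) in _FORBIDDEN:
            out.pop()
    return "".join(out)


def _safe_codons(rng: np.random.Generator, n_codons: int) -> str:
    """In-frame stop-free codons forming no ATG/CAT in any frame."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) // 3 < n_codons:
        codon = "".join(bases[int(rng.integers(4))] for _ in range(3))
        if codon in _STOPS or codon == "ATG":
            continue
        trial = out + list(codon)
        window = "".join(trial[-5:])
        if any(f in window for f in _FORBIDDEN):
            continue
        out = trial
    return "".join(out)


def _seq_with_orf(rng: np.random.Generator, length: int, orf_nt: int) -> str:
    """Sequence of given length whose maximal complete ORF is exactly orf_nt."""
    if orf_nt % 3 != 0:
        raise ValueError("requested ORF length must be a multiple of 3")
    if orf_nt < 0 or (orf_nt > 0 and orf_nt + 3 > length - 3):
        raise ValueError(f"ORF of {orf_nt} nt incompatible with length {length}")
    for _ in range(200):
        if orf_nt == 0:
            seq = _safe_random_seq(rng, length)
        else:
            block = "ATG" + _safe_codons(rng, orf_nt // 3 - 1) + "TAA"
            pos = int(rng.integers(0, length - len(block) + 1))
            seq = (
                _safe_random_seq(rng, pos)
                + block
                + _safe_random_seq(rng, length - pos - len(block))
            )
        if max_orf_length(seq) == orf_nt:
            return seq
    raise RuntimeError("failed to construct sequence with requested ORF")


def generate_sequences(
    novel: Sequence[TranscriptModel],
    orf_spec: Optional[dict[str, int]] = None,
    seed: int = 0,
) -> dict[str, str]:
    """Transcript sequences whose maximal ORF length is exactly as requested.

    Transcripts absent from ``orf_spec`` get a random small ORF in
    {0, 30, ..., 150} nt (always below the 300 nt coding filter).
    """
    rng = _rng(seed, _STREAM_SEQ)
    orf_spec = orf_spec or {}
    seqs = {}
    for t in sorted(novel, key=lambda t: t.id):
        length = t.length
        want = orf_spec.get(t.id)
        if want is None:
            want = int(rng.choice([0, 30, 60, 90, 120, 150]))
            want = min(want, max(0, ((length - 6) // 3) * 3))
        seqs[t.id] = _seq_with_orf(rng, length, want)
    return seqs


# ---------------------------------------------------------------------------
# Auxiliary databases
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one stop-free codon per amino acid for reverse translation
_CODON_OF = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}


def generate_protein_db(
    n: int = 8, min_len: int = 120, max_len: int = 200, seed: int = 0
) -> list[tuple[str, str]]:
    rng = _rng(seed, _STREAM_PROTEIN)
    db = []
    for i in range(n):
        ln = int(rng.integers(min_len, max_len + 1))
        pep = "".join(rng.choice(list(_AA), ln))
        db.append((f"SP{i:04d}", pep))
    return db


def reverse_translate(peptide: str) -> str:
    return "".join(_CODON_OF[a] for a in peptide)


def generate_mirna_db(
    n: int = 12, seed: int = 0
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(mature 22-mers, precursor ~72-mers carrying a diverged mature copy).

    The mature copy inside each hairpin is mutated at three positions so
    that a planted perfect sponge site (the antisense of a mature
    sequence) cannot reach precursor-homology significance on its own;
    precursor ground truth stays separable from sponge ground truth.
    """
    rng = _rng(seed, _STREAM_MIRNA)
    letters = list("ACGU")
    mature, precursors = [], []
    for i in range(n):
        m = "".join(rng.choice(letters, 22))
        name = f"bta-miR-{1000 + i}"
        mature.append((name, m))
        diverged = list(m)
        for pos in (3, 10, 17):
            diverged[pos] = rng.choice([c for c in letters if c != diverged[pos]])
        flank5 = "".join(rng.choice(letters, 25))
        flank3 = "".join(rng.choice(letters, 25))
        precursors.append((f"bta-mir-{1000 + i}", flank5 + "".join(diverged) + flank3))
    return mature, precursors


def plant_sponge_sites(
    seqs: dict[str, str],
    targets: dict[str, list[str]],
    mature_db: Sequence[tuple[str, str]],
    seed: int = 0,
    max_orf_nt: int = 300,
) -> dict[str, str]:
    """Embed perfect antisense miRNA sites into chosen lncRNA sequences.

    ``targets`` maps lncRNA id -> list of miRNA ids to embed. Each site is
    the DNA reverse complement of the mature sequence, placed so planted
    sites do not overlap; sequences keep their length and stay below the
    ORF filter threshold.
    """
    rng = _rng(seed, _STREAM_MIRNA + 50)
    mature = dict(mature_db)
    out = dict(seqs)
    for lnc_id in sorted(targets):
        base = out[lnc_id]
        mirs = targets[lnc_id]
        site_len = 22
        for attempt in range(200):
            seq = base
            spans: list[tuple[int, int]] = []
            ok = True
            for mir_id in mirs:
                site = reverse_complement(mature[mir_id].replace("U", "T"))
                placed = False
                for _ in range(50):
                    p = int(rng.integers(0, len(seq) - site_len + 1))
                    if all(p + site_len <= s or p >= e for s, e in spans):
                        seq = seq[:p] + site + seq[p + site_len:]
                        spans.append((p, p + site_len))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok and max_orf_length(seq) <= max_orf_nt:
                out[lnc_id] = seq
                break
        else:
            raise RuntimeError(f"could not plant sponge sites into {lnc_id}")
    return out


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _loading(r: float) -> tuple[float, float]:
    return float(np.sign(r) * np.sqrt(abs(r))), float(np.sqrt(1.0 - abs(r)))


def generate_counts(
    cfg: SimulationConfig,
    novel_ids: Optional[Sequence[str]] = None,
    truth: Optional[GroundTruth] = None,
) -> tuple[dict[str, CountMatrix], GroundTruth]:
    """Per-tissue negative-binomial counts with planted DE and wiring.

    Rows are the novel lncRNA plus an mRNA panel (``MRNA_xxxxx``). DE
    transcripts get a multiplicative 2**de_log2fc group effect; each
    regulator shares a latent Gaussian factor with its target mRNA on the
    log2-mean scale, with loading sqrt(r_high) in the high-FE group and
    sqrt(r_low) in the low-FE group. The same planted structure is used
    in every tissue.
    """
    if novel_ids is None:
        _, novels, truth0 = generate_annotation(cfg)
        novel_ids = [t.id for t in novels]
        truth = truth0 if truth is None else truth
    if truth is None:
        truth = GroundTruth()
    novel_ids = list(novel_ids)
    mrna_ids = [f"MRNA_{i:05d}" for i in range(cfg.n_mrna)]
    all_ids = novel_ids + mrna_ids

    pick = _rng(cfg.seed, _STREAM_COUNTS - 1)
    # plant DE and regulators on transcripts that can survive the lncRNA
    # cascade (multi-exon novel classes), so downstream recovery is testable
    eligible = sorted(
        tid for tid in novel_ids if truth.true_class.get(tid, "u") in {"j", "u"}
    ) or list(novel_ids)
    if not truth.true_de and cfg.n_de:
        truth.true_de = set(
            pick.choice(eligible, size=cfg.n_de, replace=False).tolist()
        )
    if not truth.true_regulators and cfg.n_regulators:
        remaining = sorted(set(eligible) - truth.true_de)
        regs = pick.choice(remaining, size=cfg.n_regulators, replace=False).tolist()
        truth.true_regulators = set(regs)
        free_mrna = list(mrna_ids)
        for reg in sorted(regs):
            chosen = pick.choice(free_mrna, size=cfg.regulator_targets, replace=False)
            truth.regulator_targets[reg] = sorted(chosen.tolist())
            free_mrna = [m for m in free_mrna if m not in set(chosen.tolist())]
    if not truth.tissue_profile and cfg.n_tissue_specific:
        eligible = sorted(
            set(novel_ids) - truth.true_de - truth.true_regulators
        )
        n_ts = min(cfg.n_tissue_specific, len(eligible))
        ts_ids = pick.choice(eligible, size=n_ts, replace=False) if n_ts else []
        for tid in sorted(ts_ids.tolist() if n_ts else []):
            k = int(pick.integers(1, len(cfg.tissues)))
            tset = pick.choice(list(cfg.tissues), size=k, replace=False)
            truth.tissue_profile[tid] = set(tset.tolist())

    n = cfg.n_samples_per_group
    matrices: dict[str, CountMatrix] = {}
    for ti, tissue in enumerate(cfg.tissues):
        rng = _rng(cfg.seed, _STREAM_COUNTS + ti)
        mu = rng.uniform(3.0, 9.0, size=len(all_ids))  # log2 base mean
        # wired rows sit in the well-expressed range so counting noise
        # does not drown the planted co-expression
        wired = set(truth.true_regulators)
        for tg in truth.regulator_targets.values():
            wired |= set(tg)
        for tid in sorted(wired):
            mu[all_ids.index(tid)] = rng.uniform(6.5, 9.0)
        for tid, tissues_on in truth.tissue_profile.items():
            if tissue not in tissues_on:
                mu[all_ids.index(tid)] = -8.0  # effectively silent here
        sample_names = [
            f"{tissue[:3]}_{grp}_{k:02d}" for grp in GROUPS for k in range(n)
        ]
        groups = [GROUPS[0]] * n + [GROUPS[1]] * n
        log2mean = np.tile(mu[:, None], (1, 2 * n))
        id_index = {tid: i for i, tid in enumerate(all_ids)}
        # planted fold-change: lowFE group shifted
        for tid in sorted(truth.true_de):
            log2mean[id_index[tid], n:] += cfg.de_log2fc
        for reg in sorted(truth.regulator_targets):
            for tid in truth.regulator_targets[reg]:
                log2mean[id_index[tid], n:] += cfg.target_log2fc
        # biological noise, factor-structured for regulators and targets
        noise = rng.standard_normal((len(all_ids), 2 * n))
        z = cfg.bio_sd * noise
        for reg in sorted(truth.true_regulators):
            f_s = rng.standard_normal(2 * n)
            members = [reg] + truth.regulator_targets.get(reg, [])
            for grp_idx, r in ((0, cfg.wiring_r_high), (1, cfg.wiring_r_low)):
                cols = slice(0, n) if grp_idx == 0 else slice(n, 2 * n)
                a, b = _loading(r)
                for mem in members:
                    i = id_index[mem]
                    z[i, cols] = cfg.wiring_sd * (
                        a * f_s[cols] + b * noise[i, cols]
                    )
        log2mean = log2mean + z
        mean = np.exp2(log2mean)
        r_nb = 1.0 / cfg.nb_dispersion
        p_nb = r_nb / (r_nb + mean)
        counts = rng.negative_binomial(r_nb, p_nb)
        values = pd.DataFrame(counts, index=all_ids, columns=sample_names)
        meta = pd.DataFrame(
            {"tissue": tissue, "group": groups}, index=pd.Index(sample_names, name="sample")
        )
        matrices[tissue] = CountMatrix(values, meta)
    return matrices, truth


# ---------------------------------------------------------------------------
# QTL intervals and gene sets
# ---------------------------------------------------------------------------

QTL_TRAITS = (
    "residual feed intake",
    "dry matter intake",
    "feed conversion ratio",
    "rib fat thickness",
)


def generate_qtl(
    novels: Sequence[TranscriptModel],
    truth: GroundTruth,
    n_overlapped: int = 10,
    n_decoys: int = 10,
    seed: int = 0,
) -> list[QtlRecord]:
    """QTL intervals overlapping a known subset of novel loci, plus decoys."""
    rng = _rng(seed, _STREAM_QTL)
    records = []
    ordered = sorted(novels, key=lambda t: t.id)
    chosen = list(
        rng.choice(len(ordered), size=min(n_overlapped, len(ordered)), replace=False)
    )
    qid = 0
    for i in sorted(chosen):
        t = ordered[i]
        trait = QTL_TRAITS[qid % len(QTL_TRAITS)]
        pad = int(rng.integers(100, 2000))
        rec = QtlRecord(
            GenomicInterval(t.seqname, max(0, t.start - pad), t.end + pad),
            f"QTL:{50000 + qid}",
            trait,
        )
        records.append(rec)
        # the padded interval may graze neighbours of the anchor locus;
        # ground truth records every transcript it actually covers
        for other in ordered:
            if other.span.overlaps(rec.interval):
                truth.planted_qtl_overlaps.add(other.id)
        qid += 1
    for d in range(n_decoys):
        chrom = f"chr{d % 5 + 1}"
        start = 10_000 + (5000 + d) * 60_000  # far from every planted locus
        records.append(
            QtlRecord(
                GenomicInterval(chrom, start, start + int(rng.integers(5000, 20000))),
                f"QTL:{60000 + d}",
                QTL_TRAITS[d % len(QTL_TRAITS)],
            )
        )
    return records


def generate_catalogue(
    seqs: dict[str, str],
    candidates: Sequence[str],
    truth: GroundTruth,
    n_entries: int = 5,
    n_decoys: int = 3,
    divergence: float = 0.12,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """External lncRNA catalogue: diverged copies of known transcripts.

    Entries are ~88%-identity point-mutated copies of chosen candidate
    transcripts (well above nucleotide-homology significance) plus random
    decoy entries matching nothing.
    """
    rng = _rng(seed, _STREAM_ANNOT + 50)
    catalogue: list[tuple[str, str]] = []
    chosen = sorted(
        rng.choice(sorted(candidates), size=min(n_entries, len(candidates)), replace=False)
    )
    for i, lnc in enumerate(chosen):
        seq = list(seqs[lnc])
        n_mut = int(len(seq) * divergence)
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = rng.choice([c for c in "ACGT" if c != seq[pos]])
        catalogue.append((f"NONSYN{i:06d}", "".join(seq)))
        truth.true_catalogue_matches.add(lnc)
    for d in range(n_decoys):
        catalogue.append(
            (f"NONSYN_DECOY{d:03d}", "".join(rng.choice(list("ACGT"), 600)))
        )
    return catalogue


def generate_mirna_sets(
    truth: GroundTruth,
    mirna_ids: Sequence[str],
    n_decoy_sets: int = 4,
    seed: int = 0,
) -> dict[str, set[str]]:
    """miRNA annotation sets: one holding the planted sponge miRNAs, plus decoys."""
    rng = _rng(seed, _STREAM_GMT + 1)
    sets: dict[str, set[str]] = {}
    planted = set()
    for mirs in truth.true_sponges.values():
        planted |= mirs
    if planted:
        sets["PLANTED_SPONGE_MIRNAS"] = planted
    for d in range(n_decoy_sets):
        size = int(rng.integers(3, max(4, len(mirna_ids) // 2)))
        sets[f"DECOY_MIRNA_SET_{d}"] = set(
            rng.choice(list(mirna_ids), size=min(size, len(mirna_ids)), replace=False).tolist()
        )
    return sets


def generate_gene_sets(
    truth: GroundTruth,
    mrna_ids: Sequence[str],
    n_decoy_sets: int = 6,
    seed: int = 0,
) -> dict[str, set[str]]:
    """GMT-style sets: one per planted regulator's targets, plus decoys."""
    rng = _rng(seed, _STREAM_GMT)
    sets: dict[str, set[str]] = {}
    for i, reg in enumerate(sorted(truth.regulator_targets)):
        sets[f"PLANTED_TARGETS_{i}"] = set(truth.regulator_targets[reg])
    for d in range(n_decoy_sets):
        size = int(rng.integers(8, 25))
        sets[f"DECOY_SET_{d}"] = set(rng.choice(mrna_ids, size=size, replace=False).tolist())
    return sets


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    cfg: SimulationConfig
    reference: list[TranscriptModel]
    novel: list[TranscriptModel]
    truth: GroundTruth
    sequences: dict[str, str]
    protein_db: list[tuple[str, str]]
    mirna_mature: list[tuple[str, str]]
    mirna_precursors: list[tuple[str, str]]
    counts: dict[str, CountMatrix]
    qtl: list[QtlRecord]
    gene_sets: dict[str, set[str]]
    mirna_sets: dict[str, set[str]] = field(default_factory=dict)
    catalogue: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mrna_ids(self) -> list[str]:
        first = next(iter(self.counts.values()))
        return [i for i in first.values.index if i.startswith("MRNA_")]

    def write(self, outdir: Union[str, Path]) -> None:
        """Write every input file the pipeline stages consume."""
        from .enrichment import write_gmt
        from .gtf import write_gtf
        from .overlap import write_qtl_bed

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.reference, out / "reference.gtf")
        write_gtf(self.novel, out / "novel.gtf")
        write_fasta(self.sequences.items(), out / "novel.fa")
        write_fasta(self.protein_db, out / "proteins.fa")
        write_fasta(self.mirna_mature, out / "mirna_mature.fa")
        write_fasta(self.mirna_precursors, out / "mirna_precursor.fa")
        for tissue, cm in self.counts.items():
            cm.to_tsv(out / f"counts_{tissue}.tsv", out / f"meta_{tissue}.tsv")
        write_qtl_bed(self.qtl, out / "qtl.bed")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        write_gmt(self.mirna_sets, out / "mirna_sets.gmt")
        write_fasta(self.catalogue, out / "catalogue.fa")


def write_fasta(records, path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate every input of the pipeline with consistent ground truth."""
    reference, novel, truth = generate_annotation(cfg)
    sequences = generate_sequences(novel, cfg.orf_spec, cfg.seed)
    counts, truth = generate_counts(cfg, [t.id for t in novel], truth)
    protein_db = generate_protein_db(seed=cfg.seed)
    mature, precursors = generate_mirna_db(cfg.n_mirna, seed=cfg.seed)

    # plant sponge sites into multi-exon lncRNA-like novels
    rng = _rng(cfg.seed, _STREAM_MIRNA + 99)
    candidates = sorted(
        t.id
        for t in novel
        if t.n_exons >= 2 and truth.true_class.get(t.id) in {"j", "u"}
    )
    sponge_plan: dict[str, list[str]] = {}
    n_sponges = min(6, len(candidates))
    if n_sponges and mature:
        chosen = rng.choice(candidates, size=n_sponges, replace=False)
        for lnc in sorted(chosen.tolist()):
            k = int(rng.integers(1, min(3, len(mature)) + 1))
            mirs = rng.choice([m for m, _ in mature], size=k, replace=False)
            sponge_plan[lnc] = sorted(mirs.tolist())
        sequences = plant_sponge_sites(sequences, sponge_plan, mature, cfg.seed)
        truth.true_sponges = {k: set(v) for k, v in sponge_plan.items()}

    # plant one precursor-derived lncRNA
    if precursors and candidates:
        lnc = sorted(set(candidates) - set(sponge_plan))[0]
        pre_seq = precursors[0][1].replace("U", "T")
        seq = sequences[lnc]
        if len(seq) > len(pre_seq) + 10:
            for p in range(5, len(seq) - len(pre_seq), 11):
                trial = seq[:p] + pre_seq + seq[p + len(pre_seq):]
                if max_orf_length(trial) <= 300:
                    sequences[lnc] = trial
                    truth.true_precursors = {lnc}
                    break

    qtl = generate_qtl(novel, truth, seed=cfg.seed)
    mrna_ids = [f"MRNA_{i:05d}" for i in range(cfg.n_mrna)]
    gene_sets = generate_gene_sets(truth, mrna_ids, seed=cfg.seed)
    mirna_sets = generate_mirna_sets(truth, [m for m, _ in mature], seed=cfg.seed)
    catalogue = (
        generate_catalogue(sequences, candidates, truth, seed=cfg.seed)
        if candidates
        else []
    )
    return SyntheticStudy(
        cfg=cfg,
        reference=reference,
        novel=novel,
        truth=truth,
        sequences=sequences,
        protein_db=protein_db,
        mirna_mature=mature,
        mirna_precursors=precursors,
        counts=counts,
        qtl=qtl,
        gene_sets=gene_sets,
        mirna_sets=mirna_sets,
        catalogue=catalogue,
    )
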