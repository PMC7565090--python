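"""End-to-end orchestration and the relevant-lncRNA set arithmetic.

``run_pipeline`` executes the stages in their analysis order on a
synthetic study (or equivalent in-memory inputs): positional
classification, the lncRNA filter cascade, miRNA precursor/sponge
scans, per-tissue normalization + expression filtering, differential
expression, RIF regulator scoring, PCIT network construction, QTL
overlap and enrichment, ending in the DE/key set arithmetic.

``relevant_summary`` implements the bookkeeping that combines per-tissue
DE and key (RIF-significant) lncRNA into the study-wide relevant set:
unique DE, unique key, their intersection, and the inclusion-exclusion
union. ``load_published_tables`` ships the per-tissue DE and key
transcript ID lists printed in the source study, the only fully
published result data, so the arithmetic can be checked exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .classify import classify_catalogue
from .enrichment import fisher_enrich, hypergeom_enrich, results_frame
from .expression import CountMatrix, cpm, de_ttest, expressed_filter, tmm_factors, GROUPS
from .filters import FilterConfig, FilterReport, run_filter_cascade
from .mirna import NtScoring, precursor_match, sponge_profile
from .models import TranscriptModel
from .overlap import catalogue_homology, qtl_overlap
from .pcit import build_network
from .rif import rif_scores
from .simulate import SyntheticStudy

logger = logging.getLogger(__name__)

LNCRNA_CANDIDATE_CLASSES = frozenset({"i", "j", "o", "u", "x"})


@dataclass(frozen=True)
class TissueResultSet:
    tissue: str
    de_ids: frozenset[str]
    key_ids: frozenset[str]


@dataclass
class RelevantSummary:
    unique_de: int
    unique_key: int
    both: int
    relevant_union: int
    de_ids: set[str] = field(default_factory=set)
    key_ids: set[str] = field(default_factory=set)

    @property
    def relevant_ids(self) -> set[str]:
        return self.de_ids | self.key_ids


def relevant_summary(results: Sequence[TissueResultSet]) -> RelevantSummary:
    """Combine per-tissue DE and key sets by inclusion-exclusion."""
    de: set[str] = set()
    key: set[str] = set()
    for r in results:
        de |= r.de_ids
        key |= r.key_ids
    both = de & key
    return RelevantSummary(
        unique_de=len(de),
        unique_key=len(key),
        both=len(both),
        relevant_union=len(de) + len(key) - len(both),
        de_ids=de,
        key_ids=key,
    )


def load_published_tables() -> list[TissueResultSet]:
    """Per-tissue DE and key lncRNA ID lists as published (fixture data)."""
    data = resources.files("lncreg") / "data"
    de = pd.read_csv(str(data / "published_de_lncrna.tsv"), sep="\t")
    key = pd.read_csv(str(data / "published_key_lncrna.tsv"), sep="\t")
    tissues = sorted(set(de["tissue"]) | set(key["tissue"]))
    return [
        TissueResultSet(
            tissue=t,
            de_ids=frozenset(de.loc[de["tissue"] == t, "transcript"]),
            key_ids=frozenset(key.loc[key["tissue"] == t, "transcript"]),
        )
        for t in tissues
    ]


@dataclass
class PipelineResult:
    class_table: pd.DataFrame
    lncrna_ids: list[str]
    filter_report: FilterReport
    catalogue_table: pd.DataFrame
    precursor_hits: pd.DataFrame
    sponge_table: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    rif_tables: dict[str, pd.DataFrame]
    networks: dict[str, nx.Graph]
    expressed: dict[str, set[str]]
    tissue_results: list[TissueResultSet]
    summary: RelevantSummary
    qtl_table: pd.DataFrame
    mrna_enrichment: pd.DataFrame
    mirna_enrichment: pd.DataFrame


def run_pipeline(
    study: SyntheticStudy,
    filter_cfg: FilterConfig = FilterConfig(),
    de_alpha: float = 0.01,
    rif_sd: float = 2.57,
    site_scoring: NtScoring = NtScoring(),
    site_min_score: float = 160.0,
    site_max_energy: float = -20.0,
    enrich_fdr: float = 0.1,
) -> PipelineResult:
    """Run every stage on a synthetic study; deterministic given its seed."""
    # 1. positional classification; lncRNA candidates are the novel classes
    logger.info("classifying %d novel transcripts", len(study.novel))
    class_table = classify_catalogue(study.novel, study.reference)
    candidate_ids = set(
        class_table.loc[
            class_table["class_code"].isin(LNCRNA_CANDIDATE_CLASSES), "id"
        ]
    )
    candidates = [t for t in study.novel if t.id in candidate_ids]

    # 2. four-filter cascade + multi-exon rule
    lncrna_ids, filter_report = run_filter_cascade(
        candidates, study.sequences, study.protein_db, filter_cfg
    )
    logger.info("%d lncRNA survive the filter cascade", len(lncrna_ids))
    lncrna_seqs = {i: study.sequences[i] for i in lncrna_ids}

    # 3. homology to the external lncRNA catalogue
    catalogue_table = catalogue_homology(lncrna_seqs, study.catalogue)

    # 4. miRNA roles
    pre_rows = []
    for lnc in sorted(lncrna_ids):
        for hit in precursor_match(lnc, study.sequences[lnc], study.mirna_precursors):
            pre_rows.append(
                {"lncrna": lnc, "precursor": hit.target_id, "evalue": hit.evalue}
            )
    precursor_hits = pd.DataFrame(pre_rows, columns=["lncrna", "precursor", "evalue"])
    sponge_table = sponge_profile(
        lncrna_seqs,
        study.mirna_mature,
        site_scoring,
        site_min_score,
        site_max_energy,
    )

    # 4. per-tissue expression analysis
    de_tables: dict[str, pd.DataFrame] = {}
    rif_tables: dict[str, pd.DataFrame] = {}
    networks: dict[str, nx.Graph] = {}
    expressed: dict[str, set[str]] = {}
    tissue_results: list[TissueResultSet] = []
    mrna_ids = set(study.mrna_ids)
    for tissue in sorted(study.counts):
        cm = study.counts[tissue]
        keep_rows = [i for i in cm.values.index if i in set(lncrna_ids) | mrna_ids]
        cm = CountMatrix(cm.values.loc[keep_rows], cm.sample_meta)
        factors = tmm_factors(cm)
        expr_sets = expressed_filter(cm, factors)
        exp_ids = expr_sets[tissue]
        expressed[tissue] = exp_ids
        exp_lnc = sorted(i for i in exp_ids if i in set(lncrna_ids))
        exp_mrna = sorted(i for i in exp_ids if i in mrna_ids)

        de = de_ttest(cm, factors, transcripts=exp_lnc, alpha=de_alpha)
        de_tables[tissue] = de
        de_ids = frozenset(de.loc[de["de_flag"], "transcript"])

        key_ids: frozenset[str] = frozenset()
        if len(exp_lnc) >= 2 and len(exp_mrna) >= 2:
            logc = cpm(cm, factors, log2=True)
            meta = cm.sample_meta
            cols_a = meta.index[meta["group"] == GROUPS[0]]
            cols_b = meta.index[meta["group"] == GROUPS[1]]
            rif = rif_scores(
                logc.loc[exp_lnc + exp_mrna, cols_a],
                logc.loc[exp_lnc + exp_mrna, cols_b],
                regulators=exp_lnc,
                targets=exp_mrna,
                sd_threshold=rif_sd,
            )
            rif_tables[tissue] = rif
            key_ids = frozenset(rif.loc[rif["key_flag"], "regulator"])
            kinds = {i: ("lncRNA" if i in set(lncrna_ids) else "mRNA") for i in exp_ids}
            flags = {
                i: {"de": i in de_ids, "key": i in key_ids}
                for i in exp_lnc + exp_mrna
            }
            networks[tissue] = build_network(
                logc.loc[exp_lnc + exp_mrna], kinds, flags
            )
        tissue_results.append(TissueResultSet(tissue, de_ids, key_ids))

    summary = relevant_summary(tissue_results)

    # 5. QTL overlap of relevant lncRNA loci
    relevant_models = [t for t in study.novel if t.id in summary.relevant_ids]
    qtl_table = qtl_overlap(relevant_models, study.qtl)

    # 6. enrichment of co-expressed mRNA neighbors of key lncRNA
    enr_frames = []
    for tissue, net in networks.items():
        universe = {n for n in net.nodes if net.nodes[n].get("kind") == "mRNA"}
        if not universe:
            continue
        for r in tissue_results:
            if r.tissue != tissue:
                continue
            for lnc in sorted(r.key_ids | r.de_ids):
                if lnc not in net:
                    continue
                neighbors = {n for n in net.neighbors(lnc)} & universe
                if not neighbors:
                    continue
                res = hypergeom_enrich(neighbors, study.gene_sets, universe, enrich_fdr)
                frame = results_frame(res)
                frame.insert(0, "lncrna", lnc)
                frame.insert(0, "tissue", tissue)
                enr_frames.append(frame)
    mrna_enrichment = (
        pd.concat(enr_frames, ignore_index=True)
        if enr_frames
        else pd.DataFrame(
            columns=["tissue", "lncrna", "set_name", "k", "K", "n", "N", "p", "fdr", "enriched_flag"]
        )
    )

    # 7. miRNA enrichment for sponges of relevant lncRNA
    mirna_universe = {m for m, _ in study.mirna_mature}
    relevant_sponge = set(
        sponge_table.loc[
            sponge_table["lncrna"].isin(summary.relevant_ids), "mirna"
        ]
    )
    mirna_enrichment = results_frame(
        fisher_enrich(relevant_sponge, study.mirna_sets, mirna_universe, enrich_fdr)
    )

    return PipelineResult(
        class_table=class_table,
        lncrna_ids=sorted(lncrna_ids),
        filter_report=filter_report,
        catalogue_table=catalogue_table,
        precursor_hits=precursor_hits,
        sponge_table=sponge_table,
        de_tables=de_tables,
        rif_tables=rif_tables,
        networks=networks,
        expressed=expressed,
        tissue_results=tissue_results,
        summary=summary,
        qtl_table=qtl_table,
        mrna_enrichment=mrna_enrichment,
        mirna_enrichment=mirna_enrichment,
    )


def summary_report(result: PipelineResult) -> str:
    """Human-readable per-stage record counts."""
    lines = ["stage\tcount"]
    lines.append(f"novel_transcripts\t{len(result.class_table)}")
    for _, row in result.filter_report.to_frame().iterrows():
        lines.append(f"filter_{row['stage']}_surviving\t{row['surviving']}")
    lines.append(f"lncrna\t{len(result.lncrna_ids)}")
    lines.append(f"catalogue_matched\t{result.catalogue_table['lncrna'].nunique()}")
    lines.append(f"precursor_candidates\t{result.precursor_hits['lncrna'].nunique()}")
    lines.append(f"sponge_lncrna\t{result.sponge_table['lncrna'].nunique()}")
    for r in result.tissue_results:
        lines.append(f"de_{r.tissue}\t{len(r.de_ids)}")
        lines.append(f"key_{r.tissue}\t{len(r.key_ids)}")
    s = result.summary
    lines.append(f"unique_de\t{s.unique_de}")
    lines.append(f"unique_key\t{s.unique_key}")
    lines.append(f"de_and_key\t{s.both}")
    lines.append(f"relevant_union\t{s.relevant_union}")
    lines.append(f"qtl_overlap_pairs\t{len(result.qtl_table)}")
    return "\n".join(lines) + "\n"
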