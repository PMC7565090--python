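"""Over-representation tests for co-expressed mRNA and miRNA sets.

Gene-set enrichment of network neighbor mRNA uses an upper-tail
hypergeometric test with Benjamini-Hochberg correction (enriched at
FDR < 0.1). miRNA set enrichment uses a one-sided Fisher's exact test
with the same correction at 0.1. The universe defaults to all expressed
genes supplied by the caller; sets are intersected with it before
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap of query with the set
    K: int  # set size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p: float
    fdr: float
    enriched_flag: bool


def read_gmt(path: Union[str, Path]) -> dict[str, set[str]]:
    """GMT gene-set file: name, description, members (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(fields[2:]) - {""}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def _bh_and_flag(rows: list[dict], threshold: float) -> list[EnrichmentResult]:
    if not rows:
        return []
    pvals = [r["p"] for r in rows]
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(
            set_name=r["set_name"],
            k=r["k"],
            K=r["K"],
            n=r["n"],
            N=r["N"],
            p=r["p"],
            fdr=float(q),
            enriched_flag=bool(q < threshold),
        )
        for r, q in zip(rows, fdr)
    ]


def hypergeom_enrich(
    query: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of query in each set."""
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    return _bh_and_flag(rows, fdr_threshold)


def fisher_enrich(
    query_mirna: set[str],
    mirna_sets: Mapping[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact test (enrichment direction) per miRNA set."""
    if not query_mirna:
        return []
    if not universe:
        raise ValueError("empty universe")
    query = query_mirna & universe
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(mirna_sets):
        members = mirna_sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": float(p)})
    return _bh_and_flag(rows, fdr_threshold)


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=["set_name", "k", "K", "n", "N", "p", "fdr", "enriched_flag"],
    )
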