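"""PCIT co-expression edge significance and network construction.

The Partial Correlation and Information Theory (PCIT) algorithm keeps a
correlation edge (x, y) only if no third gene z can explain it away. For
every trio (x, y, z) the three first-order partial correlations are
computed; the trio's local tolerance is the mean ratio of partial to
direct correlation,

    eps = (1/3) * (rxy.z/rxy + rxz.y/rxz + ryz.x/ryz)

and the edge (x, y) is flagged non-significant when, for some z, both
|rxy| <= |eps * rxz| and |rxy| <= |eps * ryz|. Edges never flagged by
any trio survive. The enumeration is exact O(n^3), vectorized over the
third index.
"""

from __future__ import annotations

from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation of x and y given z."""
    denom_sq = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom_sq <= 0:
        raise ZeroDivisionError("degenerate trio: |rxz| or |ryz| is 1")
    return (rxy - rxz * ryz) / np.sqrt(denom_sq)


def pcit_edges(corr: np.ndarray) -> np.ndarray:
    """Boolean mask of PCIT-significant edges from a full correlation matrix.

    Trios with a zero direct correlation or a unit correlation in a
    partial's denominator are skipped (no flag from that trio).
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != n:
        raise ValueError("correlation matrix must be square")
    if n < 3:
        raise ValueError("PCIT needs at least 3 nodes")
    if np.isnan(corr).any():
        raise ValueError("correlation matrix contains NaN")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")

    flagged = np.zeros((n, n), dtype=bool)
    eye = np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            cz = corr[:, z]
            one_minus = 1.0 - cz**2
            # rxy.z over all pairs (x, y)
            pxy = (corr - np.outer(cz, cz)) / np.sqrt(np.outer(one_minus, one_minus))
            # rxz.y for pair (x, y): partial of (x, z) given y
            denom_b = np.sqrt((1.0 - corr**2) * one_minus[None, :])
            b = (cz[:, None] - corr * cz[None, :]) / denom_b
            eps = (pxy / corr + b / cz[:, None] + b.T / cz[None, :]) / 3.0
            cond = (np.abs(corr) <= np.abs(eps * cz[:, None])) & (
                np.abs(corr) <= np.abs(eps * cz[None, :])
            )
            valid = np.isfinite(eps)
            valid &= corr != 0
            valid &= (cz[:, None] != 0) & (cz[None, :] != 0)
            valid &= np.abs(cz[:, None]) < 1 - 1e-15
            valid &= np.abs(cz[None, :]) < 1 - 1e-15
            valid &= np.abs(corr) < 1 - 1e-15
            valid[:, z] = False
            valid[z, :] = False
            valid &= ~eye
            flagged |= cond & valid
    significant = ~flagged & ~eye & (corr != 0)
    return significant & significant.T


def build_network(
    expr: pd.DataFrame,
    node_kind: Optional[dict[str, str]] = None,
    node_flags: Optional[dict[str, dict[str, bool]]] = None,
    min_abs_corr: float = 0.0,
) -> nx.Graph:
    """PCIT-filtered co-expression network from log-expression rows.

    Pearson correlations across all samples, PCIT mask applied; edges
    weighted by the raw correlation. ``node_kind`` maps IDs to
    "lncRNA"/"mRNA"; ``node_flags`` attaches boolean attributes (e.g. DE,
    key).
    """
    ids = list(expr.index)
    x = expr.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x)
    # zero-variance rows yield NaN correlations; treat them as uncorrelated
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    mask = pcit_edges(corr)
    g = nx.Graph()
    for i, node in enumerate(ids):
        attrs = {"kind": (node_kind or {}).get(node, "mRNA")}
        if node_flags and node in node_flags:
            attrs.update(node_flags[node])
        g.add_node(node, **attrs)
    iu = np.triu_indices(len(ids), k=1)
    for i, j in zip(*iu):
        if mask[i, j] and abs(corr[i, j]) > min_abs_corr:
            g.add_edge(ids[i], ids[j], weight=float(corr[i, j]))
    return g


def first_neighbors(net: nx.Graph, node: str) -> nx.Graph:
    """Induced subgraph of a node and its direct partners."""
    if node not in net:
        raise KeyError(
            f"node {node!r} not in network; valid nodes include "
            f"{sorted(net.nodes)[:10]}..."
        )
    return net.subgraph([node, *net.neighbors(node)]).copy()


def degree_table(net: nx.Graph) -> pd.DataFrame:
    """Connectivity report sorted by degree (desc), then node ID."""
    rows = [
        {"node": n, "kind": net.nodes[n].get("kind", "?"), "degree": d}
        for n, d in net.degree()
    ]
    return (
        pd.DataFrame(rows, columns=["node", "kind", "degree"])
        .sort_values(["degree", "node"], ascending=[False, True])
        .reset_index(drop=True)
    )
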