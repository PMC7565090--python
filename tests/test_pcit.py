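"""PCIT edge significance: formula cases, brute-force oracle, simulations."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncreg.pcit import (
    build_network,
    degree_table,
    first_neighbors,
    partial_correlation,
    pcit_edges,
)


def pcit_bruteforce(c):
    """Independently coded triple loop over all ordered trios."""
    n = c.shape[0]
    flagged = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z in (x, y):
                    continue
                rxy, rxz, ryz = c[x, y], c[x, z], c[y, z]
                if 0.0 in (rxy, rxz, ryz):
                    continue
                if max(abs(rxy), abs(rxz), abs(ryz)) >= 1 - 1e-15:
                    continue
                pxy = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
                pxz = (rxz - rxy * ryz) / np.sqrt((1 - rxy**2) * (1 - ryz**2))
                pyz = (ryz - rxy * rxz) / np.sqrt((1 - rxy**2) * (1 - rxz**2))
                eps = (pxy / rxy + pxz / rxz + pyz / ryz) / 3.0
                if not np.isfinite(eps):
                    continue
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    flagged[x, y] = True
    sig = ~flagged & ~np.eye(n, dtype=bool)
    return sig & sig.T


@pytest.mark.parametrize(
    "rxy,rxz,ryz,expected",
    [
        (0.4, 0.0, 0.0, 0.4),  # conditioning on an unrelated gene is a no-op
        (0.35, 0.7, 0.5, 0.0),  # rxy = rxz*ryz: fully explained away
        (0.8, 0.5, 0.5, (0.8 - 0.25) / 0.75),  # direct formula, 0.7333...
    ],
)
def test_partial_correlation_formula(rxy, rxz, ryz, expected):
    assert partial_correlation(rxy, rxz, ryz) == pytest.approx(expected)


def test_partial_correlation_degenerate():
    with pytest.raises(ZeroDivisionError):
        partial_correlation(0.5, 1.0, 0.2)


def test_independent_third_gene_cannot_remove_an_edge():
    c = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
    mask = pcit_edges(c)
    assert mask[0, 1]


def test_mask_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(4, 16))
        x = rng.standard_normal((n, 20))
        c = np.corrcoef(x)
        assert (pcit_edges(c) == pcit_bruteforce(c)).all()


def test_mask_symmetric_and_permutation_equivariant():
    rng = np.random.default_rng(1)
    c = np.corrcoef(rng.standard_normal((10, 30)))
    mask = pcit_edges(c)
    assert (mask == mask.T).all()
    assert not mask.diagonal().any()
    perm = rng.permutation(10)
    mask_p = pcit_edges(c[np.ix_(perm, perm)])
    assert (mask_p == mask[np.ix_(perm, perm)]).all()


def test_input_validation():
    with pytest.raises(ValueError):
        pcit_edges(np.eye(2))
    c = np.eye(4)
    c[0, 1] = 0.5  # asymmetric
    with pytest.raises(ValueError):
        pcit_edges(c)
    c2 = np.eye(4)
    c2[0, 1] = c2[1, 0] = np.nan
    with pytest.raises(ValueError):
        pcit_edges(c2)


def test_chain_edge_removed_direct_edges_kept():
    """x <- z -> y with moderate links: the indirect edge is pruned far
    more often than the direct ones once correlations are well estimated."""
    a, n, n_seeds = 0.35, 200, 20
    removed_indirect = kept_direct = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        x = a * z + np.sqrt(1 - a * a) * rng.standard_normal(n)
        y = a * z + np.sqrt(1 - a * a) * rng.standard_normal(n)
        mask = pcit_edges(np.corrcoef([x, y, z]))
        removed_indirect += int(not mask[0, 1])
        kept_direct += int(mask[0, 2] and mask[1, 2])
    assert removed_indirect >= 0.9 * n_seeds
    assert kept_direct >= 0.9 * n_seeds


def test_exactly_uncorrelated_nodes_have_no_edges():
    """A diagonal correlation matrix yields an empty edge set."""
    c = np.eye(5)
    assert not pcit_edges(c).any()


def test_null_network_is_sparse():
    """Independent noise: most spurious correlations are pruned.

    The trio tolerance retains a minority of weak edges on pure noise
    (~15-20% here); the contrast with the planted-module test, where
    every within-module edge survives, is what carries the signal.
    """
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(
        rng.standard_normal((30, 40)), index=[f"G{i}" for i in range(30)]
    )
    net = build_network(expr)
    possible = 30 * 29 / 2
    assert net.number_of_edges() < 0.25 * possible


def test_planted_module_fully_connected():
    rng = np.random.default_rng(3)
    n_samples = 50
    factor = rng.standard_normal(n_samples)
    module = [
        0.95 * factor + np.sqrt(1 - 0.95**2) * rng.standard_normal(n_samples)
        for _ in range(5)
    ]
    noise = [rng.standard_normal(n_samples) for _ in range(10)]
    expr = pd.DataFrame(
        module + noise, index=[f"M{i}" for i in range(5)] + [f"N{i}" for i in range(10)]
    )
    net = build_network(expr)
    for i in range(5):
        for j in range(i + 1, 5):
            assert net.has_edge(f"M{i}", f"M{j}")


def test_first_neighbors_and_degree_report():
    g = nx.Graph()
    g.add_nodes_from(["a", "b", "c", "iso"], kind="mRNA")
    g.add_edge("a", "b", weight=0.9)
    g.add_edge("b", "c", weight=0.8)
    sub = first_neighbors(g, "a")
    assert set(sub.nodes) == {"a", "b"}
    iso = first_neighbors(g, "iso")
    assert set(iso.nodes) == {"iso"}
    with pytest.raises(KeyError):
        first_neighbors(g, "nope")
    table = degree_table(g)
    assert table.iloc[0]["node"] == "b" and table.iloc[0]["degree"] == 2


def test_edge_weights_are_pearson_r():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(60)
    expr = pd.DataFrame(
        [x, x + 0.1 * rng.standard_normal(60), rng.standard_normal(60)],
        index=["a", "b", "c"],
    )
    net = build_network(expr)
    expected = np.corrcoef(expr.loc["a"], expr.loc["b"])[0, 1]
    assert net["a"]["b"]["weight"] == pytest.approx(expected)
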