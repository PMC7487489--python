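import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mignet.diffexpr import ExpressionMatrix
from mignet.network import GENE_GENE, MIRNA_GENE, SignedRegulatoryNetwork


def build_network(gene_edges, mirna_edges=(), cell_fate=None):
    """Construct a SignedRegulatoryNetwork directly from edge tuples.

    gene_edges: iterable of (source, target, sign); mirna_edges:
    iterable of (mirna, gene) with sign forced to -1; cell_fate: mapping
    gene -> fate class.
    """
    g = nx.DiGraph()
    mirnas = {u for u, _ in mirna_edges}
    for u, v, s in gene_edges:
        g.add_edge(u, v, sign=s, kind=GENE_GENE)
    for u, v in mirna_edges:
        g.add_edge(u, v, sign=-1, kind=MIRNA_GENE)
    for n in g.nodes:
        g.nodes[n]["kind"] = "mirna" if n in mirnas else "gene"
    return SignedRegulatoryNetwork(g, dict(cell_fate or {}))


@pytest.fixture
def two_hop_network():
    """Two-hop toy topology: mir-5 -(-1)-> Gene1 -(+1)-> Gene*."""
    return build_network(
        gene_edges=[("Gene1", "Gene*", 1)],
        mirna_edges=[("mir-5", "Gene1")],
        cell_fate={"Gene*": "proliferation"},
    )


def make_expression(values, groups):
    """ExpressionMatrix from a dict of feature -> per-sample values."""
    sample_ids = [f"s{i}" for i in range(len(next(iter(values.values()))))]
    frame = pd.DataFrame(values, index=sample_ids).T
    return ExpressionMatrix(frame, pd.Series(groups, index=sample_ids))


def random_expression(rng, n_features=10, n_cancer=3, n_control=3, scale=50.0):
    samples = [f"c{i}" for i in range(n_cancer)] + [f"n{i}" for i in range(n_control)]
    values = pd.DataFrame(
        rng.uniform(0.0, scale, (n_features, len(samples))),
        index=[f"f{i}" for i in range(n_features)],
        columns=samples,
    )
    groups = pd.Series(
        ["cancer"] * n_cancer + ["control"] * n_control, index=samples
    )
    return ExpressionMatrix(values, groups)


def random_signed_digraph(rng, n_nodes, edge_prob=0.3, inhibition=0.5):
    """Random signed gene digraph plus one source miRNA node.

    Returns (network, mirna_id, gene_ids).  The miRNA targets a random
    non-empty subset of genes; it never receives edges.
    """
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    gene_edges = []
    for u in genes:
        for v in genes:
            if u != v and rng.random() < edge_prob:
                sign = -1 if rng.random() < inhibition else 1
                gene_edges.append((u, v, sign))
    k = int(rng.integers(1, max(2, n_nodes // 2)))
    hit = rng.choice(genes, size=min(k, n_nodes), replace=False)
    mirna_edges = [("mirX", str(g)) for g in hit]
    net = build_network(gene_edges, mirna_edges, cell_fate={})
    for g in genes:  # isolated genes stay part of the node universe
        if g not in net.graph:
            net.graph.add_node(g, kind="gene")
    return net, "mirX", genes


def enumerate_shortest_paths(net, source, target):
    """All minimum-length simple paths by exhaustive DFS (test oracle)."""
    best = {"L": None}
    found = []

    def dfs(node, path):
        if best["L"] is not None and len(path) - 1 > best["L"]:
            return
        if node == target and len(path) > 1:
            L = len(path) - 1
            if best["L"] is None or L < best["L"]:
                best["L"] = L
                found.clear()
            if L == best["L"]:
                found.append(list(path))
            return
        for nxt in net.graph.successors(node):
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(source, [source])
    return best["L"], found


def oracle_pair_sign(net, source, target, policy):
    """Pair sign by exhaustive shortest-path enumeration (test oracle)."""
    L, paths = enumerate_shortest_paths(net, source, target)
    assert paths, "oracle called on unreachable pair"

    def psign(path):
        s = 1
        for u, v in zip(path, path[1:]):
            s *= net.graph.edges[u, v]["sign"]
        return s

    signs = [psign(p) for p in paths]
    if policy == "lexicographic":
        return L, psign(min(paths))
    total = sum(signs)
    return L, (1 if total > 0 else (-1 if total < 0 else 0))
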