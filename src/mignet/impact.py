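"""Shortest-path impact scoring of miRNAs on cell-fate genes.

Each pair (miRNA *i*, cell-fate gene *j*) reachable in the signed
network is scored

    I_ij = S_ij * log2(FC_i) / L_ij

L_ij is the number of edges on the shortest directed path from *i* to
*j* and S_ij the product of edge signs along it (the miRNA's first hop
is always -1), so the perturbation decays linearly with path length and
flips sign at every inhibitory edge.  When several shortest paths exist
with conflicting sign products the pair sign is resolved by a policy:

``majority``
    sign held by the strict majority of all shortest paths, 0 on ties
    (the pair is flagged ambiguous and contributes nothing);
``lexicographic``
    sign of the shortest path minimal in node-id lexicographic order;
``all_paths_mean``
    sign of the mean of all shortest-path signs (0 when it vanishes) —
    for signs in {-1, +1} this coincides with ``majority``.

Majority and mean policies are computed exactly by a signed path-count
dynamic programme over the shortest-path DAG, so graphs with
exponentially many shortest paths are handled without enumeration.

Per-gene totals I_gene-j (sum over upstream miRNAs), per-miRNA totals
I_miR-i (sum over downstream cell-fate genes) and an absolute-magnitude
ranking of miRNAs complete the analysis.  I_gene-j > 0 means the gene
is promoted by its upstream miRNAs, I_gene-j < 0 that it is repressed;
symmetrically for I_miR-i.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from mignet.errors import ContractViolation
from mignet.network import APOPTOSIS, PROLIFERATION, SignedRegulatoryNetwork

POLICIES = ("majority", "lexicographic", "all_paths_mean")


@dataclasses.dataclass(frozen=True)
class PairImpact:
    """Impact of one miRNA on one cell-fate gene along shortest paths."""

    mirna_id: str
    gene_id: str
    L: int
    S: int
    log2fc: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ContractViolation("shortest-path length must be >= 1")
        if self.S not in (-1, 0, 1):
            raise ContractViolation("pair sign must be in {-1, 0, +1}")

    @property
    def I(self) -> float:
        return self.S * self.log2fc / self.L

    @property
    def ambiguous(self) -> bool:
        return self.S == 0


@dataclasses.dataclass
class ImpactSummary:
    """Aggregated impact tables and the critical-miRNA ranking.

    ``gene_table`` has one row per reached cell-fate gene
    (fate_class, I_gene, n_upstream); ``mirna_table`` one row per miRNA
    of the network (log2fc, I_miR, class averages over reached genes and
    over all class genes, rank).  ``ranking`` is the miRNA order by
    |I_miR| descending with lexicographic tie-break.
    """

    pair_table: pd.DataFrame
    gene_table: pd.DataFrame
    mirna_table: pd.DataFrame
    ranking: list[str]


def _bfs_dist(adj: Mapping[str, Sequence[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _adjacency(net: SignedRegulatoryNetwork) -> tuple[dict, dict]:
    fwd: dict[str, list[str]] = {}
    rev: dict[str, list[str]] = {}
    for u, v in net.graph.edges():
        fwd.setdefault(u, []).append(v)
        rev.setdefault(v, []).append(u)
    return fwd, rev


def shortest_path_length(
    net: SignedRegulatoryNetwork, source: str, target: str
) -> int | None:
    """Edges on the shortest directed path, or None when unreachable."""
    if source not in net.graph:
        raise KeyError(f"unknown node {source!r}")
    if target not in net.graph:
        raise KeyError(f"unknown node {target!r}")
    fwd, _ = _adjacency(net)
    dist = _bfs_dist(fwd, source)
    d = dist.get(target)
    return None if d is None or d == 0 else d


def path_sign(net: SignedRegulatoryNetwork, path: Sequence[str]) -> int:
    """Product of edge signs along a path given as a node sequence."""
    if len(path) < 2:
        raise ContractViolation("a path needs at least two nodes")
    sign = 1
    for u, v in zip(path, path[1:]):
        if not net.graph.has_edge(u, v):
            raise ContractViolation(f"({u!r}, {v!r}) is not an edge of the network")
        sign *= net.sign(u, v)
    return sign


def _signed_path_counts(
    net: SignedRegulatoryNetwork,
    source: str,
    ds: Mapping[str, int],
    dt: Mapping[str, int],
    length: int,
) -> tuple[int, int]:
    """Counts of shortest source->target paths with sign +1 and -1.

    ``ds``/``dt`` are BFS distances from the source / to the target; a
    node lies on some shortest path iff ds + dt == length.  Signed
    counts propagate along the shortest-path DAG in order of ds.
    """
    on_path = [
        n
        for n in ds
        if n in dt and ds[n] + dt[n] == length
    ]
    on_path.sort(key=lambda n: ds[n])
    pos = {source: 1}
    neg = {source: 0}
    for u in on_path:
        pu, nu = pos.get(u, 0), neg.get(u, 0)
        if pu == 0 and nu == 0:
            continue
        for v in net.graph.successors(u):
            if v in dt and ds.get(v) == ds[u] + 1 and ds[v] + dt[v] == length:
                if net.sign(u, v) == 1:
                    pos[v] = pos.get(v, 0) + pu
                    neg[v] = neg.get(v, 0) + nu
                else:
                    pos[v] = pos.get(v, 0) + nu
                    neg[v] = neg.get(v, 0) + pu
    target = next(n for n in dt if dt[n] == 0)
    return pos.get(target, 0), neg.get(target, 0)


def _lexicographic_sign(
    net: SignedRegulatoryNetwork,
    source: str,
    dt: Mapping[str, int],
    length: int,
) -> int:
    """Sign of the lexicographically minimal shortest path (greedy walk)."""
    sign = 1
    node = source
    remaining = length
    while remaining > 0:
        nxt = min(
            v
            for v in net.graph.successors(node)
            if dt.get(v) == remaining - 1
        )
        sign *= net.sign(node, nxt)
        node = nxt
        remaining -= 1
    return sign


def pair_sign(
    net: SignedRegulatoryNetwork,
    source: str,
    target: str,
    policy: str = "majority",
) -> int:
    """Resolved sign over all shortest source->target paths."""
    if policy not in POLICIES:
        raise ContractViolation(f"unknown sign policy {policy!r}")
    fwd, rev = _adjacency(net)
    ds = _bfs_dist(fwd, source)
    if target not in ds or ds[target] == 0:
        raise ContractViolation(f"{target!r} is unreachable from {source!r}")
    dt = _bfs_dist(rev, target)
    length = ds[target]
    if policy == "lexicographic":
        return _lexicographic_sign(net, source, dt, length)
    pos, neg = _signed_path_counts(net, source, ds, dt, length)
    if pos > neg:
        return 1
    if neg > pos:
        return -1
    return 0


def pair_impact(
    net: SignedRegulatoryNetwork,
    mirna_id: str,
    gene_id: str,
    log2fc: float,
    policy: str = "majority",
) -> PairImpact | None:
    """Score one (miRNA, cell-fate gene) pair; None when unreachable."""
    L = shortest_path_length(net, mirna_id, gene_id)
    if L is None:
        return None
    S = pair_sign(net, mirna_id, gene_id, policy)
    return PairImpact(mirna_id, gene_id, L, S, float(log2fc))


def score_pairs(
    net: SignedRegulatoryNetwork,
    log2fc: Mapping[str, float] | pd.Series,
    policy: str = "majority",
) -> pd.DataFrame:
    """Pair-impact table over every reachable (miRNA, cell-fate gene) pair.

    ``log2fc`` maps each miRNA node of the network to its log2 fold
    change.  Returns a DataFrame sorted by (mirna, gene) with columns
    ``mirna, gene, fate_class, L, S, log2fc, I, ambiguous``;
    unreachable pairs are omitted (they lie outside the summation index
    sets of the per-gene and per-miRNA totals).
    """
    if policy not in POLICIES:
        raise ContractViolation(f"unknown sign policy {policy!r}")
    fwd, rev = _adjacency(net)
    fate = net.cell_fate
    dist_to: dict[str, dict[str, int]] = {
        g: _bfs_dist(rev, g) for g in sorted(fate)
    }
    rows = []
    for mir in net.mirnas:
        fc = float(log2fc[mir])
        ds = _bfs_dist(fwd, mir)
        for gene in sorted(fate):
            L = ds.get(gene)
            if L is None or L == 0:
                continue
            dt = dist_to[gene]
            if policy == "lexicographic":
                S = _lexicographic_sign(net, mir, dt, L)
            else:
                pos, neg = _signed_path_counts(net, mir, ds, dt, L)
                S = 1 if pos > neg else (-1 if neg > pos else 0)
            rows.append(
                (mir, gene, fate[gene], L, S, fc, S * fc / L, S == 0)
            )
    return pd.DataFrame(
        rows,
        columns=["mirna", "gene", "fate_class", "L", "S", "log2fc", "I", "ambiguous"],
    )


def gene_impact(pairs: pd.DataFrame, gene_id: str) -> float:
    """Total impact of upstream miRNAs on one gene (sum of its pair impacts)."""
    return float(pairs.loc[pairs["gene"] == gene_id, "I"].sum())


def mirna_impact(pairs: pd.DataFrame, mirna_id: str) -> float:
    """Total impact of one miRNA over its reached cell-fate genes."""
    return float(pairs.loc[pairs["mirna"] == mirna_id, "I"].sum())


def rank_mirnas(mirna_impacts: Mapping[str, float], k: int | None = None) -> list[str]:
    """miRNA ids by |I_miR| descending, ties broken lexicographically."""
    if k is not None and k < 1:
        raise ContractViolation("k must be >= 1")
    order = sorted(mirna_impacts, key=lambda m: (-abs(mirna_impacts[m]), m))
    return order if k is None else order[:k]


def _class_average(sub: pd.DataFrame, fate: str, n_class_genes: int) -> tuple[float, float]:
    """(mean over reached class genes, sum over class genes / all class genes)."""
    cls = sub.loc[sub["fate_class"] == fate, "I"]
    reached = float(cls.mean()) if len(cls) else 0.0
    overall = float(cls.sum() / n_class_genes) if n_class_genes else 0.0
    return reached, overall


def summarize(
    net: SignedRegulatoryNetwork,
    log2fc: Mapping[str, float] | pd.Series,
    policy: str = "majority",
    pairs: pd.DataFrame | None = None,
) -> ImpactSummary:
    """Pair table, per-gene and per-miRNA totals, class averages and ranking.

    Class averages are reported with two denominators (the field offers
    no canonical one): ``avg_I_<class>`` divides by the number of class
    genes the miRNA actually reaches, ``avg_I_<class>_all`` by the total
    number of class genes in the network.  Genes with no upstream miRNA
    and miRNAs reaching no cell-fate gene appear with zero totals and a
    ``no_upstream``/``no_reached`` flag rather than being dropped.
    """
    if pairs is None:
        pairs = score_pairs(net, log2fc, policy)
    fate = net.cell_fate
    n_prolif = sum(1 for f in fate.values() if f == PROLIFERATION)
    n_apop = sum(1 for f in fate.values() if f == APOPTOSIS)

    gene_rows = []
    by_gene = dict(tuple(pairs.groupby("gene"))) if len(pairs) else {}
    for g in sorted(fate):
        sub = by_gene.get(g)
        total = float(sub["I"].sum()) if sub is not None else 0.0
        n_up = int(len(sub)) if sub is not None else 0
        gene_rows.append((g, fate[g], total, n_up, n_up == 0))
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene", "fate_class", "I_gene", "n_upstream", "no_upstream"]
    ).set_index("gene")

    mirna_rows = []
    by_mirna = dict(tuple(pairs.groupby("mirna"))) if len(pairs) else {}
    for m in net.mirnas:
        sub = by_mirna.get(m)
        if sub is None:
            sub = pairs.iloc[0:0]
        total = float(sub["I"].sum())
        avg_p, avg_p_all = _class_average(sub, PROLIFERATION, n_prolif)
        avg_a, avg_a_all = _class_average(sub, APOPTOSIS, n_apop)
        mirna_rows.append(
            (
                m,
                float(log2fc[m]),
                total,
                len(sub),
                avg_p,
                avg_a,
                avg_p_all,
                avg_a_all,
                len(sub) == 0,
            )
        )
    mirna_table = pd.DataFrame(
        mirna_rows,
        columns=[
            "mirna",
            "log2fc",
            "I_miR",
            "n_reached",
            "avg_I_proliferation",
            "avg_I_apoptosis",
            "avg_I_proliferation_all",
            "avg_I_apoptosis_all",
            "no_reached",
        ],
    ).set_index("mirna")
    ranking = rank_mirnas(mirna_table["I_miR"].to_dict())
    mirna_table["rank"] = pd.Series(
        {m: i + 1 for i, m in enumerate(ranking)}, dtype=int
    )
    mirna_table = mirna_table.loc[ranking]
    return ImpactSummary(pairs, gene_table, mirna_table, ranking)
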