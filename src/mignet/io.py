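"""Shared table readers and writers.

All tables are plain TSV with header rows.  Floats are serialised with
six significant digits so repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mignet.diffexpr import ExpressionMatrix
from mignet.errors import InputError, ParseError
from mignet.network import SignedEdge, SignedRegulatoryNetwork

FLOAT_FORMAT = "%.6g"


def read_expression(values_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Expression TSV (first column feature id) plus a sample->group TSV."""
    values_path, groups_path = Path(values_path), Path(groups_path)
    for p in (values_path, groups_path):
        if not p.exists():
            raise InputError(f"input file not found: {p}")
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    if values.shape[1] == 0:
        raise ParseError(f"{values_path}: no sample columns")
    groups = read_groups(groups_path)
    return ExpressionMatrix(values, groups)


def read_groups(path: str | Path) -> pd.Series:
    path = Path(path)
    if not path.exists():
        raise InputError(f"groups file not found: {path}")
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    if table.iloc[0, 0].lower() in ("sample", "sample_id"):
        table = table.iloc[1:]
    groups = pd.Series(
        table.iloc[:, 1].str.strip().str.lower().to_numpy(),
        index=table.iloc[:, 0].str.strip(),
        name="group",
    )
    if groups.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    return groups


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Re-read a DE table written by `write_table` (round-trip safe)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"DE table not found: {path}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2fc", "p_value", "fdr", "significant"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("significant", "untestable"):
        if col in table.columns and table[col].dtype == object:
            table[col] = table[col].astype(str).str.lower() == "true"
    return table


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_network(net: SignedRegulatoryNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Export the network as an edge-list TSV plus a node-annotation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"edges": out / "network_edges.tsv", "nodes": out / "network_nodes.tsv"}
    write_table(net.edge_records(), paths["edges"], index=False)
    write_table(net.node_records(), paths["nodes"], index=False)
    return paths


def read_network(net_dir: str | Path) -> SignedRegulatoryNetwork:
    """Re-load a network exported by `write_network`."""
    import networkx as nx

    net_dir = Path(net_dir)
    edges_path = net_dir / "network_edges.tsv"
    nodes_path = net_dir / "network_nodes.tsv"
    for p in (edges_path, nodes_path):
        if not p.exists():
            raise InputError(f"network export not found: {p}")
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
    edges = pd.read_csv(edges_path, sep="\t", dtype={"sign": int})
    graph = nx.DiGraph()
    cell_fate: dict[str, str] = {}
    for _, row in nodes.iterrows():
        graph.add_node(row["node"], kind=row["kind"])
        if row["fate_class"] in ("proliferation", "apoptosis"):
            cell_fate[row["node"]] = row["fate_class"]
    for _, row in edges.iterrows():
        graph.add_edge(
            row["source"], row["target"], sign=int(row["sign"]), kind=row["kind"]
        )
    return SignedRegulatoryNetwork(graph, cell_fate)


def read_targets(path: str | Path) -> list[SignedEdge]:
    """miRNA->target TSV; any annotation column is ignored, sign forced to -1."""
    from mignet.network import load_edges

    return load_edges(path, strict=False, kind="mirna_gene")
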