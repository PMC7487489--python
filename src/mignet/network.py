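"""Construction of the signed miRNA-gene regulatory network.

The network is built in two steps.  First the gene-gene regulatory
universe is traced backward from the cell-fate genes: only vertices with
a directed path into the cell-fate sink set are retained (cycles are
permitted and kept).  Second, every significantly differentially
expressed miRNA is attached as a source node with inhibitory (sign -1)
edges to those of its targets already present in the network — miRNAs
are assumed to repress their targets, so miRNA->gene edges are always
-1 regardless of the annotation in the interaction file.

Node kinds are ``gene`` and ``mirna``; miRNA nodes have out-edges only.
Edge signs are +1 (activation/promotion) or -1 (inhibition/repression).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import pandas as pd

from mignet.errors import ContractViolation, InputError, ParseError

logger = logging.getLogger(__name__)

GENE_GENE = "gene_gene"
MIRNA_GENE = "mirna_gene"
PROLIFERATION = "proliferation"
APOPTOSIS = "apoptosis"
FATE_CLASSES = (PROLIFERATION, APOPTOSIS)

#: Interaction-type strings understood out of the box (lower-cased).
DEFAULT_SIGN_VOCABULARY: dict[str, int] = {
    "activation": 1,
    "activate": 1,
    "activates": 1,
    "promote": 1,
    "promotes": 1,
    "promotion": 1,
    "+1": 1,
    "1": 1,
    "+": 1,
    "inhibition": -1,
    "inhibit": -1,
    "inhibits": -1,
    "repress": -1,
    "represses": -1,
    "repression": -1,
    "-1": -1,
    "-": -1,
}


@dataclasses.dataclass(frozen=True)
class SignedEdge:
    """One signed directed regulatory interaction."""

    source: str
    target: str
    sign: int
    kind: str = GENE_GENE

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ContractViolation(f"edge sign must be +1/-1, got {self.sign}")
        if self.kind not in (GENE_GENE, MIRNA_GENE):
            raise ContractViolation(f"unknown edge kind {self.kind!r}")
        if self.kind == MIRNA_GENE and self.sign != -1:
            raise ContractViolation("miRNA->gene edges are repressive (sign -1)")
        if self.source == self.target:
            raise ContractViolation(f"self-loop on {self.source!r}")


@dataclasses.dataclass(frozen=True)
class CellFateGene:
    gene_id: str
    fate_class: str

    def __post_init__(self) -> None:
        if self.fate_class not in FATE_CLASSES:
            raise InputError(
                f"fate class for {self.gene_id!r} must be one of {FATE_CLASSES}"
            )


class SignedRegulatoryNetwork:
    """Directed graph with signed edges, node kinds and cell-fate annotation.

    Wraps a :class:`networkx.DiGraph` whose nodes carry a ``kind``
    attribute (``gene`` | ``mirna``) and whose edges carry ``sign``
    (+1/-1) and ``kind`` attributes.  ``cell_fate`` maps each sink gene
    to its fate class.
    """

    def __init__(self, graph: nx.DiGraph, cell_fate: Mapping[str, str]):
        for g, fc in cell_fate.items():
            if fc not in FATE_CLASSES:
                raise InputError(f"bad fate class {fc!r} for {g!r}")
            if g not in graph:
                raise ContractViolation(f"cell-fate gene {g!r} not in graph")
        for node, data in graph.nodes(data=True):
            if data.get("kind") == "mirna" and graph.in_degree(node) > 0:
                raise ContractViolation(f"miRNA node {node!r} has in-edges")
        self.graph = graph
        self.cell_fate = dict(cell_fate)

    @property
    def mirnas(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"
        )

    @property
    def genes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"
        )

    def sign(self, source: str, target: str) -> int:
        return int(self.graph.edges[source, target]["sign"])

    def edge_records(self) -> pd.DataFrame:
        rows = [
            (u, v, int(d["sign"]), d["kind"])
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["source", "target", "sign", "kind"])

    def node_records(self) -> pd.DataFrame:
        rows = [
            (n, d["kind"], self.cell_fate.get(n, "none"))
            for n, d in self.graph.nodes(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["node", "kind", "fate_class"])

    def copy(self) -> "SignedRegulatoryNetwork":
        return SignedRegulatoryNetwork(self.graph.copy(), dict(self.cell_fate))


def _dedupe(edges: Iterable[SignedEdge], strict: bool) -> list[SignedEdge]:
    seen: dict[tuple[str, str], SignedEdge] = {}
    conflicts = 0
    for e in edges:
        key = (e.source, e.target)
        prev = seen.get(key)
        if prev is None:
            seen[key] = e
        elif prev.sign != e.sign:
            if strict:
                raise ParseError(
                    f"conflicting signs for duplicate edge {e.source}->{e.target}"
                )
            conflicts += 1
    if conflicts:
        logger.warning(
            "kept first occurrence of %d duplicate edges with conflicting signs",
            conflicts,
        )
    return list(seen.values())


def load_edges(
    path: str | Path,
    sign_vocabulary: Mapping[str, int] | None = None,
    strict: bool = True,
    kind: str = GENE_GENE,
    neutral_sign: int | None = 1,
) -> list[SignedEdge]:
    """Read a signed edge list from a TSV of (source, target, interaction) rows.

    Interaction strings are mapped to signs through ``sign_vocabulary``
    (case-insensitive; defaults cover activation/promote/inhibit/repress
    and literal +1/-1).  For ``kind="mirna_gene"`` the sign is forced to
    -1 whatever the annotation says, and a missing third column is
    allowed.  Unknown interaction strings are an error in strict mode;
    otherwise they receive ``neutral_sign`` (pass-through +1 by default)
    or are dropped when ``neutral_sign`` is None.  Malformed rows abort
    in strict mode and are skipped with a warning in lenient mode.
    Self-loops are always dropped with a warning; duplicate
    (source, target) rows with conflicting signs abort in strict mode
    and keep the first occurrence otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge file not found: {path}")
    vocab = {
        k.lower(): v for k, v in (sign_vocabulary or DEFAULT_SIGN_VOCABULARY).items()
    }
    edges: list[SignedEdge] = []
    bad_lines: list[int] = []
    unmapped_lines: list[int] = []
    neutral_count = 0
    self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("source", "mirna", "regulator"):
                continue  # optional header row
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                bad_lines.append(lineno)
                continue
            source, target = fields[0].strip(), fields[1].strip()
            if source == target:
                self_loops += 1
                logger.warning("dropping self-loop on %r (line %d)", source, lineno)
                continue
            if kind == MIRNA_GENE:
                sign = -1
            else:
                if len(fields) < 3 or not fields[2].strip():
                    bad_lines.append(lineno)
                    continue
                word = fields[2].strip().lower()
                if word in vocab:
                    sign = vocab[word]
                elif strict:
                    unmapped_lines.append(lineno)
                    continue
                elif neutral_sign is None:
                    neutral_count += 1
                    continue
                else:
                    sign = neutral_sign
                    neutral_count += 1
            edges.append(SignedEdge(source, target, sign, kind))
    if strict and (bad_lines or unmapped_lines):
        parts = []
        if bad_lines:
            parts.append(f"malformed rows at lines {bad_lines}")
        if unmapped_lines:
            parts.append(f"unmappable interaction strings at lines {unmapped_lines}")
        raise ParseError(f"{path}: " + "; ".join(parts))
    for lineno in bad_lines:
        logger.warning("%s: skipping malformed row at line %d", path, lineno)
    if neutral_count:
        logger.info(
            "%s: %d edges with unknown interaction type (%s)",
            path,
            neutral_count,
            "dropped" if neutral_sign is None else f"mapped to {neutral_sign:+d}",
        )
    return _dedupe(edges, strict)


def load_cell_fate(path: str | Path) -> dict[str, str]:
    """Read the cell-fate gene list from a two-column TSV or a GMT file.

    TSV rows are ``gene<TAB>fate_class``; a GMT file must contain two
    gene sets named ``proliferation`` and ``apoptosis``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cell-fate file not found: {path}")
    fate: dict[str, str] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for raw in fh:
                fields = raw.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                name = fields[0].strip().lower()
                if name not in FATE_CLASSES:
                    raise ParseError(
                        f"{path}: GMT set {fields[0]!r} is not proliferation/apoptosis"
                    )
                for g in fields[2:]:
                    if g.strip():
                        fate[g.strip()] = name
        if not fate:
            raise ParseError(f"{path}: no gene sets found")
        return fate
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("gene", "gene_id"):
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}: malformed row at line {lineno}")
            gene, fc = fields[0].strip(), fields[1].strip().lower()
            if fc not in FATE_CLASSES:
                raise ParseError(
                    f"{path}: fate class {fields[1]!r} at line {lineno} "
                    f"must be one of {FATE_CLASSES}"
                )
            fate[gene] = fc
    return fate


def _reverse_reachable(
    adj_rev: Mapping[str, list[str]], sinks: Iterable[str], max_depth: int | None
) -> set[str]:
    """Vertices with a directed path into the sink set (BFS on reversed edges)."""
    seen = set(sinks)
    frontier = deque((s, 0) for s in seen)
    while frontier:
        node, depth = frontier.popleft()
        if max_depth is not None and depth >= max_depth:
            continue
        for pred in adj_rev.get(node, ()):
            if pred not in seen:
                seen.add(pred)
                frontier.append((pred, depth + 1))
    return seen


def trace_upstream(
    edges: Iterable[SignedEdge],
    cell_fate: Mapping[str, str] | Iterable[CellFateGene],
    max_depth: int | None = None,
) -> SignedRegulatoryNetwork:
    """Back-trace the regulatory universe from the cell-fate sink genes.

    Returns the vertex-induced subgraph on all vertices that reach at
    least one cell-fate gene by a directed path (cycles retained),
    together with the cell-fate genes themselves.  Cell-fate genes
    absent from the edge universe are kept as isolated annotated nodes
    with a warning.  ``max_depth`` optionally limits the number of
    back-trace steps.
    """
    if not isinstance(cell_fate, Mapping):
        cell_fate = {g.gene_id: g.fate_class for g in cell_fate}
    if not cell_fate:
        raise InputError("cell-fate gene set is empty")
    edges = list(edges)
    adj_rev: dict[str, list[str]] = {}
    universe: set[str] = set()
    for e in edges:
        if e.kind != GENE_GENE:
            raise ContractViolation("trace_upstream expects gene-gene edges only")
        adj_rev.setdefault(e.target, []).append(e.source)
        universe.add(e.source)
        universe.add(e.target)
    missing = sorted(set(cell_fate) - universe)
    if missing:
        logger.warning(
            "%d cell-fate genes absent from the edge universe (kept isolated): %s",
            len(missing),
            missing[:10],
        )
    keep = _reverse_reachable(adj_rev, cell_fate, max_depth)
    graph = nx.DiGraph()
    graph.add_nodes_from((n, {"kind": "gene"}) for n in keep | set(cell_fate))
    graph.add_edges_from(
        (e.source, e.target, {"sign": e.sign, "kind": e.kind})
        for e in edges
        if e.source in keep and e.target in keep
    )
    return SignedRegulatoryNetwork(graph, cell_fate)


def attach_mirnas(
    net: SignedRegulatoryNetwork,
    targets: Iterable[SignedEdge],
    de_mirnas: pd.DataFrame,
) -> tuple[SignedRegulatoryNetwork, dict[str, int]]:
    """Attach significantly differentially expressed miRNAs to the gene network.

    ``de_mirnas`` is a DE table (indexed by miRNA id with a boolean
    ``significant`` column).  Each significant miRNA with at least one
    target gene already present in the network is added as a ``mirna``
    node with sign -1 edges to those targets.  Gene-gene edges are never
    modified.  Returns the augmented network plus a diagnostics dict
    with counts of attached and skipped miRNAs.
    """
    targets = list(targets)
    for e in targets:
        if e.kind != MIRNA_GENE:
            raise ContractViolation("attach_mirnas expects mirna_gene edges")
    significant = set(de_mirnas.index[de_mirnas["significant"].astype(bool)])
    if not significant:
        logger.warning("no significant miRNAs: network left unchanged")
    by_mirna: dict[str, set[str]] = {}
    for e in targets:
        by_mirna.setdefault(e.source, set()).add(e.target)
    out = net.copy()
    gene_nodes = set(out.graph) - set(out.mirnas)
    attached = 0
    no_target = 0
    for mir in sorted(significant):
        hits = sorted(by_mirna.get(mir, set()) & gene_nodes)
        if not hits:
            no_target += 1
            continue
        out.graph.add_node(mir, kind="mirna")
        for g in hits:
            out.graph.add_edge(mir, g, sign=-1, kind=MIRNA_GENE)
        attached += 1
    diagnostics = {
        "significant_mirnas": len(significant),
        "mirnas_attached": attached,
        "mirnas_without_in_network_targets": no_target,
    }
    logger.info(
        "attached %d miRNAs (%d significant; %d with no in-network target)",
        attached,
        len(significant),
        no_target,
    )
    return SignedRegulatoryNetwork(out.graph, out.cell_fate), diagnostics
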