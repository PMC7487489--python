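"""Seeded synthetic benchmark inputs for the whole pipeline.

The generator emulates the four study inputs: a layered signed
gene-gene regulatory graph whose final layer is the cell-fate sink set,
a miRNA target map, and group-structured miRNA/mRNA expression matrices
with planted fold changes.  Gene layers only feed forward (layer t ->
layer t+1, optional skip and back edges), which keeps shortest paths
unique with high probability and isolates the path-scoring arithmetic;
a ``cyclic`` switch adds back-edges to exercise cycle handling.

Expression is log-normal: each feature draws a baseline log2 abundance,
each sample adds Gaussian noise on the log2 scale, and planted driver
miRNAs have their cancer-group mean multiplied by 2**log2fc.  All
randomness flows from the single integer ``seed`` through one
``numpy.random.default_rng`` stream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mignet.diffexpr import ExpressionMatrix
from mignet.errors import ConfigError
from mignet.network import (
    APOPTOSIS,
    GENE_GENE,
    MIRNA_GENE,
    PROLIFERATION,
    SignedEdge,
    SignedRegulatoryNetwork,
    trace_upstream,
)


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults describe a small three-layer regulatory cascade with a
    9:3 proliferation:apoptosis sink split (mirroring the roughly 3.5:1
    class imbalance of curated cell-fate gene lists), 20+20 samples and
    biological noise of 0.5 on the log2 scale.
    """

    n_genes: int = 45
    n_layers: int = 3
    n_mirnas: int = 15
    n_cellfate: int = 12
    n_proliferation: int = 9
    edge_density: float = 0.12
    inhibition_fraction: float = 0.1
    targets_per_mirna: int = 3
    #: (miRNA index, planted log2 fold change) pairs; all other miRNAs are null.
    planted_drivers: list[tuple[int, float]] = dataclasses.field(default_factory=list)
    #: When set, planted drivers target this fraction of first-layer genes
    #: instead of `targets_per_mirna` random genes.
    driver_target_fraction: float | None = None
    #: Non-planted miRNAs receive a uniform log2 shift in [-max, max]
    #: (0 means truly null background).
    background_log2fc_max: float = 0.0
    perturb_mrna: bool = False
    cyclic: bool = False
    noise_sd: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    n_cancer: int = 20
    n_control: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cellfate > self.n_genes:
            raise ConfigError("n_cellfate cannot exceed n_genes")
        if self.n_proliferation > self.n_cellfate:
            raise ConfigError("n_proliferation cannot exceed n_cellfate")
        if self.n_layers < 1:
            raise ConfigError("need at least one layer")
        if self.n_layers > 1 and self.n_genes - self.n_cellfate < self.n_layers - 1:
            raise ConfigError("not enough genes to populate every upstream layer")
        if self.n_layers == 1 and self.n_genes != self.n_cellfate:
            raise ConfigError("with one layer every gene must be a cell-fate gene")
        if not 0 < self.edge_density <= 1:
            raise ConfigError("edge_density must lie in (0, 1]")
        if not 0 <= self.inhibition_fraction <= 1:
            raise ConfigError("inhibition_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.n_cancer < 2 or self.n_control < 2:
            raise ConfigError("need at least 2 samples per group")
        for idx, _ in self.planted_drivers:
            if not 0 <= idx < self.n_mirnas:
                raise ConfigError(f"planted driver index {idx} out of range")

    @property
    def mirna_ids(self) -> list[str]:
        width = len(str(max(self.n_mirnas - 1, 1)))
        return [f"mir-{i:0{width}d}" for i in range(self.n_mirnas)]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(max(self.n_genes - 1, 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


def _layer_assignment(spec: SyntheticSpec) -> list[list[str]]:
    genes = spec.gene_ids
    sinks = genes[-spec.n_cellfate:]
    upstream = genes[: spec.n_genes - spec.n_cellfate]
    if spec.n_layers == 1:
        return [sinks]
    layers = [[str(g) for g in part] for part in np.array_split(upstream, spec.n_layers - 1)]
    layers.append(sinks)
    return layers


def generate_network(
    spec: SyntheticSpec,
) -> tuple[SignedRegulatoryNetwork, list[SignedEdge], dict]:
    """Layered signed gene graph plus miRNA target edges and ground truth.

    Every non-sink gene is guaranteed at least one outgoing edge so the
    whole gene universe reaches the sink layer.  Returns the traced
    network (genes only; miRNAs are attached downstream after DE), the
    miRNA target edge list, and a ground-truth dict (layers, planted
    drivers, cell-fate classes).
    """
    rng = np.random.default_rng(spec.seed)
    layers = _layer_assignment(spec)
    sinks = layers[-1]
    fate = {
        g: (PROLIFERATION if i < spec.n_proliferation else APOPTOSIS)
        for i, g in enumerate(sinks)
    }
    edges: list[SignedEdge] = []
    seen: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v and (u, v) not in seen:
            seen.add((u, v))
            sign = -1 if rng.random() < spec.inhibition_fraction else 1
            edges.append(SignedEdge(u, v, sign, GENE_GENE))

    for t in range(len(layers) - 1):
        cur, nxt = layers[t], layers[t + 1]
        fed: set[str] = set()
        for u in cur:
            hit = False
            for v in nxt:
                if rng.random() < spec.edge_density:
                    add(u, v)
                    hit = True
                    fed.add(v)
            if not hit:  # keep every upstream gene connected to the cascade
                v = nxt[rng.integers(len(nxt))]
                add(u, v)
                fed.add(v)
        for v in nxt:  # and every downstream gene reachable from it
            if v not in fed:
                add(cur[rng.integers(len(cur))], v)
    if spec.cyclic and len(layers) > 2:
        # a few back-edges from deep layers to layer 0 to exercise cycles
        n_back = max(1, spec.n_genes // 20)
        for _ in range(n_back):
            deep = layers[rng.integers(1, len(layers) - 1)]
            add(deep[rng.integers(len(deep))], layers[0][rng.integers(len(layers[0]))])

    planted = dict(spec.planted_drivers)
    mirna_ids = spec.mirna_ids
    targets: list[SignedEdge] = []
    first_layer = layers[0]
    for i, mir in enumerate(mirna_ids):
        if i in planted and spec.driver_target_fraction is not None:
            k = max(1, round(spec.driver_target_fraction * len(first_layer)))
            hit_genes = rng.choice(first_layer, size=k, replace=False)
        else:
            k = min(spec.targets_per_mirna, spec.n_genes)
            hit_genes = rng.choice(spec.gene_ids, size=k, replace=False)
        for g in sorted(str(g) for g in hit_genes):
            targets.append(SignedEdge(mir, g, -1, MIRNA_GENE))

    net = trace_upstream(edges, fate)
    truth = {
        "layers": [list(layer) for layer in layers],
        "cell_fate": fate,
        "planted_drivers": {mirna_ids[i]: float(fc) for i, fc in planted.items()},
        "seed": spec.seed,
    }
    return net, targets, truth


def generate_expression(
    spec: SyntheticSpec,
    targets: list[SignedEdge] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series]:
    """miRNA and mRNA expression matrices plus the sample-group labelling.

    Planted driver miRNAs get their cancer-group mean multiplied by
    2**log2fc; every other feature differs between groups only through
    i.i.d. Gaussian noise (sd ``noise_sd``) on the log2 scale.  With
    ``perturb_mrna`` the direct targets of each planted driver are
    shifted in the cancer group by half the driver's log2fc with
    opposite sign, emulating repression, so cell-fate gene DE can be
    exercised end to end.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of topology stream
    samples = [f"C{i:03d}" for i in range(spec.n_cancer)] + [
        f"N{i:03d}" for i in range(spec.n_control)
    ]
    groups = pd.Series(
        ["cancer"] * spec.n_cancer + ["control"] * spec.n_control,
        index=samples,
        name="group",
    )
    is_cancer = np.array([1.0] * spec.n_cancer + [0.0] * spec.n_control)

    def matrix(ids: list[str], shifts: dict[str, float]) -> pd.DataFrame:
        base = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, len(ids))
        noise = rng.normal(0.0, spec.noise_sd, (len(ids), len(samples)))
        log2 = base[:, None] + noise
        for row, fid in enumerate(ids):
            if fid in shifts:
                log2[row] += shifts[fid] * is_cancer
        return pd.DataFrame(2.0 ** log2, index=ids, columns=samples)

    planted = {spec.mirna_ids[i]: fc for i, fc in dict(spec.planted_drivers).items()}
    shifts = dict(planted)
    if spec.background_log2fc_max > 0:
        for mid in spec.mirna_ids:
            if mid not in shifts:
                shifts[mid] = float(
                    rng.uniform(-spec.background_log2fc_max, spec.background_log2fc_max)
                )
    mirna = ExpressionMatrix(matrix(spec.mirna_ids, shifts), groups)

    gene_shifts: dict[str, float] = {}
    if spec.perturb_mrna and targets is not None:
        for e in targets:
            if e.source in planted:
                shift = -0.5 * planted[e.source]
                gene_shifts[e.target] = gene_shifts.get(e.target, 0.0) + shift
    mrna = ExpressionMatrix(matrix(spec.gene_ids, gene_shifts), groups)
    return mirna, mrna, groups


def recovery_benchmark_spec(seed: int, driver_log2fc: float = 3.0) -> SyntheticSpec:
    """Driver-recovery benchmark instance.

    One planted driver (miRNA index 0) with |log2FC| = ``driver_log2fc``
    targeting 30% of the first-layer genes, against background miRNAs
    whose true |log2FC| stays below 0.5.  The driver's sign alternates
    with the seed so both over- and under-expressed drivers are covered.
    """
    sign = 1.0 if seed % 2 == 0 else -1.0
    return SyntheticSpec(
        planted_drivers=[(0, sign * driver_log2fc)],
        driver_target_fraction=0.3,
        background_log2fc_max=0.5,
        seed=seed,
    )


def write_inputs(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs plus ground truth under ``out_dir``.

    Produces ``mirna_expression.tsv``, ``mrna_expression.tsv``,
    ``groups.tsv``, ``edges.tsv``, ``targets.tsv``, ``cell_fate.tsv``
    and ``truth.yaml`` in exactly the formats the reader functions
    consume.  Returns the path of each file by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, targets, truth = generate_network(spec)
    mirna, mrna, groups = generate_expression(spec, targets)

    paths = {
        "mirna": out / "mirna_expression.tsv",
        "mrna": out / "mrna_expression.tsv",
        "groups": out / "groups.tsv",
        "edges": out / "edges.tsv",
        "targets": out / "targets.tsv",
        "cellfate": out / "cell_fate.tsv",
        "truth": out / "truth.yaml",
    }
    mirna.values.to_csv(paths["mirna"], sep="\t", index_label="feature_id")
    mrna.values.to_csv(paths["mrna"], sep="\t", index_label="feature_id")
    groups.rename_axis("sample_id").to_csv(paths["groups"], sep="\t")
    edge_rows = [
        (u, v, "activation" if int(d["sign"]) == 1 else "inhibition")
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(sorted(edge_rows), columns=["source", "target", "interaction"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    pd.DataFrame(
        sorted((e.source, e.target) for e in targets), columns=["mirna", "gene"]
    ).to_csv(paths["targets"], sep="\t", index=False)
    pd.DataFrame(
        sorted(net.cell_fate.items()), columns=["gene", "fate_class"]
    ).to_csv(paths["cellfate"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths
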