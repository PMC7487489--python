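"""End-to-end pipeline: differential expression -> network -> impact.

`run_pipeline` chains the three stages, writes every intermediate and
final table under the output directory, and records a run manifest
(package version, configuration hash, per-stage counts and warnings).
Given identical inputs and configuration the outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from mignet import __version__, diffexpr, impact, io, network
from mignet.config import RunConfig
from mignet.errors import ConfigError, MignetError

logger = logging.getLogger(__name__)


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MignetError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return wrapper

    return decorate


@_stage("de")
def _run_de(config: RunConfig, out: Path, manifest: dict):
    if not config.mirna_expression or not config.groups:
        raise ConfigError("mirna_expression and groups paths are required")
    mirna = io.read_expression(config.mirna_expression, config.groups)
    de_mirna = diffexpr.differential_expression(
        mirna,
        alpha=config.alpha,
        fc_threshold=config.fc_threshold,
        method=config.method,
        pseudocount=config.pseudocount,
    )
    io.write_table(de_mirna, out / "de_mirna.tsv")
    manifest["counts"]["mirnas_tested"] = int(len(de_mirna))
    manifest["counts"]["mirnas_significant"] = int(de_mirna["significant"].sum())

    de_cellfate = None
    if config.mrna_expression:
        mrna = io.read_expression(config.mrna_expression, config.groups)
        de_mrna = diffexpr.differential_expression(
            mrna,
            alpha=config.alpha,
            fc_threshold=config.fc_threshold,
            method=config.method,
            pseudocount=config.pseudocount,
        )
        io.write_table(de_mrna, out / "de_mrna.tsv")
        manifest["counts"]["mrnas_tested"] = int(len(de_mrna))
        if config.cell_fate:
            fate = network.load_cell_fate(config.cell_fate)
            de_cellfate = diffexpr.restrict_to_features(
                de_mrna,
                sorted(fate),
                readjust=config.readjust_cellfate,
                alpha=config.alpha,
                fc_threshold=config.fc_threshold,
            )
            io.write_table(de_cellfate, out / "de_cellfate.tsv")
            manifest["counts"]["cellfate_genes_significant"] = int(
                de_cellfate["significant"].sum()
            )
    return de_mirna, de_cellfate


@_stage("build")
def _run_build(config: RunConfig, de_mirna, out: Path, manifest: dict):
    for key in ("edges", "targets", "cell_fate"):
        if not getattr(config, key):
            raise ConfigError(f"{key} path is required")
    edges = network.load_edges(config.edges, strict=config.strict)
    fate = network.load_cell_fate(config.cell_fate)
    targets = io.read_targets(config.targets)
    gene_net = network.trace_upstream(edges, fate, max_depth=config.max_depth)
    net, diag = network.attach_mirnas(gene_net, targets, de_mirna)
    io.write_network(net, out)
    manifest["counts"]["edges_read"] = len(edges)
    manifest["counts"]["genes_traced"] = len(net.genes)
    manifest["counts"].update(diag)
    return net


@_stage("impact")
def _run_impact(config: RunConfig, net, de_mirna, out: Path, manifest: dict):
    log2fc = de_mirna["log2fc"].to_dict()
    summary = impact.summarize(net, log2fc, policy=config.policy)
    io.write_table(summary.pair_table, out / "pair_impacts.tsv", index=False)
    io.write_table(summary.gene_table, out / "gene_impacts.tsv")
    io.write_table(summary.mirna_table, out / "mirna_impacts.tsv")
    top = summary.ranking[: config.top_k]
    ranking_json = {
        "ranking": top,
        "I_miR": {m: round(float(summary.mirna_table.loc[m, "I_miR"]), 6) for m in top},
    }
    with open(out / "ranking.json", "w") as fh:
        json.dump(ranking_json, fh, indent=2, sort_keys=True)
    manifest["counts"]["pairs_scored"] = int(len(summary.pair_table))
    manifest["counts"]["pairs_ambiguous"] = int(summary.pair_table["ambiguous"].sum())
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run de -> build -> impact and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mignet",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "counts": {},
    }
    de_mirna, _ = _run_de(config, out, manifest)
    net = _run_build(config, de_mirna, out, manifest)
    _run_impact(config, net, de_mirna, out, manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
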