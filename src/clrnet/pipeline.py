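"""End-to-end orchestration: differential filter -> CLR network ->
bottlenecks -> communities/enrichment -> cross-network comparison.

A YAML config describes one or more datasets plus comparison settings; each
dataset run writes every stage output under its own subdirectory together
with a JSON manifest of parameters and per-stage row counts (so e.g. the
number of probes dropped for having no edges can be audited). Reruns with
the same config and seed are byte-identical up to the manifest timestampless
content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from . import (
    clr,
    coherence,
    communities,
    diffexpr,
    expr_data,
    multinet,
    synthetic,
    topology,
)

logger = logging.getLogger("clrnet")

DEFAULT_Z_GRID = [round(0.25 * i, 2) for i in range(2, 49)]  # 0.5 .. 12.0


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass(frozen=True)
class DatasetConfig:
    label: str
    expression: Path
    design: Path
    annotation: Path
    z_threshold: float | None = None
    target_nodes: int | None = None
    match_nodes_to: str | None = None  # label of an earlier dataset to match
    z_grid: tuple[float, ...] = tuple(DEFAULT_Z_GRID)
    bottleneck_fraction: float = 0.2
    min_cluster_size: int = 10
    alpha: float = 0.05
    fc_threshold: float = 2.0
    mi_bins: int = 10
    spline_order: int = 3

    def validate(self) -> None:
        given = [
            x is not None
            for x in (self.z_threshold, self.target_nodes, self.match_nodes_to)
        ]
        if sum(given) != 1:
            raise ConfigError(
                f"dataset {self.label!r}: give exactly one of "
                "z_threshold / target_nodes / match_nodes_to"
            )
        if self.z_threshold is not None and self.z_threshold < 0:
            raise ConfigError("z_threshold must be >= 0")
        if not 0 < self.bottleneck_fraction <= 1:
            raise ConfigError("bottleneck_fraction must be in (0, 1]")
        for p, name in [(self.expression, "expression"), (self.design, "design"),
                        (self.annotation, "annotation")]:
            if not Path(p).exists():
                raise ConfigError(f"dataset {self.label!r}: {name} file {p} not found")


@dataclass(frozen=True)
class PipelineConfig:
    datasets: tuple[DatasetConfig, ...]
    output_dir: Path
    gene_sets: Path | None = None
    n_permutations: int = 100_000
    seed: int = 0
    focal_genes: tuple[str, ...] = ()

    def validate(self) -> None:
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ConfigError("dataset labels must be unique")
        for d in self.datasets:
            d.validate()
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise ConfigError(f"gene_sets file {self.gene_sets} not found")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        datasets = tuple(
            DatasetConfig(
                label=d["label"],
                expression=Path(d["expression"]),
                design=Path(d["design"]),
                annotation=Path(d["annotation"]),
                z_threshold=d.get("z_threshold"),
                target_nodes=d.get("target_nodes"),
                match_nodes_to=d.get("match_nodes_to"),
                z_grid=tuple(d.get("z_grid", DEFAULT_Z_GRID)),
                bottleneck_fraction=d.get("bottleneck_fraction", 0.2),
                min_cluster_size=d.get("min_cluster_size", 10),
                alpha=d.get("alpha", 0.05),
                fc_threshold=d.get("fc_threshold", 2.0),
                mi_bins=d.get("mi_bins", 10),
                spline_order=d.get("spline_order", 3),
            )
            for d in raw["datasets"]
        )
        comparison = raw.get("comparison", {})
        cfg = PipelineConfig(
            datasets=datasets,
            output_dir=Path(raw["output_dir"]),
            gene_sets=Path(raw["gene_sets"]) if raw.get("gene_sets") else None,
            n_permutations=comparison.get("n_permutations", 100_000),
            seed=comparison.get("seed", 0),
            focal_genes=tuple(comparison.get("focal_genes", [])),
        )
    except KeyError as e:
        raise ConfigError(f"missing config key: {e}") from e
    cfg.validate()
    return cfg


@dataclass
class DatasetResult:
    label: str
    diffexpr_table: "object"
    network: nx.Graph
    threshold: float
    ranking: topology.BottleneckRanking
    partition: communities.CommunityPartition
    enrichment: dict
    condensed: nx.Graph
    annotation: expr_data.ProbeAnnotation
    manifest: dict


def run_dataset(
    dcfg: DatasetConfig,
    output_dir: Path,
    gene_sets: expr_data.GeneSetCollection | None = None,
    louvain_seed: int = 0,
    target_nodes_override: int | None = None,
    anchor_z: float | None = None,
) -> DatasetResult:
    """Run every stage for one dataset and write stage outputs + manifest.

    ``target_nodes_override`` and ``anchor_z`` carry the resolved node count
    and threshold of the anchor dataset when the config asked to match
    another dataset (``match_nodes_to``); the anchor threshold only breaks
    node-count ties.
    """
    dcfg.validate()
    out = Path(output_dir) / dcfg.label
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "label": dcfg.label,
        "version": __version__,
        "seed": louvain_seed,
        "parameters": {
            "z_threshold": dcfg.z_threshold,
            "target_nodes": dcfg.target_nodes,
            "bottleneck_fraction": dcfg.bottleneck_fraction,
            "min_cluster_size": dcfg.min_cluster_size,
            "alpha": dcfg.alpha,
            "fc_threshold": dcfg.fc_threshold,
            "mi_bins": dcfg.mi_bins,
            "spline_order": dcfg.spline_order,
        },
        "stages": {},
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            manifest["stages"][name] = {"error": str(e)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {name!r} failed for {dcfg.label!r}: {e}") from e

    matrix = _stage("load", lambda: expr_data.read_expression(dcfg.expression))
    design = expr_data.read_design(dcfg.design)
    annot = expr_data.read_annotation(dcfg.annotation)

    results = _stage(
        "diffexpr",
        lambda: diffexpr.select_differential(matrix, design, dcfg.alpha, dcfg.fc_threshold),
    )
    table = diffexpr.results_to_frame(results)
    table.to_csv(out / "diffexpr.tsv", sep="\t", index=False)
    selected = diffexpr.selected_probes(results)
    manifest["stages"]["diffexpr"] = {
        "probes_tested": len(results), "probes_selected": len(selected),
    }
    logger.info("[%s] diffexpr: %d/%d probes selected", dcfg.label,
                len(selected), len(results))
    if len(selected) < 3:
        raise RuntimeError(f"stage 'diffexpr' left {len(selected)} probes; need >= 3")

    sub = matrix.subset_probes(selected)
    mim = _stage(
        "mi", lambda: clr.mi_matrix(sub.values, sub.probe_ids,
                                    dcfg.mi_bins, dcfg.spline_order)
    )
    clrm = clr.clr_scores(mim)
    if dcfg.z_threshold is not None:
        z_min = float(dcfg.z_threshold)
    else:
        target = (
            target_nodes_override
            if target_nodes_override is not None
            else dcfg.target_nodes
        )
        if target is None:
            raise ConfigError(
                f"dataset {dcfg.label!r}: match_nodes_to requires run_all to "
                "resolve the anchor node count"
            )
        z_min = clr.select_threshold_for_node_count(
            clrm, target, dcfg.z_grid, prefer_near=anchor_z
        )
    net = _stage("network", lambda: clr.threshold_network(clrm, z_min))
    clr.write_edge_list(net, out / "edges.tsv")
    clr.write_graphml(net, out / "network.graphml")
    clr.write_xgmml(net, out / "network.xgmml", name=dcfg.label)
    dropped = len(selected) - net.number_of_nodes()
    manifest["stages"]["network"] = {
        "threshold": z_min,
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "probes_without_edges_dropped": dropped,
    }
    logger.info("[%s] network: z>=%.2f, %d nodes, %d edges (%d probes dropped)",
                dcfg.label, z_min, net.number_of_nodes(), net.number_of_edges(), dropped)

    b = _stage("betweenness", lambda: topology.betweenness(net))
    ranking = topology.rank_bottlenecks(b, dcfg.bottleneck_fraction)
    topology.write_ranking(ranking, out / "bottlenecks.tsv")
    manifest["stages"]["bottlenecks"] = {
        "nodes_ranked": len(b), "bottlenecks": len(ranking.bottleneck_nodes),
    }

    partition = _stage(
        "communities", lambda: communities.louvain_partition(net, seed=louvain_seed)
    )
    manifest["stages"]["communities"] = {
        "clusters": len(partition.clusters()), "modularity": partition.modularity,
    }
    enrichment: dict = {}
    if gene_sets is not None:
        enrichment = _stage(
            "enrichment",
            lambda: communities.enrich_clusters(
                partition, annot, gene_sets, dcfg.min_cluster_size
            ),
        )
        communities.enrichment_to_frame(enrichment).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        manifest["stages"]["enrichment"] = {"clusters_tested": len(enrichment)}

    condensed = communities.condense(
        net, partition, ranking, enrichment, gene_sets, dcfg.min_cluster_size
    )
    nx.write_graphml(condensed, out / "condensed.graphml")
    manifest["stages"]["condensed"] = {
        "nodes": condensed.number_of_nodes(), "edges": condensed.number_of_edges(),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return DatasetResult(
        dcfg.label, table, net, z_min, ranking, partition,
        enrichment, condensed, annot, manifest,
    )


def run_comparison(
    results: dict[str, DatasetResult],
    output_dir: Path,
    n_permutations: int = 100_000,
    seed: int = 0,
    focal_genes: tuple[str, ...] = (),
) -> tuple[multinet.ConservedBottleneckReport, dict]:
    """Conserved-bottleneck report plus a shared-neighbor table per focal gene."""
    if len(results) < 2:
        raise ConfigError("comparison needs >= 2 completed dataset runs")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rankings = {k: r.ranking for k, r in results.items()}
    annots = {k: r.annotation for k, r in results.items()}
    universes = {
        k: r.annotation.genes_of(r.network.nodes) for k, r in results.items()
    }
    report = multinet.conserved_bottleneck_report(
        rankings, annots, universes, n_permutations=n_permutations, seed=seed
    )
    (out / "conserved_bottlenecks.json").write_text(report.to_json())
    with open(out / "bottleneck_genes.tsv", "w") as fh:
        fh.write("network\tgene\n")
        for name in report.network_names:
            for g in sorted(report.bottleneck_sets[name]):
                fh.write(f"{name}\t{g}\n")

    focal = tuple(focal_genes) or tuple(sorted(report.intersection))
    nets = {k: r.network for k, r in results.items()}
    tables = {}
    for gene in focal:
        annot = next(iter(annots.values()))
        # all annotations share the probe->gene namespace in a comparison
        merged = expr_data.ProbeAnnotation(
            {p: g for a in annots.values() for p, g in a.mapping.items()}
        )
        try:
            tab = multinet.shared_neighbor_table(nets, merged, gene)
        except KeyError:
            logger.warning("focal gene %r absent from all networks; skipped", gene)
            continue
        tables[gene] = tab
        tab.to_frame().to_csv(out / f"neighbors_{gene}.tsv", sep="\t", index=False)
    return report, tables


def run_all(cfg: PipelineConfig, louvain_seed: int | None = None):
    """Run every dataset then the comparison; returns (results, report, tables)."""
    cfg.validate()
    gene_sets = (
        expr_data.read_gene_sets(cfg.gene_sets) if cfg.gene_sets is not None else None
    )
    seed = cfg.seed if louvain_seed is None else louvain_seed
    results: dict[str, DatasetResult] = {}
    for d in cfg.datasets:
        override = anchor_z = None
        if d.match_nodes_to is not None:
            if d.match_nodes_to not in results:
                raise ConfigError(
                    f"dataset {d.label!r}: match_nodes_to target "
                    f"{d.match_nodes_to!r} must be an earlier dataset"
                )
            anchor = results[d.match_nodes_to]
            override = anchor.network.number_of_nodes()
            anchor_z = anchor.threshold
        results[d.label] = run_dataset(
            d, cfg.output_dir, gene_sets, louvain_seed=seed,
            target_nodes_override=override, anchor_z=anchor_z,
        )
    report, tables = (None, {})
    if len(results) >= 2:
        report, tables = run_comparison(
            results, cfg.output_dir,
            n_permutations=cfg.n_permutations, seed=cfg.seed,
            focal_genes=cfg.focal_genes,
        )
    return results, report, tables


# ---------------------------------------------------------------------------
# synthetic benchmark study
# ---------------------------------------------------------------------------

def run_synthetic_study(
    seed: int,
    n_permutations: int = 10_000,
    params: synthetic.SyntheticParams | None = None,
    bottleneck_fraction: float = 0.2,
    min_cluster_size: int = 10,
    n_regulators: int = 125,
    z_grid=None,
) -> dict:
    """Full pipeline benchmark on three generated datasets sharing bridges.

    Three datasets are generated from independent child seeds of ``seed``
    (same planted gene table, fresh profiles and noise, mimicking the same
    biology measured in different tissues). The first network is thresholded
    at the declared synthetic anchor score; the others are harmonized to its
    node count. Each run is scored against the planted truth (bridge
    recall/precision, cluster labels), bottleneck gene sets are intersected
    across networks with a permutation p-value, and a regulator-knockdown
    coherence test is run on one planted module.
    """
    if z_grid is None:
        z_grid = DEFAULT_Z_GRID
    ds_seeds = [
        int(s) for s in np.random.SeedSequence(seed).generate_state(3) % (2**31)
    ]
    base = params or synthetic.SyntheticParams()
    runs: dict[str, dict] = {}
    anchor_nodes = anchor_z = None
    first_truth = None
    for k, ds_seed in enumerate(ds_seeds):
        p = dataclasses.replace(base, seed=ds_seed)
        matrix, design, annot, truth = synthetic.generate_dataset(p)
        if first_truth is None:
            first_truth = truth
        results = diffexpr.select_differential(matrix, design)
        selected = diffexpr.selected_probes(results)
        sub = matrix.subset_probes(selected)
        clrm = clr.clr_scores(
            clr.mi_matrix(sub.values, sub.probe_ids)
        )
        if k == 0:
            z_min = synthetic.DEFAULT_SYNTHETIC_Z
        else:
            z_min = clr.select_threshold_for_node_count(
                clrm, anchor_nodes, z_grid, prefer_near=anchor_z
            )
        net = clr.threshold_network(clrm, z_min)
        if k == 0:
            anchor_nodes, anchor_z = net.number_of_nodes(), z_min
        ranking = topology.rank_bottlenecks(
            topology.betweenness(net), bottleneck_fraction
        )
        precision, recall = synthetic.evaluate_recovery(ranking, truth)
        partition = communities.louvain_partition(net, seed=seed)
        gene_sets = synthetic.generate_gene_sets(truth)
        enr = communities.enrich_clusters(partition, annot, gene_sets, min_cluster_size)
        # does each large cluster carry its dominant planted module's term?
        labels_correct, n_large = 0, 0
        for cid, members in partition.clusters().items():
            if len(members) < min_cluster_size:
                continue
            n_large += 1
            counts: dict[str, int] = {}
            for probe in members:
                lab = truth.gene_module[truth.probe_gene[probe]]
                counts[lab] = counts.get(lab, 0) + 1
            dominant = max(sorted(counts), key=counts.get)
            if not dominant.startswith("module_"):
                continue
            expected = "MODULE_" + dominant.split("_")[1]
            best = enr[cid].best_term if cid in enr else None
            if best is not None and best.term_id == expected:
                labels_correct += 1
        runs[f"dataset_{k}"] = {
            "seed": ds_seed,
            "threshold": z_min,
            "n_selected": len(selected),
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "modularity": partition.modularity,
            "bridge_recall": recall,
            "bridge_precision": precision,
            "n_large_clusters": n_large,
            "clusters_labeled_correctly": labels_correct,
            "_ranking": ranking,
            "_annot": annot,
            "_net": net,
            "_truth": truth,
        }

    rankings = {k: r["_ranking"] for k, r in runs.items()}
    annots = {k: r["_annot"] for k, r in runs.items()}
    universes = {
        k: r["_annot"].genes_of(r["_net"].nodes) for k, r in runs.items()
    }
    report = multinet.conserved_bottleneck_report(
        rankings, annots, universes, n_permutations=n_permutations, seed=seed
    )
    bridges = first_truth.bridge_genes
    knockdowns = synthetic.generate_knockdown_matrix(
        first_truth, n_regulators=n_regulators, seed=seed
    )
    group = first_truth.module_members(0)
    coh = coherence.coherence_test(knockdowns, group)

    for r in runs.values():  # strip non-serializable internals
        for key in ("_ranking", "_annot", "_net", "_truth"):
            r.pop(key)
    return {
        "datasets": runs,
        "conserved": {
            "overlap": report.observed_overlap,
            "intersection": sorted(report.intersection),
            "planted_bridges_recovered": len(report.intersection & bridges),
            "n_planted_bridges": len(bridges),
            "p_perm": report.p_perm,
            "n_permutations": n_permutations,
        },
        "coherence": {
            "r_in": coh.r_in,
            "r_out": coh.r_out,
            "t": coh.t_statistic,
            "p": coh.p_value,
        },
    }
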