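"""Cross-network comparison at the gene level.

Bottleneck probesets from each network are mapped to gene symbols, the
conserved set is their exact intersection, and its significance is assessed
by a permutation null: random gene sets of each network's bottleneck-set
size are drawn uniformly from that network's own node-gene universe and
intersected, with the add-one Monte-Carlo estimator

    p = (1 + #{permutation overlap >= observed}) / (n_permutations + 1).

Shared-neighborhood tables report, for a focal gene, which genes sit at
first order (direct neighbor of any of its probes) or only at second order
in each network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr_data import ProbeAnnotation
from .topology import BottleneckRanking, neighborhood

logger = logging.getLogger("clrnet")


@dataclass(frozen=True)
class ConservedBottleneckReport:
    network_names: tuple[str, ...]
    bottleneck_sets: dict  # name -> frozenset of genes
    intersection: frozenset
    observed_overlap: int
    p_perm: float
    n_permutations: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "networks": list(self.network_names),
                "sizes": {k: len(v) for k, v in self.bottleneck_sets.items()},
                "intersection": sorted(self.intersection),
                "observed_overlap": self.observed_overlap,
                "p_perm": self.p_perm,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
            },
            indent=2,
        )


def bottleneck_genes(ranking: BottleneckRanking, annot: ProbeAnnotation) -> frozenset:
    """Gene symbols with >= 1 bottleneck-flagged probe; unannotated dropped."""
    return frozenset(annot.genes_of(ranking.bottleneck_nodes))


def conserved_bottlenecks(sets) -> frozenset:
    """Exact intersection of >= 2 gene sets."""
    sets = [frozenset(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 gene sets to intersect")
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def overlap_pvalue(
    universes,
    set_sizes,
    observed: int,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the size of a multi-set intersection.

    Each permutation draws, for every network, a uniform random subset of
    its stated bottleneck-set size from its own gene universe, and counts
    the size of the joint intersection.
    """
    if observed < 0:
        raise ValueError("observed overlap must be >= 0")
    universes = [np.array(sorted(u)) for u in universes]
    set_sizes = [int(s) for s in set_sizes]
    if len(universes) != len(set_sizes):
        raise ValueError("one set size per universe required")
    for u, s in zip(universes, set_sizes):
        if s > len(u):
            raise ValueError("set size exceeds universe size")
    if observed == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        inter = None
        for u, s in zip(universes, set_sizes):
            draw = frozenset(rng.choice(u, size=s, replace=False))
            inter = draw if inter is None else inter & draw
            if not inter:
                break
        if inter is not None and len(inter) >= observed:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def conserved_bottleneck_report(
    rankings: dict,
    annots: dict,
    universes: dict,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> ConservedBottleneckReport:
    """Full conserved-bottleneck analysis over named networks.

    ``universes`` maps network name -> gene universe (the genes of all its
    network nodes), the reference population for the permutation null.
    """
    names = tuple(sorted(rankings))
    sets = {n: bottleneck_genes(rankings[n], annots[n]) for n in names}
    inter = conserved_bottlenecks([sets[n] for n in names])
    p = overlap_pvalue(
        [universes[n] for n in names],
        [len(sets[n]) for n in names],
        len(inter),
        n_permutations=n_permutations,
        seed=seed,
    )
    return ConservedBottleneckReport(
        names, sets, inter, len(inter), p, n_permutations, seed
    )


@dataclass(frozen=True)
class NeighborhoodTable:
    """gene -> per-network order code (1 = direct neighbor, 2 = second order)."""

    focal_gene: str
    network_names: tuple[str, ...]
    codes: dict  # gene -> {network: 1|2}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, per_net in self.codes.items():
            row = {"gene": gene}
            for name in self.network_names:
                row[name] = per_net.get(name, "")
            rows.append(row)
        df = pd.DataFrame(rows, columns=["gene", *self.network_names])
        if df.empty:
            return df
        n_first = df[list(self.network_names)].apply(
            lambda r: sum(1 for v in r if v == 1), axis=1
        )
        df = df.assign(_k=n_first).sort_values(
            ["_k", "gene"], ascending=[False, True]
        ).drop(columns="_k")
        return df.reset_index(drop=True)


def shared_neighbor_table(
    nets: dict,
    annot: ProbeAnnotation,
    focal_gene: str,
    max_order: int = 2,
) -> NeighborhoodTable:
    """Per-network neighbor order codes for every gene near ``focal_gene``.

    For each network, the first-order set is the union of direct neighbors
    over all probes of the focal gene; second order adds nodes one more hop
    out. A gene coded 1 is never also coded 2 in the same network.
    """
    names = tuple(sorted(nets))
    codes: dict[str, dict] = {}
    found_anywhere = False
    for name in names:
        net = nets[name]
        probes = [p for p in net.nodes if annot.gene_of(p) == focal_gene]
        if not probes:
            continue
        found_anywhere = True
        first: set = set()
        second: set = set()
        for p in probes:
            first |= neighborhood(net, p, 1)
            if max_order >= 2:
                second |= neighborhood(net, p, 2)
        first_genes = annot.genes_of(first) - {focal_gene}
        second_genes = annot.genes_of(second) - first_genes - {focal_gene}
        for g in first_genes:
            codes.setdefault(g, {})[name] = 1
        for g in second_genes:
            codes.setdefault(g, {})[name] = 2
    if not found_anywhere:
        raise KeyError(f"focal gene {focal_gene!r} has no probe in any network")
    return NeighborhoodTable(focal_gene, names, codes)
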