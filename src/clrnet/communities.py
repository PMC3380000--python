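"""Louvain communities, hypergeometric enrichment, and graph condensation.

Communities are found by two-phase Louvain modularity optimization on the
thresholded network (unweighted by default, matching the betweenness
convention). Clusters of at least ``min_cluster_size`` probes are tested
for gene-set enrichment with the exact upper-tail hypergeometric
probability, with the background universe being the gene symbols of the
network's own nodes — enrichment is relative to the rest of the network,
not the whole array. The condensed graph summarizes how each bottleneck
relates to the enriched clusters: a *membership* edge to its own cluster
and *linkage* edges to other clusters holding at least one of its network
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log10

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .expr_data import GeneSetCollection, ProbeAnnotation
from .topology import BottleneckRanking


@dataclass(frozen=True)
class CommunityPartition:
    """node -> cluster id (0-based) and the modularity Q of the partition."""

    assignment: dict
    modularity: float

    def clusters(self) -> dict:
        out: dict[int, set] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out


@dataclass(frozen=True)
class TermEnrichment:
    term_id: str
    p_hyper: float
    p_adjusted: float
    k: int  # overlap
    K: int  # term size in background
    n: int  # cluster size in background
    N: int  # background size


@dataclass(frozen=True)
class ClusterEnrichment:
    cluster_id: int
    results: tuple[TermEnrichment, ...]

    @property
    def best_term(self) -> TermEnrichment | None:
        if not self.results:
            return None
        return min(self.results, key=lambda t: (t.p_hyper, t.term_id))


def louvain_partition(
    net: nx.Graph, seed: int, weighted: bool = False
) -> CommunityPartition:
    """Two-phase Louvain modularity optimization; node order shuffled by seed."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    weight = "clr_z" if weighted else None
    comms = nx.community.louvain_communities(net, weight=weight, seed=seed)
    comms = sorted(comms, key=lambda c: sorted(str(n) for n in c)[0])
    q = nx.community.modularity(net, comms, weight=weight)
    assignment = {node: cid for cid, comm in enumerate(comms) for node in comm}
    return CommunityPartition(assignment, float(q))


def hypergeometric_enrichment(
    cluster_genes: set,
    terms: GeneSetCollection,
    background: set,
    cluster_id: int = 0,
) -> ClusterEnrichment:
    """Exact upper-tail hypergeometric P(X >= k) for every term.

    Population N = |background|, successes K = |term ∩ background|, draws
    n = |cluster_genes|, observed k = |cluster ∩ term|. Terms reduce to the
    background before testing; a Benjamini-Hochberg adjusted p is reported
    alongside the raw p, but cluster labels use the raw smallest-p term.
    """
    if not background:
        raise ValueError("empty enrichment background")
    if not cluster_genes <= background:
        raise ValueError("cluster genes must be a subset of the background")
    N = len(background)
    n = len(cluster_genes)
    raw = []
    for term_id, (_, members) in sorted(terms):
        in_bg = members & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(cluster_genes & in_bg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append((term_id, min(p, 1.0), k, K))
    if not raw:
        return ClusterEnrichment(cluster_id, ())
    pvals = np.array([r[1] for r in raw])
    m = len(pvals)
    order = np.argsort(pvals)[::-1]
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order):
        i = m - rank_from_top  # BH rank of this p among sorted ascending
        running = min(running, pvals[idx] * m / i)
        adj[idx] = running
    results = tuple(
        TermEnrichment(term_id, p, float(adj[i]), k, K, n, N)
        for i, (term_id, p, k, K) in enumerate(raw)
    )
    return ClusterEnrichment(cluster_id, results)


def enrich_clusters(
    partition: CommunityPartition,
    annot: ProbeAnnotation,
    terms: GeneSetCollection,
    min_cluster_size: int = 10,
) -> dict[int, ClusterEnrichment]:
    """Enrichment for every cluster of >= min_cluster_size probes.

    The background is the gene-symbol set of all network nodes; cluster
    size and overlap are counted on genes (unannotated probes drop out).
    """
    background = annot.genes_of(partition.assignment.keys())
    out = {}
    for cid, members in partition.clusters().items():
        if len(members) < min_cluster_size:
            continue
        genes = annot.genes_of(members)
        out[cid] = hypergeometric_enrichment(genes, terms, background, cid)
    return out


def condense(
    net: nx.Graph,
    partition: CommunityPartition,
    ranking: BottleneckRanking,
    enrich: dict[int, ClusterEnrichment],
    terms: GeneSetCollection | None = None,
    min_cluster_size: int = 10,
) -> nx.Graph:
    """Bipartite-like summary graph of bottlenecks and enriched clusters.

    Circle nodes are bottlenecks; square nodes are clusters of at least
    ``min_cluster_size`` probes, labeled by their best term and the ceiling
    of -log10(p). Edge attribute ``edge_type`` distinguishes *membership*
    (the bottleneck's own cluster) from *linkage* (a cluster holding one of
    its network neighbors).
    """
    clusters = {
        cid: members
        for cid, members in partition.clusters().items()
        if len(members) >= min_cluster_size
    }
    G = nx.Graph()
    for cid, members in clusters.items():
        label = f"cluster_{cid}"
        neg_log_p = 0.0
        if cid in enrich and enrich[cid].best_term is not None:
            best = enrich[cid].best_term
            name = terms.name(best.term_id) if terms is not None else best.term_id
            neg_log_p = -log10(best.p_hyper) if best.p_hyper > 0 else float("inf")
            label = f"{name} ({ceil(neg_log_p) if np.isfinite(neg_log_p) else 'inf'})"
        G.add_node(
            f"cluster:{cid}",
            kind="cluster",
            shape="square",
            size=len(members),
            label=label,
            neg_log10_p=float(neg_log_p),
        )
    for node in ranking.bottleneck_nodes:
        G.add_node(str(node), kind="bottleneck", shape="circle", label=str(node))
        own = partition.assignment.get(node)
        if own in clusters:
            G.add_edge(str(node), f"cluster:{own}", edge_type="membership")
        if node in net:
            neighbor_clusters = {
                partition.assignment[nb]
                for nb in net.neighbors(node)
                if partition.assignment.get(nb) in clusters
            }
            for cid in neighbor_clusters - {own}:
                G.add_edge(str(node), f"cluster:{cid}", edge_type="linkage")
    return G


def enrichment_to_frame(enrich: dict[int, ClusterEnrichment]) -> pd.DataFrame:
    rows = []
    for cid in sorted(enrich):
        for t in enrich[cid].results:
            rows.append(
                {
                    "cluster_id": cid,
                    "term_id": t.term_id,
                    "p_hyper": t.p_hyper,
                    "p_adjusted": t.p_adjusted,
                    "k": t.k,
                    "K": t.K,
                    "n": t.n,
                    "N": t.N,
                    "is_best": enrich[cid].best_term is not None
                    and t.term_id == enrich[cid].best_term.term_id,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "term_id", "p_hyper", "p_adjusted",
            "k", "K", "n", "N", "is_best",
        ],
    )
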