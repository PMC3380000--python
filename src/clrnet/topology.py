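"""Betweenness-centrality bottlenecks and neighborhood extraction.

A bottleneck is a node through which a large share of shortest paths pass —
a point of constriction for information flow. Betweenness is computed on
the unweighted thresholded network (edge presence only; CLR weights do not
enter path lengths) with the unnormalized unordered-pair convention: each
pair {s, t} with s, t != v contributes sigma_st(v) / sigma_st once.
Disconnected pairs contribute nothing. Nodes in the top ``fraction`` of the
betweenness ranking are flagged as bottlenecks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class BottleneckRanking:
    """Per-node betweenness, 1-based rank (1 = highest), bottleneck flag."""

    betweenness: dict
    rank: dict
    is_bottleneck: dict
    fraction: float

    @property
    def bottleneck_nodes(self) -> list:
        return sorted(n for n, f in self.is_bottleneck.items() if f)

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.rank, key=self.rank.get)
        return pd.DataFrame(
            {
                "node": nodes,
                "betweenness": [self.betweenness[n] for n in nodes],
                "rank": [self.rank[n] for n in nodes],
                "is_bottleneck": [self.is_bottleneck[n] for n in nodes],
            }
        )


def betweenness(net: nx.Graph) -> dict:
    """Unnormalized betweenness (Brandes), each unordered pair counted once."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    return nx.betweenness_centrality(net, normalized=False, weight=None)


def rank_bottlenecks(b: dict, fraction: float = 0.2) -> BottleneckRanking:
    """Flag the top ceil(fraction * N) nodes by betweenness.

    Ties are broken by node id (lexicographic), making the flag set
    deterministic.
    """
    if not b:
        raise ValueError("empty betweenness map")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ordered = sorted(b, key=lambda n: (-b[n], str(n)))
    n_flag = math.ceil(fraction * len(ordered))
    rank = {n: i + 1 for i, n in enumerate(ordered)}
    flags = {n: rank[n] <= n_flag for n in ordered}
    return BottleneckRanking(dict(b), rank, flags, float(fraction))


def neighborhood(net: nx.Graph, node, order: int = 1) -> set:
    """Nodes at hop distance 1..order from ``node`` (the node itself excluded)."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    if order < 1:
        raise ValueError("order must be >= 1")
    dist = nx.single_source_shortest_path_length(net, node, cutoff=order)
    return {n for n, d in dist.items() if 1 <= d <= order}


def write_ranking(ranking: BottleneckRanking, path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)
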