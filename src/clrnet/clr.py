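"""Coexpression-network inference by context likelihood of relatedness (CLR).

Pairwise mutual information (MI) between probe expression profiles is
estimated with a fractional B-spline binning scheme: each observation is
spread over adjacent histogram bins with weights given by B-spline basis
functions, which smooths the histogram and stabilizes MI for the few dozen
samples typical of designed expression studies. MI is in nats.

CLR then scores each pair against the background of both probes: for pair
(i, j), z_i = (MI(i,j) - mean_i) / sd_i over probe i's off-diagonal MI
values (sample sd, n-1), negative deviations floored at zero, and

    z(i, j) = sqrt(max(0, z_i)^2 + max(0, z_j)^2).

A network edge is kept when z reaches the chosen threshold; nodes left
without edges are dropped from the network.

B-spline convention: ``spline_order`` k is the B-spline *order* (degree
k - 1), so the default order 3 uses quadratic basis functions. Knots are
0 repeated k times, then 1, 2, ..., bins - k, then bins - k + 1 repeated
k times; data are min-max rescaled onto [0, bins - k + 1]. With k = 1 the
scheme reduces to ordinary hard binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from xml.sax.saxutils import escape

import networkx as nx
import numpy as np
from scipy.interpolate import BSpline

logger = logging.getLogger("clrnet")


# ---------------------------------------------------------------------------
# mutual information with B-spline binning
# ---------------------------------------------------------------------------

def _spline_knots(bins: int, order: int) -> np.ndarray:
    interior = np.arange(1, bins - order + 1, dtype=float)
    return np.concatenate(
        [np.zeros(order), interior, np.full(order, bins - order + 1.0)]
    )


def bin_weights(x: np.ndarray, bins: int = 10, spline_order: int = 3) -> np.ndarray:
    """Fractional bin-membership weights, shape (n_samples, bins).

    Each row sums to 1 (B-spline partition of unity). A constant vector has
    zero range and yields all-zero weights; callers treat that probe as
    carrying no information.
    """
    x = np.asarray(x, dtype=float)
    if spline_order < 1 or bins < spline_order:
        raise ValueError("need bins >= spline_order >= 1")
    if x.size < spline_order + 1:
        raise ValueError(
            f"need at least spline_order + 1 = {spline_order + 1} samples"
        )
    rng = x.max() - x.min()
    if rng == 0:
        logger.warning("constant vector in MI estimation; treating as zero information")
        return np.zeros((x.size, bins))
    z = (x - x.min()) / rng * (bins - spline_order + 1)
    knots = _spline_knots(bins, spline_order)
    W = BSpline.design_matrix(z, knots, spline_order - 1, extrapolate=False).toarray()
    assert W.shape == (x.size, bins)
    return W


def _mi_from_weights(Wx: np.ndarray, Wy: np.ndarray) -> float:
    n = Wx.shape[0]
    pj = Wx.T @ Wy / n
    px = Wx.sum(axis=0) / n
    py = Wy.sum(axis=0) / n
    mask = pj > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pj[mask] * np.log(pj[mask] / outer[mask])))
    return max(mi, 0.0)


def mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int = 10, spline_order: int = 3
) -> float:
    """MI between two sample vectors, in nats. Zero for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    Wx = bin_weights(x, bins, spline_order)
    Wy = bin_weights(y, bins, spline_order)
    if not Wx.any() or not Wy.any():
        return 0.0
    return _mi_from_weights(Wx, Wy)


@dataclass(frozen=True)
class MIMatrix:
    probe_ids: tuple[str, ...]
    mi: np.ndarray  # symmetric, >= 0, diagonal zeroed by convention

    def __post_init__(self) -> None:
        m = np.asarray(self.mi, dtype=float)
        if m.shape != (len(self.probe_ids),) * 2:
            raise ValueError("MI matrix shape does not match probe count")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("MI matrix must be symmetric")


@dataclass(frozen=True)
class CLRMatrix:
    probe_ids: tuple[str, ...]
    z: np.ndarray  # symmetric, >= 0


def mi_matrix(
    values: np.ndarray,
    probe_ids,
    bins: int = 10,
    spline_order: int = 3,
    block: int = 64,
) -> MIMatrix:
    """All pairwise MI values for a probes x samples matrix.

    Bin weights are computed once per probe; joint histograms for all pairs
    are then formed blockwise with einsum. Memory per block pair is
    block^2 * bins^2 doubles.
    """
    values = np.asarray(values, dtype=float)
    P, n = values.shape
    W = np.zeros((P, n, bins))
    for i in range(P):
        rng = values[i].max() - values[i].min()
        if rng == 0:
            continue  # zero weights: no information
        W[i] = bin_weights(values[i], bins, spline_order)
    marg = W.sum(axis=1) / n  # (P, bins)
    with np.errstate(divide="ignore"):
        log_marg = np.where(marg > 0, np.log(np.maximum(marg, 1e-300)), 0.0)
    # entropy term sum_a p ln p per probe, reused via MI = sum pj ln pj - terms
    mi = np.zeros((P, P))
    for a0 in range(0, P, block):
        a1 = min(a0 + block, P)
        for b0 in range(a0, P, block):
            b1 = min(b0 + block, P)
            pj = np.einsum("isa,jsb->ijab", W[a0:a1], W[b0:b1]) / n
            mask = pj > 0
            log_pj = np.where(mask, np.log(np.maximum(pj, 1e-300)), 0.0)
            term = pj * (
                log_pj
                - log_marg[a0:a1][:, None, :, None]
                - log_marg[b0:b1][None, :, None, :]
            )
            blockmi = np.where(mask, term, 0.0).sum(axis=(2, 3))
            mi[a0:a1, b0:b1] = blockmi
            mi[b0:b1, a0:a1] = blockmi.T
    np.maximum(mi, 0.0, out=mi)
    np.fill_diagonal(mi, 0.0)
    # probes with zero weights (constant) carry no information
    dead = ~W.any(axis=(1, 2))
    mi[dead, :] = 0.0
    mi[:, dead] = 0.0
    return MIMatrix(tuple(probe_ids), mi)


# ---------------------------------------------------------------------------
# CLR scoring and thresholding
# ---------------------------------------------------------------------------

def clr_scores(mi: MIMatrix) -> CLRMatrix:
    """Background-corrected CLR Z-scores from an MI matrix."""
    m = np.asarray(mi.mi, dtype=float)
    P = m.shape[0]
    if P < 3:
        raise ValueError("CLR needs >= 3 probes for row background statistics")
    off = m.copy()
    np.fill_diagonal(off, np.nan)
    means = np.nanmean(off, axis=1)
    sds = np.nanstd(off, axis=1, ddof=1)
    zero_sd = sds == 0
    if zero_sd.any():
        logger.warning("%d probes with zero MI spread; their z contribution is 0",
                       int(zero_sd.sum()))
    safe_sd = np.where(zero_sd, 1.0, sds)
    zi = (m - means[:, None]) / safe_sd[:, None]
    zi[zero_sd, :] = 0.0
    np.maximum(zi, 0.0, out=zi)
    z = np.sqrt(zi**2 + zi.T**2)
    np.fill_diagonal(z, 0.0)
    return CLRMatrix(mi.probe_ids, z)


def threshold_network(clr: CLRMatrix, z_min: float) -> nx.Graph:
    """Keep edges with z >= z_min; drop isolated nodes; record the threshold.

    The returned graph carries edge attribute ``clr_z`` and graph attribute
    ``threshold``.
    """
    if z_min < 0:
        raise ValueError("z_min must be >= 0")
    z = clr.z
    ids = clr.probe_ids
    G = nx.Graph(threshold=float(z_min))
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = z[iu, ju] >= z_min
    for i, j in zip(iu[keep], ju[keep]):
        G.add_edge(ids[i], ids[j], clr_z=float(z[i, j]))
    return G


def network_node_count(clr: CLRMatrix, z_min: float) -> int:
    """Number of probes retaining >= 1 edge at the given threshold."""
    z = clr.z.copy()
    np.fill_diagonal(z, -np.inf)
    return int(np.count_nonzero((z >= z_min).any(axis=1)))


def select_threshold_for_node_count(
    clr: CLRMatrix, target_nodes: int, z_grid, prefer_near: float | None = None
) -> float:
    """Grid threshold whose network node count is closest to ``target_nodes``.

    Ties are broken toward the larger (more conservative) threshold. This
    mirrors matching node counts across networks so bottlenecks can be
    compared fairly between them.

    ``prefer_near`` changes only the tie rule: among thresholds with equal
    node-count error, prefer the one closest to the given value. Used when
    harmonizing several networks to a common anchor: on data where the
    node-count curve plateaus, plain matching is degenerate and any plateau
    point "matches", so the anchor's own threshold is the meaningful pick.
    """
    z_grid = sorted(float(g) for g in z_grid)
    if not z_grid:
        raise ValueError("z_grid must be non-empty")
    if prefer_near is None:
        def better(g, err, best, best_err):
            return err < best_err or (err == best_err and g > best)
    else:
        def better(g, err, best, best_err):
            if err != best_err:
                return err < best_err
            da, db = abs(g - prefer_near), abs(best - prefer_near)
            return da < db or (da == db and g > best)
    best, best_err = None, None
    for g in z_grid:
        err = abs(network_node_count(clr, g) - target_nodes)
        if best is None or better(g, err, best, best_err):
            best, best_err = g, err
    return best


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_a\tprobe_b\tclr_z\n")
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['clr_z']:.6g}\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_xgmml(net: nx.Graph, path, name: str = "coexpression") -> None:
    """Minimal XGMML export so the network opens directly in Cytoscape."""
    idx = {node: i for i, node in enumerate(sorted(net.nodes))}
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(
            f'<graph label="{escape(name)}" directed="0" '
            'xmlns="http://www.cs.rpi.edu/XGMML">\n'
        )
        for node, i in idx.items():
            fh.write(f'  <node id="{i}" label="{escape(str(node))}"/>\n')
        for u, v, d in net.edges(data=True):
            fh.write(
                f'  <edge source="{idx[u]}" target="{idx[v]}">\n'
                f'    <att name="clr_z" type="real" value="{d["clr_z"]:.6g}"/>\n'
                "  </edge>\n"
            )
        fh.write("</graph>\n")
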