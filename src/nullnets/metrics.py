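"""Per-layer and cross-layer network statistics.

The statistics mirrored here are the ones a permutation test compares
against its null ensembles: degree assortativity (edge-endpoint
attribute correlation, the homophily reading — *not* Newman's
excess-degree variant), in-eccentricity dispersion, betweenness
variance, and the unfolded dyadic (phi) correlation between two layers.

Undefined values (zero-variance attributes, empty layers) are explicit
:class:`StatisticValue` markers, never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .data_model import DirectedLayer

__all__ = [
    "StatisticValue",
    "in_degree",
    "out_degree",
    "attribute_assortativity",
    "degree_assortativity",
    "in_eccentricity",
    "dispersion",
    "betweenness_variance",
    "dyadic_correlation",
    "LAYER_STATISTICS",
]


@dataclass(frozen=True)
class StatisticValue:
    """A named statistic for one or two layers, possibly undefined."""

    name: str
    value: float | None
    layers: tuple[str, ...] = ()
    defined: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.defined and self.value is not None:
            raise ValueError("undefined statistic must carry value=None")

    @classmethod
    def undefined(cls, name: str, reason: str, layers: tuple[str, ...] = ()) -> "StatisticValue":
        return cls(name=name, value=None, layers=layers, defined=False, reason=reason)


def _degree_vectors(layer: DirectedLayer) -> tuple[np.ndarray, np.ndarray]:
    n = layer.n_nodes
    indeg = np.zeros(n, dtype=np.int64)
    outdeg = np.zeros(n, dtype=np.int64)
    if layer.n_edges:
        arr = layer.edge_array()
        np.add.at(outdeg, arr[:, 0], 1)
        np.add.at(indeg, arr[:, 1], 1)
    return indeg, outdeg


def in_degree(layer: DirectedLayer) -> dict[str, int]:
    """Incoming-edge count per roster node (0 for the unnominated)."""
    indeg, _ = _degree_vectors(layer)
    return dict(zip(layer.roster.node_ids, indeg.tolist()))


def out_degree(layer: DirectedLayer) -> dict[str, int]:
    """Outgoing-edge count per roster node."""
    _, outdeg = _degree_vectors(layer)
    return dict(zip(layer.roster.node_ids, outdeg.tolist()))


def _endpoint_pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation of edge-endpoint value pairs; None if degenerate."""
    m = len(x)
    sx, sy = x.sum(), y.sum()
    vx = x @ x - sx * sx / m
    vy = y @ y - sy * sy / m
    if vx <= 0 or vy <= 0:
        return None
    return float((x @ y - sx * sy / m) / math.sqrt(vx * vy))


def attribute_assortativity(
    layer: DirectedLayer, values: dict[str, float], name: str = "attribute_assortativity"
) -> StatisticValue:
    """Assortativity of a node attribute over the directed edges.

    Pearson correlation of (value(sender), value(receiver)) across the
    edge list; positive values mean nodes link to similarly valued
    nodes.  Undefined when the layer is empty or either endpoint value
    set has zero variance across edges.
    """
    if layer.n_edges == 0:
        return StatisticValue.undefined(name, "no edges")
    arr = layer.edge_array()
    vals = np.array([values[n] for n in layer.roster.node_ids], dtype=np.float64)
    r = _endpoint_pearson(vals[arr[:, 0]], vals[arr[:, 1]])
    if r is None:
        return StatisticValue.undefined(name, "zero variance across edge endpoints")
    return StatisticValue(name, r)


def degree_assortativity(layer: DirectedLayer, mode: str = "in") -> StatisticValue:
    """Degree homophily: endpoint correlation of in- or out-degree."""
    if mode not in ("in", "out"):
        raise ValueError("mode must be 'in' or 'out'")
    name = f"{mode}_degree_assortativity"
    if layer.n_edges == 0:
        return StatisticValue.undefined(name, "no edges")
    indeg, outdeg = _degree_vectors(layer)
    deg = (indeg if mode == "in" else outdeg).astype(np.float64)
    arr = layer.edge_array()
    r = _endpoint_pearson(deg[arr[:, 0]], deg[arr[:, 1]])
    if r is None:
        return StatisticValue.undefined(name, "zero variance across edge endpoints")
    return StatisticValue(name, r)


def _distance_matrix(layer: DirectedLayer) -> np.ndarray:
    n = layer.n_nodes
    if layer.n_edges == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    arr = layer.edge_array()
    adj = csr_matrix(
        (np.ones(len(arr)), (arr[:, 0], arr[:, 1])), shape=(n, n)
    )
    return shortest_path(adj, method="D", directed=True, unweighted=True)


def in_eccentricity(layer: DirectedLayer) -> dict[str, int]:
    """Longest shortest-path distance *into* each node.

    For node v this is max over nodes u that can reach v of d(u → v);
    unreachable pairs are ignored, and a node nobody reaches scores 0.
    """
    d = _distance_matrix(layer)
    finite = np.where(np.isfinite(d), d, 0.0)
    ecc = finite.max(axis=0).astype(np.int64)
    return dict(zip(layer.roster.node_ids, ecc.tolist()))


def dispersion(
    values: dict[str, float], stat: str, name: str | None = None
) -> StatisticValue:
    """Mean or sample variance (n−1 divisor) of a node-value vector."""
    if stat not in ("variance", "mean"):
        raise ValueError("stat must be 'variance' or 'mean'")
    name = name or f"dispersion_{stat}"
    v = np.fromiter(values.values(), dtype=np.float64)
    if stat == "mean":
        if len(v) == 0:
            return StatisticValue.undefined(name, "empty vector")
        return StatisticValue(name, float(v.mean()))
    if len(v) < 2:
        return StatisticValue.undefined(name, "fewer than 2 nodes")
    return StatisticValue(name, float(v.var(ddof=1)))


def eccentricity_variance(layer: DirectedLayer) -> StatisticValue:
    return dispersion(in_eccentricity(layer), "variance", name="eccentricity_variance")


def eccentricity_mean(layer: DirectedLayer) -> StatisticValue:
    return dispersion(in_eccentricity(layer), "mean", name="eccentricity_mean")


def betweenness_variance(layer: DirectedLayer) -> StatisticValue:
    """Sample variance of unnormalized directed shortest-path betweenness."""
    import networkx as nx

    if layer.n_nodes < 2:
        return StatisticValue.undefined("betweenness_variance", "fewer than 2 nodes")
    g = nx.DiGraph()
    g.add_nodes_from(layer.roster.node_ids)
    g.add_edges_from(layer.edges)
    bc = nx.betweenness_centrality(g, normalized=False)
    v = np.array([bc[n] for n in layer.roster.node_ids], dtype=np.float64)
    return StatisticValue("betweenness_variance", float(v.var(ddof=1)))


def phi_from_counts(n11: int, r1: int, c1: int, n_cells: int) -> float | None:
    """Phi coefficient of a 2×2 co-occurrence table given margin counts."""
    denom = r1 * (n_cells - r1) * c1 * (n_cells - c1)
    if denom <= 0:
        return None
    return float((n_cells * n11 - r1 * c1) / math.sqrt(denom))


def dyadic_correlation(a: DirectedLayer, b: DirectedLayer) -> StatisticValue:
    """Unfolded correlation of two layers' directed adjacency matrices.

    Pearson correlation of the two binary adjacency matrices vectorized
    over all n(n−1) ordered off-diagonal cells (the full matrix, since
    the networks are directed); identical to the phi coefficient of the
    2×2 cell co-occurrence table.  Undefined if either layer is empty
    or complete.
    """
    if a.roster.node_ids != b.roster.node_ids:
        raise ValueError("layers must share the same roster")
    n = a.n_nodes
    n_cells = n * (n - 1)
    r1, c1 = a.n_edges, b.n_edges
    phi = phi_from_counts(len(a.edges & b.edges), r1, c1, n_cells)
    if phi is None:
        return StatisticValue.undefined(
            "dyadic_correlation", "a layer is empty or complete"
        )
    return StatisticValue("dyadic_correlation", phi)


def export_statistics_csv(m, path, statistics=None) -> None:
    """Write a tidy per-layer statistics table.

    Columns: layer, statistic, value, defined.  Undefined entries keep
    an empty value cell and ``defined=False`` rather than a fake zero.
    """
    import csv

    names = tuple(statistics) if statistics is not None else (
        "in_degree_assortativity",
        "out_degree_assortativity",
        "eccentricity_variance",
        "eccentricity_mean",
        "betweenness_variance",
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["layer", "statistic", "value", "defined"])
        for topic, layer in m.layers.items():
            for name in names:
                sv = LAYER_STATISTICS[name](layer)
                w.writerow(
                    [topic, name, "" if sv.value is None else repr(sv.value), sv.defined]
                )


#: Per-layer statistics the structural comparison can plug in.
LAYER_STATISTICS = {
    "in_degree_assortativity": lambda layer: degree_assortativity(layer, "in"),
    "out_degree_assortativity": lambda layer: degree_assortativity(layer, "out"),
    "eccentricity_variance": eccentricity_variance,
    "eccentricity_mean": eccentricity_mean,
    "betweenness_variance": betweenness_variance,
    "edge_count": lambda layer: StatisticValue("edge_count", float(layer.n_edges)),
}
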