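"""The four permutation null models, as pure seeded transformations.

Two act on a single directed layer:

* ``edge1`` (outgoing-edge permutation) — each sender keeps its number
  of nominations but the receivers are redrawn uniformly; only the
  out-degree sequence is conserved.
* ``edge2`` (edge swap) — a chain of directed double-edge swaps; both
  the out-degree and the in-degree sequence are conserved.

Two act on the dyad-by-layer incidence:

* ``cross1`` (free layer shuffle) — each dyad's k nominations are
  reassigned to k distinct layers drawn uniformly; row sums and the
  union network are conserved, column sums are free.
* ``cross2`` (constrained layer shuffle) — checkerboard swaps on the
  binary incidence; row sums *and* column sums are conserved.

The swap chains (edge2, cross2) are lazy Metropolis chains: ``n_swaps``
counts *attempted* moves, proposals are drawn with replacement, and an
invalid proposal leaves the state unchanged.  Laziness makes the chains
aperiodic, so at chain lengths well past mixing every member of the
constrained ensemble is equally likely — including on tiny two-state
instances, where success-counted chains would be deterministic in the
swap parity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .data_model import (
    N_LAYERS,
    TOPICS,
    TOPIC_INDEX,
    DirectedLayer,
    DyadLayerIncidence,
    MultilayerNetwork,
    to_incidence,
)
from . import metrics
from .metrics import StatisticValue

logger = logging.getLogger(__name__)

NULL_MODELS = ("edge1", "edge2", "cross1", "cross2")
_MODEL_CODE = {m: i for i, m in enumerate(NULL_MODELS, start=1)}

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def default_n_swaps(n_ones: int) -> int:
    """Default chain length: 10 attempted moves per 1-entry (edge),
    floored at 5000 attempts.

    On small instances the proposal acceptance rate can be low (few
    cells to hit), so scaling by size alone leaves the chain unmixed;
    the floor guarantees each 1-entry is moved many times over.
    """
    return max(5000, 10 * n_ones)


# ---------------------------------------------------------------------------
# edge null model 1: outgoing-edge permutation


def permute_out_edges(layer: DirectedLayer, rng_seed: SeedLike) -> DirectedLayer:
    """Redraw every sender's receivers uniformly, keeping out-degrees.

    For a sender with k nominations, a fresh k-subset of the roster
    minus the sender is drawn uniformly (layers are binary, so
    receivers are distinct); in-degrees are free to change.
    """
    rng = _rng(rng_seed)
    n = layer.n_nodes
    nodes = layer.roster.node_ids
    outdeg: dict[str, int] = {}
    for s, _ in layer.edges:
        outdeg[s] = outdeg.get(s, 0) + 1
    edges: set[tuple[str, str]] = set()
    for s in nodes:  # roster order keeps the draw sequence deterministic
        k = outdeg.get(s, 0)
        if k == 0:
            continue
        si = layer.roster.index(s)
        picks = rng.choice(n - 1, size=k, replace=False)
        for p in picks:
            ri = int(p) + (1 if p >= si else 0)  # skip the sender's own slot
            edges.add((s, nodes[ri]))
    return DirectedLayer(layer.roster, frozenset(edges))


# ---------------------------------------------------------------------------
# edge null model 2: degree-preserving double-edge swap chain


def permute_double_swap(
    layer: DirectedLayer, n_swaps: int | None = None, rng_seed: SeedLike = 0
) -> DirectedLayer:
    """Randomize a layer by directed double-edge swaps.

    A move picks two edges a→b and c→d (with replacement) and proposes
    a→d, c→b; it is rejected if it would create a self-loop or a
    duplicate edge.  Both degree sequences are conserved exactly.  If
    the layer admits no valid swap at all, the input is returned
    unchanged with a logged warning.
    """
    m = layer.n_edges
    if m < 2:
        logger.warning("double swap: layer has %d edge(s), returning input unchanged", m)
        return layer
    if n_swaps is None:
        n_swaps = default_n_swaps(m)
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    rng = _rng(rng_seed)
    n = layer.n_nodes
    arr = layer.edge_array()
    src, dst = arr[:, 0].copy(), arr[:, 1].copy()
    adj = np.zeros((n, n), dtype=np.bool_)
    adj[src, dst] = True
    picks = rng.integers(0, m, size=(n_swaps, 2))
    n_success = _edge_swap_chain(src, dst, adj, picks)
    if n_success == 0 and not _swap_exists(src, dst, adj):
        logger.warning("double swap: no valid swap exists, returning input unchanged")
        return layer
    nodes = layer.roster.node_ids
    return DirectedLayer(
        layer.roster, frozenset((nodes[s], nodes[d]) for s, d in zip(src, dst))
    )


def _edge_swap_chain_py(src, dst, adj, picks) -> int:
    n_success = 0
    for k in range(picks.shape[0]):
        i1, i2 = picks[k, 0], picks[k, 1]
        if i1 == i2:
            continue
        a, b = src[i1], dst[i1]
        c, d = src[i2], dst[i2]
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[c, d] = False
        adj[a, d] = True
        adj[c, b] = True
        dst[i1] = d
        dst[i2] = b
        n_success += 1
    return n_success


_edge_swap_chain = _njit(cache=False)(_edge_swap_chain_py) if _HAVE_NUMBA else _edge_swap_chain_py


def _swap_exists(src, dst, adj) -> bool:
    m = len(src)
    for i in range(m):
        a, b = src[i], dst[i]
        for j in range(i + 1, m):
            c, d = src[j], dst[j]
            if a != d and c != b and not adj[a, d] and not adj[c, b]:
                return True
    return False


# ---------------------------------------------------------------------------
# cross-network null model 1: free layer shuffle


def shuffle_layers_free(
    inc: DyadLayerIncidence, rng_seed: SeedLike
) -> DyadLayerIncidence:
    """Reassign each dyad's nominations to uniformly random distinct layers.

    Every row with sum k is replaced by a uniform k-subset of the 9
    layers; row sums — hence the union network — are conserved, column
    sums are free.
    """
    rng = _rng(rng_seed)
    mat = inc.matrix
    k = mat.sum(axis=1, dtype=np.int64)
    keys = rng.random(mat.shape)
    # rank of each column key within its row; the k smallest win
    ranks = keys.argsort(axis=1).argsort(axis=1)
    new = (ranks < k[:, None]).astype(np.uint8)
    return DyadLayerIncidence(inc.dyads, new)


# ---------------------------------------------------------------------------
# cross-network null model 2: margin-preserving checkerboard chain


def shuffle_layers_constrained(
    inc: DyadLayerIncidence, n_swaps: int | None = None, rng_seed: SeedLike = 0
) -> DyadLayerIncidence:
    """Randomize the incidence preserving all row and column sums.

    A move draws two 1-entries (d1,t1), (d2,t2) with replacement from
    the list of 1-cells and flips the 2×2 checkerboard if d1 ≠ d2,
    t1 ≠ t2 and (d1,t2) = (d2,t1) = 0; other proposals are rejected
    (the cell count is invariant, so the kernel is symmetric and the
    stationary law uniform over the fixed-margin ensemble).  On
    margin-rigid matrices (no checkerboard anywhere) the input is
    returned unchanged with a logged warning.
    """
    mat = inc.matrix
    n_ones = int(mat.sum())
    if n_ones < 2:
        logger.warning("constrained shuffle: fewer than 2 nominations, input unchanged")
        return inc
    if n_swaps is None:
        n_swaps = default_n_swaps(n_ones)
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    rng = _rng(rng_seed)
    picks = rng.integers(0, n_ones, size=(n_swaps, 2))
    m = mat.astype(np.uint8).copy()
    one_rows, one_cols = (a.astype(np.int64) for a in np.nonzero(mat))
    n_success = _checkerboard_chain(m, one_rows, one_cols, picks)
    if n_success == 0 and not _checkerboard_exists(mat):
        logger.warning("constrained shuffle: matrix is margin-rigid, input unchanged")
        return inc
    return DyadLayerIncidence(inc.dyads, m)


def _checkerboard_chain_py(m, one_rows, one_cols, picks) -> int:
    n_success = 0
    for k in range(picks.shape[0]):
        i, j = picks[k, 0], picks[k, 1]
        if i == j:
            continue
        d1, t1 = one_rows[i], one_cols[i]
        d2, t2 = one_rows[j], one_cols[j]
        if d1 == d2 or t1 == t2:
            continue
        if m[d1, t2] or m[d2, t1]:
            continue
        m[d1, t1] = 0
        m[d2, t2] = 0
        m[d1, t2] = 1
        m[d2, t1] = 1
        one_cols[i] = t2
        one_cols[j] = t1
        n_success += 1
    return n_success


_checkerboard_chain = (
    _njit(cache=False)(_checkerboard_chain_py) if _HAVE_NUMBA else _checkerboard_chain_py
)


def _checkerboard_exists(mat: np.ndarray) -> bool:
    a = mat.astype(bool)
    for i in range(a.shape[0] - 1):
        rest = a[i + 1 :]
        # a 2x2 checkerboard with row i needs some row below differing both ways
        hi = (a[i] & ~rest).any(axis=1)
        lo = (~a[i] & rest).any(axis=1)
        if (hi & lo).any():
            return True
    return False


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class NullEnsemble:
    """Observed statistic plus its null-replicate distribution."""

    statistic: str
    layers: tuple[str, ...]
    null_model: str
    observed: StatisticValue
    null_values: np.ndarray
    n_undefined: int
    n_perm: int
    seed: int
    n_swaps: int | None = None
    meta: dict = field(default_factory=dict)


def replicate_seed(
    master_seed: int, null_model: str, layer: str | None, replicate: int
) -> np.random.SeedSequence:
    """Deterministic sub-seed for one null replicate.

    Spawned from (master seed, null-model code, layer code, replicate
    index) so ensembles are reproducible, resumable, and invariant to
    the order replicates are executed in.
    """
    layer_code = TOPIC_INDEX[layer] if layer is not None else 255
    return np.random.SeedSequence(
        (int(master_seed), _MODEL_CODE[null_model], layer_code, int(replicate))
    )


def _layer_from_incidence_col(
    inc: DyadLayerIncidence, roster, topic: str
) -> DirectedLayer:
    col = TOPIC_INDEX[topic]
    rows = np.flatnonzero(inc.matrix[:, col])
    return DirectedLayer(roster, frozenset(inc.dyads[i] for i in rows))


def generate_ensemble(
    m: MultilayerNetwork,
    statistic: str | Callable[[DirectedLayer], StatisticValue],
    null_model: str,
    n_perm: int,
    seed: int,
    layer: str | None = None,
    layer2: str | None = None,
    n_swaps: int | None = None,
) -> NullEnsemble:
    """Build the null distribution of a statistic under one null model.

    ``statistic`` is a name from :data:`nullnets.metrics.LAYER_STATISTICS`
    (or a callable on a layer), acting on ``layer``; the special name
    ``"dyadic_correlation"`` acts on the pair (``layer``, ``layer2``).
    Edge nulls permute ``layer`` alone; cross nulls permute the
    dyad-by-layer incidence and the statistic is recomputed on the
    reconstructed layer(s).  Undefined replicates are counted, not
    interleaved.
    """
    if null_model not in NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pair = statistic == "dyadic_correlation"
    if pair:
        if layer is None or layer2 is None:
            raise ValueError("dyadic_correlation needs layer and layer2")
        if null_model in ("edge1", "edge2"):
            raise ValueError("edge nulls permute a single layer; use cross1/cross2")
        stat_name = "dyadic_correlation"
        observed = metrics.dyadic_correlation(m.layers[layer], m.layers[layer2])
        layers = (layer, layer2)
    else:
        if layer is None:
            raise ValueError("a focal layer is required")
        if callable(statistic):
            stat_fn = statistic
            stat_name = getattr(statistic, "__name__", "custom_statistic")
        else:
            stat_fn = metrics.LAYER_STATISTICS[statistic]
            stat_name = statistic
        observed = stat_fn(m.layers[layer])
        layers = (layer,)

    inc = to_incidence(m) if null_model in ("cross1", "cross2") else None
    values: list[float] = []
    n_undefined = 0
    for rep in range(n_perm):
        sub = replicate_seed(seed, null_model, layer, rep)
        if null_model == "edge1":
            perm_layer = permute_out_edges(m.layers[layer], sub)
            sv = stat_fn(perm_layer)
        elif null_model == "edge2":
            perm_layer = permute_double_swap(m.layers[layer], n_swaps, sub)
            sv = stat_fn(perm_layer)
        else:
            if null_model == "cross1":
                perm_inc = shuffle_layers_free(inc, sub)
            else:
                perm_inc = shuffle_layers_constrained(inc, n_swaps, sub)
            a = _layer_from_incidence_col(perm_inc, m.roster, layer)
            if pair:
                b = _layer_from_incidence_col(perm_inc, m.roster, layer2)
                sv = metrics.dyadic_correlation(a, b)
            else:
                sv = stat_fn(a)
        if sv.defined:
            values.append(sv.value)
        else:
            n_undefined += 1
    return NullEnsemble(
        statistic=stat_name,
        layers=layers,
        null_model=null_model,
        observed=observed,
        null_values=np.asarray(values, dtype=np.float64),
        n_undefined=n_undefined,
        n_perm=n_perm,
        seed=seed,
        n_swaps=n_swaps,
    )


def export_ensemble(ensemble: NullEnsemble, csv_path, sidecar_path=None) -> None:
    """Write replicate values as tidy CSV plus a JSON metadata sidecar."""
    import csv as _csv

    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(["statistic", "layers", "null_model", "replicate", "value"])
        for i, v in enumerate(ensemble.null_values):
            w.writerow(
                [ensemble.statistic, "|".join(ensemble.layers), ensemble.null_model, i, repr(float(v))]
            )
    if sidecar_path is not None:
        meta = {
            "statistic": ensemble.statistic,
            "layers": list(ensemble.layers),
            "null_model": ensemble.null_model,
            "observed": ensemble.observed.value,
            "observed_defined": ensemble.observed.defined,
            "seed": ensemble.seed,
            "n_perm": ensemble.n_perm,
            "n_swaps": ensemble.n_swaps,
            "n_undefined": ensemble.n_undefined,
        }
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)
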