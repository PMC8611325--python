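"""Multilayer directed nomination-network data model.

A fixed-choice sociometric survey yields *nominations*: a respondent
(sender) names another individual (receiver) and ticks the subset of
discussion topics the tie refers to.  Each topic induces a binary
directed network layer on a shared roster of respondents; the union of
the nine layers is the overall information-sharing network.  The
dyad-by-layer incidence matrix (rows = directed dyads present in at
least one layer, columns = topic layers) is the substrate of the
cross-network null models.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical topic-layer short names, in fixed roster order.
TOPICS: tuple[str, ...] = (
    "T.Bycatch",
    "gear",
    "weather",
    "location",
    "activity",
    "tech",
    "regs",
    "finance",
    "crew",
)

N_LAYERS = len(TOPICS)

TOPIC_INDEX: dict[str, int] = {t: i for i, t in enumerate(TOPICS)}


class DataModelError(ValueError):
    """Raised when an invariant of the network data model is violated."""


@dataclass(frozen=True)
class Roster:
    """Ordered, duplicate-free sequence of surveyed node identifiers.

    The roster order is fixed for the lifetime of an analysis and
    defines every matrix row/column ordering downstream.
    """

    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise DataModelError("roster contains duplicate node identifiers")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.node_ids)})

    def __len__(self) -> int:
        return len(self.node_ids)

    def __contains__(self, node: object) -> bool:
        return node in self._index  # type: ignore[attr-defined]

    def index(self, node: str) -> int:
        return self._index[node]  # type: ignore[attr-defined]


@dataclass(frozen=True)
class NominationRecord:
    """One survey answer: sender names receiver for a set of topics."""

    sender: str
    receiver: str
    topics: frozenset[str]

    def __post_init__(self) -> None:
        if self.sender == self.receiver:
            raise DataModelError("self-nomination is not permitted")
        if not self.topics:
            raise DataModelError("topic set must be non-empty")
        unknown = set(self.topics) - set(TOPICS)
        if unknown:
            raise DataModelError(f"unknown topic label(s): {sorted(unknown)}")


@dataclass(frozen=True)
class DirectedLayer:
    """Binary directed network on a roster: edge (s, r) = s nominated r."""

    roster: Roster
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for s, r in self.edges:
            if s == r:
                raise DataModelError(f"self-loop {s}->{r}")
            if s not in self.roster or r not in self.roster:
                raise DataModelError(f"edge endpoint off roster: {s}->{r}")

    @property
    def n_nodes(self) -> int:
        return len(self.roster)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) integer array of roster indices, sorted."""
        idx = self.roster.index
        arr = np.array(
            sorted((idx(s), idx(r)) for s, r in self.edges), dtype=np.int64
        ).reshape(-1, 2)
        return arr


@dataclass(frozen=True)
class MultilayerNetwork:
    """Nine directed binary layers sharing one roster."""

    roster: Roster
    layers: dict[str, DirectedLayer]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if set(self.layers) != set(TOPICS):
            raise DataModelError("a multilayer network must have exactly the 9 topic layers")
        for t, layer in self.layers.items():
            if layer.roster.node_ids != self.roster.node_ids:
                raise DataModelError(f"layer {t!r} has a different roster")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return self.roster == other.roster and all(
            self.layers[t].edges == other.layers[t].edges for t in TOPICS
        )

    def replace_layer(self, topic: str, layer: DirectedLayer) -> "MultilayerNetwork":
        new_layers = dict(self.layers)
        new_layers[topic] = layer
        return MultilayerNetwork(self.roster, new_layers, dict(self.meta))


@dataclass(frozen=True)
class DyadLayerIncidence:
    """Binary dyad-by-layer matrix.

    Row d, column t is 1 iff directed dyad ``dyads[d]`` is an edge in
    topic layer ``TOPICS[t]``.  Rows are lexicographically ordered by
    roster index of (sender, receiver); every row has at least one 1.
    """

    dyads: tuple[tuple[str, str], ...]
    matrix: np.ndarray  # (n_dyads, 9) uint8

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.uint8)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.dyads), N_LAYERS):
            raise DataModelError("incidence matrix shape does not match dyad list")
        if len(self.dyads) and m.sum(axis=1).min() < 1:
            raise DataModelError("incidence has a zero row (dyad present in no layer)")

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


class NominationRecords(Sequence):
    """Sequence of parsed nomination records plus an ingestion report.

    ``rejections`` lists ``(line_number, reason)`` pairs for rows that
    were dropped (self-nominations, empty topic sets).
    """

    def __init__(self, records: list[NominationRecord], rejections: list[tuple[int, str]]):
        self._records = records
        self.rejections = rejections

    def __getitem__(self, i):
        return self._records[i]

    def __len__(self) -> int:
        return len(self._records)


def _parse_topics_cell(cell: str) -> frozenset[str]:
    labels = [t.strip() for t in cell.split("|") if t.strip()]
    return frozenset(labels)


def read_nominations(path) -> NominationRecords:
    """Read nomination records from CSV.

    Two dialects are auto-detected from the header: a ``topics`` column
    holding a ``|``-delimited list of canonical short names, or a wide
    form with one 0/1 column per topic.  Malformed rows (self-
    nominations, empty topic sets) are rejected with a logged line
    number; an unknown topic label anywhere is a hard error.
    """
    records: list[NominationRecord] = []
    rejections: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataModelError(f"{path}: empty file")
        cols = set(reader.fieldnames)
        if not {"sender", "receiver"} <= cols:
            raise DataModelError(f"{path}: header must contain sender and receiver")
        wide = "topics" not in cols
        if wide:
            topic_cols = [c for c in reader.fieldnames if c not in ("sender", "receiver")]
            unknown = set(topic_cols) - set(TOPICS)
            if unknown:
                raise DataModelError(f"{path}: unknown topic column(s) {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            sender = row["sender"].strip()
            receiver = row["receiver"].strip()
            if wide:
                topics = frozenset(t for t in topic_cols if row[t].strip() == "1")
            else:
                topics = _parse_topics_cell(row["topics"])
                unknown = topics - set(TOPICS)
                if unknown:
                    raise DataModelError(
                        f"{path}:{lineno}: unknown topic label(s) {sorted(unknown)}"
                    )
            if sender == receiver:
                rejections.append((lineno, "self-nomination"))
                logger.warning("%s:%d: rejected self-nomination %r", path, lineno, sender)
                continue
            if not topics:
                rejections.append((lineno, "empty topic set"))
                logger.warning("%s:%d: rejected row with empty topic set", path, lineno)
                continue
            records.append(NominationRecord(sender, receiver, topics))
    return NominationRecords(records, rejections)


def write_nominations(records: Iterable[NominationRecord], path) -> None:
    """Write records in the narrow CSV dialect ``read_nominations`` accepts."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sender", "receiver", "topics"])
        for rec in records:
            topics = "|".join(t for t in TOPICS if t in rec.topics)
            writer.writerow([rec.sender, rec.receiver, topics])


def build_multilayer(
    records: Iterable[NominationRecord],
    roster: Roster,
    off_roster_policy: str = "drop",
) -> MultilayerNetwork:
    """Assemble the nine topic layers from nomination records.

    Receivers not on the roster are dropped and counted (the analysis
    covers respondent-to-respondent ties only); duplicate
    (sender, receiver, topic) triples collapse to one binary edge.
    Counters land in ``MultilayerNetwork.meta``.
    """
    if off_roster_policy != "drop":
        raise ValueError(f"unsupported off_roster_policy {off_roster_policy!r}")
    edge_sets: dict[str, set[tuple[str, str]]] = {t: set() for t in TOPICS}
    n_dropped = 0
    n_duplicate = 0
    for rec in records:
        if rec.sender not in roster:
            raise DataModelError(f"sender {rec.sender!r} is not on the roster")
        if rec.receiver not in roster:
            n_dropped += 1
            continue
        for t in rec.topics:
            if (rec.sender, rec.receiver) in edge_sets[t]:
                n_duplicate += 1
            else:
                edge_sets[t].add((rec.sender, rec.receiver))
    if n_dropped:
        logger.info("dropped %d off-roster nominations", n_dropped)
    layers = {t: DirectedLayer(roster, frozenset(es)) for t, es in edge_sets.items()}
    meta = {"n_dropped_off_roster": n_dropped, "n_duplicate_triples": n_duplicate}
    return MultilayerNetwork(roster, layers, meta)


def union_layer(m: MultilayerNetwork) -> DirectedLayer:
    """Directed layer of dyads connected in at least one topic layer."""
    edges: set[tuple[str, str]] = set()
    for layer in m.layers.values():
        edges |= layer.edges
    return DirectedLayer(m.roster, frozenset(edges))


def to_incidence(m: MultilayerNetwork) -> DyadLayerIncidence:
    """Unfold a multilayer network into its dyad-by-layer incidence.

    Dyad rows are sorted lexicographically by roster index of
    (sender, receiver) so the representation is deterministic.
    """
    idx = m.roster.index
    union = union_layer(m).edges
    dyads = tuple(sorted(union, key=lambda e: (idx(e[0]), idx(e[1]))))
    mat = np.zeros((len(dyads), N_LAYERS), dtype=np.uint8)
    dyad_row = {d: i for i, d in enumerate(dyads)}
    for t, layer in m.layers.items():
        col = TOPIC_INDEX[t]
        for e in layer.edges:
            mat[dyad_row[e], col] = 1
    return DyadLayerIncidence(dyads, mat)


def from_incidence(inc: DyadLayerIncidence, roster: Roster) -> MultilayerNetwork:
    """Fold an incidence back into a multilayer network (inverse of
    :func:`to_incidence` for networks on the same roster)."""
    edge_sets: dict[str, set[tuple[str, str]]] = {t: set() for t in TOPICS}
    mat = inc.matrix
    for i, dyad in enumerate(inc.dyads):
        for j in np.flatnonzero(mat[i]):
            edge_sets[TOPICS[j]].add(dyad)
    layers = {t: DirectedLayer(roster, frozenset(es)) for t, es in edge_sets.items()}
    return MultilayerNetwork(roster, layers)


def export_layer_edgelist(layer: DirectedLayer, path) -> None:
    """Write a layer as a sender,receiver CSV edge list (sorted)."""
    idx = layer.roster.index
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sender", "receiver"])
        for s, r in sorted(layer.edges, key=lambda e: (idx(e[0]), idx(e[1]))):
            writer.writerow([s, r])


def export_graphml(m: MultilayerNetwork, path) -> None:
    """Export the union network as GraphML with a ``layers`` edge attribute."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(m.roster.node_ids)
    inc = to_incidence(m)
    for i, (s, r) in enumerate(inc.dyads):
        labels = [TOPICS[j] for j in np.flatnonzero(inc.matrix[i])]
        g.add_edge(s, r, layers="|".join(labels))
    nx.write_graphml(g, path)


def export_incidence_csv(inc: DyadLayerIncidence, path) -> None:
    """Write the incidence as CSV: dyad id column then 9 binary topic columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dyad", *TOPICS])
        for (s, r), row in zip(inc.dyads, inc.matrix):
            writer.writerow([f"{s}→{r}", *row.tolist()])
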