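"""Shared fixtures: small random networks built programmatically."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nullnets.data_model import (
    TOPICS,
    DirectedLayer,
    MultilayerNetwork,
    Roster,
)


def make_roster(n: int) -> Roster:
    return Roster(tuple(f"N{i:03d}" for i in range(n)))


def random_layer(rng: np.random.Generator, n: int, p: float, roster: Roster | None = None) -> DirectedLayer:
    """Directed G(n, p) layer (no self-loops)."""
    roster = roster or make_roster(n)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    nodes = roster.node_ids
    edges = frozenset((nodes[i], nodes[j]) for i, j in zip(*np.nonzero(mask)))
    return DirectedLayer(roster, edges)


def random_multilayer(rng: np.random.Generator, n: int, p: float = 0.08) -> MultilayerNetwork:
    """Nine independent G(n, p) layers on a shared roster."""
    roster = make_roster(n)
    layers = {t: random_layer(rng, n, p * rng.uniform(0.5, 1.5), roster) for t in TOPICS}
    return MultilayerNetwork(roster, layers)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170701)


@pytest.fixture
def small_multilayer(rng) -> MultilayerNetwork:
    return random_multilayer(rng, n=12, p=0.15)
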