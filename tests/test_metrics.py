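"""Statistics vs independent brute-force oracles, plus invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nullnets.data_model import DirectedLayer, Roster
from nullnets.metrics import (
    attribute_assortativity,
    betweenness_variance,
    degree_assortativity,
    dispersion,
    dyadic_correlation,
    in_degree,
    in_eccentricity,
    out_degree,
)

import oracles
from conftest import make_roster, random_layer


def layer_from_edges(nodes, edges):
    return DirectedLayer(Roster(tuple(nodes)), frozenset(edges))


class TestDegrees:
    def test_small_example(self):
        layer = layer_from_edges("ABC", {("A", "B"), ("C", "B")})
        assert in_degree(layer) == {"A": 0, "B": 2, "C": 0}
        assert out_degree(layer) == {"A": 1, "B": 0, "C": 1}

    def test_empty_layer_all_zero(self):
        layer = layer_from_edges("ABC", set())
        assert set(in_degree(layer).values()) == {0}

    def test_degree_sums_equal_edge_count(self, rng):
        for _ in range(20):
            layer = random_layer(rng, 15, 0.2)
            assert sum(in_degree(layer).values()) == layer.n_edges
            assert sum(out_degree(layer).values()) == layer.n_edges


class TestAssortativity:
    def test_perfectly_assorted_disjoint_edges(self):
        layer = layer_from_edges("ABCD", {("A", "B"), ("C", "D")})
        values = {"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0}
        assert attribute_assortativity(layer, values).value == pytest.approx(1.0)

    def test_constant_values_undefined(self):
        layer = layer_from_edges("ABCD", {("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")})
        sv = attribute_assortativity(layer, {n: 2.0 for n in "ABCD"})
        assert not sv.defined and "variance" in sv.reason

    def test_empty_layer_undefined_with_reason(self):
        sv = attribute_assortativity(layer_from_edges("AB", set()), {"A": 1, "B": 2})
        assert not sv.defined and sv.reason == "no edges"

    def test_directed_cycle_degree_assortativity_undefined(self):
        layer = layer_from_edges("ABC", {("A", "B"), ("B", "C"), ("C", "A")})
        assert not degree_assortativity(layer, "in").defined

    def test_matches_brute_force_oracle(self, rng):
        n_checked = 0
        for _ in range(250):
            layer = random_layer(rng, int(rng.integers(6, 16)), 0.2)
            values = {n: float(rng.normal()) for n in layer.roster.node_ids}
            mine = attribute_assortativity(layer, values)
            ref = oracles.edge_assortativity(set(layer.edges), values)
            if ref is None:
                assert not mine.defined
            else:
                assert mine.value == pytest.approx(ref, abs=1e-10)
                n_checked += 1
        assert n_checked >= 200

    def test_degree_variant_delegates_to_attribute_variant(self, rng):
        layer = random_layer(rng, 15, 0.2)
        for mode, deg_fn in (("in", in_degree), ("out", out_degree)):
            direct = degree_assortativity(layer, mode)
            via_attr = attribute_assortativity(layer, {k: float(v) for k, v in deg_fn(layer).items()})
            assert direct.value == pytest.approx(via_attr.value, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.1, 5.0), beta=st.floats(-10, 10), seed=st.integers(0, 10**6))
    def test_affine_invariance(self, alpha, beta, seed):
        """r(αv+β) == r(v) for any α ≠ 0: the transform hits both
        endpoints of every edge, so even a negative α cancels."""
        rng = np.random.default_rng(seed)
        layer = random_layer(rng, 10, 0.3)
        values = {n: float(rng.normal()) for n in layer.roster.node_ids}
        base = attribute_assortativity(layer, values)
        if not base.defined:
            return
        up = attribute_assortativity(layer, {k: alpha * v + beta for k, v in values.items()})
        dn = attribute_assortativity(layer, {k: -alpha * v + beta for k, v in values.items()})
        assert up.value == pytest.approx(base.value, abs=1e-9)
        assert dn.value == pytest.approx(base.value, abs=1e-9)


class TestInEccentricity:
    def test_directed_path(self):
        layer = layer_from_edges("ABC", {("A", "B"), ("B", "C")})
        assert in_eccentricity(layer) == {"A": 0, "B": 1, "C": 2}

    def test_empty_layer_all_zero(self):
        assert set(in_eccentricity(layer_from_edges("ABCD", set())).values()) == {0}

    def test_matches_all_pairs_bfs_oracle(self, rng):
        for _ in range(220):
            layer = random_layer(rng, int(rng.integers(5, 31)), 0.1)
            ref = oracles.all_pairs_in_eccentricity(layer.roster.node_ids, set(layer.edges))
            assert in_eccentricity(layer) == ref

    def test_bounded_by_roster_size_minus_one(self, rng):
        for _ in range(20):
            layer = random_layer(rng, 12, 0.3)
            vals = list(in_eccentricity(layer).values())
            assert all(0 <= v <= 11 for v in vals)
            assert all(isinstance(v, int) for v in vals)


class TestDispersionAndBetweenness:
    def test_variance_and_mean_of_known_vector(self):
        values = {"A": 0.0, "B": 1.0, "C": 2.0}
        assert dispersion(values, "variance").value == pytest.approx(1.0)
        assert dispersion(values, "mean").value == pytest.approx(1.0)

    def test_constant_vector_zero_variance(self):
        assert dispersion({"A": 3.0, "B": 3.0}, "variance").value == 0.0

    def test_single_node_variance_undefined(self):
        assert not dispersion({"A": 1.0}, "variance").defined

    def test_betweenness_variance_matches_path_enumeration_oracle(self, rng):
        for _ in range(200):
            layer = random_layer(rng, int(rng.integers(5, 13)), 0.2)
            ref_bc = oracles.betweenness_by_path_enumeration(
                layer.roster.node_ids, set(layer.edges)
            )
            ref = oracles.sample_variance(list(ref_bc.values()))
            assert betweenness_variance(layer).value == pytest.approx(ref, abs=1e-10)


class TestStatisticsExport:
    def test_tidy_table_covers_all_layers_and_flags_undefined(self, rng, tmp_path):
        import csv

        from conftest import random_multilayer
        from nullnets.data_model import DirectedLayer
        from nullnets.metrics import export_statistics_csv

        m = random_multilayer(rng, 8, 0.2)
        m = m.replace_layer("crew", DirectedLayer(m.roster, frozenset()))
        export_statistics_csv(m, tmp_path / "stats.csv")
        with open(tmp_path / "stats.csv", newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 9 * 5
        crew_assort = [
            r for r in rows
            if r["layer"] == "crew" and r["statistic"] == "in_degree_assortativity"
        ][0]
        assert crew_assort["defined"] == "False" and crew_assort["value"] == ""


class TestDyadicCorrelation:
    def test_identical_layers_correlate_perfectly(self, rng):
        a = random_layer(rng, 8, 0.25)
        assert dyadic_correlation(a, a).value == pytest.approx(1.0)

    def test_complement_layers_anticorrelate_perfectly(self):
        roster = make_roster(4)
        nodes = roster.node_ids
        all_dyads = {(s, r) for s in nodes for r in nodes if s != r}
        edges_a = {d for d in all_dyads if hash(d) % 2 == 0} or {next(iter(all_dyads))}
        a = DirectedLayer(roster, frozenset(edges_a))
        b = DirectedLayer(roster, frozenset(all_dyads - edges_a))
        assert dyadic_correlation(a, b).value == pytest.approx(-1.0)

    def test_empty_or_complete_layer_undefined(self, rng):
        roster = make_roster(5)
        empty = DirectedLayer(roster, frozenset())
        a = random_layer(rng, 5, 0.4, roster)
        assert not dyadic_correlation(a, empty).defined

    def test_roster_mismatch_is_hard_error(self, rng):
        a = random_layer(rng, 5, 0.3)
        b = random_layer(rng, 6, 0.3)
        with pytest.raises(ValueError, match="roster"):
            dyadic_correlation(a, b)

    def test_matches_contingency_oracle_and_is_symmetric(self, rng):
        n_checked = 0
        for _ in range(250):
            roster = make_roster(int(rng.integers(5, 13)))
            a = random_layer(rng, len(roster), 0.25, roster)
            b = random_layer(rng, len(roster), 0.25, roster)
            ref = oracles.phi_by_contingency(roster.node_ids, set(a.edges), set(b.edges))
            mine = dyadic_correlation(a, b)
            if ref is None:
                assert not mine.defined
            else:
                assert mine.value == pytest.approx(ref, abs=1e-10)
                assert dyadic_correlation(b, a).value == pytest.approx(mine.value, abs=1e-12)
                assert -1.0 - 1e-12 <= mine.value <= 1.0 + 1e-12
                n_checked += 1
        assert n_checked >= 200
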