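"""Null models: conservation laws, forced configurations, seeding."""

import numpy as np
import pytest

from nullnets.data_model import (
    TOPICS,
    DirectedLayer,
    DyadLayerIncidence,
    Roster,
    to_incidence,
)
from nullnets.metrics import _degree_vectors
from nullnets.null_models import (
    generate_ensemble,
    permute_double_swap,
    permute_out_edges,
    replicate_seed,
    shuffle_layers_constrained,
    shuffle_layers_free,
)

from conftest import make_roster, random_layer, random_multilayer


def degree_sequences(layer):
    i, o = _degree_vectors(layer)
    return i.tolist(), o.tolist()


class TestPermuteOutEdges:
    def test_forced_configuration_is_identity(self):
        """A sender nominating everyone else has only one receiver set."""
        roster = Roster(("A", "B", "C", "D"))
        layer = DirectedLayer(roster, frozenset({("A", "B"), ("A", "C"), ("A", "D")}))
        for seed in range(20):
            assert permute_out_edges(layer, seed).edges == layer.edges

    def test_out_degrees_and_edge_count_conserved(self, rng):
        for _ in range(30):
            layer = random_layer(rng, 12, 0.2)
            perm = permute_out_edges(layer, rng)
            assert degree_sequences(perm)[1] == degree_sequences(layer)[1]
            assert perm.n_edges == layer.n_edges

    def test_no_self_loops_ever(self, rng):
        layer = random_layer(rng, 8, 0.4)
        for seed in range(200):
            for s, r in permute_out_edges(layer, seed).edges:
                assert s != r

    def test_single_edge_receiver_uniform_over_two_choices(self):
        """n=3, edge A→B: receiver must be B or C, each ~50% of seeds."""
        roster = Roster(("A", "B", "C"))
        layer = DirectedLayer(roster, frozenset({("A", "B")}))
        hits_b = sum(
            ("A", "B") in permute_out_edges(layer, seed).edges for seed in range(10_000)
        )
        # 99% binomial interval around 0.5 at n=10000: ±2.576*sqrt(.25/1e4)
        assert abs(hits_b / 10_000 - 0.5) < 2.576 * np.sqrt(0.25 / 10_000)


class TestPermuteDoubleSwap:
    def test_single_edge_returned_unchanged(self):
        roster = Roster(("A", "B"))
        layer = DirectedLayer(roster, frozenset({("A", "B")}))
        assert permute_double_swap(layer, 10, 0).edges == layer.edges

    def test_both_degree_sequences_conserved(self, rng):
        for _ in range(30):
            layer = random_layer(rng, 12, 0.2)
            perm = permute_double_swap(layer, rng_seed=rng)
            assert degree_sequences(perm) == degree_sequences(layer)
            assert perm.n_edges == layer.n_edges

    def test_two_state_instance_reaches_both_configurations_uniformly(self):
        roster = Roster(("A", "B", "C", "D"))
        layer = DirectedLayer(roster, frozenset({("A", "B"), ("C", "D")}))
        start = 0
        for seed in range(10_000):
            out = permute_double_swap(layer, rng_seed=seed)
            assert out.edges in (
                frozenset({("A", "B"), ("C", "D")}),
                frozenset({("A", "D"), ("C", "B")}),
            )
            start += out.edges == layer.edges
        assert abs(start / 10_000 - 0.5) < 2.576 * np.sqrt(0.25 / 10_000)

    def test_rigid_layer_warns_and_returns_input(self, caplog):
        """Two antiparallel edges admit no valid swap."""
        roster = Roster(("A", "B"))
        layer = DirectedLayer(roster, frozenset({("A", "B"), ("B", "A")}))
        with caplog.at_level("WARNING"):
            out = permute_double_swap(layer, 100, 3)
        assert out.edges == layer.edges
        assert any("swap" in r.message for r in caplog.records)


class TestShuffleLayersFree:
    def test_full_row_is_forced(self):
        inc = DyadLayerIncidence((("A", "B"),), np.ones((1, 9), dtype=np.uint8))
        for seed in range(50):
            assert shuffle_layers_free(inc, seed).matrix.sum() == 9

    def test_row_sums_conserved(self, rng):
        m = random_multilayer(rng, 10, 0.12)
        inc = to_incidence(m)
        for seed in range(100):
            out = shuffle_layers_free(inc, seed)
            assert (out.row_sums == inc.row_sums).all()
            assert out.dyads == inc.dyads

    def test_single_nomination_uniform_over_nine_layers(self):
        row = np.zeros((1, 9), dtype=np.uint8)
        row[0, 0] = 1
        inc = DyadLayerIncidence((("A", "B"),), row)
        counts = np.zeros(9, dtype=int)
        for seed in range(9_000):
            counts += shuffle_layers_free(inc, seed).matrix[0]
        p = 1 / 9
        half_width = 2.576 * np.sqrt(p * (1 - p) / 9_000)
        assert (np.abs(counts / 9_000 - p) < half_width).all()


class TestShuffleLayersConstrained:
    def test_all_ones_matrix_is_rigid(self, caplog):
        inc = DyadLayerIncidence(
            (("A", "B"), ("B", "A")), np.ones((2, 9), dtype=np.uint8)
        )
        with caplog.at_level("WARNING"):
            out = shuffle_layers_constrained(inc, 50, 0)
        assert (out.matrix == inc.matrix).all()
        assert any("rigid" in r.message for r in caplog.records)

    def test_margins_conserved(self, rng):
        m = random_multilayer(rng, 10, 0.12)
        inc = to_incidence(m)
        for seed in range(50):
            out = shuffle_layers_constrained(inc, rng_seed=seed)
            assert (out.row_sums == inc.row_sums).all()
            assert (out.column_sums == inc.column_sums).all()

    def test_two_state_incidence_uniform(self):
        mat = np.zeros((2, 9), dtype=np.uint8)
        mat[0, 0] = mat[1, 1] = 1
        inc = DyadLayerIncidence((("A", "B"), ("B", "A")), mat)
        same = 0
        for seed in range(10_000):
            out = shuffle_layers_constrained(inc, rng_seed=seed)
            same += (out.matrix == mat).all()
        assert abs(same / 10_000 - 0.5) < 2.576 * np.sqrt(0.25 / 10_000)


class TestSeeding:
    def test_same_seed_bit_identical_different_seed_differs(self, rng):
        layer = random_layer(rng, 15, 0.15)
        a = permute_out_edges(layer, 7)
        b = permute_out_edges(layer, 7)
        c = permute_out_edges(layer, 8)
        assert a.edges == b.edges
        assert a.edges != c.edges  # non-rigid input

    def test_replicate_seeds_distinct_across_axes(self):
        seen = set()
        for nm in ("edge1", "edge2"):
            for layer in (TOPICS[0], TOPICS[1], None):
                for rep in range(5):
                    seen.add(replicate_seed(11, nm, layer, rep).entropy)
        assert len(seen) == 2 * 3 * 5


class TestGenerateEnsemble:
    def test_conserved_statistic_has_zero_null_sd(self, small_multilayer):
        ens = generate_ensemble(
            small_multilayer, "edge_count", "edge1", n_perm=50, seed=1, layer="gear"
        )
        assert (ens.null_values == ens.observed.value).all()

    def test_union_edge_count_conserved_under_cross1(self, small_multilayer):
        from nullnets.data_model import union_layer

        observed = union_layer(small_multilayer).n_edges
        ens = generate_ensemble(
            small_multilayer,
            lambda layer: __import__("nullnets").metrics.StatisticValue(
                "probe", float(layer.n_edges)
            ),
            "cross1",
            n_perm=30,
            seed=2,
            layer="location",
        )
        # per-layer counts vary under cross1 but the union row set is fixed:
        # verified directly on the incidence
        inc = to_incidence(small_multilayer)
        from nullnets.null_models import shuffle_layers_free

        for seed in range(30):
            assert shuffle_layers_free(inc, seed).dyads == inc.dyads
        assert observed == len(inc.dyads)
        assert ens.n_perm == 30

    def test_ensembles_reproducible_and_order_invariant(self, small_multilayer):
        kw = dict(n_perm=25, seed=5, layer="gear")
        a = generate_ensemble(small_multilayer, "in_degree_assortativity", "edge1", **kw)
        b = generate_ensemble(small_multilayer, "in_degree_assortativity", "edge1", **kw)
        assert (a.null_values == b.null_values).all()

    def test_undefined_replicates_counted_not_interleaved(self):
        """A 2-node layer always permutes to itself; a constant-degree
        layer yields undefined assortativity in every replicate."""
        roster = Roster(("A", "B", "C"))
        layer = DirectedLayer(roster, frozenset({("A", "B"), ("B", "C"), ("C", "A")}))
        layers = {t: layer for t in TOPICS}
        from nullnets.data_model import MultilayerNetwork

        m = MultilayerNetwork(roster, dict(layers))
        ens = generate_ensemble(m, "in_degree_assortativity", "edge2", n_perm=10, seed=0, layer="gear")
        assert len(ens.null_values) + ens.n_undefined == 10

    def test_incompatible_pairing_rejected(self, small_multilayer):
        with pytest.raises(ValueError, match="cross"):
            generate_ensemble(
                small_multilayer,
                "dyadic_correlation",
                "edge1",
                n_perm=5,
                seed=0,
                layer="gear",
                layer2="regs",
            )
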