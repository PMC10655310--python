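"""Median-joining network construction checked against brute-force toys."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ystrkit.forensic import ClassSpectrum
from ystrkit.io import get_panel
from ystrkit.network import (
    NetworkInput,
    median_joining,
    preprocess_network_input,
    quasi_median,
    weighted_distance,
)
from ystrkit.simulate import (
    smm_populations,
    star_expansion_table,
    table_from_spectrum,
)


def unit_input(vectors, mult=None):
    L = len(vectors[0])
    return NetworkInput(
        loci=tuple(f"L{i}" for i in range(L)),
        vectors=[tuple(v) for v in vectors],
        multiplicities=mult or [1] * len(vectors),
        weights=np.ones(L),
    )


class TestPreprocess:
    def test_dys385_dropped_intermediates_rounded_nulls_coded(self):
        t = table_from_spectrum(ClassSpectrum(6, {1: 6}), "MH9", seed=0)
        s0 = t.sample_ids[0]
        t.data.at[s0, "DYS391"] = "17.2"
        t.data.at[s0, "DYS392"] = "0"
        inp = preprocess_network_input(t)
        assert "DYS385" not in inp.loci
        j391 = inp.loci.index("DYS391")
        j392 = inp.loci.index("DYS392")
        vec = next(v for v, ids in zip(inp.vectors, inp.sample_ids)
                   if s0 in ids)
        assert vec[j391] == 17     # 17.2 rounded to nearest repeat
        assert vec[j392] == 99     # null recoded

    def test_identical_vectors_merge_with_multiplicity(self):
        t = table_from_spectrum(ClassSpectrum(5, {1: 3, 2: 1}), "MH9", seed=1)
        inp = preprocess_network_input(t)
        assert sorted(inp.multiplicities) == [1, 1, 1, 2]
        assert sum(inp.multiplicities) == 5

    def test_uniform_default_weight_is_ten(self, small_table):
        inp = preprocess_network_input(small_table)
        assert (inp.weights == 10.0).all()


class TestWeightedDistance:
    def test_identity_zero(self):
        assert weighted_distance((15, 12), (15, 12), [10, 10]) == 0.0

    def test_single_step_weighted(self):
        assert weighted_distance((15,), (16,), [10]) == 10.0

    def test_stepwise_multi_step(self):
        assert weighted_distance((15,), (18,), [2]) == 6.0

    def test_null_state_is_categorical(self):
        # (15, 99) vs (16, 14): one repeat step + one null mismatch
        assert weighted_distance((15, 99), (16, 14), [1, 1]) == 2.0
        assert weighted_distance((99,), (99,), [5]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_distance((1, 2), (1,), [1, 1])


class TestQuasiMedian:
    def test_plain_median(self):
        assert quasi_median((1, 0, 5), (0, 1, 7), (0, 0, 6)) == (0, 0, 6)

    def test_null_majority(self):
        assert quasi_median((99, 1), (99, 2), (5, 3)) == (99, 2)

    def test_single_null_midpoint(self):
        assert quasi_median((99,), (14,), (18,)) == (16,)


def brute_force_steiner_star(vectors):
    """Exhaustively verify that the all-zero median minimises total length
    for the 3-haplotype disjoint-difference instance."""
    best = None
    for extra in itertools.product([0, 1], repeat=3):
        pts = [tuple(v) for v in vectors] + [extra]
        total = sum(
            sum(abs(a - b) for a, b in zip(extra, v)) for v in vectors
        )
        if best is None or total < best[0]:
            best = (total, extra)
    return best


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        net = median_joining(unit_input([(14, 12), (16, 12)]))
        assert net.graph.number_of_nodes() == 2
        [(u, v, d)] = net.graph.edges(data="length")
        assert d == 2.0

    def test_single_haplotype_trivial(self):
        net = median_joining(unit_input([(14, 12)]))
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_three_disjoint_differences_add_one_median(self):
        vectors = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        total, extra = brute_force_steiner_star(vectors)
        assert (total, extra) == (3, (0, 0, 0))  # star beats MST length 4
        net = median_joining(unit_input(vectors), epsilon=0.0)
        medians = net.median_nodes()
        assert len(medians) == 1
        assert net.graph.nodes[medians[0]]["vector"] == (0, 0, 0)
        assert net.total_length == 3.0
        assert all(net.graph.degree(m) == 3 for m in medians)

    def test_founder_star_no_medians(self):
        table = star_expansion_table(n_offspring=6, founder_multiplicity=4)
        net = median_joining(preprocess_network_input(table, weights=1.0))
        assert net.median_nodes() == []
        founder = max(
            net.graph.nodes, key=lambda n: net.graph.nodes[n]["multiplicity"]
        )
        assert net.graph.degree(founder) == 6
        assert net.graph.number_of_edges() == 6

    def test_observed_subgraph_contains_mst_when_no_medians(self):
        table = star_expansion_table(n_offspring=5, founder_multiplicity=3)
        inp = preprocess_network_input(table, weights=1.0)
        net = median_joining(inp, epsilon=0.0)
        # every offspring sits one step from the founder: star IS the MST
        obs = net.observed_nodes()
        sub = net.graph.subgraph(obs)
        assert nx.is_connected(sub)
        mst_len = sum(
            d for _, _, d in nx.minimum_spanning_tree(
                sub, weight="length"
            ).edges(data="length")
        )
        assert net.total_length == mst_len

    def test_all_observed_present_and_connected(self):
        tables = smm_populations(1, 25, divergence_generations=0, seed=21)
        inp = preprocess_network_input(tables["Pop1"], weights=10.0)
        net = median_joining(inp)
        assert nx.is_connected(net.graph)
        got = {net.graph.nodes[n]["vector"] for n in net.observed_nodes()}
        assert got == set(inp.vectors)
        total_mult = sum(
            net.graph.nodes[n]["multiplicity"] for n in net.observed_nodes()
        )
        assert total_mult == 25

    def test_idempotent_on_own_node_set(self):
        net = median_joining(unit_input([(1, 0, 0), (0, 1, 0), (0, 0, 1)]))
        vectors = sorted(
            net.graph.nodes[n]["vector"] for n in net.graph.nodes
        )
        again = median_joining(unit_input(vectors))
        assert again.median_nodes() == []
        assert again.graph.number_of_nodes() == len(vectors)

    def test_mismatch_mode(self):
        net = median_joining(unit_input([(14,), (18,)]), mode="mismatch")
        [(u, v, d)] = net.graph.edges(data="length")
        assert d == 1.0

    def test_epsilon_negative_rejected(self):
        with pytest.raises(ValueError):
            median_joining(unit_input([(1,), (2,)]), epsilon=-1)

    def test_tables_export(self):
        net = median_joining(unit_input([(1, 0, 0), (0, 1, 0), (0, 0, 1)]))
        nodes = net.nodes_table()
        edges = net.edges_table()
        assert set(nodes["kind"]) == {"observed", "median"}
        assert (edges["length"] == 1.0).all()

    def test_graphml_round_trip(self, tmp_path):
        net = median_joining(unit_input([(14, 12), (16, 12)]))
        path = tmp_path / "net.graphml"
        net.write_graphml(str(path))
        g = nx.read_graphml(str(path))
        assert g.number_of_nodes() == 2
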