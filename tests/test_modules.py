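"""Multilayer network construction, scoring, annealing, consensus, enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import (
    brute_coupled_score,
    brute_modularity,
    hypergeom_upper_tail,
    set_partitions,
)

from xspecies.io_core import ExpressionMatrix, OrthologyMap, ValidationError
from xspecies.modules import (
    AnnealSchedule,
    CoAssociationMatrix,
    MultilayerNetwork,
    Partition,
    anneal_partition,
    build_coexpression_layer,
    classify_module,
    coassociation,
    conservation_fraction,
    consensus_modules,
    ortholog_enrichment,
    score_partition,
    term_enrichment,
)
from xspecies.synthetic import simulate_multilayer_expression


def expr_of(data, species="sp0"):
    genes = [f"g{i}" for i in range(len(data))]
    samples = [f"s{j}" for j in range(len(data[0]))]
    meta = pd.DataFrame(
        {"species": species, "stage_index": range(len(samples)),
         "stage_label": samples, "tissue": ""},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(
        species, pd.DataFrame(data, index=genes, columns=samples), meta
    )


def random_two_layer_net(rng, n_per_layer=4, p=0.6, kappa=1.0, gamma=1.0):
    layers = {}
    for sp in ("a", "b"):
        g = nx.Graph()
        nodes = [(sp, f"g{i}") for i in range(n_per_layer)]
        g.add_nodes_from(nodes)
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < p:
                g.add_edge(u, v, weight=float(np.round(rng.random() + 0.1, 3)))
        layers[sp] = g
    couplings = []
    for i in range(n_per_layer):
        if rng.random() < 0.5:
            couplings.append((("a", f"g{i}"), ("b", f"g{i}")))
    return MultilayerNetwork(layers=layers, couplings=couplings,
                             kappa=kappa, gamma=gamma)


class TestCoexpressionLayer:
    def test_identical_profiles_get_unit_weight(self):
        expr = expr_of([[1, 2, 3, 4], [2, 4, 6, 8], [9, 1, 5, 2]])
        g = build_coexpression_layer(expr, top_k=1)
        assert g["sp0", "g0"]["sp0", "g1"]["weight"] == pytest.approx(1.0)

    def test_large_top_k_gives_complete_positive_graph(self, rng):
        data = rng.random((6, 10))
        expr = expr_of(data)
        g = build_coexpression_layer(expr, top_k=5)
        logged = np.log(data + 1)
        ranked = stats.rankdata(logged, axis=1)
        corr = np.corrcoef(ranked)
        for i, j in itertools.combinations(range(6), 2):
            if corr[i, j] > 0:
                assert g.has_edge(("sp0", f"g{i}"), ("sp0", f"g{j}"))
            else:
                assert not g.has_edge(("sp0", f"g{i}"), ("sp0", f"g{j}"))

    def test_edge_set_matches_brute_force_top_k(self, rng):
        data = rng.random((12, 8))
        expr = expr_of(data)
        top_k = 3
        g = build_coexpression_layer(expr, top_k=top_k)
        logged = np.log(data + 1)
        corr = np.corrcoef(stats.rankdata(logged, axis=1))
        want = set()
        genes = [f"g{i}" for i in range(12)]
        for i in range(12):
            order = sorted(
                (j for j in range(12) if j != i),
                key=lambda j: (-corr[i, j], genes[j]),
            )
            for j in order[:top_k]:
                if corr[i, j] > 0:
                    want.add(frozenset((genes[i], genes[j])))
        got = {frozenset((u[1], v[1])) for u, v in g.edges}
        assert got == want

    def test_constant_gene_is_isolated(self):
        expr = expr_of([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]])
        g = build_coexpression_layer(expr, top_k=2)
        assert g.degree[("sp0", "g1")] == 0

    def test_requires_enough_samples(self):
        with pytest.raises(ValidationError):
            build_coexpression_layer(expr_of([[1, 2], [3, 4]]))


class TestScorePartition:
    def test_single_module_has_zero_modularity(self):
        g = nx.Graph()
        g.add_edge(("a", "x"), ("a", "y"), weight=1.0)
        net = MultilayerNetwork(layers={"a": g}, couplings=[], kappa=0.0)
        labels = {("a", "x"): 0, ("a", "y"): 0}
        assert score_partition(net, labels) == pytest.approx(0.0)

    def test_two_disjoint_edges_split_scores_half(self):
        g = nx.Graph()
        g.add_edge(("a", "A"), ("a", "B"), weight=1.0)
        g.add_edge(("a", "C"), ("a", "D"), weight=1.0)
        net = MultilayerNetwork(layers={"a": g}, couplings=[], kappa=0.0)
        labels = {("a", "A"): 0, ("a", "B"): 0, ("a", "C"): 1, ("a", "D"): 1}
        assert score_partition(net, labels) == pytest.approx(0.5)

    def test_coupling_term_arithmetic(self):
        layers = {}
        for sp in ("a", "b"):
            g = nx.Graph()
            g.add_edge((sp, "x"), (sp, "y"), weight=1.0)
            layers[sp] = g
        net = MultilayerNetwork(
            layers=layers, couplings=[(("a", "x"), ("b", "x"))], kappa=1.0
        )
        together = {("a", "x"): 0, ("a", "y"): 0, ("b", "x"): 0, ("b", "y"): 0}
        apart = dict(together)
        apart[("b", "x")] = 1
        apart[("b", "y")] = 1
        assert score_partition(net, together) - score_partition(net, apart) == (
            pytest.approx(1.0)
        )

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            net = random_two_layer_net(rng, n_per_layer=int(rng.integers(2, 9)),
                                       kappa=float(rng.random() * 2),
                                       gamma=float(0.5 + rng.random()))
            nodes = net.nodes
            labels = {n: int(rng.integers(3)) for n in nodes}
            got = score_partition(net, labels)
            want = brute_coupled_score(net, labels)
            assert got == pytest.approx(want)

    def test_agrees_with_networkx_modularity(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(7, 0.5, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: ("a", f"g{i}") for i in g.nodes})
            for u, v in g.edges:
                g[u][v]["weight"] = float(np.round(rng.random() + 0.1, 3))
            if g.number_of_edges() == 0:
                continue
            net = MultilayerNetwork(layers={"a": g}, couplings=[], kappa=0.0)
            labels = {n: int(rng.integers(3)) for n in g.nodes}
            comms = {}
            for n, lab in labels.items():
                comms.setdefault(lab, set()).add(n)
            want = nx.algorithms.community.modularity(
                g, comms.values(), weight="weight"
            )
            assert score_partition(net, labels) == pytest.approx(want)

    def test_missing_node_is_an_error(self):
        g = nx.Graph()
        g.add_edge(("a", "x"), ("a", "y"), weight=1.0)
        net = MultilayerNetwork(layers={"a": g}, couplings=[])
        with pytest.raises(ValidationError):
            score_partition(net, {("a", "x"): 0})


class TestAnneal:
    fast = AnnealSchedule(t0=0.5, cooling=0.85, moves_per_node=15, t_min=1e-2)

    def test_edgeless_network_scores_zero(self):
        g = nx.Graph()
        g.add_nodes_from([("a", "x"), ("a", "y")])
        net = MultilayerNetwork(layers={"a": g}, couplings=[], kappa=0.0)
        part = anneal_partition(net, self.fast, seed=0)
        assert part.score == 0.0

    def test_toy_network_reaches_enumerated_global_optimum(self, rng):
        for rep in range(6):
            net = random_two_layer_net(rng, n_per_layer=3)
            nodes = net.nodes
            best = -np.inf
            for part in set_partitions(nodes):
                labels = {}
                for lab, block in enumerate(part):
                    for n in block:
                        labels[n] = lab
                best = max(best, score_partition(net, labels))
            got = anneal_partition(net, self.fast, seed=rep)
            assert got.score == pytest.approx(best, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        net = random_two_layer_net(rng, n_per_layer=6)
        a = anneal_partition(net, self.fast, seed=3)
        b = anneal_partition(net, self.fast, seed=3)
        assert a.assignment == b.assignment and a.score == b.score

    def test_result_is_single_move_locally_optimal(self, rng):
        net = random_two_layer_net(rng, n_per_layer=6)
        part = anneal_partition(net, self.fast, seed=1)
        base = part.score
        labels = dict(part.assignment)
        all_labels = set(labels.values()) | {max(labels.values()) + 1}
        for node in labels:
            for lab in all_labels:
                if lab == labels[node]:
                    continue
                trial = dict(labels)
                trial[node] = lab
                assert score_partition(net, trial) <= base + 1e-9


class TestCoassociation:
    def test_identical_partitions_give_binary_matrix(self):
        assignment = {("a", "x"): 0, ("a", "y"): 0, ("a", "z"): 1}
        parts = [Partition(assignment, 0.0)] * 5
        co = coassociation(parts)
        assert set(np.unique(co.frequency)) <= {0.0, 1.0}
        np.testing.assert_array_equal(np.diag(co.frequency), 1.0)

    def test_counting_matches_direct_oracle(self, rng):
        nodes = [("a", f"g{i}") for i in range(8)]
        parts = [
            Partition({n: int(rng.integers(3)) for n in nodes}, 0.0)
            for _ in range(10)
        ]
        co = coassociation(parts)
        for i, u in enumerate(co.nodes):
            for j, v in enumerate(co.nodes):
                want = np.mean(
                    [p.assignment[u] == p.assignment[v] for p in parts]
                )
                assert co.frequency[i, j] == pytest.approx(want)

    def test_run_order_invariance(self, rng):
        nodes = [("a", f"g{i}") for i in range(6)]
        parts = [
            Partition({n: int(rng.integers(2)) for n in nodes}, 0.0)
            for _ in range(7)
        ]
        a = coassociation(parts)
        b = coassociation(parts[::-1])
        np.testing.assert_array_equal(a.frequency, b.frequency)

    def test_mismatched_node_sets_error(self):
        p1 = Partition({("a", "x"): 0}, 0.0)
        p2 = Partition({("a", "y"): 0}, 0.0)
        with pytest.raises(ValidationError):
            coassociation([p1, p2])


class TestConsensus:
    def test_block_diagonal_matrix_recovers_blocks(self):
        nodes = [("a", f"g{i}") for i in range(6)]
        freq = np.zeros((6, 6))
        freq[:3, :3] = 1.0
        freq[3:, 3:] = 1.0
        co = CoAssociationMatrix(nodes=nodes, frequency=freq)
        ms = consensus_modules(co, cutoff=0.5)
        assert sorted(len(m) for m in ms.modules.values()) == [3, 3]

    def test_cutoff_one_requires_perfect_coassignment(self):
        nodes = [("a", "x"), ("a", "y"), ("a", "z")]
        freq = np.array([[1.0, 0.9, 1.0], [0.9, 1.0, 0.9], [1.0, 0.9, 1.0]])
        co = CoAssociationMatrix(nodes=nodes, frequency=freq)
        ms = consensus_modules(co, cutoff=1.0)
        assert list(ms.modules.values()) == [{("a", "x"), ("a", "z")}]

    def test_composition_classes(self):
        m3 = {("a", "1"), ("b", "2"), ("c", "3")}
        m1 = {("a", str(i)) for i in range(10)} | {("b", "x")}
        assert classify_module(m3) == "conserved-3"
        assert classify_module({("a", "1"), ("b", "2")}) == "conserved-2"
        assert classify_module(m1, min_share=0.1) == "species-specific"


class TestEnrichment:
    def test_ortholog_enrichment_matches_exact_tail(self):
        omap = OrthologyMap([("a", f"g{i}", "b", f"h{i}") for i in range(4)])
        module = {("a", f"g{i}") for i in range(4)} | {("b", f"h{i}") for i in range(4)}
        background = set(module)
        background |= {("a", f"x{i}") for i in range(12)}
        background |= {("b", f"y{i}") for i in range(12)}
        fold, p = ortholog_enrichment(module, omap, background)
        # all 8 module genes have partners, 8 of 32 background genes do
        want = hypergeom_upper_tail(8, 32, 8, 8)
        assert p == pytest.approx(want)
        assert fold == pytest.approx(8 / (8 * 8 / 32))

    def test_no_orthologs_gives_p_one(self):
        omap = OrthologyMap()
        module = {("a", "g1"), ("b", "h1")}
        fold, p = ortholog_enrichment(module, omap, module | {("a", "g2")})
        assert p == 1.0

    def test_module_equal_background_is_null(self):
        omap = OrthologyMap([("a", "g1", "b", "h1")])
        module = {("a", "g1"), ("b", "h1"), ("a", "g2")}
        fold, p = ortholog_enrichment(module, omap, set(module))
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_term_enrichment_matches_exact_tail(self):
        background = {f"g{i}" for i in range(20)}
        term_map = {f"g{i}": {"T"} for i in range(5)}
        module = {f"g{i}" for i in range(5)}
        table = term_enrichment(module, term_map, background, fdr=0.05)
        want = hypergeom_upper_tail(5, 20, 5, 5)
        assert table.loc[0, "p"] == pytest.approx(want)
        assert bool(table.loc[0, "significant"])

    def test_term_covering_background_and_empty_intersection(self):
        background = {f"g{i}" for i in range(10)}
        term_map = {g: {"ALL"} for g in background}
        term_map["g0"] = {"ALL", "RARE"}
        module = {"g5", "g6"}
        table = term_enrichment(module, term_map, background).set_index("term")
        assert table.loc["ALL", "p"] == pytest.approx(1.0)
        assert table.loc["RARE", "p"] == pytest.approx(1.0)  # k = 0

    def test_conservation_fraction(self):
        presence = {"g1": 56, "g2": 3, "g3": 10}
        assert conservation_fraction({"g1", "g2", "g3"}, presence, 1) == 1.0
        assert conservation_fraction({"g1", "g2", "g3"}, presence, 60) == 0.0
        assert conservation_fraction({"g1", "g2", "g3"}, presence, 10) == (
            pytest.approx(2 / 3)
        )
        with pytest.raises(ValidationError):
            conservation_fraction({"g9"}, presence, 1)


class TestPlantedDirectionality:
    def test_conserved_modules_hold_more_ortholog_pairs_than_specific(self):
        """With high ortholog consistency, planted cross-species modules
        contain ortholog pairs at a higher within-module rate than
        species-specific gene sets of the same size."""
        exprs, omap, truth = simulate_multilayer_expression(
            3, 30, 3, 0.8, 0.8, 0.95, 40, 17
        )
        pair_list = list(omap)

        def within_rate(nodeset):
            inside = sum(1 for a, b in pair_list if a in nodeset and b in nodeset)
            return inside / max(len(pair_list), 1)

        conserved = {
            n for n, m in truth.assignment.items() if m == 0
        }
        specific = {
            ("sp0", g) for (sp, g), m in truth.assignment.items()
            if sp == "sp0"
        }
        specific = set(list(specific)[: len(conserved)])
        assert within_rate(conserved) > within_rate(specific)
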