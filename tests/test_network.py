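"""Network construction, editing, and the connection strategies."""

import random

import pytest

import seednet as sn
from seednet.universe import Effect, Interaction

from conftest import oracle_adjacency, oracle_simple_paths


class TestInitNetwork:
    def test_missing_seeds_ignored_with_warning(self, toy, caplog):
        with caplog.at_level("WARNING"):
            net = sn.init_network(["A", "C", "ZZZ"], toy)
        assert set(net.nodes) == {"A", "C"}
        assert not net.edges  # no direct A-C edge in the fixture
        assert "ZZZ" in caplog.text

    def test_edges_between_seeds_are_induced(self, toy):
        net = sn.init_network(["A", "B"], toy)
        assert set(net.edges) == {("A", "B", "stimulation")}

    def test_all_seeds_absent_is_fatal(self, toy):
        with pytest.raises(ValueError, match="no seeds found"):
            sn.init_network(["ZZZ"], toy)

    def test_seed_flag_set(self, toy):
        net = sn.init_network(["A", "C"], toy)
        assert all(n.is_seed for n in net.nodes.values())


class TestLoadSif:
    def test_basic_parse(self, tmp_path, toy):
        path = tmp_path / "n.sif"
        path.write_text("A\tstimulation\tB\n")
        net = sn.load_sif_network(path, toy)
        assert set(net.nodes) == {"A", "B"}
        assert net.edges[("A", "B", "stimulation")].edge_type == "database"
        assert all(n.is_seed for n in net.nodes.values())

    def test_unknown_pairs_retained_as_user_edges(self, tmp_path, toy):
        path = tmp_path / "n.sif"
        path.write_text("X\tstimulation\tY\n")
        net = sn.load_sif_network(path, toy)
        assert net.edges[("X", "Y", "stimulation")].edge_type == "user"

    def test_empty_file_is_fatal(self, tmp_path, toy):
        path = tmp_path / "empty.sif"
        path.write_text("")
        with pytest.raises(ValueError):
            sn.load_sif_network(path, toy)

    def test_malformed_line_reports_line_number(self, tmp_path, toy):
        path = tmp_path / "bad.sif"
        path.write_text("A\tstimulation\tB\nA\tfrobnicates\tC\n")
        with pytest.raises(sn.exports.SifFormatError, match="line 2"):
            sn.load_sif_network(path, toy)


class TestModifyNetwork:
    def test_remove_node_cascades_to_incident_edges(self, toy):
        net = sn.init_network(["A", "B", "C"], toy)
        sn.modify_network(net, "remove_node", "B")
        assert set(net.nodes) == {"A", "C"}
        assert not net.edges

    def test_remove_path_deletes_edges_and_isolated_intermediates(self, toy):
        net = sn.init_network(["A", "B", "C"], toy)
        sn.modify_network(net, "remove_path", ["A", "B", "C"])
        assert ("A", "B", "stimulation") not in net.edges
        assert ("B", "C", "inhibition") not in net.edges
        assert "B" not in net.nodes

    def test_add_edge_requires_universe_record(self, toy):
        net = sn.init_network(["A", "C"], toy)
        with pytest.raises(ValueError):
            sn.modify_network(net, "add_edge_from_universe", ("A", "C"), universe=toy)
        sn.modify_network(net, "add_edge_from_universe", ("A", "B"), universe=toy)
        assert ("A", "B", "stimulation") in net.edges

    def test_remove_absent_node_is_warned_noop(self, toy, caplog):
        net = sn.init_network(["A", "C"], toy)
        with caplog.at_level("WARNING"):
            sn.modify_network(net, "remove_node", "QQQ")
        assert set(net.nodes) == {"A", "C"}
        assert "no-op" in caplog.text


class TestRpe:
    def test_toy_seed_pair_connects_both_directions(self, toy):
        net = sn.init_network(["A", "C"], toy).connect_rpe(toy, maxlen=3)
        assert set(net.nodes) == {"A", "B", "C", "D", "E"}
        assert net.has_path("A", "C", 3) and net.has_path("C", "A", 3)

    def test_connected_seeds_are_noop(self, toy):
        net = sn.init_network(["A", "B"], toy)
        # A->B direct; B->A via C,E within maxlen 3
        before_nodes = set(net.nodes)
        net.connect_rpe(toy, maxlen=3)
        assert net.has_path("B", "A", 3)
        assert before_nodes <= set(net.nodes)
        net2 = sn.Network(["A", "B"], toy).connect_rpe(toy, maxlen=3)
        net2_snapshot = (set(net2.nodes), set(net2.edges))
        net2.connect_rpe(toy, maxlen=3)
        assert (set(net2.nodes), set(net2.edges)) == net2_snapshot

    def test_signed_only_leaves_f_unconnected(self, toy):
        net = sn.init_network(["A", "F"], toy)
        net.connect_rpe(toy, maxlen=3, signed_only=True)
        record = net.provenance_log[-1]["params"]
        assert ("A", "F") in record["unconnected_pairs"]
        assert ("F", "A") in record["unconnected_pairs"]

    def test_dfs_algorithm_adds_single_path(self, toy):
        net = sn.init_network(["A", "E"], toy).connect_rpe(
            toy, maxlen=4, algorithm="dfs"
        )
        assert net.has_path("A", "E", 4)
        assert {"B", "C"} <= set(net.nodes)

    def test_completeness_and_parsimony_on_random_universes(self):
        """Every seed pair with a universe path within the bound ends up
        connected within the bound, and every non-seed node lies on a
        seed-to-seed path within the bound."""
        maxlen = 3
        for seed in range(100):
            uni = sn.generate_universe(
                sn.UniverseSpec(n_nodes=18, n_edges=40, seed=seed)
            )
            nodes = sorted(uni.node_set)
            rng = random.Random(seed)
            seeds = rng.sample(nodes, 4)
            try:
                net = sn.Network(seeds, uni)
            except ValueError:
                continue
            net.connect_rpe(uni, maxlen=maxlen)
            adj = oracle_adjacency(uni)
            present = [s for s in seeds if s in net.nodes]
            for s in present:
                for t in present:
                    if s == t:
                        continue
                    if oracle_simple_paths(adj, s, t, maxlen):
                        assert net.has_path(s, t, maxlen), (seed, s, t)
            # parsimony: non-seed nodes sit on a bounded seed-to-seed path
            for v in net.nodes:
                if net.nodes[v].is_seed:
                    continue
                ok = any(
                    net.has_path(s, v, k) and net.has_path(v, t, maxlen - k)
                    for s in present
                    for t in present
                    if s != t
                    for k in range(1, maxlen)
                )
                assert ok, (seed, v)


class TestIne:
    def test_one_iteration_expands_and_prunes(self, toy):
        net = sn.init_network(["A", "C"], toy).connect_ine(toy, max_iterations=1)
        assert set(net.nodes) == {"A", "B", "C", "D", "E"}

    def test_directly_connected_seeds_stop_early(self, toy):
        net = sn.init_network(["A", "B"], toy).connect_ine(toy, max_iterations=3)
        assert net.provenance_log[-1]["params"]["iterations_run"] == 0
        assert set(net.nodes) == {"A", "B"}

    def test_unreachable_seeds_warn_and_return_partial(self, caplog):
        uni = sn.Universe(
            [
                Interaction(source="A", target="B", is_directed=True),
                Interaction(source="X", target="Y", is_directed=True),
            ]
        )
        with caplog.at_level("WARNING"):
            net = sn.Network(["A", "Y"], uni).connect_ine(uni, max_iterations=2)
        assert "disconnected" in caplog.text
        assert {"A", "Y"} <= set(net.nodes)

    def test_postconditions_on_random_runs(self):
        """After INE+prune no non-seed node lacks sources or sits outside
        the seed component (independent audit over the edge table)."""
        import networkx as nx

        for seed in range(100):
            uni = sn.generate_universe(
                sn.UniverseSpec(n_nodes=20, n_edges=45, seed=1000 + seed)
            )
            rng = random.Random(seed)
            seeds = rng.sample(sorted(uni.node_set), 3)
            net = sn.Network(seeds, uni).connect_ine(uni, max_iterations=2)
            indeg = {n: 0 for n in net.nodes}
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            for e in net.edges.values():
                indeg[e.target] += 1
                if not e.directed:
                    indeg[e.source] += 1
                g.add_edge(e.source, e.target)
            seed_set = {n for n in net.nodes if net.nodes[n].is_seed}
            comps = sorted(
                nx.connected_components(g),
                key=lambda c: (-len(c & seed_set), -len(c), min(c)),
            )
            keep = comps[0] if comps else set()
            for n in net.nodes:
                if n in seed_set:
                    continue
                assert indeg[n] > 0, (seed, n)
                assert n in keep, (seed, n)


class TestRce:
    def test_rankings_on_toy(self, toy):
        net = sn.init_network(list("ABCDEF"), toy)
        cascade = net.connect_rce(toy, ["C", "E"], depth=1)
        assert cascade.layers[0] == {
            "B": frozenset({"C"}),
            "C": frozenset({"E"}),
            "D": frozenset({"C"}),
            "F": frozenset({"C"}),
        }
        assert cascade.ranking == [("B", 1), ("C", 1), ("D", 1), ("F", 1)]

    def test_shared_regulator_ranks_first(self):
        uni = sn.Universe(
            [
                Interaction(source="R", target="T1", is_directed=True),
                Interaction(source="R", target="T2", is_directed=True),
                Interaction(source="S", target="T2", is_directed=True),
            ]
        )
        net = sn.Network(["T1", "T2"], uni)
        cascade = net.connect_rce(uni, ["T1", "T2"], depth=1)
        assert cascade.ranking[0] == ("R", 2)

    def test_depth_two_reaches_indirect_regulators(self, toy):
        net = sn.init_network(["C"], toy)
        cascade = net.connect_rce(toy, ["C"], depth=2)
        assert ("A", 2) in cascade.rankings[1]

    def test_attach_adds_cover_regulators_and_edges(self, toy):
        net = sn.init_network(["C"], toy)
        net.connect_rce(toy, ["C"], depth=1, attach=True)
        attached = net.provenance_log[-1]["params"]["attached"]
        assert len(attached) == 1  # any single direct regulator covers {C}
        reg = attached[0]
        assert (reg, "C", toy.edges_between(reg, "C")[0].effect.value) in net.edges

    def test_outputs_outside_network_rejected(self, toy):
        net = sn.init_network(["A"], toy)
        with pytest.raises(ValueError, match="ZZ"):
            net.connect_rce(toy, ["ZZ"])


class TestMcm:
    def test_out_mode_paths_and_group_c(self, toy):
        net = sn.init_network(["A", "C"], toy)
        net.connect_mcm(toy, {"A"}, {"C"}, mode="OUT", maxlen=2)
        record = net.provenance_log[-1]["params"]
        assert record["group_c"] == ["B", "D"]
        assert {"B", "D"} <= set(net.nodes)

    def test_in_mode_finds_reverse_path(self, toy):
        net = sn.init_network(["A", "C"], toy)
        net.connect_mcm(toy, {"A"}, {"C"}, mode="IN", maxlen=2)
        record = net.provenance_log[-1]["params"]
        assert record["group_c"] == ["E"]
        assert net.has_path("C", "A", 2)

    def test_overlapping_groups_rejected(self, toy):
        net = sn.init_network(["A", "C"], toy)
        with pytest.raises(ValueError, match="overlap"):
            net.connect_mcm(toy, {"A", "C"}, {"C"}, mode="OUT")

    def test_fully_absent_group_is_fatal(self, toy):
        net = sn.init_network(["A"], toy)
        with pytest.raises(ValueError, match="absent"):
            net.connect_mcm(toy, {"A"}, {"ZZ", "QQ"}, mode="OUT")

    def test_in_mode_directionality_audit_on_random_instances(self):
        """Edges added by IN-mode path search all lie on directed b->a paths."""
        for seed in range(50):
            uni = sn.generate_universe(
                sn.UniverseSpec(n_nodes=15, n_edges=40, seed=2000 + seed)
            )
            nodes = sorted(uni.node_set)
            rng = random.Random(seed)
            picked = rng.sample(nodes, 5)
            group_a, group_b = set(picked[:2]), set(picked[2:])
            net = sn.Network(sorted(group_a | group_b), uni)
            net.connect_mcm(uni, group_a, group_b, mode="IN", maxlen=3)
            record = net.provenance_log[-1]["params"]
            adj = oracle_adjacency(uni, directed_only=True)
            legal = set()
            for b in group_b:
                for a in group_a:
                    for p in oracle_simple_paths(adj, b, a, 3):
                        legal.update(zip(p, p[1:]))
            assert set(map(tuple, record["path_edges"])) <= legal, seed


class TestExpandComplexes:
    def test_components_and_membership_edges_added(self, complex_toy):
        net = sn.Network(["CPLX1", "A"], complex_toy)
        net.expand_complexes(complex_toy)
        assert {"P", "Q"} <= set(net.nodes)
        assert ("P", "CPLX1", "form_complex") in net.edges
        assert ("Q", "CPLX1", "form_complex") in net.edges
        # component P also connects to the pre-existing node A
        assert ("P", "A", "stimulation") in net.edges

    def test_network_without_complexes_unchanged(self, toy):
        net = sn.init_network(["A", "B"], toy)
        before = (set(net.nodes), set(net.edges))
        net.expand_complexes(toy)
        assert (set(net.nodes), set(net.edges)) == before


class TestPrune:
    def test_isolated_node_removed(self, toy):
        net = sn.init_network(["A", "B"], toy)
        net.nodes["LONER"] = sn.Node(symbol="LONER")
        net.prune()
        assert "LONER" not in net.nodes

    def test_sourceless_chain_removed_iteratively(self):
        uni = sn.Universe(
            [
                Interaction(source="F", target="C", is_directed=True),
                Interaction(source="A", target="B", is_directed=True),
                Interaction(source="B", target="A", is_directed=True),
            ]
        )
        net = sn.Network(["A", "B", "C", "F"], uni)
        for n in ("C", "F"):
            net.nodes[n].is_seed = False
        net.prune()
        assert "F" not in net.nodes and "C" not in net.nodes
        assert {"A", "B"} == set(net.nodes)

    def test_protected_seed_survives_without_sources(self, toy):
        net = sn.init_network(["F", "C"], toy)
        net.prune(protect_seeds=True)
        assert "F" in net.nodes
        net.prune(protect_seeds=False)
        assert "F" not in net.nodes


def test_every_strategy_appends_one_provenance_record(toy):
    net = sn.init_network(["A", "C"], toy)
    baseline = len(net.provenance_log)
    net.connect_rpe(toy, maxlen=3)
    net.connect_ine(toy, max_iterations=1)
    net.connect_rce(toy, ["C"], depth=1)
    net.connect_mcm(toy, {"A"}, {"C"}, mode="OUT", maxlen=2)
    net.expand_complexes(toy)
    net.prune()
    assert len(net.provenance_log) == baseline + 6
    assert [r["strategy"] for r in net.provenance_log[baseline:]] == [
        "rpe",
        "ine",
        "rce",
        "mcm",
        "expand_complexes",
        "prune",
    ]


def test_strategies_are_deterministic(toy, tmp_path):
    def run(tag):
        uni = sn.generate_universe(sn.UniverseSpec(n_nodes=20, n_edges=50, seed=5))
        net = sn.Network(sorted(uni.node_set)[:4], uni)
        net.connect_rpe(uni, maxlen=3)
        net.connect_ine(uni, max_iterations=1)
        net.connect_mcm(
            uni, {sorted(net.nodes)[0]}, {sorted(net.nodes)[-1]}, mode="ALL", maxlen=2
        )
        out = tmp_path / f"{tag}.sif"
        sn.write_sif(net, out)
        return out.read_bytes()

    assert run("first") == run("second")
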