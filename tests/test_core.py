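import networkx as nx
import numpy as np
import pytest

from cytobool import core as CR
from cytobool import stp
from cytobool.network import BooleanNetwork, BoolRule
from cytobool.synthetic import generate_ground_truth_bn


def graph_oracle_strip(bn):
    """Independent closure oracle: iteratively delete out-degree-0 nodes of
    the parent-list digraph using networkx only."""
    g = bn.to_digraph()
    while True:
        sinks = [n for n in g.nodes if g.out_degree(n) == 0]
        if not sinks:
            return set(g.nodes)
        g.remove_nodes_from(sinks)


class TestStripOutputs:
    def test_chain_cascades_to_single_node(self):
        rules = {
            "a": BoolRule.identity("a"),
            "b": BoolRule.identity("a"),
            "c": BoolRule.identity("b"),
        }
        bn = BooleanNetwork(rules)
        red = CR.strip_outputs(bn)
        assert red.network.nodes == ("a",)
        assert {r.name for r in red.removed} == {"b", "c"}

    def test_m2c_strip_matches_graph_oracle(self, m2c):
        red = CR.strip_outputs(m2c.network)
        assert set(red.network.nodes) == graph_oracle_strip(m2c.network)
        assert set(red.network.nodes) == {
            "IFN-gamma", "IL-1alpha", "IL-11", "MCP-3", "MCP-5", "SCF",
        }

    def test_cycle_left_unchanged(self):
        rules = {
            "a": BoolRule.identity("c"),
            "b": BoolRule.identity("a"),
            "c": BoolRule.identity("b"),
        }
        bn = BooleanNetwork(rules)
        assert CR.strip_outputs(bn).network.nodes == bn.nodes

    def test_never_removes_cycle_nodes(self):
        for seed in range(15):
            bn = generate_ground_truth_bn(7, 3, seed=seed)
            g = bn.to_digraph()
            on_cycle = set().union(
                *(set(c) for c in nx.simple_cycles(g)), set()
            )
            removed = {r.name for r in CR.strip_outputs(bn).removed}
            assert not (removed & on_cycle)


class TestRemoveInputs:
    def net_with_input(self):
        rules = {
            "x": BoolRule.from_sop(
                ["a", "y"], [(("a", False), ("y", False))]
            ),
            "y": BoolRule.identity("x"),
        }
        return BooleanNetwork(rules, nodes=["a", "x", "y"], inputs=["a"])

    def test_clamp_one_simplifies_and(self):
        red = CR.remove_inputs(self.net_with_input(), {"a": 1})
        assert red.network.rules["x"].parents == ("y",)
        assert red.network.rules["x"].table == (0, 1)

    def test_clamp_zero_annihilates_and(self):
        red = CR.remove_inputs(self.net_with_input(), {"a": 0})
        assert red.network.rules["x"].is_constant()

    def test_clamping_node_with_parents_rejected(self):
        with pytest.raises(ValueError, match="has parents"):
            CR.remove_inputs(self.net_with_input(), {"y": 1})

    def test_m2a_il1a_clamp_silences_lymphotactin(self, m2a):
        """The published M2a input IL-1alpha stays low; clamping it to 0
        makes Lymphotactin's rule (IL-1alpha & MCP-5) constant 0."""
        red = CR.remove_inputs(m2a.network, {"IL-1alpha": 0})
        rule = red.network.rules["Lymphotactin"]
        assert rule.is_constant() and rule.table[0] == 0


class TestCollapseChains:
    def test_double_negation_parity(self):
        # x -> m1 (NOT) -> m2 (NOT) -> y: collapsing both relays must leave
        # y depending *positively* on x, with the two-step delay recorded
        rules = {
            "x": BoolRule.from_sop(["x"], [(("x", True),)]),  # oscillator
            "m1": BoolRule.from_sop(["x"], [(("x", True),)]),
            "m2": BoolRule.from_sop(["m1"], [(("m1", True),)]),
            "y": BoolRule.from_sop(
                ["m2", "y"], [(("m2", False), ("y", False))]
            ),
        }
        bn = BooleanNetwork(rules)
        red = CR.collapse_chains(bn)
        assert set(red.network.nodes) == {"x", "y"}
        recs = {r.name: r for r in red.removed}
        assert set(recs) == {"m1", "m2"}
        assert {recs["m1"].delay, recs["m2"].delay} == {1, 2}
        rule = red.network.rules["y"]
        assert set(rule.parents) == {"x", "y"}
        # y' = x & y: positive (double-negated) dependence on x
        bits = {p: i for i, p in enumerate(rule.parents)}
        vec = [0, 0]
        vec[bits["x"]], vec[bits["y"]] = 1, 1
        assert rule(vec) == 1
        vec[bits["x"]] = 0
        assert rule(vec) == 0

    def test_m2c_collapse_gives_published_five_node_core(self, m2c):
        red = CR.reduce_network(m2c.network, collapse=True)
        assert set(red.network.nodes) == set(m2c.core_nodes)
        # MCP-3 is the only collapsed transduction node
        collapsed = [r for r in red.removed if r.kind == "collapsed"]
        assert [r.name for r in collapsed] == ["MCP-3"]
        # collapsed rule: IL-1alpha now reads IL-11 & IFN-gamma
        got = red.network.rules["IL-1alpha"]
        want = m2c.core.rules["IL-1alpha"]
        assert set(got.parents) == set(want.parents)
        for r in range(4):
            bits = [(r >> 1) & 1, r & 1]
            w_bits = [
                bits[got.parents.index(p)] for p in want.parents
            ]
            assert got(bits) == want(w_bits)

    def test_two_cycle_nodes_protected(self, m2c):
        """The published MCP-5/SCF mutual-inhibition loop survives the
        collapse even though MCP-5 has one parent and one child."""
        red = CR.reduce_network(m2c.network, collapse=True)
        assert "MCP-5" in red.network.nodes
        assert "SCF" in red.network.nodes

    def test_collapsed_core_dynamics_match_published_rules(self, m2c):
        red = CR.reduce_network(m2c.network, collapse=True)
        sub = red.network.subnetwork(list(m2c.core.nodes))
        for r in range(32):
            bits = [(r >> (4 - i)) & 1 for i in range(5)]
            assert sub.step(bits) == m2c.core.step(bits)

    def test_idempotent(self, m2c):
        red = CR.reduce_network(m2c.network, collapse=True)
        again = CR.reduce_network(red.network, collapse=True)
        assert again.network.nodes == red.network.nodes
        assert again.removed == []


class TestReconstruct:
    def test_single_output_shifted_copy(self):
        rules = {
            "x": BoolRule.from_sop(["x"], [(("x", True),)]),  # oscillates
            "o": BoolRule.identity("x"),
        }
        bn = BooleanNetwork(rules)
        red = CR.strip_outputs(bn)
        traj = bn.trajectory((1, 0), 6)
        core_traj = [(s[0],) for s in traj]
        rec = CR.reconstruct(core_traj, red, {"x": 1, "o": 0})
        for k in range(len(traj)):
            assert rec[k]["o"] == traj[k][1]
            assert rec[k]["x"] == traj[k][0]

    def test_empty_removed_set_is_identity(self):
        rules = {"a": BoolRule.from_sop(["a"], [(("a", True),)])}
        bn = BooleanNetwork(rules)
        red = CR.strip_outputs(bn)
        assert red.removed == []
        rec = CR.reconstruct([(1,), (0,)], red, {"a": 1})
        assert rec == [{"a": 1}, {"a": 0}]

    def test_full_m2c_reconstruction_equals_full_simulation(self, m2c):
        """Simulate the complete published network 10 steps; stripping
        outputs and reconstructing them from the core trajectory must
        reproduce every node's course exactly."""
        bn = m2c.network
        red = CR.reduce_network(bn, collapse=False)
        rng = np.random.default_rng(11)
        for _ in range(5):
            init_bits = tuple(int(b) for b in rng.integers(0, 2, bn.n))
            init = dict(zip(bn.nodes, init_bits))
            full = bn.trajectory(init_bits, 10)
            core_idx = [bn.nodes.index(n) for n in red.network.nodes]
            core_traj = [tuple(s[i] for i in core_idx) for s in full]
            rec = CR.reconstruct(core_traj, red, init)
            for k, state in enumerate(full):
                for i, nd in enumerate(bn.nodes):
                    assert rec[k][nd] == state[i], (k, nd)

    def test_random_networks_projection_preserved(self):
        """Output-stripping is dynamics-exact: the full trajectory projected
        onto the core equals the core's own trajectory (random networks)."""
        rng = np.random.default_rng(5)
        checked = 0
        for seed in range(60):
            bn = generate_ground_truth_bn(6, 2, seed=seed)
            red = CR.strip_outputs(bn)
            if not red.removed or red.network.n == 0:
                continue
            checked += 1
            init = tuple(int(b) for b in rng.integers(0, 2, bn.n))
            full = bn.trajectory(init, 12)
            core_idx = [bn.nodes.index(n) for n in red.network.nodes]
            start = tuple(init[i] for i in core_idx)
            core_traj = red.network.trajectory(start, 12)
            for k in range(13):
                assert tuple(full[k][i] for i in core_idx) == core_traj[k]
            if checked >= 50:
                break
        assert checked >= 20
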