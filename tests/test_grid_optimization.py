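"""Stage 3: node weight scheme and region-constrained optimization."""

import itertools

import numpy as np
import pytest

from gmlayout import (
    GridLayout,
    ModuleAssignment,
    ModuleRegion,
    Network,
    OptimizerParams,
    edge_edge_crossing_ratio,
    expand_modules,
    generate_modular_network,
    layout_cost,
    manhattan,
    optimize_nodes,
    set_node_weight,
)


class TestSetNodeWeight:
    def test_same_module_weights_by_path_length(self, path_abc):
        net, assign = path_abc
        w = set_node_weight(net, assign)
        assert w.get("a", "b") == 40.0   # path length 1
        assert w.get("a", "c") == 0.0    # path length 2

    def test_long_paths_and_unreachable_pairs_repel(self):
        # path of 5 nodes: ends are 4 steps apart; z is disconnected
        nodes = ["p1", "p2", "p3", "p4", "p5", "z"]
        edges = [("p1", "p2"), ("p2", "p3"), ("p3", "p4"), ("p4", "p5")]
        net = Network(nodes, edges)
        assign = ModuleAssignment({u: "M" for u in nodes})
        w = set_node_weight(net, assign)
        assert w.get("p1", "p5") == -10.0
        assert w.get("p1", "p4") == -10.0  # length 3 is already "beyond"
        assert w.get("p1", "z") == -10.0   # unreachable

    def test_intermodule_adjacent_pair_gets_extra(self):
        net = Network(["a", "b"], [("a", "b")])
        assign = ModuleAssignment({"a": "A", "b": "B"})
        w = set_node_weight(net, assign)
        w_off = set_node_weight(net, assign, extra_weight=0.0)
        assert w.get("a", "b") - w_off.get("a", "b") == 40.0

    def test_extra_applies_only_at_path_length_one(self):
        net = Network(["a", "b", "c"], [("a", "b"), ("b", "c")])
        assign = ModuleAssignment({"a": "A", "b": "A", "c": "B"})
        w = set_node_weight(net, assign)
        assert w.get("b", "c") == 40.0  # inter-module adjacent: the extra
        assert w.get("a", "c") == 0.0   # inter-module but length 2: nothing

    def test_accumulating_variant_stacks_base_and_extra(self):
        net = Network(["a", "b"], [("a", "b")])
        assign = ModuleAssignment({"a": "A", "b": "B"})
        w = set_node_weight(net, assign, inter_base="path")
        assert w.get("a", "b") == 80.0  # base 40 + extra 40

    def test_configurable_scheme(self):
        net = Network(["a", "b", "c"], [("a", "b")])
        assign = ModuleAssignment({"a": "A", "b": "A", "c": "A"})
        w = set_node_weight(net, assign, base_weights=(7, 1, -2))
        assert w.get("a", "b") == 7.0
        assert w.get("a", "c") == -2.0

    def test_symmetry(self, path_abc):
        net, assign = path_abc
        w = set_node_weight(net, assign)
        for u, v in itertools.combinations(net.nodes, 2):
            assert w.get(u, v) == w.get(v, u)


def region_points(region: ModuleRegion):
    return region.rect.points()


class TestOptimizeNodes:
    def params(self, seed=0, niter=60):
        return OptimizerParams(niter=niter, perturb_prob=0.2, seed=seed)

    def test_single_node_module(self):
        net = Network(["a"], [])
        assign = ModuleAssignment({"a": "A"})
        regions = {"A": ModuleRegion("A", 0, 0, 2)}
        w = set_node_weight(net, assign)
        out = optimize_nodes(net, w, regions, assign, self.params())
        assert regions["A"].rect.contains(out["a"])
        assert layout_cost(w, out) == 0.0

    def test_bridged_singleton_modules_meet_at_facing_borders(self):
        """Two 1-node modules with an edge: the optimum from brute force over
        both regions' point sets is the minimal cross-region distance."""
        net = Network(["a", "b"], [("a", "b")])
        assign = ModuleAssignment({"a": "A", "b": "B"})
        regions = {
            "A": ModuleRegion("A", 0, 0, 2),
            "B": ModuleRegion("B", 6, 0, 2),
        }
        best = min(
            manhattan(p, q)
            for p in region_points(regions["A"])
            for q in region_points(regions["B"])
        )
        out = optimize_nodes(net, set_node_weight(net, assign), regions,
                             assign, self.params(seed=2))
        assert manhattan(out["a"], out["b"]) == best

    def test_capacity_violation_raises_before_optimizing(self):
        net = Network(["a", "b", "c", "d", "e"], [])
        assign = ModuleAssignment({u: "A" for u in net.nodes})
        regions = {"A": ModuleRegion("A", 0, 0, 2)}  # 4 points < 5 nodes
        with pytest.raises(ValueError, match="capacity|holds"):
            optimize_nodes(net, set_node_weight(net, assign), regions,
                           assign, self.params())

    def test_containment_and_injectivity(self):
        net, planted = generate_modular_network([6, 6, 6], 0.8, 0.05, seed=3)
        w = set_node_weight(net, planted)
        placed = GridLayout({"M1": (0, 0), "M2": (1, 0), "M3": (0, 1)})
        regions = expand_modules(placed, planted)
        out = optimize_nodes(net, w, regions, planted, self.params(seed=5))
        assert len(out.occupied()) == net.n
        for u in net.nodes:
            assert regions[planted.module_of[u]].rect.contains(out[u])

    def test_cost_not_above_initial_random_layout(self):
        net, planted = generate_modular_network([5, 5], 0.9, 0.1, seed=1)
        w = set_node_weight(net, planted)
        placed = GridLayout({"M1": (0, 0), "M2": (1, 0)})
        regions = expand_modules(placed, planted)
        params = self.params(seed=11)
        # replicate the documented initial placement to compare costs
        rng = np.random.default_rng(params.seed)
        pos = {}
        for mod in sorted(planted.modules):
            pts = regions[mod].rect.points()
            chosen = rng.choice(len(pts), size=len(planted.members(mod)),
                                replace=False)
            for u, i in zip(planted.members(mod), chosen):
                pos[u] = pts[int(i)]
        initial = GridLayout({u: pos[u] for u in net.nodes})
        out = optimize_nodes(net, w, regions, planted, params)
        assert layout_cost(w, out) <= layout_cost(w, initial)


def _bridged_pair_instance(seed):
    """Two dense 8-node modules with exactly one bridge edge."""
    net, planted = generate_modular_network([8, 8], 0.8, 0.0, seed=seed)
    bridge = (net.nodes[0], net.nodes[8])
    edges = list(net.edges) + [bridge]
    return Network(net.nodes, edges), planted, bridge


class TestInterModulePull:
    def test_bridge_endpoints_pulled_together(self):
        """The +40 inter-module bonus drags bridge endpoints below the mean
        distance of random intra-region placements."""
        placed = GridLayout({"M1": (0, 0), "M2": (1, 0)})
        gaps, baselines = [], []
        for seed in range(10):
            net, planted, (u, v) = _bridged_pair_instance(seed)
            regions = expand_modules(placed, planted)
            w = set_node_weight(net, planted)
            out = optimize_nodes(net, w, regions, planted,
                                 OptimizerParams(60, 0.2, seed))
            gaps.append(manhattan(out[u], out[v]))
            rng = np.random.default_rng(1000 + seed)
            pts_u = regions[planted.module_of[u]].rect.points()
            pts_v = regions[planted.module_of[v]].rect.points()
            base = [
                manhattan(pts_u[int(rng.integers(len(pts_u)))],
                          pts_v[int(rng.integers(len(pts_v)))])
                for _ in range(100)
            ]
            baselines.append(np.mean(base))
        assert np.mean(gaps) <= np.mean(baselines)

    def test_extra_weight_reduces_edge_crossings(self):
        """Disabling the inter-module bonus must not lower the mean edge-edge
        crossing ratio on bridged planted networks."""
        placed = GridLayout({"M1": (0, 0), "M2": (1, 0)})
        with_extra, without_extra = [], []
        for seed in range(10):
            net, planted = generate_modular_network([8, 8], 0.7, 0.06,
                                                    seed=100 + seed)
            if net.m < 2:
                continue
            regions = expand_modules(placed, planted)
            for extra, sink in ((40.0, with_extra), (0.0, without_extra)):
                w = set_node_weight(net, planted, extra_weight=extra)
                out = optimize_nodes(net, w, regions, planted,
                                     OptimizerParams(60, 0.2, seed))
                sink.append(edge_edge_crossing_ratio(out, net))
        assert np.mean(without_extra) >= np.mean(with_extra)
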