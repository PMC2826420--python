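"""Statechart construction: hierarchy, concurrency, recursion, sizes."""

from itertools import product

import pytest

from genecharts import (
    Gene,
    GeneNetwork,
    Junction,
    RegulatoryInput,
    UnsupportedStructureError,
    build_c1_ffl,
    build_dense_overlapping_regulon,
    build_ic1_ffl,
    build_interlocked_ffl_network,
    build_simple_regulation,
    build_single_input_module,
    builtin_gate,
    initial_configuration,
    network_to_statechart,
    run_to_completion,
    statechart_size,
)
from conftest import motif_fixtures


class TestStructure:
    def test_simple_regulation_one_superstate_two_substates(self):
        chart = network_to_statechart(build_simple_regulation())
        assert chart.root.label == "X=1"
        assert [c.label for c in chart.root.children] == ["Y=0", "Y=1"]
        assert [c.name for c in chart.root.children] == ["I", "II"]
        n_nodes, n_trans, depth = statechart_size(chart)
        assert (n_nodes, depth) == (3, 2)

    def test_cascade_recursion_nests_z_inside_y_on(self):
        chart = network_to_statechart(build_c1_ffl())
        y_on = chart.node("Y=1")
        assert y_on.kind == "composite"
        assert [c.label for c in y_on.children] == ["Z=0", "Z=1"]

    def test_dor_two_targets_one_parallel_node_two_regions(self):
        chart = network_to_statechart(build_dense_overlapping_regulon())
        assert chart.root.label == "X1X2X3=111"
        (par,) = chart.root.children
        assert par.kind == "parallel"
        assert len(par.regions) == 2
        assert sorted(n.gene for r in par.regions for n in r) == ["Y1", "Y1", "Y2", "Y2"]

    def test_c1_and_ic1_trees_identical_apart_from_gate_metadata(self):
        c1 = network_to_statechart(build_c1_ffl())
        ic1 = network_to_statechart(build_ic1_ffl())

        def shape(node):
            return (node.id, node.kind, node.label,
                    tuple(shape(c) for c in node.children))

        assert shape(c1.root) == shape(ic1.root)
        # only the guard text (junction gate) differs
        diff = [
            (a.guard, b.guard)
            for a, b in zip(c1.transitions, ic1.transitions)
            if a.guard != b.guard
        ]
        assert diff and all("and" in a and "does_not_imply" in b for a, b in diff)

    def test_lock_in_substate_has_no_off_transition(self):
        from genecharts import build_autoregulation

        chart = network_to_statechart(build_autoregulation("positive", lock_in=True))
        sources = [t.source for t in chart.transitions]
        assert "Y=0" in sources and "Y=1" not in sources

    def test_feedback_rejected(self):
        net = GeneNetwork(
            genes=[Gene(id="A"), Gene(id="B")],
            junctions=[
                Junction("A", [RegulatoryInput("activity", "B")], builtin_gate("identity")),
                Junction("B", [RegulatoryInput("activity", "A")], builtin_gate("identity")),
            ],
        )
        with pytest.raises(UnsupportedStructureError):
            network_to_statechart(net)

    def test_interlocked_nesting_depth_and_concurrency(self):
        chart = network_to_statechart(build_interlocked_ffl_network())
        n_nodes, n_trans, depth = statechart_size(chart)
        assert n_nodes == 15 and depth == 7
        par = chart.node("par:Y1")
        assert {n.gene for r in par.regions for n in r} == {"Z1", "X2"}
        par2 = chart.node("par:Y2")
        assert {n.gene for r in par2.regions for n in r} == {"Z2", "Z3"}


class TestInitialConfiguration:
    def test_signal_selects_initial_substate(self):
        chart = network_to_statechart(build_simple_regulation())
        assert initial_configuration(chart, {"S_x": 0}) == {"Y=0"}
        assert initial_configuration(chart, {"S_x": 1}) == {"Y=1"}

    @pytest.mark.parametrize("name, net", [f for f in motif_fixtures() if len(f[1].signals) <= 4])
    def test_exactly_one_substate_active_per_active_region(self, name, net):
        chart = network_to_statechart(net)
        for bits in product((0, 1), repeat=len(net.signals)):
            config = initial_configuration(chart, dict(zip(net.signals, bits)))
            per_gene = {}
            for nid in config:
                node = chart.node(nid)
                per_gene.setdefault(node.gene, []).append(nid)
            assert all(len(v) == 1 for v in per_gene.values())

    def test_initial_rule_total_over_composites(self):
        chart = network_to_statechart(build_interlocked_ffl_network())
        sig = {s: 0 for s in chart.network.signals}
        for node in chart.root.walk():
            if node.kind in ("composite", "parallel") and node.children:
                subs = chart.initial_rule(node.id, sig)
                assert subs  # a choice exists for every region


class TestSizeScaling:
    def test_node_count_linear_in_sim_width(self):
        sizes = {}
        for n in range(1, 51):
            chart = network_to_statechart(build_single_input_module(n))
            sizes[n] = statechart_size(chart)[0]
        # 2 substates per target plus root and one parallel wrapper
        assert all(sizes[n] == 2 * n + 2 for n in range(2, 51))
        assert sizes[1] == 3

    def test_statechart_linear_while_flat_exponential(self):
        from genecharts import state_space_size

        net = build_interlocked_ffl_network()
        chart_nodes = statechart_size(network_to_statechart(net))[0]
        _, flat, _ = state_space_size(net)
        assert chart_nodes == 15
        assert flat == 2**117
        assert chart_nodes < flat

    def test_network_of_only_always_on_genes_has_no_transitions(self):
        net = GeneNetwork(genes=[Gene(id="X", always_on=True, initial_expression=1)])
        chart = network_to_statechart(net)
        assert statechart_size(chart)[1] == 0


class TestExecutionAgreement:
    @pytest.mark.parametrize("name, net", motif_fixtures())
    def test_initial_configuration_matches_engine_fixed_point(self, name, net):
        # executing the statechart's underlying network and reading the
        # chart's initial configuration must agree on every valuation
        chart = network_to_statechart(net)
        for bits in product((0, 1), repeat=len(net.signals)):
            event = dict(zip(net.signals, bits))
            trace = run_to_completion(net, event=event)
            final = trace.states[-1].expression
            config = initial_configuration(chart, event)
            for nid in config:
                node = chart.node(nid)
                assert final[node.gene] == node.expression_bit
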