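"""Flat state diagrams: expansion, exact sizes, enumeration, oracle."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecharts import (
    StateSpaceTooLarge,
    build_c1_ffl,
    build_interlocked_ffl_network,
    build_simple_regulation,
    build_single_input_module,
    enumerate_flat_diagram,
    expand_multiplicities,
    format_sci,
    network_to_dict,
    oracle_check,
    random_motif_composition,
    run_to_completion,
    state_space_size,
    validate_network,
)
from conftest import ALL_ON, motif_fixtures


class TestExpansion:
    def test_interlocked_expands_to_118_genes(self, interlocked):
        exp = expand_multiplicities(interlocked)
        assert len(exp.genes) == 118
        assert validate_network(exp) == []
        assert sum(1 for g in exp.genes if g.id.startswith("Z1_")) == 112

    def test_multiplicity_one_network_unchanged(self, c1_ffl):
        assert network_to_dict(expand_multiplicities(c1_ffl)) == network_to_dict(c1_ffl)

    def test_copies_trace_identically(self):
        net = build_interlocked_ffl_network(3)
        exp = expand_multiplicities(net)
        trace = run_to_completion(exp, event=ALL_ON)
        cols = {g: trace.bits(exp, g) for g in ("Z1_1", "Z1_2", "Z1_3")}
        assert cols["Z1_1"] == cols["Z1_2"] == cols["Z1_3"]


class TestStateSpaceSize:
    def test_interlocked_headline_number(self, interlocked):
        n_free, size, rendering = state_space_size(interlocked)
        assert n_free == 117
        assert size == 2**117
        assert rendering == "1.66×10^35"

    def test_small_networks(self):
        assert state_space_size(build_simple_regulation())[:2] == (1, 2)
        assert state_space_size(build_single_input_module(3))[:2] == (3, 8)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(0, 200))
    def test_exact_power_matches_repeated_doubling(self, n):
        from genecharts import Gene, GeneNetwork, Junction, RegulatoryInput, builtin_gate

        net = GeneNetwork(
            genes=[Gene(id="X", always_on=True, initial_expression=1)]
            + [Gene(id=f"Y{i}") for i in range(n)],
            junctions=[
                Junction(f"Y{i}", [RegulatoryInput("activity", "X")], builtin_gate("identity"))
                for i in range(n)
            ],
        )
        size = state_space_size(net)[1]
        doubled = 1
        for _ in range(n):
            doubled += doubled
        assert size == doubled

    @pytest.mark.parametrize(
        "n, expected",
        [(1, "1.00×10^0"), (1024, "1.02×10^3"), (2**117, "1.66×10^35"), (999_600, "1.00×10^6")],
    )
    def test_three_sig_fig_rendering(self, n, expected):
        assert format_sci(n, 3) == expected


class TestEnumeration:
    def test_simple_regulation_successors_brute_force(self):
        net = build_simple_regulation()
        diag = enumerate_flat_diagram(net)
        assert len(diag.states) == 2
        from genecharts import GlobalState, next_expression

        for (y,), sx in product(((0,), (1,)), (0, 1)):
            s = GlobalState(expression={"X": 1, "Y": y}, signal_values={"S_x": sx})
            expected = next_expression(s, "Y", net)
            src = diag.states.index((y,))
            assert diag.states[diag.successor(src, (sx,))] == (expected,)

    def test_c1_ffl_every_slot_has_one_successor(self):
        diag = enumerate_flat_diagram(build_c1_ffl())
        assert len(diag.states) == 4
        for src in range(4):
            for val in product((0, 1), repeat=2):
                targets = [
                    t for s, pat, t in diag.transitions
                    if s == src and all(p is None or p == v for p, v in zip(pat, val))
                ]
                assert len(set(targets)) == 1

    @pytest.mark.parametrize(
        "name, net", [f for f in motif_fixtures() if state_space_size(f[1])[0] <= 4]
    )
    def test_dont_care_merge_preserves_relation(self, name, net):
        # expanding every cube over its X positions must give exactly
        # one successor per concrete (state, valuation), and it must be
        # the synchronous-cascade successor computed independently
        from genecharts.network import compiled_step

        exp = expand_multiplicities(net)
        step = compiled_step(exp)
        diag = enumerate_flat_diagram(net)
        free = [i for i, g in enumerate(exp.genes) if not g.always_on]
        n_sig = len(exp.signals)
        for src, state in enumerate(diag.states):
            full = [1] * len(exp.genes)
            for k, i in enumerate(free):
                full[i] = state[k]
            for val in product((0, 1), repeat=n_sig):
                nxt = step(tuple(full), val)
                expected = tuple(nxt[i] for i in free)
                assert diag.states[diag.successor(src, val)] == expected

    def test_size_guard_refuses_interlocked(self, interlocked):
        with pytest.raises(StateSpaceTooLarge, match="1.66×10\\^35"):
            enumerate_flat_diagram(interlocked)

    def test_flat_slot_counts(self):
        # n free genes, s signals: 2^n states, 2^n*2^s concrete slots
        net = build_c1_ffl()
        diag = enumerate_flat_diagram(net)
        concrete = {
            (src, val)
            for src, pat, tgt in diag.transitions
            for val in product((0, 1), repeat=2)
            if all(p is None or p == v for p, v in zip(pat, val))
        }
        assert len(concrete) == 4 * 4


class TestOracle:
    @pytest.mark.parametrize("name, net", motif_fixtures())
    def test_all_motifs_all_events_match_flat_relation(self, name, net):
        diag = enumerate_flat_diagram(net)
        for bits in product((0, 1), repeat=len(net.signals)):
            event = dict(zip(net.signals, bits))
            assert oracle_check(net, event, diagram=diag)

    def test_corrupted_successor_detected(self):
        net = build_c1_ffl()
        diag = enumerate_flat_diagram(net)
        bad = [
            (src, pat, (tgt + 1) % len(diag.states))
            for src, pat, tgt in diag.transitions
        ]
        diag.transitions = bad
        assert not oracle_check(net, {"S_x": 1, "S_y": 1}, diagram=diag)

    def test_random_compositions_sweep(self):
        # the statechart execution agrees with the brute-force flat
        # relation on composed motifs (spot sweep; the full 100-seed
        # sweep runs in the acceptance suite)
        for seed in range(10):
            net = random_motif_composition(2, seed=seed)
            event = {s: 1 for s in net.signals}
            assert oracle_check(net, event)
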