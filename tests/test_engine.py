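"""Execution semantics: scheduling policies, traces, pulses and delays."""

from itertools import product

import pytest

from genecharts import (
    Gene,
    GeneNetwork,
    Junction,
    RegulatoryInput,
    SchedulePolicy,
    activation_delay,
    builtin_gate,
    detect_pulse,
    next_expression,
    run_to_completion,
    step,
)
from conftest import ALL_ON, motif_fixtures


class TestStep:
    def test_fixed_point_maps_to_itself(self, c1_ffl):
        s = c1_ffl.initial_state()
        out = step(c1_ffl, s, SchedulePolicy())
        assert out.expression == s.expression

    def test_sync_step_sees_stale_values(self, c1_ffl):
        # after both signals go on, Y rises first; Z's and-gate still
        # reads the old Y=0 in the same macro-step
        s = c1_ffl.initial_state({"S_x": 1, "S_y": 1})
        out = step(c1_ffl, s, SchedulePolicy())
        assert out.expression["Y"] == 1
        assert out.expression["Z"] == 0

    def test_async_deterministic_flips_first_enabled_gene(self):
        from genecharts import build_single_input_module

        net = build_single_input_module(3)
        s = net.initial_state({"S_x": 1})
        out = step(net, s, SchedulePolicy(mode="async_deterministic"))
        flipped = [g for g in net.gene_ids() if out.expression[g] != s.expression[g]]
        assert flipped == ["Y1"]  # lexicographically first enabled

    def test_async_random_flips_exactly_one_enabled_gene(self):
        from genecharts import build_single_input_module

        net = build_single_input_module(3)
        s = net.initial_state({"S_x": 1})
        out = step(net, s, SchedulePolicy(mode="async_random", seed=5))
        flipped = [g for g in net.gene_ids() if out.expression[g] != s.expression[g]]
        assert len(flipped) == 1 and flipped[0] in ("Y1", "Y2", "Y3")


class TestRunToCompletion:
    def test_interlocked_all_signals_on_visits_six_states(self, interlocked):
        trace = run_to_completion(interlocked, event=ALL_ON)
        assert trace.terminal == "fixed_point"
        assert len(trace.states) == 6
        keys = [s.key(interlocked) for s in trace.states]
        assert len(set(keys)) == 6  # pairwise distinct

    def test_simple_regulation_turn_on(self):
        from genecharts import build_simple_regulation

        net = build_simple_regulation()
        trace = run_to_completion(net, event={"S_x": 1})
        assert trace.bits(net, "Y") == [0, 0, 1]
        assert trace.terminal == "fixed_point"

    def test_step_limit_marks_terminal(self):
        # hand-built oscillator: Y's junction negates Y itself
        y = Gene(id="Y", autoregulation="negative")
        net = GeneNetwork(
            genes=[y],
            junctions=[Junction("Y", [RegulatoryInput("activity", "Y")], builtin_gate("not"))],
        )
        trace = run_to_completion(net, policy=SchedulePolicy(step_limit=3))
        assert trace.terminal in ("cycle", "step_limit")

    def test_cycle_detection_terminates(self):
        # two genes negating each other synchronously oscillate
        net = GeneNetwork(
            genes=[Gene(id="A", autoregulation="negative"),
                   Gene(id="B", autoregulation="negative")],
            junctions=[
                Junction("A", [RegulatoryInput("activity", "B")], builtin_gate("not")),
                Junction("B", [RegulatoryInput("activity", "A")], builtin_gate("not")),
            ],
        )
        trace = run_to_completion(net, policy=SchedulePolicy(step_limit=100))
        assert trace.terminal == "cycle"
        assert len(trace.states) < 10

    @pytest.mark.parametrize("name, net", motif_fixtures())
    def test_replay_through_next_expression_reproduces_trace(self, name, net):
        # internal-consistency oracle: each post-event step of a sync
        # trace must equal the per-gene next_expression of its precursor
        for bits in product((0, 1), repeat=len(net.signals)):
            event = dict(zip(net.signals, bits))
            trace = run_to_completion(net, event=event)
            start = trace.events[-1][0] if trace.events else 0
            for a, b in zip(trace.states[start:], trace.states[start + 1 :]):
                for g in net.gene_ids():
                    assert next_expression(a, g, net) == b.expression[g]

    @pytest.mark.parametrize("name, net", motif_fixtures())
    def test_async_policies_reach_sync_fixed_point(self, name, net):
        # confluence on the feedback-free motifs: all schedules agree on
        # the final state for every signal event
        for bits in product((0, 1), repeat=len(net.signals)):
            event = dict(zip(net.signals, bits))
            ref = run_to_completion(net, event=event)
            assert ref.terminal == "fixed_point"
            for policy in (
                SchedulePolicy(mode="async_deterministic"),
                SchedulePolicy(mode="async_random", seed=1),
                SchedulePolicy(mode="async_random", seed=99),
            ):
                t = run_to_completion(net, event=event, policy=policy)
                assert t.terminal == "fixed_point"
                assert t.states[-1].expression == ref.states[-1].expression

    @pytest.mark.parametrize("name, net", [f for f in motif_fixtures() if "lock" in f[0]])
    def test_lock_in_bits_monotone_along_any_trace(self, name, net):
        for policy in (SchedulePolicy(), SchedulePolicy(mode="async_random", seed=3)):
            trace = run_to_completion(net, event={"S_x": 1}, policy=policy)
            bits = trace.bits(net, "Y")
            assert all(a <= b for a, b in zip(bits, bits[1:]))


class TestPulseAndDelay:
    def test_ic1_ffl_pulse_width_one(self, ic1_ffl):
        trace = run_to_completion(ic1_ffl, event={"S_x": 1, "S_y": 1})
        pulse = detect_pulse(trace, "Z", ic1_ffl)
        assert pulse is not None
        on, off = pulse
        assert off - on == 1

    def test_c1_ffl_delay_without_pulse(self, c1_ffl):
        trace = run_to_completion(c1_ffl, event={"S_x": 1, "S_y": 1})
        assert detect_pulse(trace, "Z", c1_ffl) is None
        assert activation_delay(trace, "Z", "Y", c1_ffl) == 1

    def test_all_zero_sequence_has_no_pulse(self, c1_ffl):
        trace = run_to_completion(c1_ffl, event={"S_x": 0})
        assert detect_pulse(trace, "Z", c1_ffl) is None

    def test_self_delay_is_zero(self):
        from genecharts import build_simple_regulation

        net = build_simple_regulation()
        trace = run_to_completion(net, event={"S_x": 1})
        assert activation_delay(trace, "Y", "Y", net) == 0

    def test_never_on_gives_none(self, c1_ffl):
        trace = run_to_completion(c1_ffl, event={"S_x": 1})  # S_y stays 0
        assert activation_delay(trace, "Z", "Y", c1_ffl) is None

    def test_interlocked_pulses_and_ordering(self, interlocked):
        trace = run_to_completion(interlocked, event=ALL_ON)
        assert detect_pulse(trace, "Z1", interlocked) is not None
        assert detect_pulse(trace, "Z2", interlocked) is not None
        first_on = {
            g: trace.bits(interlocked, g).index(1)
            for g in ("Z1", "X2", "Z2", "Z3")
        }
        assert first_on["Z1"] < first_on["X2"] <= first_on["Z2"]
        assert first_on["Z3"] == max(first_on.values())
        assert activation_delay(trace, "Z3", "Z1", interlocked) > 0
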