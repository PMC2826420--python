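"""Logical execution engine: run networks through (abstract) time.

Logical models are asynchronous in principle — a transition may fire
whenever its conditions hold — but a deterministic reference semantics
is needed to talk about *which* transient states occur.  Three policies
are provided:

``synchronous_cascade``
    every gene simultaneously takes its next-expression bit of the
    current state (one macro-step).  This is the reference semantics:
    it exposes the transient-state sequence of cascaded regulations
    (pulses of incoherent FFLs, delays of coherent FFLs).
``async_deterministic``
    exactly one enabled gene (next bit differs from current) updates
    per step, the lexicographically first.
``async_random``
    one enabled gene updates, chosen uniformly by a seeded generator.

On the feedback-free motif networks all three converge to the same
fixed point; the traversed transient states differ.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .network import GeneNetwork, GlobalState, compiled_step

__all__ = [
    "SchedulePolicy",
    "ExecutionTrace",
    "step",
    "run_to_completion",
    "detect_pulse",
    "activation_delay",
]

_MODES = ("synchronous_cascade", "async_deterministic", "async_random")


@dataclass
class SchedulePolicy:
    mode: str = "synchronous_cascade"
    seed: Optional[int] = None
    step_limit: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.step_limit < 1:
            raise ValueError("step_limit must be >= 1")
        if self.mode == "async_random" and self.seed is None:
            raise ValueError("async_random mode requires a seed")


@dataclass
class ExecutionTrace:
    """Ordered distinct global states visited during one run.

    ``states`` starts with the pre-stimulus state, followed by the state
    after the signal event is applied, followed by every state the
    update rule produces until termination; consecutive duplicates are
    collapsed.  ``events`` marks where signal assignments were applied.
    ``terminal`` is ``fixed_point``, ``cycle`` or ``step_limit``.
    """

    states: list[GlobalState]
    events: list[tuple[int, str]] = field(default_factory=list)
    terminal: str = "fixed_point"

    def bits(self, net: GeneNetwork, gene_id: str) -> list[int]:
        """Expression bit of one gene across the trace."""
        net.gene(gene_id)
        return [int(s.expression[gene_id]) for s in self.states]


def _one_async_step(
    net: GeneNetwork,
    expr: tuple[int, ...],
    sigs: tuple[int, ...],
    sync,
    mode: str,
    rng: Optional[random.Random],
) -> tuple[int, ...]:
    target = sync(expr, sigs)
    enabled = [i for i, (a, b) in enumerate(zip(expr, target)) if a != b]
    if not enabled:
        return expr
    if mode == "async_deterministic":
        order = sorted(enabled, key=lambda i: net.genes[i].id)
        pick = order[0]
    else:
        assert rng is not None
        pick = rng.choice(enabled)
    out = list(expr)
    out[pick] = target[pick]
    return tuple(out)


def step(net: GeneNetwork, state: GlobalState, policy: SchedulePolicy) -> GlobalState:
    """Apply one update step; a fixed point maps to itself.

    For ``async_random`` a fresh generator is seeded from the policy on
    every call; for reproducible multi-step random runs use
    :func:`run_to_completion`, which threads one generator through.
    """
    sync = compiled_step(net)
    expr = state.expr_tuple(net)
    sigs = state.signal_tuple(net)
    if policy.mode == "synchronous_cascade":
        nxt = sync(expr, sigs)
    else:
        rng = random.Random(policy.seed) if policy.mode == "async_random" else None
        nxt = _one_async_step(net, expr, sigs, sync, policy.mode, rng)
    return GlobalState.from_tuples(net, nxt, sigs)


def run_to_completion(
    net: GeneNetwork,
    initial: Optional[GlobalState] = None,
    event: Optional[Mapping[str, int]] = None,
    policy: Optional[SchedulePolicy] = None,
) -> ExecutionTrace:
    """Apply a signal event and step until fixed point, cycle or limit.

    The trace opens with the pre-event state.  The event (a partial
    signal assignment) is then applied; if it changes any signal bit the
    resulting state is recorded as a distinct state.  Stepping proceeds
    under the policy until the state repeats: an immediate repeat is a
    fixed point, a repeat of an earlier state is a cycle, and running
    out of ``step_limit`` marks the trace accordingly (no exception).
    """
    policy = policy or SchedulePolicy()
    state0 = initial if initial is not None else net.initial_state()
    sync = compiled_step(net)
    rng = random.Random(policy.seed) if policy.mode == "async_random" else None

    expr = state0.expr_tuple(net)
    sigs0 = state0.signal_tuple(net)
    states = [GlobalState.from_tuples(net, expr, sigs0)]
    events: list[tuple[int, str]] = []

    sigs = sigs0
    if event:
        sidx = {s: i for i, s in enumerate(net.signals)}
        new = list(sigs0)
        for k, v in event.items():
            if k not in sidx:
                raise KeyError(f"unknown signal {k!r}")
            new[sidx[k]] = int(v)
        sigs = tuple(new)
        desc = ",".join(f"{k}={int(event[k])}" for k in net.signals if k in event)
        if sigs != sigs0:
            states.append(GlobalState.from_tuples(net, expr, sigs))
            events.append((len(states) - 1, desc))
        else:
            events.append((len(states) - 1, desc))

    seen = {(expr, sigs0), (expr, sigs)}
    terminal = "step_limit"
    for _ in range(policy.step_limit):
        if policy.mode == "synchronous_cascade":
            nxt = sync(expr, sigs)
        else:
            nxt = _one_async_step(net, expr, sigs, sync, policy.mode, rng)
        if nxt == expr:
            terminal = "fixed_point"
            break
        if (nxt, sigs) in seen:
            states.append(GlobalState.from_tuples(net, nxt, sigs))
            terminal = "cycle"
            break
        seen.add((nxt, sigs))
        states.append(GlobalState.from_tuples(net, nxt, sigs))
        expr = nxt
    return ExecutionTrace(states=states, events=events, terminal=terminal)


def detect_pulse(trace: ExecutionTrace, gene_id: str, net: GeneNetwork) -> Optional[tuple[int, int]]:
    """Detect a single clean pulse in one gene's expression sequence.

    Returns ``(on_index, off_index)`` — the trace indices where the gene
    first turns on and first turns back off — iff the bit sequence has
    the shape ``0...0 1...1 0...0`` with non-empty on- and off-runs.
    Monotone rises, constant sequences and multi-pulse sequences return
    ``None``.
    """
    bits = trace.bits(net, gene_id)
    try:
        on = bits.index(1)
    except ValueError:
        return None
    try:
        off = bits.index(0, on)
    except ValueError:
        return None  # never turns off: a delay, not a pulse
    if any(b != 0 for b in bits[off:]):
        return None  # re-activation: not a single pulse
    return (on, off)


def activation_delay(
    trace: ExecutionTrace, gene_id: str, reference_gene_id: str, net: GeneNetwork
) -> Optional[int]:
    """First-on index of ``gene_id`` minus that of ``reference_gene_id``.

    ``None`` if either gene never turns on within the trace.
    """
    bits = trace.bits(net, gene_id)
    ref = trace.bits(net, reference_gene_id)
    if 1 not in bits or 1 not in ref:
        return None
    return bits.index(1) - ref.index(1)
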