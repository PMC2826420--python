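"""Classical flat state-diagram view of a network.

The hierarchical statechart representation stays linear in gene count;
the classical (flat) state diagram does not: every combination of free
gene expression bits is a distinct state, and every signal valuation
contributes a transition out of every state.  This module materializes
that blow-up — exact state-space sizes as big integers, full transition
enumeration for small networks, and don't-care compression of the
transition labels — and doubles as the brute-force oracle against which
statechart execution is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional

from .engine import SchedulePolicy, run_to_completion
from .network import (
    Gene,
    GeneNetwork,
    Junction,
    RegulatoryInput,
    SignalBinding,
    compiled_step,
)

__all__ = [
    "FlatStateDiagram",
    "StateSpaceTooLarge",
    "expand_multiplicities",
    "state_space_size",
    "format_sci",
    "enumerate_flat_diagram",
    "oracle_check",
]

DEFAULT_MAX_FREE_GENES = 20


class StateSpaceTooLarge(ValueError):
    """Raised when flat enumeration is requested beyond the size guard."""


@dataclass
class FlatStateDiagram:
    """All global expression states and their synchronous successors.

    ``states`` lists the free-gene bit vectors (always-on genes are
    clamped to 1 and excluded); ``transitions`` are
    ``(source_index, pattern, target_index)`` where ``pattern`` assigns
    each signal 0, 1 or ``None`` ("don't care": the successor is the
    same for either value).  Expanding every pattern over its don't-care
    positions recovers exactly one successor per (state, valuation).
    """

    free_gene_ids: list[str]
    signal_ids: list[str]
    states: list[tuple[int, ...]]
    transitions: list[tuple[int, tuple[Optional[int], ...], int]]
    always_on_ids: list[str] = field(default_factory=list)

    def successor(self, source: int, valuation: tuple[int, ...]) -> int:
        """Target state index for a concrete signal valuation."""
        for src, pattern, tgt in self.transitions:
            if src != source:
                continue
            if all(p is None or p == v for p, v in zip(pattern, valuation)):
                return tgt
        raise KeyError(f"no transition from state {source} under {valuation}")


def expand_multiplicities(net: GeneNetwork) -> GeneNetwork:
    """Materialize grouped genes into explicit copies.

    A gene with multiplicity k > 1 becomes k genes ``id_1 .. id_k``
    sharing its junction, signal binding and flags.  Junction inputs in
    *other* genes that referenced the grouped node resolve to copy
    ``_1`` (the copies are behaviorally identical, so any one stands for
    the group).  Networks with all multiplicities 1 are returned as a
    structural copy, unchanged.
    """
    rename: dict[str, str] = {}
    genes: list[Gene] = []
    for g in net.genes:
        if g.multiplicity == 1:
            genes.append(
                Gene(
                    id=g.id,
                    always_on=g.always_on,
                    lock_in=g.lock_in,
                    multiplicity=1,
                    initial_expression=g.initial_expression,
                    autoregulation=g.autoregulation,
                )
            )
        else:
            rename[g.id] = f"{g.id}_1"
            for i in range(1, g.multiplicity + 1):
                genes.append(
                    Gene(
                        id=f"{g.id}_{i}",
                        always_on=g.always_on,
                        lock_in=g.lock_in,
                        multiplicity=1,
                        initial_expression=g.initial_expression,
                        autoregulation=g.autoregulation,
                    )
                )

    bindings: list[SignalBinding] = []
    for b in net.bindings:
        g = net.gene(b.gene_id)
        if g.multiplicity == 1:
            bindings.append(SignalBinding(b.gene_id, b.signal_id, b.mode))
        else:
            for i in range(1, g.multiplicity + 1):
                bindings.append(SignalBinding(f"{b.gene_id}_{i}", b.signal_id, b.mode))

    def _remap_inputs(inputs: list[RegulatoryInput]) -> list[RegulatoryInput]:
        return [
            RegulatoryInput(
                kind=i.kind,
                ref=rename.get(i.ref, i.ref) if i.kind == "activity" else i.ref,
                negated=i.negated,
            )
            for i in inputs
        ]

    junctions: list[Junction] = []
    for j in net.junctions:
        g = net.gene(j.target_gene)
        if g.multiplicity == 1:
            junctions.append(Junction(j.target_gene, _remap_inputs(j.inputs), j.gate))
        else:
            for i in range(1, g.multiplicity + 1):
                junctions.append(
                    Junction(f"{j.target_gene}_{i}", _remap_inputs(j.inputs), j.gate)
                )

    return GeneNetwork(
        genes=genes, signals=list(net.signals), bindings=bindings, junctions=junctions
    )


def format_sci(n: int, sig_figs: int = 3) -> str:
    """Render an exact integer as m×10^e with ``sig_figs`` significant figures."""
    if n < 0:
        raise ValueError("expected a non-negative integer")
    s = str(n)
    exp = len(s) - 1
    digits = s.ljust(sig_figs + 1, "0")[: sig_figs + 1]
    mant = int(digits[:sig_figs])
    if int(digits[sig_figs]) >= 5:
        mant += 1
        if len(str(mant)) > sig_figs:  # rounding carried: 999.6 -> 1.00e+1
            mant //= 10
            exp += 1
    m = str(mant).zfill(sig_figs)
    mantissa = m[0] + ("." + m[1:] if sig_figs > 1 else "")
    return f"{mantissa}×10^{exp}"


def state_space_size(net: GeneNetwork) -> tuple[int, int, str]:
    """Exact size of the flat expression-state space.

    Returns ``(n_free_genes, size, rendering)`` where ``n_free`` is the
    expanded gene count minus the always-on (clamped) genes, ``size`` is
    the exact integer ``2**n_free`` and ``rendering`` is its scientific
    notation at 3 significant figures.  Exact integer arithmetic
    throughout; rounding happens only in the presentation string.
    """
    expanded = expand_multiplicities(net)
    n_free = sum(1 for g in expanded.genes if not g.always_on)
    size = 1 << n_free
    return n_free, size, format_sci(size, 3)


def _merge_cubes(valuations: set[tuple[int, ...]]) -> list[tuple[Optional[int], ...]]:
    """Merge a set of concrete valuations into don't-care cubes.

    Repeatedly joins pairs of cubes that differ in exactly one defined
    position (replacing it with ``None``).  The union of the returned
    cubes equals the input set exactly, so merging never changes the
    transition relation — it only compresses labels.
    """
    cubes: set[tuple[Optional[int], ...]] = set(valuations)
    changed = True
    while changed:
        changed = False
        merged: set[tuple[Optional[int], ...]] = set()
        used: set[tuple[Optional[int], ...]] = set()
        lst = sorted(cubes, key=lambda c: tuple(-1 if x is None else x for x in c))
        for a_i, a in enumerate(lst):
            for b in lst[a_i + 1 :]:
                diff = [
                    k
                    for k, (x, y) in enumerate(zip(a, b))
                    if x != y
                ]
                if len(diff) == 1 and a[diff[0]] is not None and b[diff[0]] is not None:
                    cube = tuple(
                        None if k == diff[0] else a[k] for k in range(len(a))
                    )
                    merged.add(cube)
                    used.add(a)
                    used.add(b)
                    changed = True
        cubes = (cubes - used) | merged
    return sorted(cubes, key=lambda c: tuple(-1 if x is None else x for x in c))


def enumerate_flat_diagram(
    net: GeneNetwork, max_free_genes: int = DEFAULT_MAX_FREE_GENES
) -> FlatStateDiagram:
    """Enumerate every state and every signal-labeled transition.

    States are all ``2**n_free`` expression vectors over the free
    (non-clamped) genes of the expanded network, in lexicographic order;
    each state has one synchronous-cascade successor per signal
    valuation.  Valuations leading to the same successor are merged into
    don't-care cubes.  Refuses (with the exact size in the message) when
    the free gene count exceeds ``max_free_genes``.
    """
    n_free, size, rendering = state_space_size(net)
    if n_free > max_free_genes:
        raise StateSpaceTooLarge(
            f"flat enumeration of {n_free} free genes would need {rendering} "
            f"({size} states); cap is {max_free_genes} free genes"
        )
    expanded = expand_multiplicities(net)
    step = compiled_step(expanded)
    free_idx = [i for i, g in enumerate(expanded.genes) if not g.always_on]
    always = [g.id for g in expanded.genes if g.always_on]
    n_genes = len(expanded.genes)

    states = [bits for bits in product((0, 1), repeat=n_free)]
    index = {s: i for i, s in enumerate(states)}

    def full(free_bits: tuple[int, ...]) -> tuple[int, ...]:
        out = [1] * n_genes
        for k, i in enumerate(free_idx):
            out[i] = free_bits[k]
        return tuple(out)

    transitions: list[tuple[int, tuple[Optional[int], ...], int]] = []
    n_sig = len(expanded.signals)
    for si, s in enumerate(states):
        expr = full(s)
        by_target: dict[int, set[tuple[int, ...]]] = {}
        for val in product((0, 1), repeat=n_sig):
            nxt = step(expr, val)
            tgt = index[tuple(nxt[i] for i in free_idx)]
            by_target.setdefault(tgt, set()).add(val)
        for tgt in sorted(by_target):
            for cube in _merge_cubes(by_target[tgt]):
                transitions.append((si, cube, tgt))

    return FlatStateDiagram(
        free_gene_ids=[expanded.genes[i].id for i in free_idx],
        signal_ids=list(expanded.signals),
        states=states,
        transitions=transitions,
        always_on_ids=always,
    )


def oracle_check(
    net: GeneNetwork,
    event: Mapping[str, int],
    policy: Optional[SchedulePolicy] = None,
    diagram: Optional[FlatStateDiagram] = None,
    max_free_genes: int = 12,
) -> bool:
    """Check an execution trace against the brute-force flat diagram.

    Runs the execution engine from the network's initial state with the
    given signal event and verifies that every post-event step of the
    trace is a transition of the exhaustively enumerated diagram under
    the event's valuation, and that a fixed-point trace ends in a state
    mapped to itself.  The flat relation uses synchronous-cascade
    successors, so the check is meaningful for synchronous policies.
    """
    policy = policy or SchedulePolicy()
    if diagram is None:
        diagram = enumerate_flat_diagram(net, max_free_genes=max_free_genes)
    expanded = expand_multiplicities(net)
    trace = run_to_completion(expanded, event=event, policy=policy)

    free = diagram.free_gene_ids
    sig_order = diagram.signal_ids

    def free_bits(state) -> tuple[int, ...]:
        return tuple(int(state.expression[g]) for g in free)

    index = {s: i for i, s in enumerate(diagram.states)}
    # post-event portion of the trace: signals constant at the event valuation
    start = trace.events[-1][0] if trace.events else 0
    valuation = tuple(int(trace.states[start].signal_values[s]) for s in sig_order)
    try:
        cur = index[free_bits(trace.states[start])]
        for nxt_state in trace.states[start + 1 :]:
            cur = diagram.successor(cur, valuation)
            if cur != index[free_bits(nxt_state)]:
                return False
        if trace.terminal == "fixed_point" and diagram.successor(cur, valuation) != cur:
            return False
    except KeyError:
        return False
    return True
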