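"""Constructors for the recurring gene-network motifs.

Transcription networks are built from a handful of recurring circuits:
simple regulation (X -> Y gated by a signal), autoregulation, the
feed-forward loop (FFL), the single-input module (SIM) and the dense
overlapping regulon (DOR).  All of them reduce, structurally, to simple
regulations wired in cascade or in parallel, which is what makes a
hierarchical statechart representation compact.

Each builder returns a validated :class:`~genecharts.network.GeneNetwork`
whose initial expression bits are settled to the quiescent fixed point
under all-zero signals.
"""

from __future__ import annotations

import random
from itertools import product
from typing import Sequence

from .gates import Gate, builtin_gate, eval_gate
from .network import (
    Gene,
    GeneNetwork,
    Junction,
    RegulatoryInput,
    SignalBinding,
    settle_initial_expressions,
    validate_network,
)

__all__ = [
    "MOTIF_KINDS",
    "build_simple_regulation",
    "build_autoregulation",
    "build_c1_ffl",
    "build_ic1_ffl",
    "build_single_input_module",
    "build_dense_overlapping_regulon",
    "build_interlocked_ffl_network",
    "build_motif",
    "random_motif_composition",
]

MOTIF_KINDS = (
    "simple_regulation",
    "autoregulation",
    "c1_ffl",
    "ic1_ffl",
    "single_input_module",
    "dense_overlapping_regulon",
    "interlocked_ffl",
)

_MODES = ("activator", "repressor")


def _finish(net: GeneNetwork) -> GeneNetwork:
    problems = validate_network(net)
    if problems:  # builders must never emit a broken network
        raise AssertionError("motif builder produced invalid network: " + "; ".join(problems))
    return settle_initial_expressions(net)


def _act(ref: str, negated: bool = False) -> RegulatoryInput:
    return RegulatoryInput(kind="activity", ref=ref, negated=negated)


def _sig(ref: str, negated: bool = False) -> RegulatoryInput:
    return RegulatoryInput(kind="signal", ref=ref, negated=negated)


def build_simple_regulation(signal_mode: str = "activator", tf_mode: str = "activator") -> GeneNetwork:
    """Simple regulation X -> Y.

    X is constitutively expressed; the signal S_x gates X's activity
    with ``signal_mode``; Y's junction applies X's activity directly
    (``tf_mode='activator'``) or inverted (``'repressor'``).  Equal
    modes give a coherent regulation (steady Y follows S_x), unequal
    modes an incoherent one (steady Y is the complement of S_x).
    """
    for m in (signal_mode, tf_mode):
        if m not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {m!r}")
    gate = builtin_gate("identity" if tf_mode == "activator" else "not")
    net = GeneNetwork(
        genes=[
            Gene(id="X", always_on=True, initial_expression=1),
            Gene(id="Y"),
        ],
        signals=["S_x"],
        bindings=[SignalBinding(gene_id="X", signal_id="S_x", mode=signal_mode)],
        junctions=[Junction(target_gene="Y", inputs=[_act("X")], gate=gate)],
    )
    return _finish(net)


def build_autoregulation(sign: str = "negative", lock_in: bool = False) -> GeneNetwork:
    """Autoregulation: Y additionally regulates its own promoter.

    In the logical domain autoregulation is indistinguishable from
    simple regulation — the self-edge changes response time and noise,
    which are physical-domain quantities — so the returned network has
    the simple-regulation junction plus a self-edge *annotation* on Y
    (kept so renderings can draw the loop).  Strong positive
    autoregulation can make activation irreversible; ``lock_in=True``
    models that by latching Y's expression once it reaches 1.
    """
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    if lock_in and sign != "positive":
        raise ValueError("lock_in is only meaningful for positive autoregulation")
    net = build_simple_regulation("activator", "activator")
    y = net.gene("Y")
    y.autoregulation = sign
    y.lock_in = lock_in
    return _finish(net)


def _ffl(z_gate_name: str) -> GeneNetwork:
    net = GeneNetwork(
        genes=[
            Gene(id="X", always_on=True, initial_expression=1),
            Gene(id="Y"),
            Gene(id="Z"),
        ],
        signals=["S_x", "S_y"],
        bindings=[
            SignalBinding(gene_id="X", signal_id="S_x", mode="activator"),
            SignalBinding(gene_id="Y", signal_id="S_y", mode="activator"),
        ],
        junctions=[
            Junction(target_gene="Y", inputs=[_act("X")], gate=builtin_gate("identity")),
            Junction(
                target_gene="Z",
                inputs=[_act("X"), _act("Y")],
                gate=builtin_gate(z_gate_name),
            ),
        ],
    )
    return _finish(net)


def build_c1_ffl() -> GeneNetwork:
    """Coherent type-1 feed-forward loop (X -> Y, X & Y -> Z).

    Z's junction is ``and`` over the activities of X and Y, so Z turns
    on one step after Y: the C1-FFL is a delay element.
    """
    return _ffl("and")


def build_ic1_ffl() -> GeneNetwork:
    """Incoherent type-1 feed-forward loop (X -> Y, X AND NOT Y -> Z).

    Z's junction is ``does_not_imply`` (activator arm X, repressor arm
    Y), so Z fires while X is active but Y has not yet caught up: the
    Ic1-FFL is a pulse generator.
    """
    return _ffl("does_not_imply")


def build_single_input_module(n_targets: int = 3) -> GeneNetwork:
    """Single-input module: one regulator X driving n parallel targets."""
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    genes = [Gene(id="X", always_on=True, initial_expression=1)]
    junctions = []
    for i in range(1, n_targets + 1):
        genes.append(Gene(id=f"Y{i}"))
        junctions.append(
            Junction(target_gene=f"Y{i}", inputs=[_act("X")], gate=builtin_gate("identity"))
        )
    net = GeneNetwork(
        genes=genes,
        signals=["S_x"],
        bindings=[SignalBinding(gene_id="X", signal_id="S_x", mode="activator")],
        junctions=junctions,
    )
    return _finish(net)


def build_dense_overlapping_regulon(
    x_ids: Sequence[str] = ("X1", "X2", "X3"),
    y_specs: Sequence[tuple[str, str | Gate, Sequence[str]]] = (
        ("Y1", "or", ("S_x1", "S_x2", "S_x3")),
        ("Y2", "and", ("S_x1", "S_x2", "S_x3")),
    ),
) -> GeneNetwork:
    """Dense overlapping regulon: several regulators, several targets.

    The x-level genes are constitutively on; each y-level gene's
    junction combines signal literals directly through its own gate
    (the regulators' identities are subsumed in the always-on context).
    Each y-gene runs in its own concurrent region of the statechart.

    ``y_specs`` entries are ``(target_id, gate, input_signal_ids)``
    where ``gate`` is a builtin name or a :class:`Gate`; for gates of
    arity 2 with more inputs, the n-ary extension is built by folding
    (only for and/or).
    """
    signals = sorted({s for _, _, inputs in y_specs for s in inputs})
    genes = [Gene(id=x, always_on=True, initial_expression=1) for x in x_ids]
    junctions = []
    for target, gate, inputs in y_specs:
        if isinstance(gate, str):
            g = builtin_gate(gate)
            if g.arity != len(inputs) and gate in ("and", "or"):
                g = _nary(gate, len(inputs))
        else:
            g = gate
        genes.append(Gene(id=target))
        junctions.append(
            Junction(target_gene=target, inputs=[_sig(s) for s in inputs], gate=g)
        )
    net = GeneNetwork(genes=genes, signals=signals, bindings=[], junctions=junctions)
    return _finish(net)


def _nary(name: str, arity: int) -> Gate:
    if name == "and":
        fn = all
    elif name == "or":
        fn = any
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"no n-ary extension for gate {name!r}")
    table = tuple(int(fn(bits)) for bits in product((0, 1), repeat=arity))
    return Gate(name=f"{name}{arity}", arity=arity, table=table)


def build_interlocked_ffl_network(z1_multiplicity: int = 112) -> GeneNetwork:
    """The interlocked feed-forward-loop network of B. subtilis sporulation.

    Two Ic1-FFLs (targets Z1, Z2) and two C1-FFLs (targets X2, Z3) share
    regulators in a cascade X1 -> Y1 -> X2 -> Y2.  The 112 genes that
    behave identically as Ic1-FFL targets are collapsed into the single
    node Z1 with ``multiplicity=112``; with the default multiplicity the
    expanded network has 118 genes, of which only X1 is clamped on.
    """
    if z1_multiplicity < 1:
        raise ValueError("z1_multiplicity must be >= 1")
    net = GeneNetwork(
        genes=[
            Gene(id="X1", always_on=True, initial_expression=1),
            Gene(id="Y1"),
            Gene(id="Z1", multiplicity=z1_multiplicity),
            Gene(id="X2"),
            Gene(id="Y2"),
            Gene(id="Z2"),
            Gene(id="Z3"),
        ],
        signals=["S_X1", "S_Y1", "S_X2", "S_Y2"],
        bindings=[
            SignalBinding(gene_id="X1", signal_id="S_X1", mode="activator"),
            SignalBinding(gene_id="Y1", signal_id="S_Y1", mode="activator"),
            SignalBinding(gene_id="X2", signal_id="S_X2", mode="activator"),
            SignalBinding(gene_id="Y2", signal_id="S_Y2", mode="activator"),
        ],
        junctions=[
            Junction(target_gene="Y1", inputs=[_act("X1")], gate=builtin_gate("identity")),
            Junction(
                target_gene="Z1",
                inputs=[_act("X1"), _act("Y1")],
                gate=builtin_gate("does_not_imply"),
            ),
            Junction(target_gene="X2", inputs=[_act("X1"), _act("Y1")], gate=builtin_gate("and")),
            Junction(target_gene="Y2", inputs=[_act("X2")], gate=builtin_gate("identity")),
            Junction(
                target_gene="Z2",
                inputs=[_act("X2"), _act("Y2")],
                gate=builtin_gate("does_not_imply"),
            ),
            Junction(target_gene="Z3", inputs=[_act("X2"), _act("Y2")], gate=builtin_gate("and")),
        ],
    )
    return _finish(net)


def build_motif(kind: str, **params) -> GeneNetwork:
    """Dispatch to a motif builder by kind name (CLI entry point)."""
    builders = {
        "simple_regulation": build_simple_regulation,
        "autoregulation": build_autoregulation,
        "c1_ffl": build_c1_ffl,
        "ic1_ffl": build_ic1_ffl,
        "single_input_module": build_single_input_module,
        "dense_overlapping_regulon": build_dense_overlapping_regulon,
        "interlocked_ffl": build_interlocked_ffl_network,
    }
    if kind not in builders:
        raise KeyError(f"unknown motif kind {kind!r}; valid: {', '.join(MOTIF_KINDS)}")
    return builders[kind](**params)


# ---------------------------------------------------------------------------
# random compositions (fixture generator for property tests)


def _and_extend(gate: Gate) -> Gate:
    """Extend a gate with one extra input AND-ed onto its output."""
    table = []
    for bits in product((0, 1), repeat=gate.arity + 1):
        table.append(eval_gate(gate, bits[:-1]) & bits[-1])
    return Gate(name=f"{gate.name}&chain", arity=gate.arity + 1, table=tuple(table))


def _rename(net: GeneNetwork, suffix: str) -> GeneNetwork:
    gmap = {g.id: f"{g.id}{suffix}" for g in net.genes}
    smap = {s: f"{s}{suffix}" for s in net.signals}
    return GeneNetwork(
        genes=[
            Gene(
                id=gmap[g.id],
                always_on=g.always_on,
                lock_in=g.lock_in,
                multiplicity=g.multiplicity,
                initial_expression=g.initial_expression,
                autoregulation=g.autoregulation,
            )
            for g in net.genes
        ],
        signals=[smap[s] for s in net.signals],
        bindings=[
            SignalBinding(gene_id=gmap[b.gene_id], signal_id=smap[b.signal_id], mode=b.mode)
            for b in net.bindings
        ],
        junctions=[
            Junction(
                target_gene=gmap[j.target_gene],
                inputs=[
                    RegulatoryInput(
                        kind=i.kind,
                        ref=gmap[i.ref] if i.kind == "activity" else smap[i.ref],
                        negated=i.negated,
                    )
                    for i in j.inputs
                ],
                gate=j.gate,
            )
            for j in net.junctions
        ],
    )


def random_motif_composition(n_motifs: int, seed: int) -> GeneNetwork:
    """Chain randomly chosen small motifs into one validated network.

    Deterministic in ``seed``.  The output gene of each motif (its last
    declared gene) becomes an extra required regulator of the next
    motif's first regulated gene: that junction's gate is AND-extended
    with the chaining activity.  Motif sizes are kept small so that
    compositions stay within brute-force reach of the flat-diagram
    oracle.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = random.Random(seed)

    def sample_motif() -> GeneNetwork:
        kind = rng.choice(
            ["simple_regulation", "autoregulation", "c1_ffl", "ic1_ffl",
             "single_input_module", "dense_overlapping_regulon"]
        )
        if kind == "simple_regulation":
            return build_simple_regulation(rng.choice(_MODES), rng.choice(_MODES))
        if kind == "autoregulation":
            sign = rng.choice(["positive", "negative"])
            lock = sign == "positive" and rng.random() < 0.5
            return build_autoregulation(sign, lock)
        if kind == "c1_ffl":
            return build_c1_ffl()
        if kind == "ic1_ffl":
            return build_ic1_ffl()
        if kind == "single_input_module":
            return build_single_input_module(rng.randint(1, 3))
        specs = [
            ("Y1", rng.choice(["and", "or"]), ("S_x1", "S_x2")),
            ("Y2", rng.choice(["and", "or"]), ("S_x1", "S_x2")),
        ]
        return build_dense_overlapping_regulon(("X1", "X2"), specs[: rng.randint(1, 2)])

    parts = [_rename(sample_motif(), f"_m{i}") for i in range(n_motifs)]
    genes, signals, bindings, junctions = [], [], [], []
    prev_out: str | None = None
    for part in parts:
        if prev_out is not None:
            # first regulated gene of this motif also requires prev_out's activity
            j = next(j for j in part.junctions)
            j.inputs = list(j.inputs) + [_act(prev_out)]
            j.gate = _and_extend(j.gate)
        genes.extend(part.genes)
        signals.extend(part.signals)
        bindings.extend(part.bindings)
        junctions.extend(part.junctions)
        prev_out = part.genes[-1].id
    net = GeneNetwork(genes=genes, signals=signals, bindings=bindings, junctions=junctions)
    return _finish(net)
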