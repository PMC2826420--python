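"""Logical-domain gene network model.

A :class:`GeneNetwork` is a Boolean model of transcriptional regulation:
genes carry a binary expression state, extracellular signals carry a
binary presence state, and each regulated gene has exactly one promoter
*junction* — an ordered list of regulatory inputs combined by a Boolean
gate.  A signal bound to a gene gates the *activity* of that gene's
protein product: an activator signal makes the protein active only when
the signal is present, a repressor signal only when it is absent.

The model is deliberately qualitative: amounts and physical time are
abstracted away, only states and the order of state transitions matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

from .gates import Gate, eval_gate

__all__ = [
    "Gene",
    "SignalBinding",
    "RegulatoryInput",
    "Junction",
    "GeneNetwork",
    "GlobalState",
    "validate_network",
    "activity",
    "next_expression",
    "compiled_step",
    "settle_initial_expressions",
]


@dataclass
class Gene:
    """One gene (or a group of identical genes, see ``multiplicity``).

    ``always_on`` marks constitutively expressed genes whose expression
    bit is clamped to 1.  ``lock_in`` marks genes whose activation is
    irreversible (strong positive autoregulation): once expressed, the
    junction is ignored and the bit stays 1.  ``multiplicity`` lets one
    node stand for k identical genes sharing regulation; flattening can
    expand it into explicit copies.
    """

    id: str
    always_on: bool = False
    lock_in: bool = False
    multiplicity: int = 1
    initial_expression: int = 0
    autoregulation: Optional[str] = None  # "positive" | "negative" | None


@dataclass
class SignalBinding:
    """Associates a signal with the activity of one gene's protein.

    mode="activator": activity = expression AND signal.
    mode="repressor": activity = expression AND NOT signal.
    """

    gene_id: str
    signal_id: str
    mode: str


@dataclass
class RegulatoryInput:
    """One ordered input to a junction: a gene activity or a raw signal."""

    kind: str  # "activity" | "signal"
    ref: str
    negated: bool = False


@dataclass
class Junction:
    """The promoter logic of one target gene."""

    target_gene: str
    inputs: list[RegulatoryInput]
    gate: Gate


@dataclass
class GeneNetwork:
    genes: list[Gene]
    signals: list[str] = field(default_factory=list)
    bindings: list[SignalBinding] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)

    # -- lookups (declaration order is authoritative everywhere) -----

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")

    def binding_for(self, gene_id: str) -> Optional[SignalBinding]:
        for b in self.bindings:
            if b.gene_id == gene_id:
                return b
        return None

    def junction_for(self, gene_id: str) -> Optional[Junction]:
        for j in self.junctions:
            if j.target_gene == gene_id:
                return j
        return None

    def initial_state(self, signals: Optional[Mapping[str, int]] = None) -> "GlobalState":
        """Initial global state (declared initial bits, signals default 0)."""
        sig = {s: 0 for s in self.signals}
        if signals:
            for k, v in signals.items():
                if k not in sig:
                    raise KeyError(f"unknown signal {k!r}")
                sig[k] = int(v)
        return GlobalState(
            expression={g.id: (1 if g.always_on else int(g.initial_expression)) for g in self.genes},
            signal_values=sig,
        )


@dataclass
class GlobalState:
    """Bit per gene (expression) and bit per signal (presence)."""

    expression: dict[str, int]
    signal_values: dict[str, int]

    def expr_tuple(self, net: GeneNetwork) -> tuple[int, ...]:
        return tuple(self.expression[g.id] for g in net.genes)

    def signal_tuple(self, net: GeneNetwork) -> tuple[int, ...]:
        return tuple(self.signal_values[s] for s in net.signals)

    def key(self, net: GeneNetwork) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return (self.expr_tuple(net), self.signal_tuple(net))

    @staticmethod
    def from_tuples(net: GeneNetwork, expr: tuple[int, ...], sigs: tuple[int, ...]) -> "GlobalState":
        return GlobalState(
            expression={g.id: e for g, e in zip(net.genes, expr)},
            signal_values={s: v for s, v in zip(net.signals, sigs)},
        )


# ---------------------------------------------------------------------------
# validation


def validate_network(net: GeneNetwork) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    An empty list means the network is well formed.  Violations are
    returned (never raised) so that a validator run can report them all
    at once.
    """
    v: list[str] = []
    if not net.genes:
        v.append("network has no genes")

    seen: set[str] = set()
    for g in net.genes:
        if g.id in seen:
            v.append(f"duplicate gene id {g.id!r}")
        seen.add(g.id)
        if g.multiplicity < 1:
            v.append(f"gene {g.id!r}: multiplicity must be >= 1, got {g.multiplicity}")
        if g.initial_expression not in (0, 1):
            v.append(f"gene {g.id!r}: initial expression must be a bit")
        if g.always_on and g.initial_expression != 1:
            v.append(f"gene {g.id!r}: always_on requires initial expression 1")
        if g.autoregulation not in (None, "positive", "negative"):
            v.append(f"gene {g.id!r}: bad autoregulation annotation {g.autoregulation!r}")
        if g.lock_in and g.autoregulation == "negative":
            v.append(f"gene {g.id!r}: lock_in requires positive autoregulation")

    gene_ids = {g.id for g in net.genes}
    sig_ids = set(net.signals)
    if len(net.signals) != len(sig_ids):
        v.append("duplicate signal ids")

    bound: set[str] = set()
    for b in net.bindings:
        if b.gene_id not in gene_ids:
            v.append(f"binding references unknown gene {b.gene_id!r}")
        if b.signal_id not in sig_ids:
            v.append(f"binding references unknown signal {b.signal_id!r}")
        if b.mode not in ("activator", "repressor"):
            v.append(f"binding for {b.gene_id!r}: bad mode {b.mode!r}")
        if b.gene_id in bound:
            v.append(f"gene {b.gene_id!r} has more than one signal binding")
        bound.add(b.gene_id)

    targets: set[str] = set()
    for j in net.junctions:
        if j.target_gene not in gene_ids:
            v.append(f"junction targets unknown gene {j.target_gene!r}")
        if j.target_gene in targets:
            v.append(f"gene {j.target_gene!r} has more than one junction")
        targets.add(j.target_gene)
        if len(j.inputs) != j.gate.arity:
            v.append(
                f"junction for {j.target_gene!r}: gate {j.gate.name!r} has arity "
                f"{j.gate.arity} but {len(j.inputs)} inputs"
            )
        for inp in j.inputs:
            if inp.kind == "activity":
                if inp.ref not in gene_ids:
                    v.append(
                        f"junction for {j.target_gene!r}: unknown gene {inp.ref!r}"
                    )
                elif inp.ref == j.target_gene:
                    tg = next(g for g in net.genes if g.id == j.target_gene)
                    if tg.autoregulation is None:
                        v.append(
                            f"junction for {j.target_gene!r}: self-reference is only "
                            "allowed on autoregulation nodes"
                        )
            elif inp.kind == "signal":
                if inp.ref not in sig_ids:
                    v.append(
                        f"junction for {j.target_gene!r}: unknown signal {inp.ref!r}"
                    )
            else:
                v.append(f"junction for {j.target_gene!r}: bad input kind {inp.kind!r}")

    for g in net.genes:
        if not g.always_on and g.id not in targets:
            v.append(f"gene {g.id!r} is not always_on but has no junction")

    return v


# ---------------------------------------------------------------------------
# semantics


def activity(state: GlobalState, gene_id: str, net: GeneNetwork) -> int:
    """Protein activity of a gene in a global state.

    Expression gated by the bound signal: activator binding gives
    expression AND signal, repressor binding expression AND NOT signal,
    no binding passes expression through.  Activity never exceeds the
    expression bit.
    """
    net.gene(gene_id)  # raises KeyError for unknown genes
    expr = int(state.expression[gene_id])
    b = net.binding_for(gene_id)
    if b is None:
        return expr
    sig = int(state.signal_values[b.signal_id])
    if b.mode == "activator":
        return expr & sig
    return expr & (1 - sig)


def _junction_input_bit(state: GlobalState, inp: RegulatoryInput, net: GeneNetwork) -> int:
    if inp.kind == "activity":
        bit = activity(state, inp.ref, net)
    else:
        bit = int(state.signal_values[inp.ref])
    return 1 - bit if inp.negated else bit


def next_expression(state: GlobalState, gene_id: str, net: GeneNetwork) -> int:
    """Next expression bit of a gene under the current global state.

    Always-on genes stay 1; locked-in genes that are already expressed
    stay 1 regardless of their junction; otherwise the junction gate is
    evaluated on its ordered inputs.  A gene with no junction (and not
    always on) holds its current bit.
    """
    g = net.gene(gene_id)
    if g.always_on:
        return 1
    if g.lock_in and state.expression[gene_id] == 1:
        return 1
    j = net.junction_for(gene_id)
    if j is None:
        return int(state.expression[gene_id])
    bits = tuple(_junction_input_bit(state, inp, net) for inp in j.inputs)
    return eval_gate(j.gate, bits)


def compiled_step(net: GeneNetwork) -> Callable[[tuple[int, ...], tuple[int, ...]], tuple[int, ...]]:
    """Compile the synchronous update into a fast tuple-to-tuple function.

    Returns ``f(expr, sigs) -> expr'`` operating on bit tuples in
    declaration order.  Semantically identical to calling
    :func:`next_expression` per gene; used by the execution engine and
    the flat-diagram enumerator, where the per-call lookups of the
    public API would dominate.
    """
    gidx = {g.id: i for i, g in enumerate(net.genes)}
    sidx = {s: i for i, s in enumerate(net.signals)}
    bindings = {b.gene_id: b for b in net.bindings}
    junctions = {j.target_gene: j for j in net.junctions}

    plans: list[tuple] = []
    for i, g in enumerate(net.genes):
        if g.always_on:
            plans.append(("const1",))
            continue
        j = junctions.get(g.id)
        if j is None:
            plans.append(("hold", i))
            continue
        terms: list[tuple] = []
        for inp in j.inputs:
            if inp.kind == "activity":
                ti = gidx[inp.ref]
                b = bindings.get(inp.ref)
                if b is None:
                    terms.append(("expr", ti, 0, inp.negated))
                elif b.mode == "activator":
                    terms.append(("act", ti, sidx[b.signal_id], inp.negated))
                else:
                    terms.append(("rep", ti, sidx[b.signal_id], inp.negated))
            else:
                terms.append(("sig", sidx[inp.ref], 0, inp.negated))
        plans.append(("gate", i, g.lock_in, j.gate.table, j.gate.arity, tuple(terms)))

    def step(expr: tuple[int, ...], sigs: tuple[int, ...]) -> tuple[int, ...]:
        out = []
        for p in plans:
            tag = p[0]
            if tag == "const1":
                out.append(1)
            elif tag == "hold":
                out.append(expr[p[1]])
            else:
                _, i, lock, table, arity, terms = p
                if lock and expr[i]:
                    out.append(1)
                    continue
                idx = 0
                for kind, a, b, neg in terms:
                    if kind == "expr":
                        bit = expr[a]
                    elif kind == "act":
                        bit = expr[a] & sigs[b]
                    elif kind == "rep":
                        bit = expr[a] & (1 - sigs[b])
                    else:
                        bit = sigs[a]
                    if neg:
                        bit = 1 - bit
                    idx = (idx << 1) | bit
                out.append(table[idx])
        return tuple(out)

    return step


def settle_initial_expressions(net: GeneNetwork, max_iter: int = 10_000) -> GeneNetwork:
    """Set each gene's initial bit to the fixed point under all-zero signals.

    Mutates and returns ``net``.  Motif builders use this so that the
    pre-stimulus state of every network is quiescent (self-consistent
    before any signal event); on the feedback-free motif topologies the
    fixed point is reached within one pass per cascade level.
    """
    step = compiled_step(net)
    sigs = tuple(0 for _ in net.signals)
    expr = tuple(1 if g.always_on else int(g.initial_expression) for g in net.genes)
    for _ in range(max_iter):
        nxt = step(expr, sigs)
        if nxt == expr:
            break
        expr = nxt
    for g, bit in zip(net.genes, expr):
        g.initial_expression = bit
    return net
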