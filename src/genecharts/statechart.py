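"""Build hierarchical statecharts from gene networks.

A statechart extends the classical state diagram with nested hierarchy,
orthogonal (concurrent) regions and reusable substructure, which is
what keeps the representation linear in gene count where the flat
diagram is exponential.

Construction rules:

* the constitutively expressed regulators form the root superstate
  (labelled e.g. ``X=1`` or ``X1X2X3=111``);
* every regulated gene contributes a two-substate block — expression 0
  ("I", drawn first) and expression 1 ("II") — nested in the context of
  its deepest regulator's *on* substate, so cascades recurse naturally;
* genes sharing a regulator context but independent of one another
  become orthogonal regions of a single parallel node;
* transitions connect the two substates of a block, guarded by the
  gene's junction condition over signals; a locked-in gene has no
  off-transition out of its on-substate.

Cyclic regulation (other than annotated self-loops) is feedback and is
rejected: the hierarchy has no consistent nesting order for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx

from .network import GeneNetwork, compiled_step, validate_network

__all__ = [
    "StatechartNode",
    "TransitionEdge",
    "Statechart",
    "UnsupportedStructureError",
    "network_to_statechart",
    "initial_configuration",
    "statechart_size",
]


class UnsupportedStructureError(ValueError):
    """Raised for regulatory structures the hierarchy cannot express (feedback)."""


@dataclass
class StatechartNode:
    id: str
    kind: str  # "atomic" | "composite" | "parallel"
    label: str
    children: list["StatechartNode"] = field(default_factory=list)
    regions: list[list["StatechartNode"]] = field(default_factory=list)
    gene: Optional[str] = None  # gene whose expression this substate asserts
    expression_bit: Optional[int] = None
    name: Optional[str] = None  # roman numeral in diagram order

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class TransitionEdge:
    source: str
    target: str
    trigger: str
    guard: str


@dataclass
class Statechart:
    root: StatechartNode
    transitions: list[TransitionEdge]
    network: GeneNetwork

    def node(self, node_id: str) -> StatechartNode:
        for n in self.root.walk():
            if n.id == node_id:
                return n
        raise KeyError(f"unknown statechart node {node_id!r}")

    def initial_rule(self, composite_id: str, signals: Mapping[str, int]) -> list[str]:
        """Initial substates of a composite under a signal valuation.

        The signal state selects which substate execution enters first:
        per orthogonal region, the substate matching its gene's settled
        expression under the given (held-constant) signals.  Returns one
        substate id per region (a plain composite is one region).
        """
        node = self.node(composite_id)
        if node.kind == "atomic":
            raise KeyError(f"node {composite_id!r} is atomic, not composite")
        steady = _steady_expression(self.network, signals)
        genes: list[str] = []
        frontier = node.children
        while frontier:
            nxt: list[StatechartNode] = []
            for c in frontier:
                if c.gene is not None:
                    if c.gene not in genes:
                        genes.append(c.gene)
                elif c.kind == "parallel":
                    nxt.extend(c.children)
            frontier = nxt
        return [f"{g}={steady[g]}" for g in genes]


def _direct_gene_regulators(net: GeneNetwork, gene_id: str) -> list[str]:
    j = net.junction_for(gene_id)
    if j is None:
        return []
    out = []
    for inp in j.inputs:
        if inp.kind == "activity" and inp.ref != gene_id and inp.ref not in out:
            out.append(inp.ref)
    return out


def _dependency_graph(net: GeneNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.gene_ids())
    for gene in net.genes:
        for reg in _direct_gene_regulators(net, gene.id):
            g.add_edge(reg, gene.id)
    return g


def _guard_text(net: GeneNetwork, gene_id: str, on: bool) -> str:
    j = net.junction_for(gene_id)
    if j is None:
        return ""
    parts = []
    for inp in j.inputs:
        txt = f"{inp.ref}*" if inp.kind == "activity" else inp.ref
        parts.append(f"not {txt}" if inp.negated else txt)
    cond = f"{j.gate.name}({', '.join(parts)})"
    return cond if on else f"not {cond}"


def network_to_statechart(net: GeneNetwork) -> Statechart:
    """Convert a validated, feedback-free network into a statechart."""
    problems = validate_network(net)
    if problems:
        raise ValueError("invalid network: " + "; ".join(problems))

    dep = _dependency_graph(net)
    if not nx.is_directed_acyclic_graph(dep):
        cyc = nx.find_cycle(dep)
        raise UnsupportedStructureError(
            f"regulatory feedback is not supported (cycle through {[e[0] for e in cyc]})"
        )

    always_on = [g.id for g in net.genes if g.always_on]
    regulated = [g.id for g in net.genes if not g.always_on]

    # depth = longest regulator chain; parent = deepest direct regulator
    depth: dict[str, int] = {g: 0 for g in always_on}
    for gid in nx.topological_sort(dep):
        if gid in depth:
            continue
        regs = _direct_gene_regulators(net, gid)
        depth[gid] = max((depth[r] + 1 for r in regs), default=1)

    order = {g.id: i for i, g in enumerate(net.genes)}
    parent: dict[str, Optional[str]] = {}
    for gid in regulated:
        regs = [r for r in _direct_gene_regulators(net, gid) if r not in always_on]
        if regs:
            parent[gid] = max(regs, key=lambda r: (depth[r], -order[r]))
        else:
            parent[gid] = None  # nests directly in the always-on context

    root_label = (
        "".join(always_on) + "=" + "1" * len(always_on) if always_on else "root"
    )
    root = StatechartNode(id="root", kind="composite", label=root_label)
    on_node: dict[Optional[str], StatechartNode] = {None: root}
    pairs: dict[str, tuple[StatechartNode, StatechartNode]] = {}

    for gid in sorted(regulated, key=lambda g: (depth[g], order[g])):
        off = StatechartNode(
            id=f"{gid}=0", kind="atomic", label=f"{gid}=0", gene=gid,
            expression_bit=0, name="I",
        )
        on = StatechartNode(
            id=f"{gid}=1", kind="atomic", label=f"{gid}=1", gene=gid,
            expression_bit=1, name="II",
        )
        pairs[gid] = (off, on)
        on_node[gid] = on

    # group blocks under their parent context; siblings are independent
    # by construction (a dependent child would nest deeper), so two or
    # more blocks in one context run as orthogonal regions.
    children_of: dict[Optional[str], list[str]] = {}
    for gid in sorted(regulated, key=lambda g: order[g]):
        children_of.setdefault(parent[gid], []).append(gid)

    def attach(context_gene: Optional[str]) -> None:
        host = on_node[context_gene]
        kids = children_of.get(context_gene, [])
        if not kids:
            return
        if host.kind == "atomic":
            host.kind = "composite"
        blocks = [[pairs[k][0], pairs[k][1]] for k in kids]
        if len(kids) >= 2:
            par = StatechartNode(
                id="par:" + (context_gene or "root"),
                kind="parallel",
                label=" | ".join(kids),
                regions=blocks,
                children=[n for b in blocks for n in b],
            )
            host.children.append(par)
        else:
            host.children.extend(blocks[0])

    attach(None)
    for gid in sorted(regulated, key=lambda g: (depth[g], order[g])):
        attach(gid)

    transitions: list[TransitionEdge] = []
    for gid in sorted(regulated, key=lambda g: order[g]):
        gene = net.gene(gid)
        transitions.append(
            TransitionEdge(
                source=f"{gid}=0", target=f"{gid}=1",
                trigger="signal-change", guard=_guard_text(net, gid, True),
            )
        )
        if not gene.lock_in:
            transitions.append(
                TransitionEdge(
                    source=f"{gid}=1", target=f"{gid}=0",
                    trigger="signal-change", guard=_guard_text(net, gid, False),
                )
            )

    return Statechart(root=root, transitions=transitions, network=net)


def _steady_expression(net: GeneNetwork, signals: Mapping[str, int]) -> dict[str, int]:
    step = compiled_step(net)
    sigs = tuple(int(signals[s]) for s in net.signals)
    expr = tuple(
        1 if g.always_on else int(g.initial_expression) for g in net.genes
    )
    for _ in range(len(net.genes) + 1):
        nxt = step(expr, sigs)
        if nxt == expr:
            break
        expr = nxt
    return {g.id: e for g, e in zip(net.genes, expr)}


def initial_configuration(chart: Statechart, signals: Mapping[str, int]) -> set[str]:
    """Active atomic substates on entry under a held signal valuation.

    The signal state selects the initial substate of every active gene
    block (one per orthogonal region); blocks nested under an inactive
    on-substate are not entered.  Returns the ids of active nodes that
    have no active children of their own.
    """
    net = chart.network
    missing = [s for s in net.signals if s not in signals]
    if missing:
        raise KeyError(f"signal valuation missing {missing}")
    steady = _steady_expression(net, signals)

    active: set[str] = set()

    def enter(node: StatechartNode) -> None:
        if node.kind == "parallel":
            for region in node.regions:
                for child in region:
                    consider(child)
            return
        kids = node.children
        if not kids:
            active.add(node.id)
            return
        gene_kids = [c for c in kids if c.gene is not None]
        other_kids = [c for c in kids if c.gene is None]
        chosen: list[StatechartNode] = []
        seen_genes: set[str] = set()
        for c in gene_kids:
            if c.gene in seen_genes:
                continue
            if c.expression_bit == steady[c.gene]:
                chosen.append(c)
                seen_genes.add(c.gene)
        for c in chosen + other_kids:
            enter(c)

    def consider(child: StatechartNode) -> None:
        if child.gene is not None and child.expression_bit != steady[child.gene]:
            return
        enter(child)

    enter(chart.root)
    # leaf-only view: drop any node that has an active descendant
    leaves = set()
    for nid in active:
        node = chart.node(nid)
        if not any(c.id in active for c in node.walk() if c.id != nid):
            leaves.add(nid)
    return leaves


def statechart_size(chart: Statechart) -> tuple[int, int, int]:
    """(node count, transition count, max nesting depth) of a chart."""

    def measure(node: StatechartNode, d: int) -> tuple[int, int]:
        n, md = 1, d
        for c in node.children:
            cn, cd = measure(c, d + 1)
            n += cn
            md = max(md, cd)
        return n, md

    n_nodes, max_depth = measure(chart.root, 1)
    return n_nodes, len(chart.transitions), max_depth
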