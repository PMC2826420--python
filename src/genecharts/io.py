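"""Readers, writers and exports.

The network JSON schema is the single authoring format::

    {"genes":    [{"id": "X1", "always_on": true, "lock_in": false,
                   "multiplicity": 1, "initial": 1}, ...],
     "signals":  ["S_X1", ...],
     "bindings": [{"gene": "X1", "signal": "S_X1", "mode": "activator"}, ...],
     "junctions":[{"target": "Z1", "gate": "does_not_imply",
                   "inputs": [{"activity": "X1"}, {"activity": "Y1"}]}, ...]}

Ids are case-sensitive; unknown keys are rejected.  Gates serialize as
a builtin name or as ``{"name":..., "arity":..., "table":[...]}`` with
the truth table in lexicographic input order.  Bits are 0/1 integers in
every serialized artifact.  All writers are deterministic: ordering
follows declaration order, never hash order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import networkx as nx

from .engine import ExecutionTrace
from .flatten import FlatStateDiagram
from .gates import BUILTIN_GATE_NAMES, Gate, builtin_gate
from .network import (
    Gene,
    GeneNetwork,
    Junction,
    RegulatoryInput,
    SignalBinding,
    validate_network,
)
from .statechart import Statechart, StatechartNode

__all__ = [
    "NetworkFormatError",
    "network_to_dict",
    "network_from_dict",
    "read_network",
    "write_network",
    "write_trace",
    "read_trace_bits",
    "chart_to_dot",
    "chart_to_graphml",
    "flat_to_dot",
    "flat_to_tsv",
    "export_chart",
]


class NetworkFormatError(ValueError):
    """Malformed network JSON (unknown keys, bad gate names, ...)."""


def _reject_unknown(obj: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(obj) - allowed)
    if unknown:
        raise NetworkFormatError(f"{where}: unknown key(s) {', '.join(unknown)}")


def _gate_to_json(g: Gate) -> Union[str, dict]:
    if g.name in BUILTIN_GATE_NAMES and builtin_gate(g.name) == g:
        return g.name
    return {"name": g.name, "arity": g.arity, "table": list(g.table)}


def _gate_from_json(obj, where: str) -> Gate:
    if isinstance(obj, str):
        try:
            return builtin_gate(obj)
        except KeyError as e:
            raise NetworkFormatError(f"{where}: {e.args[0]}") from None
    if isinstance(obj, dict):
        _reject_unknown(obj, {"name", "arity", "table"}, where)
        try:
            return Gate(name=obj["name"], arity=int(obj["arity"]), table=tuple(int(b) for b in obj["table"]))
        except (KeyError, ValueError) as e:
            raise NetworkFormatError(f"{where}: bad gate object ({e})") from None
    raise NetworkFormatError(f"{where}: gate must be a name or an object")


def network_to_dict(net: GeneNetwork) -> dict:
    genes = []
    for g in net.genes:
        entry: dict = {
            "id": g.id,
            "always_on": bool(g.always_on),
            "lock_in": bool(g.lock_in),
            "multiplicity": int(g.multiplicity),
            "initial": int(g.initial_expression),
        }
        if g.autoregulation is not None:
            entry["autoregulation"] = g.autoregulation
        genes.append(entry)
    junctions = []
    for j in net.junctions:
        inputs = []
        for i in j.inputs:
            d: dict = {i.kind: i.ref}
            if i.negated:
                d["negated"] = True
            inputs.append(d)
        junctions.append({"target": j.target_gene, "gate": _gate_to_json(j.gate), "inputs": inputs})
    return {
        "genes": genes,
        "signals": list(net.signals),
        "bindings": [
            {"gene": b.gene_id, "signal": b.signal_id, "mode": b.mode} for b in net.bindings
        ],
        "junctions": junctions,
    }


def network_from_dict(data: dict) -> GeneNetwork:
    if not isinstance(data, dict):
        raise NetworkFormatError("top level must be an object")
    _reject_unknown(data, {"genes", "signals", "bindings", "junctions"}, "top level")
    genes = []
    for k, g in enumerate(data.get("genes", [])):
        where = f"genes[{k}]"
        _reject_unknown(
            g, {"id", "always_on", "lock_in", "multiplicity", "initial", "autoregulation"}, where
        )
        if "id" not in g:
            raise NetworkFormatError(f"{where}: missing id")
        genes.append(
            Gene(
                id=g["id"],
                always_on=bool(g.get("always_on", False)),
                lock_in=bool(g.get("lock_in", False)),
                multiplicity=int(g.get("multiplicity", 1)),
                initial_expression=int(g.get("initial", 0)),
                autoregulation=g.get("autoregulation"),
            )
        )
    signals = list(data.get("signals", []))
    bindings = []
    for k, b in enumerate(data.get("bindings", [])):
        where = f"bindings[{k}]"
        _reject_unknown(b, {"gene", "signal", "mode"}, where)
        try:
            bindings.append(SignalBinding(gene_id=b["gene"], signal_id=b["signal"], mode=b["mode"]))
        except KeyError as e:
            raise NetworkFormatError(f"{where}: missing {e.args[0]}") from None
    junctions = []
    for k, j in enumerate(data.get("junctions", [])):
        where = f"junctions[{k}]"
        _reject_unknown(j, {"target", "gate", "inputs"}, where)
        if "target" not in j or "gate" not in j:
            raise NetworkFormatError(f"{where}: missing target or gate")
        inputs = []
        for ki, inp in enumerate(j.get("inputs", [])):
            iwhere = f"{where}.inputs[{ki}]"
            _reject_unknown(inp, {"activity", "signal", "negated"}, iwhere)
            kinds = [kk for kk in ("activity", "signal") if kk in inp]
            if len(kinds) != 1:
                raise NetworkFormatError(f"{iwhere}: need exactly one of activity/signal")
            inputs.append(
                RegulatoryInput(kind=kinds[0], ref=inp[kinds[0]], negated=bool(inp.get("negated", False)))
            )
        junctions.append(
            Junction(target_gene=j["target"], inputs=inputs, gate=_gate_from_json(j["gate"], where))
        )
    return GeneNetwork(genes=genes, signals=signals, bindings=bindings, junctions=junctions)


def read_network(path: Union[str, Path]) -> GeneNetwork:
    """Parse and validate a network JSON file.

    Raises :class:`NetworkFormatError` on malformed JSON or schema
    violations, and ``ValueError`` listing every structural violation if
    the parsed network is not well formed.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise NetworkFormatError(f"{path}: invalid JSON at line {e.lineno} col {e.colno}: {e.msg}") from None
    net = network_from_dict(data)
    problems = validate_network(net)
    if problems:
        raise ValueError(f"{path}: invalid network: " + "; ".join(problems))
    return net


def write_network(net: GeneNetwork, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=2) + "\n")


# ---------------------------------------------------------------------------
# traces


def write_trace(trace: ExecutionTrace, net: GeneNetwork, path: Union[str, Path]) -> None:
    """Write a trace as TSV: one row per state, genes then signals.

    Columns: state index, event marker (the applied signal assignment,
    empty otherwise), one bit per gene and per signal in declaration
    order.  Ends with a trailing newline.
    """
    events = dict(trace.events)
    lines = ["\t".join(["state", "event"] + net.gene_ids() + list(net.signals))]
    for i, st in enumerate(trace.states):
        row = [str(i), events.get(i, "")]
        row += [str(int(st.expression[g.id])) for g in net.genes]
        row += [str(int(st.signal_values[s])) for s in net.signals]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_bits(path: Union[str, Path]) -> tuple[list[str], list[list[int]]]:
    """Read back a trace TSV: (bit column names, rows of bits)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")[2:]
    rows = [[int(x) for x in ln.split("\t")[2:]] for ln in lines[1:]]
    return header, rows


# ---------------------------------------------------------------------------
# statechart exports


def _dot_escape(s: str) -> str:
    return s.replace('"', '\\"')


def chart_to_dot(chart: Statechart) -> str:
    """Deterministic DOT rendering: composites as clusters, regions dashed."""
    lines = ["digraph statechart {", "  compound=true;", "  node [shape=box];"]

    def emit(node: StatechartNode, indent: str) -> None:
        if node.kind == "atomic" and not node.children:
            label = node.label + (f" ({node.name})" if node.name else "")
            lines.append(f'{indent}"{_dot_escape(node.id)}" [label="{_dot_escape(label)}"];')
            return
        style = "dashed" if node.kind == "parallel" else "solid"
        lines.append(f'{indent}subgraph "cluster_{_dot_escape(node.id)}" {{')
        lines.append(f'{indent}  label="{_dot_escape(node.label)}"; style={style};')
        if node.kind == "parallel":
            for r, region in enumerate(node.regions):
                lines.append(f'{indent}  subgraph "cluster_{_dot_escape(node.id)}_r{r}" {{')
                lines.append(f'{indent}    label=""; style=dashed;')
                for child in region:
                    emit(child, indent + "    ")
                lines.append(f"{indent}  }}")
        else:
            for child in node.children:
                emit(child, indent + "  ")
        lines.append(f"{indent}}}")

    emit(chart.root, "  ")
    for t in sorted(chart.transitions, key=lambda t: (t.source, t.target)):
        lines.append(
            f'  "{_dot_escape(t.source)}" -> "{_dot_escape(t.target)}" '
            f'[label="{_dot_escape(t.guard)}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _chart_graph(chart: Statechart) -> nx.DiGraph:
    g = nx.DiGraph()
    def add(node: StatechartNode, parent: str | None) -> None:
        g.add_node(node.id, kind=node.kind, label=node.label,
                   parent=parent if parent is not None else "")
        for c in node.children:
            add(c, node.id)
    add(chart.root, None)
    for t in chart.transitions:
        g.add_edge(t.source, t.target, trigger=t.trigger, guard=t.guard)
    return g


def chart_to_graphml(chart: Statechart, path: Union[str, Path]) -> None:
    nx.write_graphml(_chart_graph(chart), str(path))


# ---------------------------------------------------------------------------
# flat-diagram exports


def _pattern_text(pattern: tuple) -> str:
    return "".join("X" if p is None else str(p) for p in pattern)


def flat_to_dot(diag: FlatStateDiagram) -> str:
    """Flat diagram as DOT: states as bit-vector nodes, X marks don't-care."""
    lines = ["digraph flat {", "  node [shape=ellipse];"]
    genes = "".join(diag.free_gene_ids)
    lines.append(f'  // state bits: {genes}; edge labels over signals {",".join(diag.signal_ids)}')
    for i, s in enumerate(diag.states):
        bits = "".join(str(b) for b in s)
        lines.append(f'  s{i} [label="{bits}"];')
    for src, pattern, tgt in sorted(diag.transitions, key=lambda t: (t[0], t[2], _pattern_text(t[1]))):
        lines.append(f'  s{src} -> s{tgt} [label="{_pattern_text(pattern)}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def flat_to_tsv(diag: FlatStateDiagram) -> str:
    """Adjacency TSV: source bits, signal pattern (X = don't care), target bits."""
    lines = ["\t".join(["source", "signals", "target"])]
    for src, pattern, tgt in sorted(diag.transitions, key=lambda t: (t[0], t[2], _pattern_text(t[1]))):
        s = "".join(str(b) for b in diag.states[src])
        t = "".join(str(b) for b in diag.states[tgt])
        lines.append("\t".join([s, _pattern_text(pattern), t]))
    return "\n".join(lines) + "\n"


def export_chart(obj: Union[Statechart, FlatStateDiagram], fmt: str, path: Union[str, Path]) -> None:
    """Export a statechart or flat diagram to dot/graphml/tsv."""
    if isinstance(obj, Statechart):
        if fmt == "dot":
            Path(path).write_text(chart_to_dot(obj))
        elif fmt == "graphml":
            chart_to_graphml(obj, path)
        else:
            raise ValueError(f"unsupported format {fmt!r} for statecharts (dot, graphml)")
    elif isinstance(obj, FlatStateDiagram):
        if fmt == "dot":
            Path(path).write_text(flat_to_dot(obj))
        elif fmt == "tsv":
            Path(path).write_text(flat_to_tsv(obj))
        else:
            raise ValueError(f"unsupported format {fmt!r} for flat diagrams (dot, tsv)")
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
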