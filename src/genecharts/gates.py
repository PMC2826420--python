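"""Combinational junction gates.

A promoter that integrates several regulatory inputs does so through a
Boolean *junction gate*: a total function from input bit-tuples to an
output bit.  The coherent type-1 feed-forward loop uses ``and``, the
incoherent type-1 loop uses ``does_not_imply`` (p AND NOT q), and any
other Boolean gate may in principle appear at a junction.

Gates are immutable.  Truth tables are stored as a flat tuple of output
bits in lexicographic input order (``(0,0), (0,1), (1,0), (1,1)`` for
arity 2), which makes serialization bit-exact and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

__all__ = [
    "Gate",
    "BUILTIN_GATE_NAMES",
    "builtin_gate",
    "eval_gate",
    "gate_from_table",
    "gate_to_table",
    "classify_coherence",
]


@dataclass(frozen=True)
class Gate:
    """A named Boolean function of fixed arity.

    ``table[i]`` is the output for the input tuple whose bits, read
    left to right, are the binary digits of ``i`` (most significant
    first).  Inputs are ordered: ``does_not_imply`` is non-commutative,
    with the activator arm first and the repressor arm second.
    """

    name: str
    arity: int
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.arity < 0:
            raise ValueError("gate arity must be non-negative")
        if len(self.table) != 2**self.arity:
            raise ValueError(
                f"gate {self.name!r}: table has {len(self.table)} entries, "
                f"expected {2 ** self.arity} for arity {self.arity}"
            )
        if any(b not in (0, 1) for b in self.table):
            raise ValueError(f"gate {self.name!r}: table bits must be 0 or 1")

    def __call__(self, *inputs: int) -> int:
        return eval_gate(self, inputs)


def _tt(name: str, arity: int, fn) -> Gate:
    table = tuple(int(fn(*bits)) for bits in product((0, 1), repeat=arity))
    return Gate(name=name, arity=arity, table=table)


_BUILTINS: dict[str, Gate] = {
    g.name: g
    for g in (
        _tt("const0", 0, lambda: 0),
        _tt("const1", 0, lambda: 1),
        _tt("identity", 1, lambda p: p),
        _tt("not", 1, lambda p: 1 - p),
        _tt("and", 2, lambda p, q: p & q),
        _tt("or", 2, lambda p, q: p | q),
        _tt("nand", 2, lambda p, q: 1 - (p & q)),
        _tt("nor", 2, lambda p, q: 1 - (p | q)),
        _tt("xor", 2, lambda p, q: p ^ q),
        _tt("xnor", 2, lambda p, q: 1 - (p ^ q)),
        _tt("implies", 2, lambda p, q: (1 - p) | q),
        _tt("does_not_imply", 2, lambda p, q: p & (1 - q)),
    )
}

BUILTIN_GATE_NAMES: tuple[str, ...] = tuple(sorted(_BUILTINS))


def builtin_gate(name: str) -> Gate:
    """Return a standard named gate.

    ``does_not_imply(p, q)`` is ``p AND NOT q``: the first input is the
    activator arm, the second the repressor arm.
    """
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown gate {name!r}; valid names: {', '.join(BUILTIN_GATE_NAMES)}"
        ) from None


def eval_gate(g: Gate, inputs: Sequence[int]) -> int:
    """Evaluate a gate on an ordered bit tuple (table lookup)."""
    if len(inputs) != g.arity:
        raise ValueError(
            f"gate {g.name!r} has arity {g.arity}, got {len(inputs)} inputs"
        )
    idx = 0
    for b in inputs:
        if b not in (0, 1):
            raise ValueError(f"gate inputs must be bits, got {b!r}")
        idx = (idx << 1) | b
    return g.table[idx]


def gate_from_table(name: str, arity: int, table: Iterable[int]) -> Gate:
    """Build a gate from an explicit truth table in lexicographic order."""
    return Gate(name=name, arity=arity, table=tuple(int(b) for b in table))


def gate_to_table(g: Gate) -> list[int]:
    """Flat truth table (lexicographic input order) as a list of bits."""
    return list(g.table)


def classify_coherence(signal_mode: str, tf_mode: str) -> str:
    """Classify a simple regulation as coherent or incoherent.

    The signal acting on the regulator and the regulator acting on the
    target each have a sign (activator or repressor).  When the two
    signs agree the regulation is *coherent*; when they differ it is
    *incoherent*.
    """
    for mode in (signal_mode, tf_mode):
        if mode not in ("activator", "repressor"):
            raise ValueError(f"mode must be 'activator' or 'repressor', got {mode!r}")
    return "coherent" if signal_mode == tf_mode else "incoherent"
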