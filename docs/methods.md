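# Methods

## Logical model

A `GeneNetwork` is a Boolean model of a transcription network.  Each
gene carries an expression bit; each extracellular signal carries a
presence bit.  A gene may be `always_on` (constitutively expressed; its
bit is clamped to 1 and it needs no junction) or `lock_in`
(irreversibly activated, modeling strong positive autoregulation whose
production outruns degradation: once the bit is 1 the junction is
ignored).  A gene node may stand for `multiplicity` k identical genes
sharing regulation; expansion into explicit copies is a separate,
explicit operation.

**Activity.** A protein's regulatory activity is its gene's expression
bit gated by the bound signal: activator binding gives
`expr AND signal`, repressor binding `expr AND NOT signal`, no binding
passes the expression through.  Activity therefore never exceeds
expression.  At most one signal binds a gene; circuits where several
signals jointly control a promoter are expressed by feeding signal
literals directly into the junction (the dense-overlapping-regulon
pattern), which keeps the binding relation unambiguous.

**Junctions.** Every non-clamped gene has exactly one junction: an
ordered list of inputs (gene activities or raw signal literals, each
optionally negated) combined by a Boolean gate.  Gate truth tables are
stored as flat bit tuples in lexicographic input order, so serialized
gates are bit-exact and order is meaningful: `does_not_imply(p, q)` =
p ∧ ¬q has the activator arm first, matching the incoherent type-1 FFL
where X activates Z and Y represses it.  A junction whose inputs are
all inactive evaluates its gate on zeros; a single negated-input
junction therefore outputs 1 when its repressor is absent, which is
what lets a repressor–repressor (coherent) simple regulation transmit
the signal by double negation.

## Execution semantics

Logical models are inherently asynchronous — a transition may fire
whenever its conditions hold — so the engine offers three scheduling
policies.  `synchronous_cascade` (the reference semantics) updates all
genes simultaneously from the current state; each macro-step advances
every cascade stage by one level, which is exactly what exposes the
transient states: the incoherent FFL's one-step pulse, the coherent
FFL's one-step delay.  `async_deterministic` updates only the
lexicographically first enabled gene per step; `async_random` picks one
enabled gene uniformly with an explicit seed held in the policy (no
global random state).  On the feedback-free motif networks all three
policies converge to the same fixed point (checked exhaustively over
signal valuations in the test suite); the transient sequences differ,
and all transient-state claims refer to the synchronous semantics.

**Traces.** `run_to_completion` records the pre-stimulus state, then
the state after the signal event is applied (distinct whenever any
signal bit changed — signal bits are part of the global state), then
every synchronous successor until a fixed point, a revisited state
(cycle; possible only in hand-authored cyclic networks, which the
engine tolerates even though the statechart builder rejects them) or
the step limit.  Under this convention the interlocked FFL network
with all four signals switched on simultaneously visits exactly six
distinct global states, the transient sequence labelled I–VI in the
README.  Time is abstract: a macro-step has no units.

**Pulse and delay.** A pulse is a bit sequence of the exact shape
`0…0 1…1 0…0` (non-empty on-run followed by an off-run); its
description is the pair of trace indices where the gene turns on and
back off.  An activation delay is the difference of first-on indices
of two genes; either quantity is `None` when undefined.

## Statechart construction

The statechart of a network is built structurally, not by state
enumeration:

* the always-on genes form the root superstate (label `X=1`, or
  `X1X2X3=111` when several are clamped);
* each regulated gene contributes a block of two substates, expression
  0 and 1, named I and II in diagram order (off first); the signal
  valuation selects which substate is entered first;
* the block nests inside the *on* substate of the gene's deepest direct
  regulator (depth = longest regulator chain), so cascades recurse:
  the Z-block of an FFL sits inside `Y=1`;
* blocks sharing a context are mutually independent by construction
  (a dependent gene would nest deeper), and two or more of them become
  orthogonal regions of one parallel node — the SIM and DOR patterns;
* transitions connect the two substates of a block, triggered by
  signal change and guarded by the junction condition; a locked-in
  gene has no off-transition.  Gene-state changes propagate through
  nesting rather than explicit inter-region events.

Node count is linear in the number of (collapsed) gene nodes: 2 per
regulated gene plus the root and one parallel wrapper per concurrent
group.  Regulatory cycles other than annotated self-loops (feedback)
are rejected with an explicit error; feedback motifs are outside the
scope of this model.  History states, entry/exit actions and timed
triggers are deliberately not implemented — the gene-network semantics
does not use them.

## Flat view and oracle

`enumerate_flat_diagram` materializes the classical state diagram: all
2ⁿ expression vectors over the free (non-clamped) genes of the expanded
network, with one synchronous successor per (state, signal valuation).
Valuations with the same successor are merged into cubes by repeated
single-bit joins, the merged positions rendered as the don't-care mark
`X`; merging compresses labels but provably never changes the relation
(the test suite re-expands every cube).  State-space sizes are computed
in exact integer arithmetic (2¹¹⁷ is never a float); rounding to three
significant figures happens only in the presentation string.  A guard
(default 20 free genes, CLI `--max-genes`) refuses enumeration beyond
brute-force reach, quoting the exact size.

`oracle_check` is the equivalence oracle: it replays an execution trace
and verifies that every post-event step is a transition of the
exhaustively enumerated diagram and that fixed points map to
themselves.  Because the flat relation is built from synchronous
successors, the oracle applies to synchronous traces; asynchronous
policies are validated separately by fixed-point agreement.  When a
junction references a grouped (multiplicity > 1) gene, expansion
resolves the reference to copy `_1`; the copies are behaviorally
identical, so any one represents the group (no network in the motif
library exercises this case).

## Continuous model

Simple regulation in physical units is modeled as two Hill stages and
first-order turnover:

* stage 1: active regulator X\* as a function of signal S, with
  maximal level `x_star_max`, half-effect constant `K1` and Hill
  coefficient `l` (activating: x\*·sˡ/(K1ˡ+sˡ); repressing:
  x\*·K1ˡ/(K1ˡ+sˡ));
* stage 2: production rate f as a function of X\*, with maximal rate
  `F_max`, constant `K2`, coefficient `m`, again activating or
  repressing;
* dynamics: dy/dt = f(S(t)) − d·y, with constant combined
  degradation/dilution rate d (> 0).  d is held constant; a
  time-varying rate would be a drop-in extension of the model object
  but no functional form is part of this model.

Signals are piecewise-constant, which makes the equation linear with a
constant forcing term per segment and hence exactly solvable as
exponential relaxation toward f/d — the closed form used as the
integrator's independent check.  The integrator is classical fixed-step
RK4 with the step capped at 0.01/d and sub-segmented at every signal
breakpoint; for this linear equation that yields relative error around
10⁻¹⁰, comfortably inside the 10⁻⁶ contract.  No canonical parameter
values exist for the abstract motif, so the defaults (all scales 1,
l = m = 2, K2 = 0.5) are nondimensional fixtures, not biological
claims.  Thresholding the steady state at half the maximal level,
F_max/(2d), reproduces the logical model's coherent/incoherent
input–output map for all four sign combinations.

## Synthetic fixtures

`random_motif_composition(n_motifs, seed)` chains independently sampled
small motifs: the output gene of each motif becomes an additional
required regulator of the next motif's first regulated gene (its
junction gate is AND-extended by one input).  It emulates the way real
networks compose motifs by sharing regulators; it does not emulate
feedback, multi-signal bindings or realistic degree distributions, so
passing the oracle sweep demonstrates correctness of the execution
semantics on feedback-free compositions, not inference on biological
data.  Sizes are capped (1–3 targets per SIM, two-input DOR junctions)
so that a three-motif composition stays within at most 12 free genes —
inside brute-force reach of the flat-diagram oracle; the acceptance
sweep runs 100 seeded compositions.

## Numerical and design choices

* Bits are 0/1 integers in all serialized artifacts, never host
  booleans; gene and signal ordering everywhere follows declaration
  order, never hash order, so all writers are byte-deterministic.
* Motif builders settle initial expression bits to the fixed point
  under all-zero signals, so every fixture starts from a quiescent,
  self-consistent pre-stimulus state (e.g. the incoherent
  repressor–activator regulation starts with Y = 1).
* The interlocked network's X2 junction takes `and` over the activities
  of X1 and Y1: the gate is given, and the input pair is the one
  cascaded-FFL wiring that makes X2 and Z3 delayed coherent-FFL
  targets; this inference is the package's design choice.
* JSON is the single authoring format (strict: unknown keys rejected,
  ids case-sensitive); DOT, GraphML and TSV are export-only.
* The flat-diagram transition semantics deliberately uses the
  synchronous successor so the statechart and flat views are comparable
  one-to-one.

## Limitations

Feedback loops, stochastic noise, multi-level (non-binary) expression,
quantitative promoter occupancy, parameter fitting and binarization of
microarray data are out of scope.  Statechart node counts for published
figures are not reproduced verbatim (figures may merge substates
visually); only structural and asymptotic properties are asserted.
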