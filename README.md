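# genecharts

Statechart modeling and logical simulation of gene regulatory network
motifs.

## The problem

Transcription networks are assembled from a small set of recurring
circuits — *network motifs*: simple regulation (X → Y gated by a signal),
autoregulation, the feed-forward loop (FFL), the single-input module
(SIM) and the dense overlapping regulon (DOR).  Qualitative (Boolean)
models capture their dynamics without physical units: gene expression
and signal presence are bits, and what matters is the *sequence* of
states, including transient ones — the pulse an incoherent FFL emits,
the delay a coherent FFL imposes.

Classical flat state diagrams represent those dynamics but scale
exponentially: a network with *n* unclamped genes has 2ⁿ global states,
and every signal combination contributes a transition out of every
state.  **Statecharts** — state diagrams extended with nested hierarchy,
orthogonal (concurrent) regions and recursive substructure — keep the
representation linear in gene count, because each gene contributes one
two-substate block nested in its regulator's context.

`genecharts` makes this executable.  It provides:

* a Boolean network model (`GeneNetwork`): genes, signals, and one
  promoter *junction* per regulated gene — an ordered list of
  regulatory inputs combined by a Boolean gate (`and`, `or`,
  `does_not_imply` = p ∧ ¬q, arbitrary truth tables);
* builders for the five motifs and for the interlocked FFL network that
  controls *Bacillus subtilis* differentiation (118 genes, 112 of them
  identical Ic1-FFL targets collapsed into one node of multiplicity 112);
* a statechart builder (hierarchy from cascades, orthogonal regions
  from independent co-regulated genes) with DOT/GraphML export;
* an execution engine with synchronous-cascade and asynchronous
  (deterministic or seeded-random) semantics, fixed-point/cycle
  detection, and pulse/delay trace analysis;
* a flattener that expands multiplicities, computes exact state-space
  sizes (big integers, 3-significant-figure rendering) and enumerates
  the full flat transition relation for small networks — the brute-force
  oracle against which statechart execution is verified;
* the continuous-domain model of simple regulation: two Hill stages
  (signal → active regulator X\*, X\* → production rate f) and the
  linear turnover ODE dy/dt = f(S_x(t)) − d·y, with a closed-form
  piecewise-exponential cross-check.

In the logical model, a gene's protein *activity* is its expression bit
gated by its bound signal (activator: expr ∧ S; repressor: expr ∧ ¬S);
the next expression bit of a regulated gene is its junction gate
evaluated on the activities (or raw signal literals) it reads.  Signal
and transcription factor acting with the same sign give *coherent*
simple regulation, with opposite signs *incoherent*.

## Worked example

```python
from genecharts import (build_interlocked_ffl_network, expand_multiplicities,
                        state_space_size, run_to_completion, detect_pulse)

net = build_interlocked_ffl_network()          # X1,Y1,Z1(×112),X2,Y2,Z2,Z3
n_free, size, rendering = state_space_size(net)
print(len(expand_multiplicities(net).genes))   # 118
print(f"2^{n_free} = {rendering}")             # 2^117 = 1.66×10^35

trace = run_to_completion(net, event={"S_X1": 1, "S_Y1": 1, "S_X2": 1, "S_Y2": 1})
print(len(trace.states), trace.terminal)       # 6 fixed_point
print(detect_pulse(trace, "Z1", net))          # (2, 3)
print(detect_pulse(trace, "Z2", net))          # (4, 5)
```

The six states are the transient sequence when all four signals turn on
simultaneously (gene bits in declaration order X1 Y1 Z1 X2 Y2 Z2 Z3):

```
state   I: 1 0 0 0 0 0 0    pre-stimulus
state  II: 1 0 0 0 0 0 0    signals applied
state III: 1 1 1 0 0 0 0    Y1 and Z1 rise
state  IV: 1 1 0 1 0 0 0    Z1 pulse ends, X2 rises (delayed)
state   V: 1 1 0 1 1 1 0    Y2 and Z2 rise
state  VI: 1 1 0 1 1 0 1    Z2 pulse ends, Z3 rises (delayed)
```

Z1 and Z2 (incoherent FFL targets) pulse for one macro-step; X2 and Z3
(coherent FFL targets) come on with a delay.  The statechart for this
network has 15 nodes; its flat state diagram would need
2¹¹⁷ ≈ 1.66×10³⁵ states (X1 is clamped on, so 117 free genes).

The same is scriptable from the shell:

```
genecharts build --motif interlocked_ffl -o net.json
genecharts simulate net.json --signals S_X1=1,S_Y1=1,S_X2=1,S_Y2=1 -o trace.tsv
genecharts chart net.json -o chart.dot
genecharts flatten net.json -o flat.dot     # refuses: 1.66×10^35 states
genecharts ode --signal 0=0,2=5.0 --t-end 6 -o traj.tsv
```

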