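# rigflow

An actor-based dataflow engine for running behavioural-neuroscience
experiments as pipelines of communicating processes — headless, scriptable,
and built so that every data packet an experiment saves can be traced back
to the device event that produced it.

## Who this is for

Experimentalists who wire cameras, DAQ boards, task logic and game engines
into one real-time pipeline and later need *exact* answers to questions
like "which frame of the saved video corresponds to which trigger pulse?"
— and tool builders who want a small, testable engine with the same
semantics to develop task nodes against, entirely on simulated rigs.

## The model

An experiment is a **graph**: nodes joined by directed links from named
output ports to named input ports. Nodes come in three kinds — **sources**
(only emit), **transforms** (receive and emit) and **sinks** (only
receive). Many-to-many fan patterns are allowed, and cycles are legal and
useful: a trial *generator* and trial *controller* feeding each other form
the canonical 2-cycle of a closed-loop task. Each node's behaviour is three
user hooks: `initialise`, `work` (an infinite loop for sources, a callback
for transforms/sinks), `end_of_life`.

At run time a graph of *N* nodes is exactly **2N + 4 OS processes**: a
director, three forwarder brokers (proof-of-life, parameters, data), and a
com/worker actor pair per node. Two rules give the engine its character:

* **No buffering, at most once.** While a node's callback is running, its
  com actor discards every arriving packet and counts it as dropped. On
  every link, `emitted = delivered + dropped` — always.
* **Everything is logged for reconciliation.** Each com actor logs, for
  every packet it delivers, the upstream packet id and the gapless local id
  it assigns (the *com log*); workers can record one provenance row per
  pass (the *substate table*). Composing these relations across a chain of
  nodes yields a one-to-one map from saved indices back to origin-device
  indices, with the drop count falling out as `origin − terminal`.

Cross-device alignment uses a shared hardware clockline: a base TTL train
(e.g. 120 Hz) triggers camera A frame-for-pulse, while a divider emits one
pulse per *k* base pulses (k = 4 → 30 Hz) to trigger camera B. Divided
pulse *j* is attributed to base pulse *k·j*, which pins every B frame to a
base pulse and hence, through chain A's correspondence table, to an A
frame. Parameters flagged updatable can be changed while the graph runs
(the worker sees the new value at its next pass, never mid-pass); a
probabilistic reversal-learning task (2 blocks × 4 stimulus types with a
reward-contingency matrix) ships as a worked closed-loop example.

## Worked example: reconciling a lossy dual-camera rig

Simulate 60 s of a two-camera rig (120 Hz base train, ÷4 divider, one
lossy relay stage per chain), then align the two saved videos:

```python
from rigflow.fixtures import RigSimConfig, simulate_rig
simulate_rig(RigSimConfig(base_rate_hz=120.0, division_factor=4, duration_s=60.0,
                          chain_a_drop_p=(0.0005,), chain_b_drop_p=(0.001,), seed=7),
             out_dir="rig")
```

```sh
rigflow align --chain-a-substate rig/chain_a.substate.csv \
              --chain-a-comlog  rig/chain_a.stage0.comlog.csv \
              --chain-b-substate rig/chain_b.substate.csv \
              --chain-b-comlog  rig/chain_b.stage0.comlog.csv \
              --pulses rig/pulses.csv -k 4 --out aligned
```

prints

```
chain a: origin 7200 -> terminal 7194, dropped 6
chain b: origin 1800 -> terminal 1798, dropped 2
frame map: 1798 B frames, 1 unmatched
```

Read: camera A was triggered 7200 times (120 Hz × 60 s) but the saved video
holds 7194 frames — the com logs account for all 6 losses. Camera B saw
1800 triggers (30 Hz × 60 s) and saved 1798 frames. Every saved B frame is
mapped to its partner A frame (`aligned/b_to_a.framemap.csv`: B frame *j*
↔ A frame *4j* when lossless); exactly one B frame's partner was dropped
from chain A, and it is kept in the table flagged unmatched rather than
silently removed.

Other entry points: `rigflow validate <graph.json>` checks a pipeline
definition, `rigflow run --graph g.json --duration 10 --seed 1` executes
one (writing the termination report, per-link counters, com logs and
substate tables to a timestamped directory), and
`rigflow scaffold transform MyFilter` emits a worker skeleton.

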