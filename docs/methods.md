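# Methods

## The execution model

A pipeline graph is executed as an actor system in which state is private
to each process and all influence travels as messages. `start_graph`
spawns a **director** process; the director spawns the three **forwarder**
brokers (proof-of-life, parameters, data) and then, for each node *in
authoring order*, a **com** actor and a **worker** actor — 2N + 4
processes for N nodes. Start order is deliberately *not* a topological
sort: cycles are first-class (closed-loop tasks are cyclic by design), so
no dependency order exists to exploit. Data flow begins only after every
worker has run its `initialise` hook and reported proof of life; any
initialisation failure aborts the whole start, and every already-spawned
process is reaped before the caller sees the error.

Channels are OS pipes; the three brokers preserve the fan-out (data,
publish–subscribe by link), routed/broadcast (parameters) and many-to-one
(proof-of-life) topologies. Data frames cross each hop in a
self-describing binary framing (type tag, dtype, shape, raw buffer for
tensors; UTF-8 JSON for records) that round-trips integer tensors
bit-exactly; the framing is decoded at the receiving com, so every
delivered packet exercises the wire contract. A malformed frame is dropped
and logged, never fatal to the relay.

## Delivery semantics and drop accounting

The engine has no queues by design: a packet arriving at a node whose
callback is running is discarded immediately. The busy window is half-open
— `[callback start, callback return)` — so a packet arriving in the same
instant the callback returns is delivered. Each com assigns delivered
packets gapless local ids starting at 0 and logs
`(upstream node, upstream id, local id, timestamp)`; emitting workers
assign their own packet ids starting at 0. Emission is counted per
outgoing link at the emitting com; delivery and drops are counted per link
at the receiving com. During shutdown the director first stops workers,
then flushes the data fabric (a marker that provably trails every
in-flight frame through the FIFO broker) before coms finalise their
counters — this is what makes `emitted = delivered + dropped` exact even
when a run is stopped mid-stream. Orphan accounting is belt-and-braces:
the director joins (escalating to SIGTERM/SIGKILL) and reports survivors;
the caller re-probes every pid after the director exits.

Timestamps are integer nanoseconds on the monotonic clock of the com actor
(the worker's clock would date relays by callback completion instead of
arrival, which is the wrong axis for drop forensics).

## Parameters, heartbeat, lifecycle

Parameter updates travel caller → director → parameter forwarder → worker.
The director validates against the graph (unknown node/parameter → error
acknowledgement; `updatable: false` → refusal) before forwarding. Workers
drain their parameter pipe only *between* work passes, so a pass never
observes a half-applied update. The director broadcasts a heartbeat every
1 s (default); a worker that misses 5 consecutive beats runs its
`end_of_life` and exits — the failsafe against a vanished director. Both
numbers are configuration, not protocol: no principled value exists, so
they are chosen human-scale (seconds to notice, not minutes to leak
hardware locks) and tests shorten them. A worker whose loop body raises is
*contained*: the fault is logged, the process stays alive (keeping the
process census intact) but idle until stop; a callback exception counts
the event as delivered-then-failed and the worker keeps serving.

## Provenance reconciliation

`compose_chain` treats each com log as a binary relation between
consecutive stages' ids and composes them relationally (pandas merges on
sorted keys), after validating strict monotonicity of upstream ids,
gapless local ids, and the subset property between stages. The result maps
terminal (saved) indices to origin-device indices for every packet that
survived all stages; both columns are strictly increasing by construction,
the drop count is `origin_total − terminal_total`, and per-stage losses
telescope to the same number. A brute-force exhaustive join serves as the
independent oracle in tests, never as the implementation.

Cross-chain alignment assumes pure pulse counting on a shared clockline:
no clock-drift estimation, no sub-frame interpolation. The divided train's
pulse *j* is attributed to base pulse *k·j* — the **group-onset
convention**. The choice of onset over offset is a genuine open point (a
hardware divider could trigger on the k-th pulse of a group instead); it
is fixed here, documented, and isolated in `divided_pulse_origin` so a rig
with offset semantics changes one function. All ids are 0-based,
including video frame indices. B frames whose A partner was dropped stay
in the output with a null partner: the audit trail never loses rows.

## The task nodes

The reversal-learning generator draws the stimulation type uniformly over
the four types (the stimulus schedule is configurable; uniform is the
neutral default) and reward availability as a Bernoulli draw from the
2 × 4 block/stimulus contingency matrix (default 0.9/0.1 cells — strongly
asymmetric, as a reversal task needs to be learnable). Block lengths are
drawn uniformly from a configured range (default 20–30 trials, a realistic
session scale; tests use 5–10 to see many reversals quickly) and the two
blocks strictly alternate. Correct licks are tallied per port; by default
the tallies drive nothing, because no recoverable rule links them to block
transitions — a performance-switching rule (advance after M correct in
the last W trials) is provided as a clearly separate, off-by-default
extension. The controller models the trial phases (odour → pre-response
delay → response window → reward window) on an internal simulated clock,
so trials cost microseconds, not seconds, in a run; reward requires
availability and, when `reward_only_after_lick` is set, a correct-port
lick inside the response window. Serial-port descriptors (COM port, baud
rate) are accepted for interface compatibility and ignored with a warning
— there is no hardware I/O anywhere in the package.

The stimulus→port map defaults to `(0, 0, 1, 1)` (two lick ports, two
stimulus types each), configurable per rig.

## What the synthetic rig does and does not emulate

`simulate_rig` generates the full observable file set of a dual-camera
session — substate tables, com logs, the common recorder's pulse record —
plus a ground-truth event table kept in a separately named file
(`*.synthetic.csv`) used only as a test oracle. It emulates: exact
pulse-count relationships between the base and divided trains,
per-stage Bernoulli frame drops, and integer-nanosecond event times (a
fixed 50 µs relay latency per stage; latency realism is irrelevant to
count-based alignment). It does **not** emulate clock drift between
devices, camera exposure jitter, partial frames, or drops at the trigger
itself (the camera is assumed to answer every pulse; losses happen in the
relay chain). Passing tests therefore demonstrate the reconciliation
arithmetic and file contracts, not robustness to analogue timing noise —
which pulse-count alignment is insensitive to by construction, provided no
pulse is missed by the recorder.

Determinism is load-bearing: all fixture randomness flows from
`default_rng([seed, stage offset])` so toggling one stage never perturbs
another, and event generation is integer-only, making same-seed outputs
byte-identical across runs and platforms.

## Numerical and interface choices

* Graph files are JSON with `schema_version: "1"`; unknown keys are
  rejected outright so a run definition can never silently change meaning.
* Display names follow `base##index`; indices auto-assign at parse.
* Duplicate identical links are forbidden (their semantics would be
  ambiguous under per-link counters).
* `placement` other than `local` parses but is refused at start with a
  clear "remote execution not implemented" error, keeping graph files
  forward-compatible with multi-machine rigs.
* `cpu_pin` is honoured best-effort via the host scheduler affinity call
  and degrades to a logged no-op where unsupported.
* Problem sizes in tests are chosen for signal, not ceremony: statistical
  checks use 10⁴ trials (binomial 99% intervals), reconciliation oracles
  go up to 10⁵ packets, and live-engine checks use graphs of up to 5–8
  nodes over ~1 s runs, which is ample to exercise every lifecycle path.

## Known limitations

* The transport is single-host OS pipes; a slow com can in principle
  exert backpressure on the broker if a pipe fills (payloads in the
  tested regimes never approach this).
* Exact drop *counts* in a live run are timing-dependent by nature; only
  the conservation and ordering invariants are guaranteed, which is
  precisely why the provenance layer exists.
* `external_process` nodes manage one child over a line-oriented local
  TCP protocol; binary-safe payloads to children are out of scope.
* No GUI: graphs are authored as files and controlled via the CLI/API.
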