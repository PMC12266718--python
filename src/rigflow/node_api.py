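"""The contract every node worker implements.

A worker definition registers three hooks:

``initialise(ctx) -> bool``
    Run once before any data flows.  Returning falsy (or raising) aborts
    the whole graph start.
``work``
    For a **source**: ``work(ctx) -> payload list | None``, called in an
    infinite loop; the body paces itself against ``ctx.clock`` and returns
    ``None`` for an idle pass (nothing emitted).
    For a **transform**: ``work(ctx, event) -> payload list`` — one item per
    declared output, first output first.
    For a **sink**: ``work(ctx, event) -> None``.
``end_of_life(ctx)``
    Run exactly once at graceful shutdown (or on heartbeat loss).

A payload list holds one item per declared output port, in port order.
Items are numeric tensors (numpy arrays) or string-keyed records (dicts).

Hooks are registered explicitly on a :class:`WorkerDefinition` rather than
discovered by name; a worker module exposes a factory
``make_worker(params: dict) -> WorkerDefinition`` referenced from the graph
file as ``"package.module:make_worker"``.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional

import pandas as pd

from .clock import MonotonicClock

RESERVED_SUBSTATE_FIELDS = ("packet_index", "timestamp_ns")


class NodeFault(RuntimeError):
    """A worker violated its contract (arity, typing, misuse of the API)."""


class SubstateError(RuntimeError):
    """Misuse of the substate recorder within a work pass."""


@dataclass
class InputEvent:
    """One delivered packet item, as seen by a callback worker."""

    input_port: str
    item: Any
    upstream_node: str
    upstream_packet_id: int
    local_packet_id: int
    timestamp_ns: int = 0


@dataclass
class WorkerDefinition:
    work: Callable
    initialise: Optional[Callable] = None
    end_of_life: Optional[Callable] = None


class WorkerContext:
    """Per-worker runtime view: parameters, clock, substate recorder.

    ``parameters`` is a live mapping; the engine applies acknowledged
    updates only *between* work passes, so a parameter never changes value
    mid-pass.
    """

    def __init__(
        self,
        node_name: str,
        node_type: str,
        output_count: int,
        parameters: Optional[Dict[str, Any]] = None,
        clock=None,
        run_seed: int = 0,
    ) -> None:
        self.node_name = node_name
        self.node_type = node_type
        self.output_count = output_count
        self.parameters: Dict[str, Any] = dict(parameters or {})
        self.clock = clock if clock is not None else MonotonicClock()
        self.run_seed = run_seed
        self.should_stop = False
        self.state: Dict[str, Any] = {}  # scratch space for worker hooks
        self._pass_index = 0  # current packet index (source pass / delivered local id)
        self._substate_rows: List[dict] = []
        self._substate_columns: List[str] = []
        self._recorded_this_pass = False

    # -- substate ----------------------------------------------------------

    def record_substate(self, fields: Dict[str, Any]) -> None:
        """Append one provenance row for the current work pass.

        The row automatically carries the current packet index and a clock
        timestamp; ``fields`` adds user columns (a device frame id, a GPIO
        pulse id, ...).  At most one row per pass; the reserved column names
        cannot be overridden.
        """
        if self._recorded_this_pass:
            raise SubstateError("record_substate called twice in one work pass")
        for k in fields:
            if k in RESERVED_SUBSTATE_FIELDS:
                raise SubstateError(f"field name {k!r} is reserved")
            if not isinstance(k, str) or not k:
                raise SubstateError(f"field names must be non-empty strings, got {k!r}")
        row = {
            "packet_index": self._pass_index,
            "timestamp_ns": self.clock.now_ns(),
            **fields,
        }
        for k in row:
            if k not in self._substate_columns:
                self._substate_columns.append(k)
        self._substate_rows.append(row)
        self._recorded_this_pass = True

    def substate_frame(self) -> pd.DataFrame:
        """The accumulated substate table (columns in first-recorded order)."""
        if not self._substate_rows:
            return pd.DataFrame(columns=list(RESERVED_SUBSTATE_FIELDS))
        return pd.DataFrame(self._substate_rows, columns=self._substate_columns)

    def _begin_pass(self, packet_index: int) -> None:
        self._pass_index = packet_index
        self._recorded_this_pass = False


def resolve_worker_ref(ref: str) -> Callable[[dict], WorkerDefinition]:
    """Resolve ``"package.module:factory"`` to the factory callable."""
    if ":" not in ref:
        raise NodeFault(f"worker_ref {ref!r} is not of the form 'module:factory'")
    mod_name, _, attr = ref.partition(":")
    try:
        mod = importlib.import_module(mod_name)
    except ImportError as exc:
        raise NodeFault(f"worker_ref {ref!r}: cannot import module {mod_name!r}: {exc}") from exc
    try:
        factory = getattr(mod, attr)
    except AttributeError as exc:
        raise NodeFault(f"worker_ref {ref!r}: module has no attribute {attr!r}") from exc
    if not callable(factory):
        raise NodeFault(f"worker_ref {ref!r} does not resolve to a callable")
    return factory


def _check_payload(payload: Any, ctx: WorkerContext) -> List[Any]:
    if not isinstance(payload, list):
        raise NodeFault(
            f"{ctx.node_name}: work must return a payload list, got {type(payload).__name__}"
        )
    if len(payload) != ctx.output_count:
        raise NodeFault(
            f"{ctx.node_name}: payload has {len(payload)} items but the node "
            f"declares {ctx.output_count} outputs"
        )
    return payload


def run_source_loop(
    defn: WorkerDefinition,
    ctx: WorkerContext,
    emit: Callable[[int, List[Any]], None],
    before_pass: Optional[Callable[[], None]] = None,
) -> int:
    """Drive a source worker until ``ctx.should_stop``; returns packets emitted.

    ``emit(packet_id, payload)`` is called once per productive pass with a
    per-node id that starts at 0 and increments by 1.  ``before_pass`` is
    the engine's hook for applying parameter updates and stop signals
    between passes (never during one).
    """
    if ctx.node_type != "source":
        raise NodeFault(f"{ctx.node_name}: run_source_loop requires a source node")
    packet_id = 0
    while not ctx.should_stop:
        if before_pass is not None:
            before_pass()
        if ctx.should_stop:
            break
        ctx._begin_pass(packet_id)
        payload = defn.work(ctx)
        if payload is None:
            continue  # idle pass
        emit(packet_id, _check_payload(payload, ctx))
        packet_id += 1
    return packet_id


def run_callback_worker(
    defn: WorkerDefinition, ctx: WorkerContext, event: InputEvent
) -> Optional[List[Any]]:
    """Invoke a transform/sink callback for one delivered event.

    Transforms return a payload list (one item per output), or ``None`` to
    emit nothing for this event (e.g. a pulse divider between groups);
    sinks must return nothing.  The engine guarantees single-flight: the
    callback is never re-entered.
    """
    if ctx.node_type not in ("transform", "sink"):
        raise NodeFault(f"{ctx.node_name}: callback workers are transforms or sinks")
    ctx._begin_pass(event.local_packet_id)
    result = defn.work(ctx, event)
    if ctx.node_type == "sink":
        if result is not None:
            raise NodeFault(f"{ctx.node_name}: sink callback must return nothing")
        return None
    if result is None:
        return None
    return _check_payload(result, ctx)
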