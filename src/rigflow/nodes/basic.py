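"""Ready-made nodes: scripted sources, function wrappers, sinks, dividers.

Each public ``make_*``/``*_source``/``*_sink`` factory takes the node's
parameter dict and returns a :class:`~rigflow.node_api.WorkerDefinition`,
so graph files reference them directly, e.g.
``"worker_ref": "rigflow.nodes.basic:scripted_source"``.
"""

from __future__ import annotations

import csv
from typing import Any, Callable, List, Optional

import numpy as np

from ..node_api import NodeFault, WorkerDefinition


def scripted_source(params: dict) -> WorkerDefinition:
    """Emit a fixed schedule of values, one per pass, then idle.

    Parameters: ``schedule`` (list; ints/floats become 1-element tensors,
    dicts pass through as records), ``interval_s`` (pacing between
    emissions, default 0 — as fast as the engine allows).
    """
    schedule = list(params.get("schedule", []))
    interval = float(params.get("interval_s", 0.0))

    def work(ctx) -> Optional[List[Any]]:
        i = ctx.state.setdefault("i", 0)
        if i >= len(schedule):
            return None  # exhausted: idle forever
        ctx.state["i"] = i + 1
        if interval > 0:
            ctx.clock.sleep(interval)
        value = schedule[i]
        item = value if isinstance(value, dict) else np.asarray([value])
        return [item] * ctx.output_count

    return WorkerDefinition(work=work)


def pulse_source(params: dict) -> WorkerDefinition:
    """Emit ``n_pulses`` tensors paced at ``rate_hz`` against the worker clock."""
    rate = float(params.get("rate_hz", 120.0))
    n_pulses = params.get("n_pulses")
    if rate <= 0:
        raise NodeFault("rate_hz must be positive")

    def work(ctx) -> Optional[List[Any]]:
        i = ctx.state.setdefault("i", 0)
        if n_pulses is not None and i >= int(n_pulses):
            return None
        ctx.state["i"] = i + 1
        ctx.clock.sleep(1.0 / rate)
        return [np.asarray([i])] * ctx.output_count

    return WorkerDefinition(work=work)


def udf_node(fn: Callable[[Any], Any]) -> WorkerDefinition:
    """Wrap a pure one-input → one-output function as a transform worker.

    The escape hatch for running plain Python functions as nodes without
    writing the full hook API — handy for probing a node under development
    with scripted inputs.
    """

    def work(ctx, event) -> List[Any]:
        return [fn(event.item)]

    return WorkerDefinition(work=work)


def identity_transform(params: dict) -> WorkerDefinition:
    return udf_node(lambda item: item)


def double_transform(params: dict) -> WorkerDefinition:
    return udf_node(lambda item: np.asarray(item) * 2)


def sleepy_transform(params: dict) -> WorkerDefinition:
    """Identity transform whose callback blocks for ``sleep_s`` — a busy
    window generator for exercising the no-buffering drop rule."""
    import time

    sleep_s = float(params.get("sleep_s", 0.2))

    def work(ctx, event) -> List[Any]:
        time.sleep(sleep_s)
        return [event.item] * ctx.output_count

    return WorkerDefinition(work=work)


def sleepy_sink(params: dict) -> WorkerDefinition:
    import time

    sleep_s = float(params.get("sleep_s", 0.2))

    def work(ctx, event) -> None:
        time.sleep(sleep_s)

    return WorkerDefinition(work=work)


def null_sink(params: dict) -> WorkerDefinition:
    def work(ctx, event) -> None:
        ctx.record_substate({"upstream_packet_id": event.upstream_packet_id})

    return WorkerDefinition(work=work)


def table_sink(params: dict) -> WorkerDefinition:
    """Append every delivered record as one row of a CSV, written at stop.

    Parameters: ``path`` (output CSV).  The header comes from the first
    record's keys; a non-record payload is a contract fault.
    """
    path = params.get("path")

    def work(ctx, event) -> None:
        if not isinstance(event.item, dict):
            raise NodeFault(
                f"{ctx.node_name}: table sink needs record payloads, "
                f"got {type(event.item).__name__}"
            )
        ctx.state.setdefault("rows", []).append(dict(event.item))

    def end_of_life(ctx) -> None:
        rows = ctx.state.get("rows", [])
        target = ctx.parameters.get("path", path)
        if not target:
            return
        columns: List[str] = []
        for r in rows:
            for k in r:
                if k not in columns:
                    columns.append(k)
        with open(target, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns)
            writer.writeheader()
            writer.writerows(rows)

    return WorkerDefinition(work=work, end_of_life=end_of_life)


def pulse_divider(params: dict) -> WorkerDefinition:
    """Emit one output per ``division_factor`` delivered inputs.

    The divide-by-k clockline relay: fed a 120 Hz train with k = 4 it emits
    a 30 Hz train.  Emission happens on the first pulse of each group of k
    (group-onset convention), and the payload is the emission count so far.
    """
    k = int(params.get("division_factor", 4))
    if k < 1:
        raise NodeFault("division_factor must be >= 1")

    def work(ctx, event) -> Optional[List[Any]]:
        seen = ctx.state.setdefault("seen", 0)
        ctx.state["seen"] = seen + 1
        if seen % k == 0:
            count = ctx.state.setdefault("count", 0) + 1
            ctx.state["count"] = count
            ctx.record_substate({"input_pulse": seen})
            return [np.asarray([count])] * ctx.output_count
        return None

    return WorkerDefinition(work=work)
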