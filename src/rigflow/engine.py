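"""Actor-based runtime: director, three forwarders, com+worker per node.

A running graph of N nodes is exactly ``2N + 4`` OS processes:

* a **director** (spawned by :func:`start_graph`, child of the caller) that
  owns the run lifecycle,
* three **forwarder** brokers — proof-of-life, parameters, data — through
  which all inter-actor traffic is routed,
* per node, a **com** actor (relays packets, enforces at-most-once delivery,
  keeps the com log) and a **worker** actor (runs the node's three hooks).

Messages travel over OS pipes.  Data-link frames are encoded with the
self-describing wire framing (:mod:`rigflow.wire`) at the emitting com and
decoded at the receiving com, so every hop exercises the wire contract.

Delivery semantics: **no buffering, at most once**.  While a node's worker
callback is running, its com discards every arriving packet and counts it
as dropped; ``emitted = delivered + dropped`` holds per link in the final
report.
"""

from __future__ import annotations

import json
import multiprocessing as mp
import os
import re
import signal
import time
import traceback
from dataclasses import dataclass, field
from multiprocessing.connection import wait as conn_wait
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

from . import wire
from .clock import MonotonicClock
from .graph import Graph, GraphValidationError, NodeSpec, validate_graph
from .node_api import (
    InputEvent,
    NodeFault,
    WorkerContext,
    resolve_worker_ref,
    run_callback_worker,
    run_source_loop,
)
from .relay import DELIVER, ComRelay

_CTX = mp.get_context("fork") if "fork" in mp.get_all_start_methods() else mp.get_context()


class EngineError(RuntimeError):
    pass


class EngineStartError(EngineError):
    """The graph failed to start; every spawned process has been reaped."""


@dataclass
class EngineConfig:
    run_seed: int = 0
    log_dir: Optional[str] = None
    heartbeat_period_s: float = 1.0
    missed_heartbeats: int = 5
    pol_timeout_s: float = 30.0
    stop_grace_s: float = 5.0
    idle_sleep_s: float = 0.002  # source pacing floor for schedule-less passes


@dataclass
class TerminationReport:
    node_status: Dict[str, Dict[str, Any]]
    link_counters: Dict[str, Dict[str, int]]
    orphan_count: int
    run_seed: int
    com_errors: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def end_of_life_all(self) -> bool:
        return all(s.get("end_of_life") for s in self.node_status.values())

    def conservation_ok(self) -> bool:
        return all(
            c["emitted"] == c["delivered"] + c["dropped"] for c in self.link_counters.values()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_status": self.node_status,
                "link_counters": self.link_counters,
                "orphan_count": self.orphan_count,
                "run_seed": self.run_seed,
                "com_errors": self.com_errors,
            },
            indent=1,
        )


def _safe_name(display_name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", display_name)


class _EventLog:
    """Line-oriented engine log: one timestamped event per line."""

    def __init__(self, path: Optional[str], actor: str) -> None:
        self._fd = None
        self._actor = actor
        if path:
            self._fd = os.open(path, os.O_WRONLY | os.O_CREAT | os.O_APPEND, 0o644)

    def log(self, event: str, **kv: Any) -> None:
        if self._fd is None:
            return
        extras = " ".join(f"{k}={v}" for k, v in kv.items())
        line = f"{time.monotonic_ns()} {self._actor} {event} {extras}\n"
        os.write(self._fd, line.encode("utf-8", "replace"))

    def close(self) -> None:
        if self._fd is not None:
            os.close(self._fd)
            self._fd = None


# ---------------------------------------------------------------------------
# forwarders


def _forwarder_data(in_conns: List[Any], route: Dict[str, str], sub_send: Dict[str, Any]) -> None:
    """Data broker: routes ('data', link_id, frame) to the target node's com."""
    conns = list(in_conns)
    while conns:
        for conn in conn_wait(conns):
            try:
                msg = conn.recv()
            except (EOFError, OSError):
                conns.remove(conn)
                continue
            if msg[0] == "data":
                target = route.get(msg[1])
                if target is not None:
                    try:
                        sub_send[target].send(msg)
                    except (BrokenPipeError, OSError):
                        pass
            elif msg[0] == "flush_all":
                # everything already written by coms sits in our in-pipes;
                # drain it before the flush marker so no frame trails it
                for c in list(conns):
                    try:
                        while c.poll(0):
                            m = c.recv()
                            if m[0] == "data":
                                t = route.get(m[1])
                                if t is not None:
                                    sub_send[t].send(m)
                    except (EOFError, OSError):
                        conns.remove(c)
                for s in sub_send.values():
                    try:
                        s.send(("flush",))
                    except (BrokenPipeError, OSError):
                        pass
            elif msg[0] == "stop":
                return


def _forwarder_params(in_conn: Any, worker_send: Dict[str, Any]) -> None:
    """Parameter broker: director -> workers (routed or broadcast)."""
    while True:
        try:
            msg = in_conn.recv()
        except (EOFError, OSError):
            return
        if msg[0] == "param":
            _, node, name, value = msg
            conn = worker_send.get(node)
            if conn is not None:
                try:
                    conn.send(("param", name, value))
                except (BrokenPipeError, OSError):
                    pass
        elif msg[0] == "broadcast":
            for conn in worker_send.values():
                try:
                    conn.send(msg[1])
                except (BrokenPipeError, OSError):
                    pass
        elif msg[0] == "stop":
            return


def _forwarder_pol(in_conns: List[Any], out_conn: Any) -> None:
    """Proof-of-life broker: workers -> director (also carries end-of-life)."""
    conns = list(in_conns)
    while conns:
        for conn in conn_wait(conns):
            try:
                msg = conn.recv()
            except (EOFError, OSError):
                conns.remove(conn)
                continue
            if msg[0] == "stop":
                return
            try:
                out_conn.send(msg)
            except (BrokenPipeError, OSError):
                return


# ---------------------------------------------------------------------------
# com actor


def _com_main(
    node_name: str,
    sub_conn: Any,
    pub_conn: Any,
    worker_conn: Any,
    ctrl_conn: Any,
    incoming: Dict[str, Tuple[str, int, str]],  # link_id -> (from_node, output_idx, to_input)
    outgoing: List[str],  # link_ids fed by this node's emissions
    com_log_path: Optional[str],
    log_dir: Optional[str],
) -> None:
    relay = ComRelay(node_name=node_name)
    elog = _EventLog(os.path.join(log_dir, "engine.log") if log_dir else None, f"com:{node_name}")
    clock = MonotonicClock()
    flushed = False
    finalize_requested = False

    def publish(packet_id: int, payload: List[Any]) -> None:
        if not outgoing:
            return
        frame = wire.encode_packet(node_name, packet_id, clock.now_ns(), payload)
        relay.on_emit(outgoing)
        for lid in outgoing:
            try:
                pub_conn.send(("data", lid, frame))
            except (BrokenPipeError, OSError):
                pass

    def finalize() -> None:
        if com_log_path or log_dir:
            path = com_log_path or os.path.join(log_dir, f"{_safe_name(node_name)}.comlog.csv")
            with open(path, "w") as fh:
                fh.write("upstream_node,upstream_packet_id,local_packet_id,timestamp_ns\n")
                for r in relay.com_log:
                    fh.write(
                        f"{r.upstream_node},{r.upstream_packet_id},{r.local_packet_id},{r.timestamp_ns}\n"
                    )
        counters = {
            lid: {"emitted": c.emitted, "delivered": c.delivered, "dropped": c.dropped}
            for lid, c in relay.counters.items()
        }
        rows = [
            (r.upstream_node, r.upstream_packet_id, r.local_packet_id, r.timestamp_ns)
            for r in relay.com_log
        ]
        try:
            ctrl_conn.send(("final", node_name, counters, rows, list(relay.errors)))
        except (BrokenPipeError, OSError):
            pass
        elog.close()

    conns = [sub_conn, worker_conn, ctrl_conn]
    while True:
        for conn in conn_wait(conns):
            try:
                msg = conn.recv()
            except (EOFError, OSError):
                if conn is worker_conn:
                    relay.on_worker_stopped()
                    conns = [c for c in conns if c is not worker_conn]
                    continue
                return
            if conn is sub_conn:
                if msg[0] == "flush":
                    flushed = True
                    if finalize_requested:
                        finalize()
                        return
                    continue
                _, link_id, frame = msg
                if link_id not in incoming:
                    relay.on_malformed(link_id, "frame for a link this node does not receive")
                    elog.log("drop", link=link_id, reason="unknown-link")
                    continue
                try:
                    src_node, pkt_id, ts, items = wire.decode_packet(frame)
                    from_node, out_idx, in_port = incoming[link_id]
                    item = items[out_idx]
                except (wire.WireError, IndexError) as exc:
                    relay.on_malformed(link_id, str(exc))
                    elog.log("drop", link=link_id, reason="malformed")
                    continue
                decision, local_id = relay.on_packet(link_id, src_node, pkt_id, clock.now_ns())
                if decision == DELIVER:
                    try:
                        worker_conn.send(("event", in_port, item, src_node, pkt_id, local_id, ts))
                    except (BrokenPipeError, OSError):
                        relay.revert_delivery(link_id)
                        relay.on_worker_stopped()
                else:
                    elog.log("drop", link=link_id, upstream_id=pkt_id, reason="busy")
            elif conn is worker_conn:
                kind = msg[0]
                if kind == "emit":
                    publish(msg[1], msg[2])
                elif kind == "done":
                    relay.on_worker_done()
                    if msg[2] is not None:  # transform output
                        publish(msg[1], msg[2])
                elif kind == "worker_exiting":
                    relay.on_worker_stopped()
            else:  # ctrl_conn
                if msg[0] == "draining":
                    relay.on_worker_stopped()
                elif msg[0] == "finalize":
                    finalize_requested = True
                    if flushed or not incoming:
                        finalize()
                        return


# ---------------------------------------------------------------------------
# worker actor


def _worker_main(
    spec: NodeSpec,
    com_conn: Any,
    param_conn: Any,
    pol_conn: Any,
    config: EngineConfig,
) -> None:
    node = spec.display_name
    elog = _EventLog(
        os.path.join(config.log_dir, "engine.log") if config.log_dir else None, f"worker:{node}"
    )
    if spec.cpu_pin is not None:
        try:
            os.sched_setaffinity(0, {spec.cpu_pin})
            elog.log("cpu-pin", core=spec.cpu_pin)
        except (AttributeError, OSError, ValueError):
            elog.log("cpu-pin-unsupported", core=spec.cpu_pin)

    ctx = WorkerContext(
        node_name=node,
        node_type=spec.node_type,
        output_count=len(spec.outputs),
        parameters=spec.parameter_values(),
        run_seed=config.run_seed,
    )

    def fail_pol(err: str) -> None:
        try:
            pol_conn.send(("pol", node, False, err))
        except (BrokenPipeError, OSError):
            pass

    try:
        factory = resolve_worker_ref(spec.worker_ref)
        defn = factory(ctx.parameters)
    except Exception as exc:  # noqa: BLE001 - any user error aborts the start
        fail_pol(f"worker factory failed: {exc}")
        return
    try:
        if defn.initialise is not None and not defn.initialise(ctx):
            fail_pol("initialise returned a falsy success flag")
            return
    except Exception as exc:  # noqa: BLE001
        fail_pol(f"initialise raised: {exc}\n{traceback.format_exc()}")
        return
    pol_conn.send(("pol", node, True, ""))
    elog.log("proof-of-life")

    hb_deadline = config.heartbeat_period_s * config.missed_heartbeats
    last_hb = time.monotonic()
    stop_reason = "stopped"

    def apply_control() -> None:
        """Drain the parameter pipe between work passes; never during one."""
        nonlocal last_hb, stop_reason
        while param_conn.poll(0):
            try:
                msg = param_conn.recv()
            except (EOFError, OSError):
                ctx.should_stop = True
                stop_reason = "parameter channel lost"
                return
            if msg[0] == "param":
                ctx.parameters[msg[1]] = msg[2]
                elog.log("param-update", name=msg[1])
            elif msg[0] == "hb":
                last_hb = time.monotonic()
            elif msg[0] == "stop":
                ctx.should_stop = True
        if time.monotonic() - last_hb > hb_deadline:
            ctx.should_stop = True
            stop_reason = "heartbeat lost"
            elog.log("heartbeat-lost")

    faulted = False
    emit_count = 0
    try:
        if spec.node_type == "source":

            def emit(packet_id: int, payload: List[Any]) -> None:
                com_conn.send(("emit", packet_id, payload))

            def before_pass() -> None:
                apply_control()
                time.sleep(config.idle_sleep_s)

            try:
                run_source_loop(defn, ctx, emit, before_pass=before_pass)
            except Exception as exc:  # noqa: BLE001 - node fault: report, stay alive
                faulted = True
                elog.log("fault", error=repr(exc))
                while not ctx.should_stop:
                    apply_control()
                    time.sleep(0.01)
        else:
            while not ctx.should_stop:
                ready = conn_wait([com_conn, param_conn], timeout=0.1)
                apply_control()
                if ctx.should_stop:
                    break
                if com_conn not in ready:
                    continue
                try:
                    msg = com_conn.recv()
                except (EOFError, OSError):
                    break
                if msg[0] != "event":
                    continue
                _, in_port, item, up_node, up_id, local_id, ts = msg
                ev = InputEvent(
                    input_port=in_port,
                    item=item,
                    upstream_node=up_node,
                    upstream_packet_id=up_id,
                    local_packet_id=local_id,
                    timestamp_ns=ts,
                )
                try:
                    payload = run_callback_worker(defn, ctx, ev)
                except Exception as exc:  # noqa: BLE001 - delivered-then-failed
                    elog.log("fault", error=repr(exc))
                    com_conn.send(("done", None, None, False))
                    continue
                if spec.node_type == "transform" and payload is not None:
                    com_conn.send(("done", emit_count, payload, True))
                    emit_count += 1
                else:
                    com_conn.send(("done", None, None, True))
    finally:
        eol_ok = False
        try:
            if defn.end_of_life is not None:
                defn.end_of_life(ctx)
            eol_ok = True
        except Exception as exc:  # noqa: BLE001
            elog.log("eol-raised", error=repr(exc))
        if config.log_dir:
            frame = ctx.substate_frame()
            if len(frame):
                frame.to_csv(
                    os.path.join(config.log_dir, f"{_safe_name(node)}.substate.csv"), index=False
                )
        try:
            com_conn.send(("worker_exiting",))
        except (BrokenPipeError, OSError):
            pass
        try:
            pol_conn.send(("eol", node, eol_ok and not faulted, stop_reason))
        except (BrokenPipeError, OSError):
            pass
        elog.log("eol", ok=eol_ok, reason=stop_reason)
        elog.close()


# ---------------------------------------------------------------------------
# director


def _reap(procs: List[Any], grace: float) -> int:
    """Join, escalating to SIGTERM then SIGKILL; return count left alive."""
    deadline = time.monotonic() + grace
    for p in procs:
        p.join(max(0.0, deadline - time.monotonic()))
    for p in procs:
        if p.is_alive():
            p.terminate()
    for p in procs:
        p.join(1.0)
    for p in procs:
        if p.is_alive():
            p.kill()
            p.join(1.0)
    return sum(1 for p in procs if p.is_alive())


def _director_main(caller_conn: Any, graph: Graph, config: EngineConfig) -> None:
    signal.signal(signal.SIGINT, signal.SIG_IGN)  # caller owns interrupt handling
    elog = _EventLog(
        os.path.join(config.log_dir, "engine.log") if config.log_dir else None, "director"
    )
    order = [n.display_name for n in graph.nodes]
    by_name = {n.display_name: n for n in graph.nodes}

    # data-link routing tables
    incoming: Dict[str, Dict[str, Tuple[str, int, str]]] = {name: {} for name in order}
    outgoing: Dict[str, List[str]] = {name: [] for name in order}
    route: Dict[str, str] = {}
    for e in graph.edges:
        src = by_name[e.from_node]
        out_idx = [p.name for p in src.outputs].index(e.from_output)
        incoming[e.to_node][e.link_id] = (e.from_node, out_idx, e.to_input)
        outgoing[e.from_node].append(e.link_id)
        route[e.link_id] = e.to_node

    # channels (created before fork; children inherit their ends)
    data_in_recv: List[Any] = []
    com_pub_send: Dict[str, Any] = {}
    for name in order:
        r, s = _CTX.Pipe(duplex=False)
        data_in_recv.append(r)
        com_pub_send[name] = s
    dfwd_inject_r, dfwd_inject_s = _CTX.Pipe(duplex=False)
    data_in_recv.append(dfwd_inject_r)
    com_sub: Dict[str, Tuple[Any, Any]] = {name: _CTX.Pipe(duplex=False) for name in order}
    worker_param: Dict[str, Tuple[Any, Any]] = {name: _CTX.Pipe(duplex=False) for name in order}
    pfwd_in_r, pfwd_in_s = _CTX.Pipe(duplex=False)
    pol_in: List[Any] = []
    worker_pol_send: Dict[str, Any] = {}
    for name in order:
        r, s = _CTX.Pipe(duplex=False)
        pol_in.append(r)
        worker_pol_send[name] = s
    polfwd_inject_r, polfwd_inject_s = _CTX.Pipe(duplex=False)
    pol_in.append(polfwd_inject_r)
    pol_out_r, pol_out_s = _CTX.Pipe(duplex=False)
    com_worker: Dict[str, Tuple[Any, Any]] = {name: _CTX.Pipe(duplex=True) for name in order}
    com_ctrl: Dict[str, Any] = {}

    forwarders = [
        _CTX.Process(
            target=_forwarder_data,
            args=(data_in_recv, route, {n: com_sub[n][1] for n in order}),
            name="rigflow-fwd-data",
        ),
        _CTX.Process(
            target=_forwarder_params,
            args=(pfwd_in_r, {n: worker_param[n][1] for n in order}),
            name="rigflow-fwd-params",
        ),
        _CTX.Process(
            target=_forwarder_pol, args=(pol_in, pol_out_s), name="rigflow-fwd-pol"
        ),
    ]
    for p in forwarders:
        p.start()
        elog.log("spawn", actor=p.name, pid=p.pid)

    com_procs: Dict[str, Any] = {}
    worker_procs: Dict[str, Any] = {}
    all_procs: List[Any] = list(forwarders)
    for name in order:
        spec = by_name[name]
        d_ctrl, c_ctrl = _CTX.Pipe(duplex=True)
        com_ctrl[name] = d_ctrl
        com_end, worker_end = com_worker[name]
        cp = _CTX.Process(
            target=_com_main,
            args=(
                name,
                com_sub[name][0],
                com_pub_send[name],
                com_end,
                c_ctrl,
                incoming[name],
                outgoing[name],
                spec.com_log_path,
                config.log_dir,
            ),
            name=f"rigflow-com-{_safe_name(name)}",
        )
        wp = _CTX.Process(
            target=_worker_main,
            args=(spec, worker_end, worker_param[name][0], worker_pol_send[name], config),
            name=f"rigflow-worker-{_safe_name(name)}",
        )
        cp.start()
        wp.start()
        elog.log("spawn", actor=cp.name, pid=cp.pid)
        elog.log("spawn", actor=wp.name, pid=wp.pid)
        com_procs[name] = cp
        worker_procs[name] = wp
        all_procs.extend([cp, wp])

    # --- proof of life: every worker must report before data flows --------
    pending = set(order)
    deadline = time.monotonic() + config.pol_timeout_s
    failure: Optional[str] = None
    while pending and failure is None:
        remaining = deadline - time.monotonic()
        if remaining <= 0 or not pol_out_r.poll(remaining):
            failure = f"proof-of-life timeout; missing {sorted(pending)}"
            break
        msg = pol_out_r.recv()
        if msg[0] == "pol":
            _, node, ok, err = msg
            if ok:
                pending.discard(node)
                elog.log("proof-of-life", node=node)
            else:
                failure = f"{node} failed to initialise: {err}"
    if failure is not None:
        elog.log("start-failed", reason=failure.splitlines()[0])
        for p in all_procs:
            p.terminate()
        _reap(all_procs, 2.0)
        caller_conn.send(("start_failed", failure))
        elog.close()
        return

    # initial parameter push, then report started
    for name in order:
        for p in by_name[name].parameters:
            pfwd_in_s.send(("param", name, p.name, p.value))
    census = {
        "director": os.getpid(),
        "forwarders": {p.name: p.pid for p in forwarders},
        "nodes": {n: {"com": com_procs[n].pid, "worker": worker_procs[n].pid} for n in order},
    }
    caller_conn.send(("started", census))

    # --- run loop: heartbeats + caller control -----------------------------
    next_hb = time.monotonic()
    stopping = False
    while not stopping:
        now = time.monotonic()
        if now >= next_hb:
            pfwd_in_s.send(("broadcast", ("hb", now)))
            next_hb = now + config.heartbeat_period_s
        timeout = max(0.0, next_hb - time.monotonic())
        if not caller_conn.poll(timeout):
            continue
        try:
            msg = caller_conn.recv()
        except (EOFError, OSError):
            msg = ("stop",)  # caller vanished: shut down rather than orphan
        if msg[0] == "param":
            _, node, pname, value = msg
            spec = by_name.get(node)
            if spec is None:
                caller_conn.send(("param_ack", False, f"unknown node {node!r}"))
                continue
            param = spec.parameter(pname)
            if param is None:
                caller_conn.send(("param_ack", False, f"{node}: unknown parameter {pname!r}"))
                continue
            if not param.updatable:
                caller_conn.send(
                    ("param_ack", False, f"{node}.{pname} is not updatable; refused")
                )
                continue
            pfwd_in_s.send(("param", node, pname, value))
            elog.log("param-update", node=node, name=pname)
            caller_conn.send(("param_ack", True, "ok"))
        elif msg[0] == "stop":
            stopping = True

    # --- graceful shutdown -------------------------------------------------
    for name in order:
        com_ctrl[name].send(("draining",))
    pfwd_in_s.send(("broadcast", ("stop",)))

    eol_flags = {name: False for name in order}
    eol_pending = set(order)
    deadline = time.monotonic() + config.stop_grace_s
    while eol_pending:
        remaining = deadline - time.monotonic()
        if remaining <= 0 or not pol_out_r.poll(remaining):
            break
        msg = pol_out_r.recv()
        if msg[0] == "eol":
            _, node, ok, _reason = msg
            eol_flags[node] = bool(ok)
            eol_pending.discard(node)
            elog.log("eol", node=node, ok=ok)
    for node in eol_pending:  # unresponsive: forced kill, end_of_life never ran
        worker_procs[node].terminate()
        elog.log("forced-kill", node=node)
    _reap(list(worker_procs.values()), config.stop_grace_s)

    # all emissions have ceased; flush the data fabric, then finalize coms
    dfwd_inject_s.send(("flush_all",))
    link_counters: Dict[str, Dict[str, int]] = {}
    com_errors: Dict[str, List[str]] = {}
    for name in order:
        com_ctrl[name].send(("finalize",))
    for name in order:
        if com_ctrl[name].poll(config.stop_grace_s):
            msg = com_ctrl[name].recv()
            if msg[0] == "final":
                _, node, counters, _rows, errors = msg
                if errors:
                    com_errors[node] = errors
                for lid, c in counters.items():
                    agg = link_counters.setdefault(
                        lid, {"emitted": 0, "delivered": 0, "dropped": 0}
                    )
                    for k in agg:
                        agg[k] += c[k]
    _reap(list(com_procs.values()), 2.0)

    dfwd_inject_s.send(("stop",))
    pfwd_in_s.send(("stop",))
    polfwd_inject_s.send(("stop",))
    orphans = _reap(forwarders, 2.0)
    orphans += sum(1 for p in all_procs if p.is_alive())

    report = TerminationReport(
        node_status={
            name: {
                "worker_exit": worker_procs[name].exitcode,
                "com_exit": com_procs[name].exitcode,
                "end_of_life": eol_flags[name],
            }
            for name in order
        },
        link_counters=link_counters,
        orphan_count=orphans,
        run_seed=config.run_seed,
        com_errors=com_errors,
    )
    if config.log_dir:
        with open(os.path.join(config.log_dir, "counters.csv"), "w") as fh:
            fh.write("link_id,emitted,delivered,dropped\n")
            for lid in sorted(link_counters):
                c = link_counters[lid]
                fh.write(f"{lid},{c['emitted']},{c['delivered']},{c['dropped']}\n")
        with open(os.path.join(config.log_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    try:
        caller_conn.send(("report", report))
    except (BrokenPipeError, OSError):
        pass
    elog.log("stopped", orphans=orphans)
    elog.close()


# ---------------------------------------------------------------------------
# caller-side handle


class RunHandle:
    """Caller-side handle on a running graph."""

    def __init__(self, graph: Graph, config: EngineConfig, proc: Any, conn: Any, census: dict):
        self.graph = graph
        self.config = config
        self.run_seed = config.run_seed
        self._proc = proc
        self._conn = conn
        self.census = census
        self.running = True

    def pids(self) -> List[int]:
        pids = [self.census["director"]]
        pids.extend(self.census["forwarders"].values())
        for pair in self.census["nodes"].values():
            pids.extend(pair.values())
        return pids

    def process_census(self) -> int:
        """Live engine + node process count (2N + 4 while healthy)."""
        if not self.running:
            raise EngineError("graph is not running")
        alive = 0
        for pid in self.pids():
            try:
                os.kill(pid, 0)
                alive += 1
            except ProcessLookupError:
                pass
        return alive

    def update_parameter(self, node: str, param: str, value: Any) -> Tuple[bool, str]:
        """Push a live parameter update; returns (accepted, message).

        The worker observes the new value no earlier than its next work
        pass — never mid-pass.  Non-updatable parameters are refused.
        """
        if not self.running:
            raise EngineError("graph is not running")
        self._conn.send(("param", node, param, value))
        if not self._conn.poll(self.config.stop_grace_s + 5.0):
            raise EngineError("no acknowledgement from director")
        kind, ok, message = self._conn.recv()
        if kind != "param_ack":
            raise EngineError(f"unexpected reply {kind!r}")
        return ok, message

    def stop(self) -> TerminationReport:
        """Gracefully stop: every healthy worker's end_of_life runs exactly once."""
        if not self.running:
            raise EngineError("graph already stopped")
        self._conn.send(("stop",))
        timeout = 4 * self.config.stop_grace_s + 30.0
        if not self._conn.poll(timeout):
            self._proc.terminate()
            self._proc.join(5.0)
            self.running = False
            raise EngineError("director did not report back; terminated")
        kind, report = self._conn.recv()
        self._proc.join(10.0)
        if self._proc.is_alive():
            self._proc.kill()
            self._proc.join(2.0)
        self.running = False
        # belt and braces: caller-side orphan sweep
        stragglers = 0
        for pid in self.pids():
            try:
                os.kill(pid, 0)
            except ProcessLookupError:
                continue
            try:
                os.kill(pid, signal.SIGKILL)
                stragglers += 1
            except ProcessLookupError:
                pass
        report.orphan_count += stragglers
        return report


def start_graph(graph: Graph, config: Optional[EngineConfig] = None) -> RunHandle:
    """Start a validated graph as its 2N+4-process actor topology.

    Spawns the director (which spawns the three forwarders and, per node in
    authoring order, a com and a worker actor), waits for every worker's
    proof-of-life and the initial parameter push, then returns a handle.
    On any start failure every spawned process is reaped before raising.
    """
    config = config or EngineConfig()
    violations = validate_graph(graph)
    if violations:
        raise GraphValidationError("; ".join(str(v) for v in violations))
    for n in graph.nodes:
        if n.placement != "local":
            raise EngineStartError(
                f"{n.display_name}: remote execution not implemented "
                f"(placement {n.placement!r}); only 'local' is supported"
            )
        resolve_worker_ref(n.worker_ref)  # unresolvable refs fail before any spawn
    if config.log_dir:
        Path(config.log_dir).mkdir(parents=True, exist_ok=True)
    caller_conn, director_conn = _CTX.Pipe(duplex=True)
    proc = _CTX.Process(
        target=_director_main, args=(director_conn, graph, config), name="rigflow-director"
    )
    proc.start()
    timeout = config.pol_timeout_s + 30.0
    if not caller_conn.poll(timeout):
        proc.terminate()
        proc.join(5.0)
        raise EngineStartError("director did not report within the start timeout")
    msg = caller_conn.recv()
    if msg[0] == "start_failed":
        proc.join(10.0)
        if proc.is_alive():
            proc.kill()
            proc.join(2.0)
        raise EngineStartError(msg[1])
    return RunHandle(graph, config, proc, caller_conn, msg[1])


def stop_graph(handle: RunHandle) -> TerminationReport:
    return handle.stop()


def run_graph(
    graph: Graph, duration_s: float, config: Optional[EngineConfig] = None
) -> TerminationReport:
    """Start, run for ``duration_s`` wall seconds (or SIGINT), stop."""
    handle = start_graph(graph, config)
    try:
        time.sleep(duration_s)
    except KeyboardInterrupt:
        pass
    return handle.stop()
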