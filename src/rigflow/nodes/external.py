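"""Sink node that manages a child executable written in any language.

The worker's three hooks wrap the child's whole lifecycle, so the child
lives strictly within the worker:

* ``initialise`` starts the executable and completes a handshake — the
  child connects back on a local endpoint the worker announces, sends the
  line ``READY``, receives one JSON parameter record, and replies ``ACK``;
* ``work`` forwards each delivered string payload to the child over the
  same one-way channel, newline-terminated;
* ``end_of_life`` sends ``QUIT``, then terminates and reaps the child.

Handshake wire format (bit-exact): newline-terminated UTF-8 lines over a
TCP connection to ``127.0.0.1:<port>``, where ``<port>`` is passed to the
child as its first command-line argument.  Line 1 child→worker: ``READY``.
Line 2 worker→child: one JSON object (the node's parameters).  Line 3
child→worker: ``ACK``.  All further lines are worker→child payload.
"""

from __future__ import annotations

import json
import socket
import subprocess
import sys
from typing import List, Optional

import numpy as np

from ..node_api import NodeFault, WorkerDefinition

HANDSHAKE_READY = "READY"
HANDSHAKE_ACK = "ACK"


def _payload_text(item) -> str:
    if isinstance(item, str):
        return item
    if isinstance(item, dict):
        return json.dumps(item, separators=(",", ":"))
    if isinstance(item, np.ndarray):
        return json.dumps(np.asarray(item).tolist())
    return str(item)


def external_process_sink(params: dict) -> WorkerDefinition:
    """Sink managing a child executable (see module docstring for the protocol).

    Parameters: ``command`` (argv list; the endpoint port is appended),
    ``handshake_timeout_s`` (default 10), plus anything the child should
    receive in the handshake parameter record.
    """
    command: Optional[List[str]] = params.get("command")
    if not command:
        raise NodeFault("external process node requires a 'command' parameter")
    timeout = float(params.get("handshake_timeout_s", 10.0))

    def initialise(ctx) -> bool:
        server = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        server.bind(("127.0.0.1", 0))
        server.listen(1)
        server.settimeout(timeout)
        port = server.getsockname()[1]
        argv = [str(c) for c in command] + [str(port)]
        try:
            child = subprocess.Popen(argv, stdin=subprocess.DEVNULL)
        except OSError as exc:
            server.close()
            raise NodeFault(f"cannot launch child {argv[0]!r}: {exc}") from exc
        try:
            conn, _ = server.accept()
        except socket.timeout:
            child.terminate()
            child.wait(timeout=5.0)
            server.close()
            raise NodeFault(f"child {argv[0]!r} never connected back (handshake timeout)")
        server.close()
        conn.settimeout(timeout)
        fh = conn.makefile("rwb")
        line = fh.readline().decode("utf-8").strip()
        if line != HANDSHAKE_READY:
            child.terminate()
            child.wait(timeout=5.0)
            raise NodeFault(f"handshake failed: expected {HANDSHAKE_READY!r}, got {line!r}")
        record = {k: v for k, v in ctx.parameters.items() if k != "command"}
        fh.write((json.dumps(record) + "\n").encode("utf-8"))
        fh.flush()
        line = fh.readline().decode("utf-8").strip()
        if line != HANDSHAKE_ACK:
            child.terminate()
            child.wait(timeout=5.0)
            raise NodeFault(f"handshake failed: expected {HANDSHAKE_ACK!r}, got {line!r}")
        ctx.state["child"] = child
        ctx.state["conn"] = conn
        ctx.state["fh"] = fh
        return True

    def work(ctx, event) -> None:
        fh = ctx.state["fh"]
        fh.write((_payload_text(event.item) + "\n").encode("utf-8"))
        fh.flush()

    def end_of_life(ctx) -> None:
        child: subprocess.Popen = ctx.state.get("child")
        fh = ctx.state.get("fh")
        if fh is not None:
            try:
                fh.write(b"QUIT\n")
                fh.flush()
            except OSError:
                pass
        conn = ctx.state.get("conn")
        if conn is not None:
            conn.close()
        if child is not None:
            try:
                child.wait(timeout=3.0)
            except subprocess.TimeoutExpired:
                child.terminate()
                try:
                    child.wait(timeout=3.0)
                except subprocess.TimeoutExpired:
                    child.kill()
                    child.wait()

    return WorkerDefinition(work=work, initialise=initialise, end_of_life=end_of_life)


def echo_child_command() -> List[str]:
    """argv for the bundled echo test child."""
    return [sys.executable, "-m", "rigflow.nodes._echo_child"]
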