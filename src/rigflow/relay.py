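"""At-most-once relay state for a node's com actor.

The com actor never buffers: while the node's worker callback is running
(the *busy window*, [callback start, callback return)), every packet that
arrives on any input link is discarded and counted as dropped.  A packet
arriving while the worker is idle is delivered, assigned the next local
packet id (gapless, starting at 0), and logged with the upstream id that
produced it — the evidence base for downstream drop reconciliation.

This class is pure state-machine logic, shared by the live com process and
by discrete-event tests that script the busy window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple


@dataclass
class LinkCounters:
    emitted: int = 0
    delivered: int = 0
    dropped: int = 0


@dataclass
class ComLogRow:
    upstream_node: str
    upstream_packet_id: int
    local_packet_id: int
    timestamp_ns: int


DELIVER = "deliver"
DROP = "drop"


@dataclass
class ComRelay:
    node_name: str
    busy: bool = False
    worker_stopped: bool = False
    next_local_id: int = 0
    counters: Dict[str, LinkCounters] = field(default_factory=dict)
    com_log: List[ComLogRow] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)

    def _link(self, link_id: str) -> LinkCounters:
        return self.counters.setdefault(link_id, LinkCounters())

    def on_packet(
        self,
        link_id: str,
        upstream_node: str,
        upstream_packet_id: int,
        timestamp_ns: int,
    ) -> Tuple[str, Optional[int]]:
        """Decide the fate of an arriving packet.

        Returns ``(DELIVER, local_id)`` or ``(DROP, None)``.  Caller marks
        the busy window: delivery sets ``busy`` and the caller must invoke
        :meth:`on_worker_done` when the callback returns.
        """
        c = self._link(link_id)
        if self.busy or self.worker_stopped:
            c.dropped += 1
            return DROP, None
        local_id = self.next_local_id
        self.next_local_id += 1
        c.delivered += 1
        self.com_log.append(
            ComLogRow(upstream_node, upstream_packet_id, local_id, timestamp_ns)
        )
        self.busy = True
        return DELIVER, local_id

    def on_worker_done(self) -> None:
        """Callback returned: the busy window closes.

        A packet arriving in the same instant the callback returns is
        delivered — the busy window is half-open.
        """
        self.busy = False

    def revert_delivery(self, link_id: str) -> None:
        """Undo the last delivery (the worker pipe broke before handover).

        The packet never reached the worker, so it is re-counted as a drop
        and its com-log row and local id are retracted.
        """
        if not self.com_log:
            return
        self.com_log.pop()
        self.next_local_id -= 1
        c = self._link(link_id)
        c.delivered -= 1
        c.dropped += 1
        self.busy = False

    def on_worker_stopped(self) -> None:
        """Worker shut down: every later arrival is a drop."""
        self.worker_stopped = True
        self.busy = False

    def on_malformed(self, link_id: str, error: str) -> None:
        """A frame that cannot be decoded is dropped, never fatal."""
        self._link(link_id).dropped += 1
        self.errors.append(f"{link_id}: {error}")

    def on_emit(self, link_ids: List[str]) -> None:
        """One packet published on each outgoing link (fan-out counts per link)."""
        for lid in link_ids:
            self._link(lid).emitted += 1
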