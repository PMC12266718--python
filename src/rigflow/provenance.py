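"""Frame/packet provenance reconciliation and cross-device alignment.

The engine never buffers, so a slow downstream node loses packets — but
every relay logs, for each packet it *did* deliver, the id the upstream
node gave it and the gapless local id it assigned (the **com log**).  That
makes a one-to-one correspondence between saved indices and origin-device
indices recoverable after the fact, by composing the logs stage by stage.

Two capture chains on different machines are then aligned through a shared
hardware clockline: a base TTL pulse train triggers device A frame-for-
pulse, and a pulse divider emits one secondary pulse per ``k`` base pulses
to trigger device B.  Divided pulse ``j`` is attributed to base pulse
``k*j`` (the first pulse of its group — the group-onset convention), which
pins every B frame to a base pulse index and hence, through chain A's
correspondence table, to an A frame.

All indices are 0-based; video frames are treated as 0-based frame ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

COMLOG_COLUMNS = ["upstream_node", "upstream_packet_id", "local_packet_id", "timestamp_ns"]
SUBSTATE_INDEX = "packet_index"


class ProvenanceError(ValueError):
    """Inconsistent or impossible provenance inputs."""


@dataclass
class CorrespondenceTable:
    """Mapping from terminal (saved) indices back to origin-device indices.

    ``table`` has columns ``terminal_index`` and ``origin_index``, one row
    per packet that survived every stage; both columns strictly increase.
    """

    table: pd.DataFrame
    origin_total: int
    terminal_total: int

    @property
    def dropped(self) -> int:
        return self.origin_total - self.terminal_total

    def origin_of(self, terminal_index: int) -> int:
        row = self.table.loc[self.table["terminal_index"] == terminal_index, "origin_index"]
        if row.empty:
            raise KeyError(f"no terminal index {terminal_index}")
        return int(row.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class PulseRecord:
    """Both TTL trains as seen by the single common recorder."""

    base_times_ns: Sequence[int]
    divided_times_ns: Sequence[int]
    base_rate_hz: float
    division_factor: int

    def validate(self) -> None:
        if self.division_factor < 1:
            raise ProvenanceError("division factor must be >= 1")
        n_base = len(self.base_times_ns)
        n_div = len(self.divided_times_ns)
        expected = n_base // self.division_factor
        if abs(n_div - expected) > 1:
            raise ProvenanceError(
                f"pulse trains inconsistent with division factor "
                f"{self.division_factor}: {n_base} base vs {n_div} divided pulses "
                f"(expected {expected} ± 1)"
            )


def count_drops(origin_total: int, terminal_total: int) -> int:
    """Packets lost between a chain's origin and its terminal stage.

    Under at-most-once delivery the terminal can never hold more packets
    than the origin emitted; that case is an input error, not a count.
    """
    if terminal_total > origin_total:
        raise ProvenanceError(
            f"terminal total {terminal_total} exceeds origin total {origin_total}: "
            "impossible under at-most-once delivery"
        )
    return origin_total - terminal_total


def _validate_comlog(log: pd.DataFrame, stage: int) -> pd.DataFrame:
    missing = [c for c in ("upstream_packet_id", "local_packet_id") if c not in log.columns]
    if missing:
        raise ProvenanceError(f"com log for stage {stage} lacks columns {missing}")
    up = log["upstream_packet_id"].to_numpy()
    loc = log["local_packet_id"].to_numpy()
    if len(up) == 0:
        return log
    bad = np.flatnonzero(np.diff(up) <= 0)
    if bad.size:
        raise ProvenanceError(
            f"com log for stage {stage}: upstream ids not strictly increasing at row {bad[0] + 1}"
        )
    if loc[0] != 0 or not np.array_equal(loc, np.arange(len(loc))):
        raise ProvenanceError(
            f"com log for stage {stage}: local ids must be gapless 0..{len(loc) - 1}"
        )
    return log


def compose_chain(
    origin_substate: pd.DataFrame, logs: List[pd.DataFrame]
) -> CorrespondenceTable:
    """Compose a capture chain's com logs into one correspondence table.

    ``origin_substate`` holds one row per packet the origin device emitted
    (its ``packet_index`` column is the origin id); each com log relates one
    stage's upstream ids to the next stage's gapless local ids.  Relational
    composition keeps only packets that survived every stage.
    """
    if SUBSTATE_INDEX not in origin_substate.columns:
        raise ProvenanceError(f"origin substate lacks a {SUBSTATE_INDEX!r} column")
    origin_ids = origin_substate[SUBSTATE_INDEX].to_numpy()
    if len(origin_ids) and not np.array_equal(origin_ids, np.arange(len(origin_ids))):
        raise ProvenanceError("origin substate packet_index must be gapless 0..n-1")

    current = pd.DataFrame(
        {"origin_index": origin_ids.astype(np.int64), "stage_id": origin_ids.astype(np.int64)}
    )
    for i, log in enumerate(logs):
        log = _validate_comlog(log, i)
        upstream = log["upstream_packet_id"].to_numpy()
        if not np.isin(upstream, current["stage_id"].to_numpy()).all():
            raise ProvenanceError(
                f"com log for stage {i} references upstream ids that do not exist "
                "in the previous stage"
            )
        merged = current.merge(
            log[["upstream_packet_id", "local_packet_id"]],
            left_on="stage_id",
            right_on="upstream_packet_id",
            how="inner",
        )
        current = pd.DataFrame(
            {
                "origin_index": merged["origin_index"].to_numpy(),
                "stage_id": merged["local_packet_id"].to_numpy(),
            }
        )
    table = pd.DataFrame(
        {
            "terminal_index": current["stage_id"].to_numpy(),
            "origin_index": current["origin_index"].to_numpy(),
        }
    )
    return CorrespondenceTable(
        table=table, origin_total=len(origin_ids), terminal_total=len(table)
    )


def divided_pulse_origin(j: int, k: int) -> int:
    """Base-train index of the pulse that produced divided pulse ``j``.

    Group-onset convention: divided pulse ``j`` fires with the first base
    pulse of its group of ``k``, i.e. base pulse ``k*j``.
    """
    if j < 0:
        raise ValueError("pulse index must be non-negative")
    if k < 1:
        raise ValueError("division factor must be >= 1")
    return k * j


@dataclass
class ChainAlignment:
    """Output of :func:`align_two_chains`: every B terminal frame, matched or not."""

    table: pd.DataFrame  # b_terminal, b_origin, divided_pulse, base_pulse, a_origin, a_terminal
    unmatched: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.unmatched = self.table[self.table["a_terminal"].isna()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def align_two_chains(
    chain_a: CorrespondenceTable,
    a_origin_to_base_pulse: pd.DataFrame,
    chain_b: CorrespondenceTable,
    b_origin_to_divided_pulse: pd.DataFrame,
    pulses: PulseRecord,
) -> ChainAlignment:
    """Map device-B saved frames onto device-A saved frames via the clockline.

    ``a_origin_to_base_pulse`` / ``b_origin_to_divided_pulse`` are substate
    tables linking each device's origin frame index (``packet_index``) to
    the TTL pulse id that triggered it.  A frames whose partner was dropped
    anywhere along chain A are reported with a null ``a_terminal`` rather
    than silently removed.
    """
    pulses.validate()
    k = pulses.division_factor

    def _pulse_map(sub: pd.DataFrame, col: str) -> pd.DataFrame:
        if SUBSTATE_INDEX not in sub.columns or col not in sub.columns:
            raise ProvenanceError(f"substate needs columns {SUBSTATE_INDEX!r} and {col!r}")
        return sub[[SUBSTATE_INDEX, col]]

    a_sub = _pulse_map(a_origin_to_base_pulse, "pulse_id")
    b_sub = _pulse_map(b_origin_to_divided_pulse, "pulse_id")

    # B terminal frame -> B origin frame -> divided pulse -> base pulse
    out = chain_b.table.rename(
        columns={"terminal_index": "b_terminal", "origin_index": "b_origin"}
    ).merge(b_sub.rename(columns={SUBSTATE_INDEX: "b_origin", "pulse_id": "divided_pulse"}))
    out["base_pulse"] = out["divided_pulse"].astype(np.int64) * k

    # base pulse -> A origin frame -> A terminal frame (when it survived)
    a_map = a_sub.rename(columns={SUBSTATE_INDEX: "a_origin", "pulse_id": "base_pulse"})
    out = out.merge(a_map, on="base_pulse", how="left")
    a_terms = chain_a.table.rename(
        columns={"terminal_index": "a_terminal", "origin_index": "a_origin"}
    )
    out = out.merge(a_terms, on="a_origin", how="left")
    out = out[["b_terminal", "b_origin", "divided_pulse", "base_pulse", "a_origin", "a_terminal"]]
    return ChainAlignment(table=out.sort_values("b_terminal").reset_index(drop=True))


# ---------------------------------------------------------------------------
# file I/O (plain CSV, the formats the engine writes)


def read_comlog(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COMLOG_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ProvenanceError(f"{path}: com log lacks columns {missing}")
    return df


def read_substate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if SUBSTATE_INDEX not in df.columns:
        raise ProvenanceError(f"{path}: substate lacks a {SUBSTATE_INDEX!r} column")
    return df


def read_pulse_record(path, division_factor: Optional[int] = None) -> PulseRecord:
    """Read the recorder's pulse CSV (columns: train {base,divided}, time_ns)."""
    df = pd.read_csv(path)
    for col in ("train", "time_ns"):
        if col not in df.columns:
            raise ProvenanceError(f"{path}: pulse record lacks column {col!r}")
    base = df.loc[df["train"] == "base", "time_ns"].to_numpy()
    div = df.loc[df["train"] == "divided", "time_ns"].to_numpy()
    if len(base) >= 2:
        rate = 1e9 / float(np.median(np.diff(base)))
    else:
        rate = float("nan")
    k = division_factor
    if k is None:
        k = max(1, int(round(len(base) / max(1, len(div)))))
    return PulseRecord(
        base_times_ns=base.tolist(),
        divided_times_ns=div.tolist(),
        base_rate_hz=rate,
        division_factor=k,
    )
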