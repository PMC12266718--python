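"""Deterministic synthetic rigs: every test input, with its ground truth.

The simulated rig mirrors a dual-camera setup synchronised by a hardware
clockline: a 120 Hz TTL train (one pulse per projector frame) triggers
camera A frame-for-pulse, and a pulse divider emits one pulse per ``k``
base pulses (k = 4 → 30 Hz) to trigger camera B.  Each camera's frames
then traverse a chain of relay stages (capture node → save node), any of
which may drop frames under the no-buffering rule.  The simulator emits
exactly the observable files the reconciliation code consumes — substate
tables, com logs, the recorder's pulse record — plus a *separate* ground
truth table used only as a test oracle.

Determinism: all event times are integer nanoseconds; all randomness comes
from ``numpy`` generators seeded as ``[seed, stage offset]``, so toggling
one stage's drop probability never perturbs another stage's draws.  The
same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .provenance import PulseRecord

# fixed RNG substream offsets per chain stage
_STREAM_CHAIN_A = 1
_STREAM_CHAIN_B = 2


class FixtureError(ValueError):
    pass


@dataclass
class RigSimConfig:
    """Study conditions for the simulated two-camera rig.

    Defaults are the reference rig: a 120 Hz base train divided by 4 into a
    30 Hz train, with one lossy relay stage per camera chain.  Drop
    probabilities are per-packet, per-stage Bernoulli rates; the reference
    chain's observed loss was ~0.02%, so the default is of that order.
    """

    base_rate_hz: float = 120.0
    division_factor: int = 4
    duration_s: float = 60.0
    chain_a_drop_p: Sequence[float] = (0.0003,)
    chain_b_drop_p: Sequence[float] = (0.0003,)
    seed: int = 0

    def validate(self) -> None:
        if self.base_rate_hz <= 0:
            raise FixtureError("base rate must be positive")
        if self.division_factor < 1:
            raise FixtureError("division factor must be >= 1")
        if self.duration_s <= 0:
            raise FixtureError("duration must be positive")
        for ps in (self.chain_a_drop_p, self.chain_b_drop_p):
            for p in ps:
                if not (0.0 <= p < 1.0):
                    raise FixtureError(f"drop probability {p} outside [0, 1)")


@dataclass
class ChainFixture:
    """One capture chain: origin substate + per-stage com logs + truth."""

    substate: pd.DataFrame  # packet_index, timestamp_ns, pulse_id
    com_logs: List[pd.DataFrame]
    survived: np.ndarray  # bool per origin frame: reached the terminal stage
    terminal_of_origin: np.ndarray  # terminal index per origin frame, -1 if lost


@dataclass
class RigSimResult:
    config: RigSimConfig
    base_times_ns: np.ndarray
    divided_times_ns: np.ndarray
    chain_a: ChainFixture
    chain_b: ChainFixture
    pulses: PulseRecord
    ground_truth: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _simulate_chain(
    n_frames: int,
    times_ns: np.ndarray,
    pulse_ids: np.ndarray,
    drop_p: Sequence[float],
    rng_stream: int,
    seed: int,
) -> ChainFixture:
    substate = pd.DataFrame(
        {
            "packet_index": np.arange(n_frames, dtype=np.int64),
            "timestamp_ns": times_ns.astype(np.int64),
            "pulse_id": pulse_ids.astype(np.int64),
        }
    )
    upstream = np.arange(n_frames, dtype=np.int64)
    up_times = times_ns.astype(np.int64)
    logs: List[pd.DataFrame] = []
    for stage, p in enumerate(drop_p):
        rng = np.random.default_rng([seed, rng_stream, stage])
        keep = rng.random(len(upstream)) >= p
        surv_up = upstream[keep]
        surv_t = up_times[keep] + 50_000  # fixed 50 µs relay latency
        logs.append(
            pd.DataFrame(
                {
                    "upstream_node": f"stage{stage}",
                    "upstream_packet_id": surv_up,
                    "local_packet_id": np.arange(len(surv_up), dtype=np.int64),
                    "timestamp_ns": surv_t,
                }
            )
        )
        upstream = np.arange(len(surv_up), dtype=np.int64)
        up_times = surv_t
        if stage == 0:
            origin_alive = surv_up
        else:
            origin_alive = origin_alive[keep]
    if not drop_p:
        origin_alive = np.arange(n_frames, dtype=np.int64)
    survived = np.zeros(n_frames, dtype=bool)
    survived[origin_alive] = True
    terminal_of_origin = np.full(n_frames, -1, dtype=np.int64)
    terminal_of_origin[origin_alive] = np.arange(len(origin_alive))
    return ChainFixture(
        substate=substate, com_logs=logs, survived=survived, terminal_of_origin=terminal_of_origin
    )


def simulate_rig(cfg: RigSimConfig, out_dir: Optional[Path] = None) -> RigSimResult:
    """Simulate the dual-camera rig; optionally write the observable files.

    Returns the in-memory fixture; when ``out_dir`` is given, also writes
    the substate/com-log/pulse CSVs (the exact formats the reconciliation
    subsystem reads) plus a manifest, keeping the ground truth in a
    separately named file so tests cannot confuse oracle and observation.
    """
    cfg.validate()
    period_ns = int(round(1e9 / cfg.base_rate_hz))
    n_base = int(np.floor(cfg.duration_s * cfg.base_rate_hz))
    base_times = np.arange(n_base, dtype=np.int64) * period_ns
    k = cfg.division_factor
    # group-onset convention: divided pulse j fires with base pulse k*j
    divided_origin = np.arange(0, n_base, k, dtype=np.int64)
    divided_times = base_times[divided_origin]

    chain_a = _simulate_chain(
        n_base, base_times, np.arange(n_base), cfg.chain_a_drop_p, _STREAM_CHAIN_A, cfg.seed
    )
    chain_b = _simulate_chain(
        len(divided_origin),
        divided_times,
        np.arange(len(divided_origin)),
        cfg.chain_b_drop_p,
        _STREAM_CHAIN_B,
        cfg.seed,
    )
    pulses = PulseRecord(
        base_times_ns=base_times.tolist(),
        divided_times_ns=divided_times.tolist(),
        base_rate_hz=cfg.base_rate_hz,
        division_factor=k,
    )

    b_of_base = np.full(n_base, -1, dtype=np.int64)
    b_of_base[divided_origin] = np.arange(len(divided_origin))
    truth = pd.DataFrame(
        {
            "base_pulse": np.arange(n_base, dtype=np.int64),
            "a_frame": np.arange(n_base, dtype=np.int64),
            "a_survived": chain_a.survived,
            "a_terminal": chain_a.terminal_of_origin,
            "b_frame": b_of_base,
            "b_survived": np.where(b_of_base >= 0, chain_b.survived[b_of_base], False),
            "b_terminal": np.where(b_of_base >= 0, chain_b.terminal_of_origin[b_of_base], -1),
        }
    )

    result = RigSimResult(
        config=cfg,
        base_times_ns=base_times,
        divided_times_ns=divided_times,
        chain_a=chain_a,
        chain_b=chain_b,
        pulses=pulses,
        ground_truth=truth,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(name: str, df: pd.DataFrame) -> None:
            p = out_dir / name
            df.to_csv(p, index=False)
            paths[name] = str(p)

        _write("chain_a.substate.csv", chain_a.substate)
        for i, log in enumerate(chain_a.com_logs):
            _write(f"chain_a.stage{i}.comlog.csv", log)
        _write("chain_b.substate.csv", chain_b.substate)
        for i, log in enumerate(chain_b.com_logs):
            _write(f"chain_b.stage{i}.comlog.csv", log)
        pulse_df = pd.DataFrame(
            {
                "train": ["base"] * n_base + ["divided"] * len(divided_times),
                "time_ns": np.concatenate([base_times, divided_times]),
            }
        )
        _write("pulses.csv", pulse_df)
        _write("ground_truth.synthetic.csv", truth)
        manifest = {
            "seed": cfg.seed,
            "base_rate_hz": cfg.base_rate_hz,
            "division_factor": k,
            "duration_s": cfg.duration_s,
            "files": sorted(paths),  # names relative to the fixture directory
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        result.paths = paths
    return result


def simulate_capture_chain(
    origin_total: int, stage_drops: Sequence[int], seed: int = 0
) -> ChainFixture:
    """A single chain with *exact* per-stage drop counts at seeded positions.

    Useful when a worked example fixes the totals (origin frames emitted vs
    frames in the saved file) rather than a drop rate.
    """
    if origin_total < 0:
        raise FixtureError("origin_total must be non-negative")
    period_ns = int(round(1e9 / 120.0))
    times = np.arange(origin_total, dtype=np.int64) * period_ns
    substate = pd.DataFrame(
        {
            "packet_index": np.arange(origin_total, dtype=np.int64),
            "timestamp_ns": times,
            "pulse_id": np.arange(origin_total, dtype=np.int64),
        }
    )
    upstream = np.arange(origin_total, dtype=np.int64)
    up_times = times
    logs: List[pd.DataFrame] = []
    origin_alive = upstream
    for stage, n_drop in enumerate(stage_drops):
        if n_drop < 0 or n_drop > len(upstream):
            raise FixtureError(f"stage {stage}: cannot drop {n_drop} of {len(upstream)} packets")
        rng = np.random.default_rng([seed, 97, stage])
        lost = rng.choice(len(upstream), size=n_drop, replace=False)
        keep = np.ones(len(upstream), dtype=bool)
        keep[lost] = False
        surv_up = upstream[keep]
        surv_t = up_times[keep] + 50_000
        logs.append(
            pd.DataFrame(
                {
                    "upstream_node": f"stage{stage}",
                    "upstream_packet_id": surv_up,
                    "local_packet_id": np.arange(len(surv_up), dtype=np.int64),
                    "timestamp_ns": surv_t,
                }
            )
        )
        origin_alive = origin_alive[keep]
        upstream = np.arange(len(surv_up), dtype=np.int64)
        up_times = surv_t
    survived = np.zeros(origin_total, dtype=bool)
    survived[origin_alive] = True
    terminal_of_origin = np.full(origin_total, -1, dtype=np.int64)
    terminal_of_origin[origin_alive] = np.arange(len(origin_alive))
    return ChainFixture(
        substate=substate, com_logs=logs, survived=survived, terminal_of_origin=terminal_of_origin
    )


# ---------------------------------------------------------------------------
# scripted rig sessions (for the trial controller)


@dataclass(frozen=True)
class RigEvent:
    time_ns: int
    kind: str  # e.g. "lick"
    data: Optional[dict] = None


class RigSession:
    """Replayable, clock-driven event stream for a simulated behavioural rig."""

    def __init__(self, events: Sequence[RigEvent]) -> None:
        self._events = tuple(events)

    def events_in(self, start_ns: int, end_ns: int, kind: Optional[str] = None) -> List[RigEvent]:
        """Events with start <= t < end, optionally filtered by kind."""
        return [
            ev
            for ev in self._events
            if start_ns <= ev.time_ns < end_ns and (kind is None or ev.kind == kind)
        ]

    def __len__(self) -> int:
        return len(self._events)


def scripted_session(events: Sequence[Tuple]) -> RigSession:
    """Build a rig session from ``(time_ns, kind[, data])`` tuples.

    Times must be non-decreasing; the session replays identically however
    many times it is consumed.
    """
    out: List[RigEvent] = []
    prev = None
    for i, ev in enumerate(events):
        if len(ev) == 2:
            t, kind = ev
            data = None
        elif len(ev) == 3:
            t, kind, data = ev
        else:
            raise FixtureError(f"event {i}: expected (time_ns, kind[, data])")
        t = int(t)
        if prev is not None and t < prev:
            raise FixtureError(f"event {i}: time {t} decreases below {prev}")
        prev = t
        out.append(RigEvent(time_ns=t, kind=str(kind), data=data))
    return RigSession(out)
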