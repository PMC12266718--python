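"""Probabilistic reversal-learning (PRL) task nodes.

The task alternates between two *blocks*; within a block, each of the four
stimulation types carries a fixed probability of reward (the 2 × 4 reward
contingency matrix).  When a block's drawn length is exhausted, the block
switches and the subject must relearn the contingencies.  Two nodes
implement the task as a request/response loop:

* the **trial generator** keeps the block state, draws the next stimulation
  type and the reward availability, and emits a trial definition;
* the **trial controller** runs one trial through its phases — odour window
  → pre-response delay → response window → reward window — scores licks
  against the correct port, and emits the trial result plus the history
  record the generator consumes to produce the next trial.

The generator also tallies correct licks per port.  The tallies influence
nothing by default (fixed drawn block lengths); an optional
performance-switching rule — advance the block once the last ``window``
trials contain ``threshold`` correct licks — is provided as a clearly
separate extension, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..clock import SimulatedClock
from ..fixtures import RigSession, scripted_session
from ..node_api import WorkerDefinition

N_STIM_TYPES = 4
N_BLOCKS = 2


class PRLConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrialDefinition:
    stim_type: int
    reward_available: bool
    block_index: int
    trial_number: int

    def to_record(self) -> dict:
        return {
            "stim_type": int(self.stim_type),
            "reward_available": bool(self.reward_available),
            "block_index": int(self.block_index),
            "trial_number": int(self.trial_number),
        }


@dataclass(frozen=True)
class TrialResult:
    stim_type: int
    licked: bool
    correct_port_licked: bool
    rewarded: bool
    phase_timestamps_ns: Tuple[int, int, int, int, int]  # odour, pre, response, reward, end

    def to_record(self) -> dict:
        names = ("odour_on", "pre_response", "response", "reward", "trial_end")
        rec = {
            "stim_type": int(self.stim_type),
            "licked": bool(self.licked),
            "correct_port_licked": bool(self.correct_port_licked),
            "rewarded": bool(self.rewarded),
        }
        rec.update({f"t_{n}_ns": int(t) for n, t in zip(names, self.phase_timestamps_ns)})
        return rec


@dataclass
class GeneratorConfig:
    """Reference task configuration: 2 blocks × 4 stim types."""

    contingencies: Sequence[Sequence[float]] = ((0.9, 0.1, 0.9, 0.1), (0.1, 0.9, 0.1, 0.9))
    block_length_range: Tuple[int, int] = (20, 30)
    n_stim_types: int = N_STIM_TYPES
    # optional performance-switching extension (off by default): advance the
    # block once the last `window` trials contain >= `threshold` correct licks
    performance_rule: Optional[Tuple[int, int]] = None  # (threshold, window)

    def validate(self) -> None:
        m = np.asarray(self.contingencies, dtype=float)
        if m.shape != (N_BLOCKS, self.n_stim_types):
            raise PRLConfigError(
                f"contingency matrix must be {N_BLOCKS} x {self.n_stim_types}, got {m.shape}"
            )
        if ((m < 0) | (m > 1)).any():
            raise PRLConfigError("reward probabilities must lie in [0, 1]")
        lo, hi = self.block_length_range
        if not (1 <= lo <= hi):
            raise PRLConfigError("block length range needs 1 <= lo <= hi")


@dataclass
class GeneratorState:
    rng: np.random.Generator
    block_index: int = 0
    remaining: int = 0
    trial_number: int = 0
    correct_lick_tallies: np.ndarray = field(
        default_factory=lambda: np.zeros(N_STIM_TYPES, dtype=np.int64)
    )
    recent_correct: List[bool] = field(default_factory=list)
    started: bool = False


def make_generator_state(seed, n_stim_types: int = N_STIM_TYPES) -> GeneratorState:
    return GeneratorState(
        rng=np.random.default_rng(seed),
        correct_lick_tallies=np.zeros(n_stim_types, dtype=np.int64),
    )


def trial_generator_step(
    state: GeneratorState, prev: Optional[TrialResult], cfg: GeneratorConfig
) -> Tuple[GeneratorState, TrialDefinition]:
    """Advance the task by one trial.

    ``prev`` is the previous trial's result (None for the start signal);
    correct licks update the per-port tallies.  On block exhaustion a new
    block length is drawn uniformly from the configured range and the block
    index alternates.  The stimulation type is drawn uniformly over the
    four types and reward availability is Bernoulli with the current
    block/stim cell of the contingency matrix.
    """
    cfg.validate()
    if prev is not None:
        if prev.correct_port_licked:
            state.correct_lick_tallies[prev.stim_type] += 1
        state.recent_correct.append(prev.correct_port_licked)

    switch = state.remaining <= 0
    if not switch and cfg.performance_rule is not None:
        threshold, window = cfg.performance_rule
        recent = state.recent_correct[-window:]
        switch = len(recent) >= window and sum(recent) >= threshold
    if switch:
        if state.started:
            state.block_index = (state.block_index + 1) % N_BLOCKS
        lo, hi = cfg.block_length_range
        state.remaining = int(state.rng.integers(lo, hi + 1))
        state.recent_correct = []
        state.started = True

    stim = int(state.rng.integers(0, cfg.n_stim_types))
    p = float(np.asarray(cfg.contingencies, dtype=float)[state.block_index, stim])
    reward_available = bool(state.rng.random() < p)
    definition = TrialDefinition(
        stim_type=stim,
        reward_available=reward_available,
        block_index=state.block_index,
        trial_number=state.trial_number,
    )
    state.trial_number += 1
    state.remaining -= 1
    return state, definition


@dataclass
class ControllerParams:
    """Trial phase durations (seconds) and reward gating."""

    odour_window_s: float = 0.5
    pre_response_delay_s: float = 0.25
    response_window_s: float = 1.0
    reward_window_s: float = 0.5
    reward_only_after_lick: bool = True
    # which lick port is correct for each stim type
    stim_to_port: Sequence[int] = (0, 0, 1, 1)
    # serial rig descriptors: accepted for interface compatibility, unused
    # by the simulated rig (a warning is logged when set)
    com_port: Optional[str] = None
    baud_rate: Optional[int] = None

    def validate(self) -> None:
        for name in ("odour_window_s", "pre_response_delay_s", "response_window_s", "reward_window_s"):
            if getattr(self, name) < 0:
                raise PRLConfigError(f"{name} must be >= 0")
        if len(self.stim_to_port) < N_STIM_TYPES:
            raise PRLConfigError("stim_to_port must cover every stim type")


def _ns(seconds: float) -> int:
    return int(round(seconds * 1_000_000_000))


def trial_controller_run_trial(
    definition: TrialDefinition,
    params: ControllerParams,
    rig: RigSession,
    start_ns: int = 0,
    clock: Optional[SimulatedClock] = None,
) -> Tuple[TrialResult, dict]:
    """Run one trial against a rig event stream; return (result, history).

    Phases execute strictly in order.  A lick on the correct port inside
    the response window scores; reward is granted when reward is available
    for this trial and — if ``reward_only_after_lick`` — the correct port
    was licked.  The history record is what the trial generator consumes.
    """
    params.validate()
    clock = clock or SimulatedClock(start_ns)
    t_odour = clock.now_ns()
    clock.sleep(params.odour_window_s)
    t_pre = clock.now_ns()
    clock.sleep(params.pre_response_delay_s)
    t_response = clock.now_ns()
    clock.sleep(params.response_window_s)
    t_reward = clock.now_ns()
    clock.sleep(params.reward_window_s)
    t_end = clock.now_ns()

    licks = rig.events_in(t_response, t_response + _ns(params.response_window_s), kind="lick")
    licked = bool(licks)
    correct_port = params.stim_to_port[definition.stim_type]
    correct_licked = any((ev.data or {}).get("port") == correct_port for ev in licks)
    if params.reward_only_after_lick:
        rewarded = definition.reward_available and correct_licked
    else:
        rewarded = definition.reward_available
    result = TrialResult(
        stim_type=definition.stim_type,
        licked=licked,
        correct_port_licked=correct_licked,
        rewarded=rewarded,
        phase_timestamps_ns=(t_odour, t_pre, t_response, t_reward, t_end),
    )
    history = {
        "stim_type": int(definition.stim_type),
        "correct_port_licked": bool(correct_licked),
        "rewarded": bool(rewarded),
        "trial_number": int(definition.trial_number),
    }
    return result, history


# ---------------------------------------------------------------------------
# worker factories (graph-file entry points)


def _result_from_history(rec: dict) -> TrialResult:
    return TrialResult(
        stim_type=int(rec["stim_type"]),
        licked=bool(rec.get("correct_port_licked", False)),
        correct_port_licked=bool(rec.get("correct_port_licked", False)),
        rewarded=bool(rec.get("rewarded", False)),
        phase_timestamps_ns=(0, 0, 0, 0, 0),
    )


def trial_generator(params: dict) -> WorkerDefinition:
    """Transform: (start signal | trial history) in → trial definition out.

    Parameters: ``contingencies`` (2×4 matrix), ``block_length_range``
    ([lo, hi]), ``max_trials`` (stop emitting after this many; keeps
    duration-limited runs deterministic), ``seed_offset``.
    """
    cfg = GeneratorConfig(
        contingencies=params.get("contingencies", GeneratorConfig.contingencies),
        block_length_range=tuple(params.get("block_length_range", GeneratorConfig.block_length_range)),
    )
    cfg.validate()
    max_trials = params.get("max_trials")
    seed_offset = int(params.get("seed_offset", 11))

    def initialise(ctx) -> bool:
        ctx.state["gen"] = make_generator_state([ctx.run_seed, seed_offset])
        return True

    def work(ctx, event):
        state: GeneratorState = ctx.state["gen"]
        if max_trials is not None and state.trial_number >= int(max_trials):
            return None
        prev = None
        if isinstance(event.item, dict) and "stim_type" in event.item:
            prev = _result_from_history(event.item)
        state, definition = trial_generator_step(state, prev, cfg)
        ctx.state["gen"] = state
        ctx.record_substate(
            {"trial_number": definition.trial_number, "block_index": definition.block_index}
        )
        return [definition.to_record()]

    return WorkerDefinition(work=work, initialise=initialise)


def trial_controller(params: dict) -> WorkerDefinition:
    """Transform: trial definition in → [trial result, trial history] out.

    Runs each trial on an internal simulated clock (phases are modelled,
    not slept, so a graph run is not paced by trial durations).  The
    subject is simulated: it licks the correct port mid-response-window
    with probability ``lick_prob``; a scripted rig session can be supplied
    instead via ``scripted_events``.
    """
    cparams = ControllerParams(
        odour_window_s=float(params.get("odour_window_s", 0.5)),
        pre_response_delay_s=float(params.get("pre_response_delay_s", 0.25)),
        response_window_s=float(params.get("response_window_s", 1.0)),
        reward_window_s=float(params.get("reward_window_s", 0.5)),
        reward_only_after_lick=bool(params.get("reward_only_after_lick", True)),
        stim_to_port=tuple(params.get("stim_to_port", (0, 0, 1, 1))),
        com_port=params.get("com_port"),
        baud_rate=params.get("baud_rate"),
    )
    cparams.validate()
    lick_prob = float(params.get("lick_prob", 0.8))
    scripted = params.get("scripted_events")
    seed_offset = int(params.get("seed_offset", 13))
    # wall-clock pacing between trials: keeps downstream consumers (e.g. the
    # trial-table sink) comfortably idle between rows, as a hardware rig does
    inter_trial_s = float(params.get("inter_trial_s", 0.0))

    def initialise(ctx) -> bool:
        if cparams.com_port is not None or cparams.baud_rate is not None:
            # serial I/O is outside the simulated rig; accepted and ignored
            import warnings

            warnings.warn("COM port / baud rate parameters are ignored by the simulated rig")
        ctx.state["rng"] = np.random.default_rng([ctx.run_seed, seed_offset])
        ctx.state["t"] = 0
        return True

    def work(ctx, event):
        rec = event.item
        if not isinstance(rec, dict) or "stim_type" not in rec:
            return None  # not a trial definition (e.g. stray start signal)
        definition = TrialDefinition(
            stim_type=int(rec["stim_type"]),
            reward_available=bool(rec["reward_available"]),
            block_index=int(rec["block_index"]),
            trial_number=int(rec["trial_number"]),
        )
        start_ns = ctx.state["t"]
        t_resp = start_ns + _ns(cparams.odour_window_s) + _ns(cparams.pre_response_delay_s)
        if scripted is not None:
            rig = scripted_session([tuple(ev) for ev in scripted])
        else:
            rng: np.random.Generator = ctx.state["rng"]
            events = []
            if cparams.response_window_s > 0 and rng.random() < lick_prob:
                lick_t = t_resp + _ns(cparams.response_window_s) // 2
                events.append((lick_t, "lick", {"port": cparams.stim_to_port[definition.stim_type]}))
            rig = scripted_session(events)
        result, history = trial_controller_run_trial(
            definition, cparams, rig, start_ns=start_ns
        )
        ctx.state["t"] = result.phase_timestamps_ns[-1] + _ns(0.001)  # inter-trial gap
        ctx.record_substate({"trial_number": definition.trial_number})
        if inter_trial_s > 0:
            import time

            time.sleep(inter_trial_s)
        return [result.to_record(), history]

    return WorkerDefinition(work=work, initialise=initialise)
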