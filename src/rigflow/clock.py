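"""Clock abstraction used by worker loops and fixtures.

All timestamps in rigflow are integer nanoseconds on a monotonic axis.
Workers pace themselves against a clock object so the same node code runs
against wall time in a live rig and against a simulated, instantly-advancing
clock in deterministic tests.
"""

from __future__ import annotations

import time


class MonotonicClock:
    """Wall clock: ``time.monotonic_ns`` plus a real sleep."""

    def now_ns(self) -> int:
        return time.monotonic_ns()

    def sleep(self, seconds: float) -> None:
        if seconds > 0:
            time.sleep(seconds)


class SimulatedClock:
    """Deterministic clock that advances only when told to.

    ``sleep`` advances the reading instantly, so a source loop paced at
    120 Hz executes 1200 passes of "10 seconds" in microseconds of wall
    time.  Time is integer nanoseconds throughout; fractional-second sleeps
    are rounded to the nearest nanosecond.
    """

    def __init__(self, start_ns: int = 0) -> None:
        self._now = int(start_ns)

    def now_ns(self) -> int:
        return self._now

    def sleep(self, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("cannot sleep a negative duration")
        self._now += int(round(seconds * 1_000_000_000))

    def advance_ns(self, ns: int) -> None:
        if ns < 0:
            raise ValueError("cannot advance backwards")
        self._now += int(ns)
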