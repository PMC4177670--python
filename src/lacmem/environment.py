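"""Square-wave glucose/lactose environment schedules.

The *environmental duration* T is the length of a single glucose or lactose
phase; a full cycle (one glucose + one lactose phase) lasts 2T.  Phase
membership uses the half-open convention: a switch time belongs to the
incoming phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GLUCOSE = "glucose"
LACTOSE = "lactose"
_PHASES = (GLUCOSE, LACTOSE)


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant environment: ordered (start, end, label) phases."""

    starts: tuple  # phase start times, minutes
    ends: tuple
    labels: tuple

    def __post_init__(self) -> None:
        if not self.starts:
            raise ValueError("schedule needs at least one phase")
        for lab in self.labels:
            if lab not in _PHASES:
                raise ValueError(f"unknown phase label {lab!r}")
        for s, e in zip(self.starts, self.ends):
            if not e > s:
                raise ValueError("phases must have positive duration")
        for e, s2 in zip(self.ends[:-1], self.starts[1:]):
            if e != s2:
                raise ValueError("phases must be contiguous")

    # -- constructors --------------------------------------------------------

    @classmethod
    def alternating(
        cls,
        T: float,
        n_cycles: int,
        first_phase: str = LACTOSE,
        t0: float = 0.0,
    ) -> "EnvironmentSchedule":
        """Alternating square wave: ``n_cycles`` full cycles of duration 2T."""
        if T <= 0:
            raise ValueError("environmental duration T must be positive")
        if n_cycles < 1:
            raise ValueError("need at least one full cycle")
        if first_phase not in _PHASES:
            raise ValueError(f"unknown phase label {first_phase!r}")
        second = GLUCOSE if first_phase == LACTOSE else LACTOSE
        labels = (first_phase, second) * int(n_cycles)
        starts = tuple(t0 + i * T for i in range(2 * n_cycles))
        ends = tuple(t0 + (i + 1) * T for i in range(2 * n_cycles))
        return cls(starts, ends, labels)

    @classmethod
    def constant(
        cls, phase: str, duration: float, t0: float = 0.0
    ) -> "EnvironmentSchedule":
        """Degenerate single-phase schedule for constant environments."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        return cls((t0,), (t0 + duration,), (phase,))

    # -- queries -------------------------------------------------------------

    @property
    def t_start(self) -> float:
        return self.starts[0]

    @property
    def t_end(self) -> float:
        return self.ends[-1]

    @property
    def environmental_duration(self) -> float | None:
        """T for alternating schedules, None for constant ones."""
        if len(self.starts) < 2:
            return None
        return self.ends[0] - self.starts[0]

    def phase_at(self, t: float) -> str:
        """Phase label at time t (half-open; the final end time is inclusive)."""
        if t < self.t_start or t > self.t_end:
            raise ValueError(f"t={t} outside schedule [{self.t_start}, {self.t_end}]")
        idx = int(np.searchsorted(np.asarray(self.ends), t, side="right"))
        idx = min(idx, len(self.labels) - 1)
        return self.labels[idx]

    def external_lactose_of(self, t: float, Le: float) -> float:
        """External lactose at time t: ``Le`` in lactose phases, 0 in glucose."""
        return Le if self.phase_at(t) == LACTOSE else 0.0

    def labels_for(self, times: np.ndarray) -> np.ndarray:
        ends = np.asarray(self.ends)
        idx = np.minimum(
            np.searchsorted(ends, np.asarray(times), side="right"),
            len(self.labels) - 1,
        )
        return np.asarray(self.labels, dtype=object)[idx]

    def segments(self):
        """Iterate (start, end, label) triples."""
        return zip(self.starts, self.ends, self.labels)
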