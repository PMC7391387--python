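"""Piecewise-constant hazard schedules over age and closed-form survival.

Rate tables (fracture incidence or all-cause mortality) become hazard
schedules that are constant within each age band; integrals over such
schedules are exact sums, so no quadrature enters the probability chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .tables import BandError, RateTable

DEFAULT_TERMINAL_AGE = 110.0


@dataclass(frozen=True)
class HazardSchedule:
    """Per-year hazard, constant between consecutive knots.

    ``hazards[i]`` applies on ``[knots[i], knots[i+1])``; the last knot is
    the terminal (truncation) age, beyond which the schedule is undefined.
    """

    sex: str
    knots: Sequence[float]
    hazards: Sequence[float]

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        hazards = np.asarray(self.hazards, dtype=float)
        if knots.ndim != 1 or len(knots) < 2:
            raise BandError("need at least two knots")
        if len(hazards) != len(knots) - 1:
            raise BandError("need exactly one hazard per inter-knot interval")
        if np.any(np.diff(knots) <= 0):
            raise BandError("knots must be strictly increasing")
        if np.any(hazards < 0) or not np.all(np.isfinite(hazards)):
            raise BandError("hazards must be finite and >= 0")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "hazards", hazards)

    @property
    def terminal_age(self) -> float:
        return float(self.knots[-1])

    @property
    def start_age(self) -> float:
        return float(self.knots[0])

    def hazard_at(self, age: float) -> float:
        """Hazard in force at ``age`` (right-continuous lookup)."""
        self._check_support(age)
        i = int(np.searchsorted(self.knots, age, side="right")) - 1
        i = min(i, len(self.hazards) - 1)
        return float(self.hazards[i])

    def cumulative(self, from_age: float, to_age: float) -> float:
        """Integrated hazard over [from_age, to_age], exactly."""
        self._check_support(from_age)
        self._check_support(to_age)
        if from_age > to_age:
            raise ValueError(f"from_age {from_age} > to_age {to_age}")
        lo = np.clip(self.knots[:-1], from_age, to_age)
        hi = np.clip(self.knots[1:], from_age, to_age)
        return float(np.sum(self.hazards * (hi - lo)))

    def _check_support(self, age: float) -> None:
        if age < self.knots[0] or age > self.knots[-1]:
            raise ValueError(
                f"age {age} outside schedule support [{self.knots[0]}, {self.knots[-1]}]"
            )


def schedule_from_rate_table(
    rt: RateTable,
    sex: str,
    terminal_age: float = DEFAULT_TERMINAL_AGE,
) -> HazardSchedule:
    """Build the piecewise-constant hazard implied by a rate table.

    Each band contributes a constant segment at its per-person-year rate;
    the open terminal band extends to ``terminal_age``; ages below the
    first band carry hazard 0 (support starts at age 0).
    """
    bands = rt.bands(sex)
    if not bands:
        raise BandError(f"rate table has no bands for sex {sex!r}")
    rt.validate_contiguous(sex)
    last = bands[-1]
    last_start = last.age_lo if last.is_open else last.age_hi
    if terminal_age <= last_start:
        raise BandError(
            f"terminal_age {terminal_age} must exceed the last band start {last_start}"
        )

    knots: List[float] = []
    hazards: List[float] = []
    if bands[0].age_lo > 0:
        knots.append(0.0)
        hazards.append(0.0)
    for band in bands:
        knots.append(float(band.age_lo))
        hazards.append(rt[band])
    if not last.is_open:
        # closed final band: rate 0 from its end to the terminal age
        knots.append(float(last.age_hi))
        hazards.append(0.0)
    knots.append(float(terminal_age))
    return HazardSchedule(sex=sex, knots=knots, hazards=hazards)


def survival(
    schedule_death: HazardSchedule,
    schedule_event: HazardSchedule,
    from_age: float,
    to_age: float,
) -> float:
    """P(alive and event-free over [from_age, to_age]).

    exp(-integral of (h_death + h_event)); exact for piecewise-constant
    hazards — no quadrature error.
    """
    total = schedule_death.cumulative(from_age, to_age) + schedule_event.cumulative(
        from_age, to_age
    )
    return float(np.exp(-total))


def zero_schedule(sex: str, terminal_age: float = DEFAULT_TERMINAL_AGE) -> HazardSchedule:
    """A no-risk schedule over [0, terminal_age] (useful as a null hazard)."""
    return HazardSchedule(sex=sex, knots=[0.0, terminal_age], hazards=[0.0])
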