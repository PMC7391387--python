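"""Fracture-probability engine under competing mortality.

MOF incidence is imputed from hip incidence via age/sex ratio tables, a
relative-risk multiplier scales the fracture hazard, and the fracture and
death hazards are integrated jointly to 10-year or remaining-lifetime
probabilities of a *first* fracture.

Within one segment of constant hazards (f = RR * h_fracture, d = h_death)
entered with event-free mass S0, the chance the fracture happens in that
segment is  S0 * f/(f+d) * (1 - exp(-(f+d)*dt)) ;  summing segments gives
the exact integral for piecewise-constant hazards.  No excess mortality
after fracture is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from .lifetable import HazardSchedule
from .tables import BandError, RateTable, RatioTable

Horizon = Union[float, str]  # years, or "lifetime"


@dataclass(frozen=True)
class RiskProfile:
    """Multiplicative relative risk on the fracture hazard (e.g. prior fracture)."""

    relative_risk: float = 1.0
    label: str = "baseline"

    def __post_init__(self) -> None:
        if not (self.relative_risk > 0 and math.isfinite(self.relative_risk)):
            raise ValueError(f"relative_risk must be positive and finite, got {self.relative_risk}")


BASELINE = RiskProfile()


@dataclass(frozen=True)
class ProbabilityResult:
    sex: str
    start_age: float
    horizon: Horizon
    outcome: str  # "hip" or "MOF"
    probability: float
    n_segments: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


def impute_mof_incidence(hip: RateTable, rho: RatioTable) -> RateTable:
    """Band-wise MOF rate = hip rate x MOF/hip ratio; bands must coincide."""
    hip_bands = set(iter(hip))
    rho_bands = set(iter(rho))
    if hip_bands != rho_bands:
        missing = sorted(hip_bands ^ rho_bands)
        raise BandError(
            "hip and ratio tables must cover the same bands; mismatched: "
            + ", ".join(str(b) for b in missing)
        )
    return RateTable({b: hip[b] * rho[b] for b in hip})


def first_event_decomposition(
    schedule_fracture: HazardSchedule,
    schedule_death: HazardSchedule,
    start_age: float,
    horizon_years: float,
    relative_risk: float = 1.0,
) -> Tuple[float, float, float, int]:
    """(P(fracture first), P(death first), P(event-free), segment count) over the horizon.

    The three terms sum to 1 exactly (up to float error); evaluated in
    closed form per constant-hazard segment, fracture absorbing.
    """
    if horizon_years < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon_years}")
    end_age = start_age + horizon_years
    for sched in (schedule_fracture, schedule_death):
        sched._check_support(start_age)
        sched._check_support(end_age)

    cuts = np.unique(
        np.concatenate(
            [
                np.asarray(schedule_fracture.knots, dtype=float),
                np.asarray(schedule_death.knots, dtype=float),
                [start_age, end_age],
            ]
        )
    )
    cuts = cuts[(cuts >= start_age) & (cuts <= end_age)]

    p_fracture = 0.0
    p_death = 0.0
    s_free = 1.0
    n_segments = 0
    for a, b in zip(cuts[:-1], cuts[1:]):
        dt = b - a
        f = relative_risk * schedule_fracture.hazard_at(a)
        d = schedule_death.hazard_at(a)
        tot = f + d
        if tot > 0.0:
            decay = -math.expm1(-tot * dt)  # 1 - exp(-(f+d) dt), accurately
            p_fracture += s_free * (f / tot) * decay
            p_death += s_free * (d / tot) * decay
            s_free *= math.exp(-tot * dt)
        n_segments += 1
    return p_fracture, p_death, s_free, n_segments


def fracture_probability(
    schedule_fracture: HazardSchedule,
    schedule_death: HazardSchedule,
    start_age: float,
    horizon_years: float,
    profile: RiskProfile = BASELINE,
    outcome: str = "hip",
) -> ProbabilityResult:
    """Probability of a first fracture within ``horizon_years`` of ``start_age``.

    Death competes: individuals dying fracture-free no longer contribute.
    ``profile.relative_risk`` scales the fracture hazard only.
    """
    if schedule_fracture.sex != schedule_death.sex:
        raise ValueError("fracture and death schedules must be for the same sex")
    p, _, _, nseg = first_event_decomposition(
        schedule_fracture, schedule_death, start_age, horizon_years, profile.relative_risk
    )
    return ProbabilityResult(
        sex=schedule_fracture.sex,
        start_age=start_age,
        horizon=horizon_years,
        outcome=outcome,
        probability=p,
        n_segments=nseg,
    )


def lifetime_probability(
    schedule_fracture: HazardSchedule,
    schedule_death: HazardSchedule,
    start_age: float,
    profile: RiskProfile = BASELINE,
    outcome: str = "hip",
) -> ProbabilityResult:
    """Remaining-lifetime fracture probability: horizon runs to the terminal age."""
    terminal = min(schedule_fracture.terminal_age, schedule_death.terminal_age)
    if start_age >= terminal:
        raise ValueError(f"start_age {start_age} must be below the terminal age {terminal}")
    res = fracture_probability(
        schedule_fracture,
        schedule_death,
        start_age,
        terminal - start_age,
        profile,
        outcome=outcome,
    )
    return ProbabilityResult(
        sex=res.sex,
        start_age=start_age,
        horizon="lifetime",
        outcome=outcome,
        probability=res.probability,
        n_segments=res.n_segments,
    )


def probability_table(
    hip: RateTable,
    rho: RatioTable,
    mortality: RateTable,
    ages: Sequence[float],
    horizon: Horizon = 10.0,
    profile: RiskProfile = BASELINE,
    terminal_age: float = 110.0,
) -> List[ProbabilityResult]:
    """Hip and MOF probabilities for every (sex, age) requested.

    MOF hazards come from :func:`impute_mof_incidence`; one result per
    outcome x sex x age, hip first.
    """
    from .lifetable import schedule_from_rate_table

    mof = impute_mof_incidence(hip, rho)
    results: List[ProbabilityResult] = []
    for sex in hip.sexes:
        sched_d = schedule_from_rate_table(mortality, sex, terminal_age)
        for outcome, rates in (("hip", hip), ("MOF", mof)):
            sched_f = schedule_from_rate_table(rates, sex, terminal_age)
            for age in ages:
                if horizon == "lifetime":
                    results.append(
                        lifetime_probability(sched_f, sched_d, age, profile, outcome=outcome)
                    )
                else:
                    results.append(
                        fracture_probability(
                            sched_f, sched_d, age, float(horizon), profile, outcome=outcome
                        )
                    )
    return results
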