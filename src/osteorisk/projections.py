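"""Fracture-burden projection: fixed rates applied to population pyramids.

Expected counts by calendar year and sex come from holding age/sex
incidence constant and letting only demography move; Poisson uncertainty
bands are available on top of the point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .tables import AgeSexBand, BandError, RateTable


@dataclass(frozen=True)
class PopulationPyramid:
    """Persons per age/sex band in one calendar year."""

    calendar_year: int
    persons: Dict[AgeSexBand, float]

    def __post_init__(self) -> None:
        for band, v in self.persons.items():
            if v < 0:
                raise BandError(f"negative population for {band} in {self.calendar_year}")


@dataclass(frozen=True)
class ProjectionResult:
    calendar_year: int
    sex: str
    outcome: str  # "hip" or "MOF"
    expected_count: float

    def __post_init__(self) -> None:
        if self.expected_count < 0:
            raise ValueError("expected_count must be >= 0")


def project_counts(
    rates: RateTable,
    pyramids: Sequence[PopulationPyramid],
    min_age: int = 50,
    outcome: str = "hip",
) -> List[ProjectionResult]:
    """Expected fracture counts per calendar year and sex.

    count(year, sex) = sum over bands with age_lo >= min_age of
    rate(band) * persons(band, year).  Rates are per person-year; every
    pyramid band at or above ``min_age`` must be covered by ``rates``.
    """
    results: List[ProjectionResult] = []
    for pyr in pyramids:
        totals = {"male": 0.0, "female": 0.0}
        for band, persons in pyr.persons.items():
            if band.age_lo < min_age:
                continue
            if band not in rates:
                raise BandError(
                    f"rate table does not cover pyramid band {band} (year {pyr.calendar_year})"
                )
            totals[band.sex] += rates[band] * persons
        for sex in ("male", "female"):
            results.append(ProjectionResult(pyr.calendar_year, sex, outcome, totals[sex]))
    return results


def uncertainty_bands(
    result: ProjectionResult,
    n_draws: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Parametric Poisson 2.5/97.5 percentile counts around the expectation."""
    if n_draws < 100:
        raise ValueError(f"n_draws must be >= 100, got {n_draws}")
    if result.expected_count == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    draws = rng.poisson(result.expected_count, size=n_draws)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)
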