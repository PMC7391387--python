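"""Incidence estimation with exact Poisson confidence intervals.

Band-level and crude rates per 100,000 person-years, with exact (Garwood)
chi-square intervals, plus the care-pathway ascertainment breakdown.

Display convention: published rate cells were evidently rounded in two
stages (to one decimal, then half-up to integer), so :func:`display_rate`
follows that; values below 1 per 100,000 keep one decimal.  All internal
computation is unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Tuple

from scipy.stats import chi2

from .registry import SOURCES, FractureCase
from .tables import AgeSexBand, BandError, PopulationTable

PER = 100_000.0


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (banker's rounding is never wanted here)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def display_rate(x: float) -> float:
    """Round a per-100,000 figure for display.

    >= 1: half-up to one decimal, then half-up to integer (two-stage, the
    convention the published table follows); < 1: one decimal.
    """
    x = float(x)
    one_dp = round_half_up(x, 1)
    if x >= 1.0:
        return round_half_up(one_dp, 0)
    return one_dp


@dataclass(frozen=True)
class IncidenceEstimate:
    """Events, exposure and exact-CI rate for one sex x age band."""

    band: AgeSexBand
    k: int
    E: float
    rate: float  # per 100,000 person-years, unrounded
    ci_lo: float
    ci_hi: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.rate <= self.ci_hi or (self.k == 0 and self.E == 0)):
            raise ValueError(f"CI ({self.ci_lo}, {self.ci_hi}) does not bracket rate {self.rate}")


def poisson_exact_ci(k: int, E: float, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact (Garwood) Poisson CI for a rate, per 100,000 person-years.

    lo = chi2.ppf(alpha/2, 2k)/2 / E (0 when k = 0),
    hi = chi2.ppf(1 - alpha/2, 2k + 2)/2 / E;
    guarantees >= 1 - alpha coverage for any Poisson mean.
    """
    if E <= 0:
        raise ValueError(f"nonpositive exposure: {E}")
    if k != int(k) or k < 0:
        raise ValueError(f"event count must be a non-negative integer, got {k}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = int(k)
    lo = 0.0 if k == 0 else chi2.ppf(alpha / 2, 2 * k) / 2.0
    hi = chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2.0
    return lo / E * PER, hi / E * PER


def band_incidence(
    cases: Sequence[FractureCase],
    pop: PopulationTable,
    alpha: float = 0.05,
) -> List[IncidenceEstimate]:
    """Per-band event counts, exposure and exact-CI rates per 100,000.

    Every case must fall in exactly one band of ``pop``; a case outside all
    bands is an error naming its ``case_id``.  Bands with zero population
    and zero events are emitted with rate 0.
    """
    counts: Dict[AgeSexBand, int] = {b: 0 for b in pop}
    for c in cases:
        band = pop.band_for(c.sex, c.age)
        if band is None:
            raise BandError(f"case {c.case_id!r} ({c.sex}, age {c.age}) falls in no population band")
        counts[band] += 1

    out = []
    for band, E in pop.items():
        k = counts[band]
        if E == 0:
            if k:
                raise BandError(f"band {band} has {k} events but zero population")
            out.append(IncidenceEstimate(band, 0, 0.0, 0.0, 0.0, 0.0, alpha))
            continue
        lo, hi = poisson_exact_ci(k, E, alpha)
        out.append(IncidenceEstimate(band, k, float(E), PER * k / E, lo, hi, alpha))
    return out


@dataclass(frozen=True)
class CrudeIncidence:
    rate_f: float  # per 100,000, unrounded
    rate_m: float
    ratio: float  # rate_f / rate_m on unrounded rates


def crude_incidence(
    cases: Sequence[FractureCase],
    pop: PopulationTable,
    min_age: int = 40,
) -> CrudeIncidence:
    """Crude per-sex rates (per 100,000) over ages >= min_age and their F/M ratio."""
    totals = {"male": 0, "female": 0}
    for c in cases:
        band = pop.band_for(c.sex, c.age)
        if band is None:
            raise BandError(f"case {c.case_id!r} ({c.sex}, age {c.age}) falls in no population band")
        if c.age >= min_age:
            totals[c.sex] += 1

    exposure = {
        sex: sum(v for b, v in pop.items() if b.sex == sex and b.age_lo >= min_age)
        for sex in ("male", "female")
    }
    for sex in ("male", "female"):
        if exposure[sex] <= 0:
            raise ValueError(f"zero {sex} population at or above age {min_age}; rate undefined")
    rate_f = PER * totals["female"] / exposure["female"]
    rate_m = PER * totals["male"] / exposure["male"]
    if rate_m == 0:
        return CrudeIncidence(rate_f, rate_m, math.inf if rate_f > 0 else math.nan)
    return CrudeIncidence(rate_f, rate_m, rate_f / rate_m)


@dataclass(frozen=True)
class SourceShare:
    count: int
    fraction: float  # unrounded, of all eligible cases

    @property
    def percent(self) -> int:
        """Nearest-integer percent, for display only."""
        return int(round_half_up(100.0 * self.fraction, 0))


def ascertainment_breakdown(cases: Sequence[FractureCase]) -> Dict[str, SourceShare]:
    """Counts and shares of eligible cases by care-pathway source.

    All five known sources appear in the result (zero if absent); an
    unknown source label is an error.
    """
    counts = {s: 0 for s in SOURCES}
    for c in cases:
        if c.source not in counts:
            raise ValueError(f"unknown ascertainment source {c.source!r} on case {c.case_id!r}")
        counts[c.source] += 1
    n = len(cases)
    return {s: SourceShare(k, k / n if n else 0.0) for s, k in counts.items()}
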