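"""Age/sex band definitions and band-keyed tables.

Every table in the pipeline (population counts, event rates, MOF/hip
ratios, pyramid slices) is a mapping from an :class:`AgeSexBand` to a
number.  Bands are half-open intervals ``[age_lo, age_hi)``; the terminal
band of a sex may be open-ended (``age_hi is None``), e.g. "90+".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

SEXES = ("male", "female")


class BandError(ValueError):
    """Raised for malformed, overlapping or non-contiguous band sets."""


@dataclass(frozen=True, order=True)
class AgeSexBand:
    """Half-open age interval for one sex: ages in ``[age_lo, age_hi)``.

    ``age_hi=None`` marks the open-ended terminal band (e.g. 90+).
    """

    sex: str
    age_lo: int
    age_hi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise BandError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.age_lo < 0:
            raise BandError(f"age_lo must be >= 0, got {self.age_lo}")
        if self.age_hi is not None and self.age_lo >= self.age_hi:
            raise BandError(
                f"age_lo must be < age_hi for closed bands, got [{self.age_lo}, {self.age_hi})"
            )

    @property
    def is_open(self) -> bool:
        return self.age_hi is None

    def contains(self, age: int) -> bool:
        if age < self.age_lo:
            return False
        return self.age_hi is None or age < self.age_hi

    def __str__(self) -> str:
        hi = "+" if self.age_hi is None else f"-{self.age_hi - 1}"
        return f"{self.sex} {self.age_lo}{hi}"


class BandTable:
    """Mapping from :class:`AgeSexBand` to a non-negative number.

    Bands for each sex must be disjoint; contiguity is additionally
    required by :meth:`validate_contiguous` (needed before building hazard
    schedules).
    """

    value_name = "value"

    def __init__(self, values: Mapping[AgeSexBand, float]):
        self._values: Dict[AgeSexBand, float] = {}
        for band, v in values.items():
            if not isinstance(band, AgeSexBand):
                raise BandError(f"table keys must be AgeSexBand, got {band!r}")
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise BandError(f"{self.value_name} for {band} must be finite and >= 0, got {v}")
            self._values[band] = v
        for sex in self.sexes:
            self._check_disjoint(sex)

    def _check_disjoint(self, sex: str) -> None:
        bands = self.bands(sex)
        for a, b in zip(bands, bands[1:]):
            if a.age_hi is None or b.age_lo < a.age_hi:
                raise BandError(f"overlapping bands for {sex}: {a} and {b}")

    # -- mapping-ish surface -------------------------------------------------
    def __getitem__(self, band: AgeSexBand) -> float:
        return self._values[band]

    def __contains__(self, band: AgeSexBand) -> bool:
        return band in self._values

    def __len__(self) -> int:
        return len(self._values)

    def __iter__(self):
        return iter(sorted(self._values))

    def items(self) -> Iterable[Tuple[AgeSexBand, float]]:
        return ((b, self._values[b]) for b in self)

    def __eq__(self, other) -> bool:
        return isinstance(other, BandTable) and dict(self.items()) == dict(other.items())

    # -- band lookup ---------------------------------------------------------
    @property
    def sexes(self) -> List[str]:
        return [s for s in SEXES if any(b.sex == s for b in self._values)]

    def bands(self, sex: str) -> List[AgeSexBand]:
        return sorted(b for b in self._values if b.sex == sex)

    def band_for(self, sex: str, age: int) -> Optional[AgeSexBand]:
        """The unique band containing (sex, age), or None."""
        for band in self.bands(sex):
            if band.contains(age):
                return band
        return None

    def value_at(self, sex: str, age: int) -> float:
        band = self.band_for(sex, age)
        if band is None:
            raise BandError(f"no {self.value_name} band covers {sex} age {age}")
        return self._values[band]

    def sex_total(self, sex: str) -> float:
        return sum(self._values[b] for b in self.bands(sex))

    def validate_contiguous(self, sex: str) -> None:
        bands = self.bands(sex)
        if not bands:
            raise BandError(f"no bands for sex {sex!r}")
        for a, b in zip(bands, bands[1:]):
            if a.age_hi != b.age_lo:
                raise BandError(f"gap between bands for {sex}: {a} then {b}")

    def map_values(self, fn) -> "BandTable":
        return type(self)({b: fn(v) for b, v in self.items()})


class PopulationTable(BandTable):
    """Person counts per band, read as person-years over a 1-year window."""

    value_name = "population"


class RateTable(BandTable):
    """Event rates per person-year (fracture incidence or mortality)."""

    value_name = "rate"


class RatioTable(BandTable):
    """Dimensionless MOF/hip incidence ratios; must be >= 1 everywhere."""

    value_name = "ratio"

    def __init__(self, values: Mapping[AgeSexBand, float]):
        super().__init__(values)
        for band, rho in self.items():
            if rho < 1.0:
                raise BandError(f"ratio for {band} must be >= 1 (MOF includes hip), got {rho}")


def five_year_bands(sex: str, start: int = 40, stop: int = 90) -> List[AgeSexBand]:
    """Standard 5-year bands from ``start`` with an open terminal band at ``stop``."""
    bands = [AgeSexBand(sex, lo, lo + 5) for lo in range(start, stop, 5)]
    bands.append(AgeSexBand(sex, stop, None))
    return bands
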