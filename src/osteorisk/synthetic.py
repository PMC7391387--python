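"""Synthetic registries with known ground truth, and the packaged district fixture.

The district fixture reconstructs the published one-year catchment
registry from its printed marginals: per-band event counts, per-band
population, and care-pathway source totals (47 inpatient, 37 outpatient,
41 primary-care, 15 community — the 26%/29% outpatient/primary-care shares
of 140 are non-integer, so 37/41 is the documented deterministic split).
Twelve labelled decoy records exercise every eligibility filter.

:func:`simulate_registry` is the parameter-recovery harness: band counts
are Poisson around rate x exposure, ages uniform within band, sources
multinomial, with optional decoys (including planted duplicates).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .registry import CASE_FIELD_NAMES, SOURCES, FractureCase
from .tables import AgeSexBand, BandError, PopulationTable, RateTable, five_year_bands

STUDY_WINDOW = (dt.date(2016, 4, 1), dt.date(2017, 3, 31))

# Printed per-band marginals of the district registry (ages 40+, 5-year
# bands, terminal 90+): population at risk and one-year fracture counts.
_BAND_STARTS = list(range(40, 90, 5)) + [90]
_POP = {
    "male": [7480, 6312, 5984, 4984, 3552, 1704, 1104, 912, 480, 216, 56],
    "female": [7760, 6768, 6632, 5536, 3968, 2064, 1344, 1208, 752, 400, 168],
}
_EVENTS = {
    "male": [2, 3, 2, 5, 6, 8, 6, 7, 7, 5, 1],
    "female": [1, 4, 4, 8, 7, 13, 9, 12, 13, 11, 6],
}
# Care-pathway totals over the 140 eligible cases.
_SOURCE_TOTALS = {"inpatient": 47, "outpatient": 37, "primary_care": 41, "coroner": 0, "community": 15}
_N_RADIOGRAPH = 125  # 89% of 140, rounded
_FIXTURE_SEED = 20160401

CASE_COLUMNS = list(CASE_FIELD_NAMES)


def district_population() -> PopulationTable:
    """The catchment population by sex and 5-year band (32,784 men, 36,600 women)."""
    values = {}
    for sex in ("male", "female"):
        for band, n in zip(five_year_bands(sex), _POP[sex]):
            values[band] = n
    return PopulationTable(values)


def _case_row(case: FractureCase, decoy: str = "") -> dict:
    row = {c: getattr(case, c) for c in CASE_COLUMNS}
    row["event_date"] = case.event_date.isoformat()
    row["decoy"] = decoy
    return row


def make_district_fixture() -> Tuple[pd.DataFrame, PopulationTable]:
    """Deterministic reconstruction of the district registry plus 12 decoys.

    Returns the raw cases table (140 eligible + 4 high-energy + 3
    non-resident + 2 pathological + 3 out-of-window decoys, flagged in the
    hidden ``decoy`` column) and the catchment population table.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    start, end = STUDY_WINDOW
    n_days = (end - start).days + 1

    cases: List[FractureCase] = []
    i = 0
    for sex in ("male", "female"):
        for lo, k in zip(_BAND_STARTS, _EVENTS[sex]):
            hi = lo + 5 if lo < 90 else 100
            for _ in range(k):
                i += 1
                cases.append(
                    FractureCase(
                        case_id=f"D{i:04d}",
                        person_key=f"P{i:04d}",
                        age=int(rng.integers(lo, hi)),
                        sex=sex,
                        event_date=start + dt.timedelta(days=int(rng.integers(0, n_days))),
                        site_code="S72.0",  # refined below
                        source="inpatient",  # refined below
                    )
                )
    assert len(cases) == 140

    # Deterministic source allocation matching the printed pathway totals.
    labels: List[str] = []
    for src, n in _SOURCE_TOTALS.items():
        labels.extend([src] * n)
    order = rng.permutation(len(labels))
    sources = [labels[j] for j in order]

    # 125 radiograph-confirmed, 15 clinically verified only; unspecified
    # site codes are allowed only on radiograph-confirmed records.
    radiograph = np.zeros(140, dtype=bool)
    radiograph[rng.choice(140, size=_N_RADIOGRAPH, replace=False)] = True
    site_cycle = ["S72.0", "S72.1", "S72.2"]
    rows = []
    for j, c in enumerate(cases):
        site = site_cycle[j % 3]
        if radiograph[j] and j % 10 == 0:
            site = "unspecified"  # code missing on the form, fracture verified on film
        c2 = FractureCase(
            case_id=c.case_id,
            person_key=c.person_key,
            age=c.age,
            sex=c.sex,
            event_date=c.event_date,
            site_code=site,
            source=sources[j],
            radiograph_confirmed=bool(radiograph[j]),
        )
        rows.append(_case_row(c2))

    rows.extend(_decoy_rows(rng))
    frame = pd.DataFrame(rows, columns=CASE_COLUMNS + ["decoy"])
    return frame, district_population()


def _decoy_rows(rng: np.random.Generator) -> List[dict]:
    start, end = STUDY_WINDOW
    mid = start + dt.timedelta(days=180)
    decoys = []

    def add(kind: str, **kw):
        i = len(decoys) + 1
        base = dict(
            case_id=f"X{i:03d}",
            person_key=f"XP{i:03d}",
            age=int(rng.integers(60, 85)),
            sex="female" if i % 2 else "male",
            event_date=mid,
            site_code="S72.1",
            energy="low",
            resident=True,
            pathological=False,
            source="inpatient",
            radiograph_confirmed=True,
        )
        base.update(kw)
        decoys.append(_case_row(FractureCase(**base), decoy=kind))

    for _ in range(4):
        add("high_energy", energy="high")
    for _ in range(3):
        add("non_resident", resident=False)
    for _ in range(2):
        add("pathological", pathological=True)
    for d in (-30, -90, 400):
        add("out_of_window", event_date=start + dt.timedelta(days=d))
    return decoys


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for registry simulation.

    ``fracture_rates`` are per person-year; ``source_probs`` must sum to 1;
    ``decoy_counts`` may include high_energy, non_resident, pathological,
    out_of_window and duplicate.
    """

    fracture_rates: RateTable
    death_rates: Optional[RateTable] = None
    source_probs: Dict[str, float] = field(
        default_factory=lambda: {k: v / 140 for k, v in _SOURCE_TOTALS.items()}
    )
    decoy_counts: Dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.source_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"source probabilities must sum to 1, got {total}")
        unknown = set(self.source_probs) - set(SOURCES)
        if unknown:
            raise ValueError(f"unknown sources in source_probs: {sorted(unknown)}")


def simulate_registry(
    truth: SyntheticTruth,
    pop: PopulationTable,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw a one-year registry: Poisson counts per band, uniform ages within band.

    Fully reproducible under ``seed`` (defaults to ``truth.seed``); decoys
    are appended per ``truth.decoy_counts`` and flagged in the ``decoy``
    column.  Planted duplicates re-report an existing case at a later date.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    start, end = STUDY_WINDOW
    n_days = (end - start).days + 1
    src_names = sorted(truth.source_probs)
    src_p = np.array([truth.source_probs[s] for s in src_names])

    rows: List[dict] = []
    i = 0
    for band, persons in pop.items():
        if band not in truth.fracture_rates:
            raise BandError(f"truth rates do not cover population band {band}")
        lam = truth.fracture_rates[band] * persons
        k = int(rng.poisson(lam))
        hi = band.age_hi if band.age_hi is not None else band.age_lo + 10
        for _ in range(k):
            i += 1
            rows.append(
                _case_row(
                    FractureCase(
                        case_id=f"S{i:06d}",
                        person_key=f"SP{i:06d}",
                        age=int(rng.integers(band.age_lo, hi)),
                        sex=band.sex,
                        event_date=start + dt.timedelta(days=int(rng.integers(0, n_days))),
                        site_code=("S72.0", "S72.1", "S72.2")[int(rng.integers(0, 3))],
                        source=src_names[int(rng.choice(len(src_names), p=src_p))],
                    )
                )
            )

    frame = pd.DataFrame(rows, columns=CASE_COLUMNS + ["decoy"])
    decoy_rows = _simulated_decoys(truth.decoy_counts, frame, rng)
    if decoy_rows:
        frame = pd.concat([frame, pd.DataFrame(decoy_rows)], ignore_index=True)
    return frame


def _simulated_decoys(
    counts: Dict[str, int], eligible: pd.DataFrame, rng: np.random.Generator
) -> List[dict]:
    start, _ = STUDY_WINDOW
    rows: List[dict] = []
    j = 0
    overrides = {
        "high_energy": {"energy": "high"},
        "non_resident": {"resident": False},
        "pathological": {"pathological": True},
        "out_of_window": {"event_date": (start - dt.timedelta(days=60)).isoformat()},
    }
    for kind, n in counts.items():
        if kind == "duplicate":
            continue
        if kind not in overrides:
            raise ValueError(f"unknown decoy kind {kind!r}")
        for _ in range(n):
            j += 1
            rows.append(
                {
                    "case_id": f"SX{j:05d}",
                    "person_key": f"SXP{j:05d}",
                    "age": int(rng.integers(60, 85)),
                    "sex": ("male", "female")[j % 2],
                    "event_date": (start + dt.timedelta(days=100)).isoformat(),
                    "site_code": "S72.0",
                    "energy": "low",
                    "resident": True,
                    "pathological": False,
                    "source": "inpatient",
                    "radiograph_confirmed": True,
                    "decoy": kind,
                    **overrides[kind],
                }
            )
    n_dup = counts.get("duplicate", 0)
    if n_dup:
        if len(eligible) == 0:
            raise ValueError("cannot plant duplicates in an empty registry")
        picks = rng.choice(len(eligible), size=n_dup, replace=n_dup > len(eligible))
        for idx in np.asarray(picks).ravel():
            j += 1
            orig = eligible.iloc[int(idx)]
            later = min(
                dt.date.fromisoformat(orig["event_date"]) + dt.timedelta(days=14), STUDY_WINDOW[1]
            )
            row = orig.to_dict()
            row.update(
                {
                    "case_id": f"SX{j:05d}",
                    "event_date": later.isoformat(),
                    "radiograph_confirmed": False if orig["site_code"] != "unspecified" else True,
                    "decoy": "duplicate",
                }
            )
            rows.append(row)
    return rows


def simulate_mortality(
    model: str,
    params: Dict[str, float],
    bands: List[AgeSexBand],
) -> RateTable:
    """Band-level all-cause mortality from a parametric hazard.

    ``constant``: rate everywhere.  ``gompertz``: a * exp(b * age) at the
    band midpoint; the open terminal band is evaluated at its lower bound
    plus 5 years.
    """
    def midpoint(band: AgeSexBand) -> float:
        if band.age_hi is None:
            return band.age_lo + 5.0
        return (band.age_lo + band.age_hi) / 2.0

    if model == "constant":
        rate = params.get("rate")
        if rate is None or rate < 0:
            raise ValueError("constant model needs a 'rate' >= 0")
        return RateTable({b: rate for b in bands})
    if model == "gompertz":
        a, b = params.get("a"), params.get("b")
        if a is None or a <= 0 or b is None:
            raise ValueError("gompertz model needs base rate a > 0 and log-slope b")
        return RateTable({band: a * float(np.exp(b * midpoint(band))) for band in bands})
    raise ValueError(f"unknown mortality model {model!r}")
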