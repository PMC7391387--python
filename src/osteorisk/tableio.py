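"""CSV schemas, validated readers and writers for every pipeline table.

All interchange is plain UTF-8 CSV with headers.  ``read_table`` does the
shared work: required columns, type coercion with row-numbered errors, and
preservation (with a log warning) of unknown columns such as the synthetic
``decoy`` flag.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .frax import ProbabilityResult
from .incidence import IncidenceEstimate, display_rate
from .projections import PopulationPyramid, ProjectionResult
from .registry import CASE_FIELD_NAMES, FilterReport, FractureCase
from .tables import AgeSexBand, PopulationTable, RateTable, RatioTable

log = logging.getLogger("osteorisk")

PathLike = Union[str, Path]


class SchemaError(ValueError):
    pass


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _parse_date(v) -> dt.date:
    return dt.date.fromisoformat(str(v).strip())


def _parse_open_int(v) -> Optional[int]:
    """Integer or empty (= open-ended age bound)."""
    if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
        return None
    return int(float(v))


#: column name -> converter; None means keep as stripped string.
CASES_SCHEMA: Dict[str, object] = {
    "case_id": None,
    "person_key": None,
    "age": int,
    "sex": None,
    "event_date": _parse_date,
    "site_code": None,
    "energy": None,
    "resident": _parse_bool,
    "pathological": _parse_bool,
    "source": None,
    "radiograph_confirmed": _parse_bool,
}
POPULATION_SCHEMA = {"sex": None, "age_lo": int, "age_hi": _parse_open_int, "count": float}
RATE_SCHEMA = {"sex": None, "age_lo": int, "age_hi": _parse_open_int, "rate": float, "units": None}
RATIO_SCHEMA = {"sex": None, "age_lo": int, "age_hi": _parse_open_int, "rho": float}
PYRAMID_SCHEMA = {
    "calendar_year": int,
    "sex": None,
    "age_lo": int,
    "age_hi": _parse_open_int,
    "persons": float,
}


def read_table(path: PathLike, schema: Dict[str, object]) -> pd.DataFrame:
    """Read a CSV and coerce it to ``schema``.

    Missing required columns raise naming the column; a cell that fails
    coercion raises with its (1-based, header-inclusive) row number.
    Unknown columns are preserved but flagged in the log.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    extra = [c for c in frame.columns if c not in schema]
    if extra:
        log.warning("%s: unknown column(s) %s preserved but not validated", path.name, extra)

    out = {}
    for col, conv in schema.items():
        if conv is None:
            out[col] = frame[col].astype(str).str.strip()
            continue
        values = []
        for i, raw in enumerate(frame[col]):
            try:
                values.append(conv(raw))
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path.name} row {i + 2}, column {col!r}: {exc}") from exc
        out[col] = values
    result = pd.DataFrame(out, index=frame.index)
    for col in extra:
        result[col] = frame[col]
    log.info("%s: read %d rows x %d columns", path.name, len(result), len(result.columns))
    return result


# -- cases --------------------------------------------------------------------

def cases_from_frame(frame: pd.DataFrame) -> List[FractureCase]:
    cols = [frame[name].tolist() for name in CASE_FIELD_NAMES]
    cases = []
    for case_id, person_key, age, sex, event_date, site, energy, resident, patho, source, radio in zip(
        *cols
    ):
        if age is None or (isinstance(age, str) and age == "") or (isinstance(age, float) and pd.isna(age)):
            age = None
        else:
            age = int(age)
        if sex not in ("male", "female"):
            sex = None
        if isinstance(event_date, str):
            event_date = _parse_date(event_date)
        cases.append(
            FractureCase(
                case_id=case_id,
                person_key=person_key,
                age=age,
                sex=sex,
                event_date=event_date,
                site_code=site,
                energy=energy,
                resident=bool(resident) if not isinstance(resident, str) else _parse_bool(resident),
                pathological=bool(patho) if not isinstance(patho, str) else _parse_bool(patho),
                source=source,
                radiograph_confirmed=bool(radio) if not isinstance(radio, str) else _parse_bool(radio),
            )
        )
    return cases


def read_cases(path: PathLike) -> List[FractureCase]:
    # tolerant on sex/age so malformed rows surface as filter rejections,
    # not parse failures
    schema = dict(CASES_SCHEMA)
    schema["age"] = _parse_open_int
    schema["sex"] = None
    return cases_from_frame(read_table(path, schema))


def write_cases(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, index=False)


# -- band tables --------------------------------------------------------------

def _age_hi(v) -> Optional[int]:
    # None becomes NaN inside a numeric DataFrame column; both mean "open"
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return int(v)


def _bands_from_frame(frame: pd.DataFrame, value_col: str) -> Dict[AgeSexBand, float]:
    return {
        AgeSexBand(row["sex"], int(row["age_lo"]), _age_hi(row["age_hi"])): float(row[value_col])
        for _, row in frame.iterrows()
    }


def read_population(path: PathLike) -> PopulationTable:
    return PopulationTable(_bands_from_frame(read_table(path, POPULATION_SCHEMA), "count"))


def read_rate_table(path: PathLike) -> RateTable:
    """Rate CSV; the ``units`` column is per_person_year or per_100k."""
    frame = read_table(path, RATE_SCHEMA)
    values = {}
    for _, row in frame.iterrows():
        rate = float(row["rate"])
        units = row["units"]
        if units == "per_100k":
            rate /= 100_000.0
        elif units != "per_person_year":
            raise SchemaError(f"unknown rate units {units!r} (per_person_year or per_100k)")
        values[AgeSexBand(row["sex"], int(row["age_lo"]), _age_hi(row["age_hi"]))] = rate
    return RateTable(values)


def read_ratio_table(path: PathLike) -> RatioTable:
    return RatioTable(_bands_from_frame(read_table(path, RATIO_SCHEMA), "rho"))


def read_pyramids(path: PathLike) -> List[PopulationPyramid]:
    frame = read_table(path, PYRAMID_SCHEMA)
    pyramids = []
    for year, grp in frame.groupby("calendar_year"):
        pyramids.append(PopulationPyramid(int(year), _bands_from_frame(grp, "persons")))
    return sorted(pyramids, key=lambda p: p.calendar_year)


def _band_cols(band: AgeSexBand) -> dict:
    return {
        "sex": band.sex,
        "age_lo": band.age_lo,
        "age_hi": "" if band.age_hi is None else band.age_hi,
    }


def write_rate_table(rt: RateTable, path: PathLike, units: str = "per_person_year") -> None:
    rows = []
    for band, rate in rt.items():
        value = rate * 100_000.0 if units == "per_100k" else rate
        rows.append({**_band_cols(band), "rate": value, "units": units})
    pd.DataFrame(rows).to_csv(path, index=False)


# -- results ------------------------------------------------------------------

def incidence_frame(estimates: Sequence[IncidenceEstimate]) -> pd.DataFrame:
    """Published-table-style layout with display-rounded rate and CI columns."""
    rows = []
    for e in estimates:
        rows.append(
            {
                **_band_cols(e.band),
                "population": int(e.E),
                "events": e.k,
                "rate_per_100k": display_rate(e.rate),
                "ci_lo": display_rate(e.ci_lo),
                "ci_hi": display_rate(e.ci_hi),
                "rate_raw": e.rate,
                "ci_lo_raw": e.ci_lo,
                "ci_hi_raw": e.ci_hi,
            }
        )
    return pd.DataFrame(rows)


def write_incidence(estimates: Sequence[IncidenceEstimate], path: PathLike) -> None:
    incidence_frame(estimates).to_csv(path, index=False)


def write_filter_report(report: FilterReport, path: PathLike, removals_path: PathLike) -> None:
    pd.DataFrame(
        [{"filter": "input", "remaining": report.n_input}]
        + [{"filter": f, "remaining": n} for f, n in report.n_after_each_filter]
    ).to_csv(path, index=False)
    pd.DataFrame(report.removed, columns=["case_id", "reason"]).to_csv(removals_path, index=False)


def probability_frame(results: Sequence[ProbabilityResult], relative_risk: float) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "sex": r.sex,
                "age": r.start_age,
                "outcome": r.outcome,
                "horizon": r.horizon,
                "rr": relative_risk,
                "probability": r.probability,
                "probability_pct": round(100.0 * r.probability, 1),
            }
        )
    return pd.DataFrame(rows)


def write_probabilities(
    results: Sequence[ProbabilityResult], relative_risk: float, path: PathLike
) -> None:
    probability_frame(results, relative_risk).to_csv(path, index=False)


def write_projections(results: Sequence[ProjectionResult], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "calendar_year": r.calendar_year,
                "sex": r.sex,
                "outcome": r.outcome,
                "expected_count": r.expected_count,
            }
            for r in results
        ]
    ).to_csv(path, index=False)
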