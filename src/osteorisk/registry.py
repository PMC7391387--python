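"""Case registry model, eligibility filters and deduplication.

Raw reports from the multi-source surveillance (hospital, outpatient
trauma, primary care, coroner, community informants) are reduced to
countable low-energy hip fractures: malformed records are rejected, then
window / residence / age / energy / pathological exclusions are applied in
a fixed order so each removal carries exactly one reason, and repeat
reports of the same fracture site for the same person are collapsed onto
the earliest record.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

SITE_CODES = ("S72.0", "S72.1", "S72.2", "unspecified")
SOURCES = ("inpatient", "outpatient", "primary_care", "coroner", "community")
ENERGIES = ("low", "high")

#: Canonical column order for case CSVs.
CASE_FIELD_NAMES = (
    "case_id",
    "person_key",
    "age",
    "sex",
    "event_date",
    "site_code",
    "energy",
    "resident",
    "pathological",
    "source",
    "radiograph_confirmed",
)

#: Fixed attribution order for eligibility filtering.  Any order yields the
#: same surviving set; the order only decides which single reason a doubly
#: excludable record is logged under.
FILTER_ORDER = ("window", "residence", "age", "energy", "pathological")


@dataclass(frozen=True)
class FractureCase:
    """One suspected fracture event with its eligibility attributes.

    ``sex`` or ``age`` may be ``None`` for malformed source rows; such rows
    are rejected (reason "malformed") rather than raising at construction.
    """

    case_id: str
    person_key: str
    age: Optional[int]
    sex: Optional[str]
    event_date: dt.date
    site_code: str = "unspecified"
    energy: str = "low"
    resident: bool = True
    pathological: bool = False
    source: str = "inpatient"
    radiograph_confirmed: bool = True

    def problems(self) -> List[str]:
        """Validation findings that make the record malformed."""
        out = []
        if self.sex not in ("male", "female"):
            out.append("missing or invalid sex")
        if self.age is None or self.age < 0:
            out.append("missing or negative age")
        if self.site_code not in SITE_CODES:
            out.append(f"unknown site code {self.site_code!r}")
        if self.site_code == "unspecified" and not self.radiograph_confirmed:
            out.append("site unspecified without radiograph confirmation")
        if self.source not in SOURCES:
            out.append(f"unknown source {self.source!r}")
        if self.energy not in ENERGIES:
            out.append(f"unknown energy {self.energy!r}")
        return out


@dataclass
class FilterReport:
    """Audit trail of a filtering pass.

    ``n_after_each_filter`` is the remaining count after each named stage,
    in application order; ``removed`` logs one (case_id, reason) per
    excluded record.  ``n_input == n_eligible + len(removed)`` always.
    """

    n_input: int = 0
    n_after_each_filter: List[Tuple[str, int]] = field(default_factory=list)
    n_eligible: int = 0
    removed: List[Tuple[str, str]] = field(default_factory=list)

    def check(self) -> None:
        counts = [self.n_input] + [n for _, n in self.n_after_each_filter]
        for a, b in zip(counts, counts[1:]):
            if b > a:
                raise AssertionError("filter counts must be non-increasing")
        if self.n_after_each_filter and self.n_after_each_filter[-1][1] != self.n_eligible:
            raise AssertionError("n_eligible must equal the final stage count")
        if self.n_input != self.n_eligible + len(self.removed):
            raise AssertionError("n_input != n_eligible + removals")


DateWindow = Tuple[dt.date, dt.date]


def apply_eligibility_filters(
    cases: Sequence[FractureCase],
    window: DateWindow,
    min_age: int = 40,
) -> Tuple[List[FractureCase], FilterReport]:
    """Reduce raw reports to eligible low-energy hip fractures.

    Surviving cases have ``energy='low'``, ``resident=True``,
    ``pathological=False``, ``age >= min_age`` and ``event_date`` inside the
    inclusive ``window``.  Malformed records (missing sex/age, unknown
    codes) are rejected first with reason ``"malformed"``; the remaining
    exclusions are applied in :data:`FILTER_ORDER` so each removal has one
    primary reason.
    """
    start, end = window
    if start > end:
        raise ValueError(f"invalid window: {start} > {end}")
    if min_age < 0:
        raise ValueError(f"min_age must be >= 0, got {min_age}")

    report = FilterReport(n_input=len(cases))

    kept: List[FractureCase] = []
    for c in cases:
        if c.problems():
            report.removed.append((c.case_id, "malformed"))
        else:
            kept.append(c)
    report.n_after_each_filter.append(("malformed", len(kept)))

    predicates = {
        "window": lambda c: start <= c.event_date <= end,
        "residence": lambda c: c.resident,
        "age": lambda c: c.age >= min_age,
        "energy": lambda c: c.energy == "low",
        "pathological": lambda c: not c.pathological,
    }
    for name in FILTER_ORDER:
        keep = predicates[name]
        passed = []
        for c in kept:
            if keep(c):
                passed.append(c)
            else:
                report.removed.append((c.case_id, name))
        kept = passed
        report.n_after_each_filter.append((name, len(kept)))

    report.n_eligible = len(kept)
    report.check()
    return kept, report


def deduplicate(cases: Sequence[FractureCase]) -> Tuple[List[FractureCase], FilterReport]:
    """Collapse repeat reports of the same fracture onto one record.

    Within each (person_key, site_code) group the earliest ``event_date``
    wins; date ties prefer the radiograph-confirmed record, then the
    lexicographically smallest ``case_id``.  Distinct site codes for the
    same person count as distinct fractures and are all retained.
    """
    report = FilterReport(n_input=len(cases))

    groups: Dict[Tuple[str, str], List[FractureCase]] = {}
    for c in cases:
        groups.setdefault((c.person_key, c.site_code), []).append(c)

    keep_ids = set()
    for group in groups.values():
        best = min(group, key=lambda c: (c.event_date, not c.radiograph_confirmed, c.case_id))
        keep_ids.add(best.case_id)

    kept = [c for c in cases if c.case_id in keep_ids]
    report.removed = [(c.case_id, "duplicate") for c in cases if c.case_id not in keep_ids]
    report.n_after_each_filter.append(("duplicate", len(kept)))
    report.n_eligible = len(kept)
    report.check()
    return kept, report
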