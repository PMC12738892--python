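"""Target-drug cohort extraction, report characteristics and time to onset.

A cohort is the set of deduplicated cases in which the target drug appears
with role code "primary suspect" (PS).  The module tabulates the standard
descriptive breakdown of such a cohort (sex, age, weight, outcome, reporter,
report year, time to onset, daily dose — each with a "Not specified" band)
and computes time to onset (TTO) as EVENT_DT minus the earliest START_DT of
the target drug, excluding cases with missing or imprecise dates or an
onset not strictly after therapy initiation.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

from .ingest import CaseRecord

logger = logging.getLogger(__name__)

NOT_SPECIFIED = "Not specified"

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention to prevent permanent impairment/Damage",
    "OT": "Other serious (important medical event)",
}

REPORTER_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "HP": "Other health - professional",
    "OT": "Other health - professional",
    "LW": "Lawyer",
    "CN": "Consumer",
}

_AGE_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.1775,
              "DY": 1 / 365.25, "HR": 1 / 8766.0, "": 1.0}


@dataclass(frozen=True)
class DrugQuery:
    """A target drug: canonical name plus brand/generic synonyms, matched
    case-insensitively as substrings of DRUGNAME / PROD_AI by default."""

    name: str
    synonyms: tuple[str, ...]
    match: Literal["exact", "substring"] = "substring"

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError("DrugQuery needs at least one synonym")

    def matches(self, drugname: str, prod_ai: str = "") -> bool:
        hay = [" ".join(drugname.split()).lower(), " ".join(prod_ai.split()).lower()]
        for syn in self.synonyms:
            s = " ".join(syn.split()).lower()
            if self.match == "exact":
                if s in hay:
                    return True
            elif any(s in h for h in hay if h):
                return True
        return False


@dataclass
class Cohort:
    drug: str
    cases: list[CaseRecord]
    #: (caseid, PT) pairs, one per distinct PT per case.
    events: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cases)


def extract_cohort(cases: Sequence[CaseRecord], query: DrugQuery) -> Cohort:
    """Cases where >=1 drug entry matches the query at role PS; each case
    contributes all its reaction PTs (deduplicated within the case)."""
    members = []
    events = []
    for c in cases:
        if any(
            d.role_cod == "PS" and query.matches(d.drugname, d.prod_ai)
            for d in c.drugs
        ):
            members.append(c)
            seen = set()
            for pt in c.reactions:
                key = " ".join(pt.split()).lower()
                if key and key not in seen:
                    seen.add(key)
                    events.append((c.caseid, pt.strip()))
    if not members:
        logger.warning("empty cohort for drug %r", query.name)
    return Cohort(query.name, members, events)


def background_events(
    cases: Sequence[CaseRecord], query: DrugQuery
) -> list[tuple[str, str]]:
    """Events of every case that is NOT in the target cohort (the full-database
    comparator).  To exclude a second drug's cohort as well, filter `cases`
    first."""
    out = []
    for c in cases:
        if any(
            d.role_cod == "PS" and query.matches(d.drugname, d.prod_ai)
            for d in c.drugs
        ):
            continue
        seen = set()
        for pt in c.reactions:
            key = " ".join(pt.split()).lower()
            if key and key not in seen:
                seen.add(key)
                out.append((c.caseid, pt.strip()))
    return out


# ---------------------------------------------------------------- dates

def parse_date(s: str) -> tuple[int | None, int | None, int | None]:
    """Split a FAERS digit-string date into (year, month, day); components
    missing from truncated strings are None.  Never imputes."""
    s = (s or "").strip()
    if not s.isdigit():
        return None, None, None
    y = int(s[:4]) if len(s) >= 4 else None
    m = int(s[4:6]) if len(s) >= 6 else None
    d = int(s[6:8]) if len(s) >= 8 else None
    return y, m, d


def _full_date(s: str) -> _dt.date | None:
    y, m, d = parse_date(s)
    if y is None or m is None or d is None:
        return None
    try:
        return _dt.date(y, m, d)
    except ValueError:
        return None


@dataclass(frozen=True)
class TtoRecord:
    caseid: str
    start_dt: _dt.date
    event_dt: _dt.date
    tto_days: int


def compute_tto(
    cohort: Cohort, strict: bool = True
) -> tuple[list[TtoRecord], dict[str, int]]:
    """Time to onset per cohort case, with an exclusion tally.

    Uses the earliest fully-specified START_DT among the case's matching
    primary-suspect drug entries.  Exclusion reasons:

    * ``missing date`` — EVENT_DT or every START_DT empty;
    * ``imprecise date`` — a date present but truncated (no day or month);
    * ``onset not after initiation`` — EVENT_DT <= START_DT (``strict=False``
      relaxes to EVENT_DT < START_DT, admitting 0-day onsets).
    """
    records = []
    tally = {"missing date": 0, "imprecise date": 0, "onset not after initiation": 0}
    for c in cohort.cases:
        starts_raw = [d.start_dt for d in c.drugs if d.role_cod == "PS" and d.start_dt]
        if not c.event_dt or not starts_raw:
            tally["missing date"] += 1
            continue
        event = _full_date(c.event_dt)
        starts = [_full_date(s) for s in starts_raw]
        if event is None or any(s is None for s in starts):
            tally["imprecise date"] += 1
            continue
        start = min(starts)  # earliest initiation among therapy rows
        delta = (event - start).days
        if delta < 1 if strict else delta < 0:
            tally["onset not after initiation"] += 1
            continue
        records.append(TtoRecord(c.caseid, start, event, delta))
    return records, tally


# ---------------------------------------------------------------- dose

_DOSE_RE = re.compile(
    r"(?P<amount>\d+(?:\.\d+)?)\s*(?P<unit>MG|MILLIGRAM[S]?|G|GRAM[S]?)\b",
    re.IGNORECASE,
)
_FREQ = {
    "QD": 1, "QAM": 1, "QPM": 1, "QHS": 1, "DAILY": 1, "OD": 1,
    "BID": 2, "TID": 3, "QID": 4,
}


def parse_dose(dose_text: str) -> float | None:
    """Daily dose in mg from FAERS free text (e.g. ``"25 MG, BID"`` -> 50.0);
    None when amount, unit or frequency do not parse.  A bare amount+unit
    with no frequency token is read as once daily."""
    text = (dose_text or "").strip()
    m = _DOSE_RE.search(text)
    if not m:
        return None
    amount = float(m.group("amount"))
    if m.group("unit").upper().startswith("G"):
        amount *= 1000.0
    freq = 1
    tokens = re.split(r"[\s,;/]+", text.upper())
    for tok in tokens:
        if tok in _FREQ:
            freq = _FREQ[tok]
            break
        if tok in {"UNK", "UNKNOWN"}:
            return None
    return amount * freq


# ---------------------------------------------------------------- bands

def _age_years(age: str, age_cod: str) -> float | None:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return None
    factor = _AGE_YEARS.get(age_cod.upper())
    return v * factor if factor is not None else None


def _weight_kg(wt: str, wt_cod: str) -> float | None:
    try:
        v = float(wt)
    except (TypeError, ValueError):
        return None
    cod = wt_cod.upper()
    if cod in {"", "KG", "KGS"}:
        return v
    if cod in {"LBS", "LB"}:
        return v * 0.45359237
    return None


def age_band(age: str, age_cod: str) -> str:
    y = _age_years(age, age_cod)
    if y is None:
        return NOT_SPECIFIED
    if y < 18:
        return "<18"
    if y < 65:
        return "18-64"
    return ">=65"


def weight_band(wt: str, wt_cod: str) -> str:
    kg = _weight_kg(wt, wt_cod)
    if kg is None:
        return NOT_SPECIFIED
    if kg <= 50:
        return "<=50"
    if kg <= 100:
        return "51-100"
    return ">100"


def tto_band(days: int | None) -> str:
    if days is None:
        return NOT_SPECIFIED
    if days <= 30:
        return "<=30"
    if days <= 180:
        return "31-180"
    if days <= 360:
        return "181-360"
    return ">=361"


def dose_band(mg_per_day: float | None) -> str:
    if mg_per_day is None:
        return NOT_SPECIFIED
    if mg_per_day <= 20:
        return "<=20"
    if mg_per_day <= 50:
        return "21-50"
    if mg_per_day <= 100:
        return "51-100"
    if mg_per_day <= 200:
        return "101-200"
    return ">=201"


def percentage(count: int, total: int) -> float:
    """100*count/total rounded half-up to two decimals (the convention used
    in published characteristics tables)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class CharacteristicsTable:
    """Per-dimension {category: count} breakdowns of one cohort.

    Every dimension except ``outcome`` partitions the cohort (counts sum to
    ``n_cases``); outcome counts may overlap because a case carries each
    outcome code it reports.
    """

    drug: str
    n_cases: int
    n_events: int
    sex: dict[str, int]
    age: dict[str, int]
    weight: dict[str, int]
    outcome: dict[str, int]
    reporter: dict[str, int]
    report_year: dict[str, int]
    tto: dict[str, int]
    dose: dict[str, int]

    def percentages(self, dimension: str) -> dict[str, float]:
        counts: dict[str, int] = getattr(self, dimension)
        return {k: percentage(v, self.n_cases) for k, v in counts.items()}


def _count(values: Iterable[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return out


def tabulate_characteristics(
    cohort: Cohort, worst_outcome_only: bool = False
) -> CharacteristicsTable:
    """Descriptive breakdown of a cohort, one case per band per dimension
    (outcome excepted — see class docstring; ``worst_outcome_only`` keeps a
    single code per case in DE > LT > HO > DS > CA > RI > OT order)."""
    sexes, ages, weights, reporters, years, ttos, doses = [], [], [], [], [], [], []
    outcome: dict[str, int] = {}
    tto_by_case = {r.caseid: r.tto_days for r in compute_tto(cohort)[0]}
    severity = list(OUTCOME_LABELS)
    for c in cohort.cases:
        sexes.append({"F": "Female", "M": "Male"}.get(c.sex, NOT_SPECIFIED))
        ages.append(age_band(c.age, c.age_cod))
        weights.append(weight_band(c.wt, c.wt_cod))
        reporters.append(REPORTER_LABELS.get(c.occp_cod, NOT_SPECIFIED))
        y, _, _ = parse_date(c.fda_dt)
        years.append(str(y) if y else NOT_SPECIFIED)
        ttos.append(tto_band(tto_by_case.get(c.caseid)))
        dose_texts = [d.dose_text for d in c.drugs if d.role_cod == "PS"]
        doses.append(dose_band(parse_dose(dose_texts[0]) if dose_texts else None))
        codes = [o for o in c.outcomes if o in OUTCOME_LABELS]
        if not codes:
            outcome[NOT_SPECIFIED] = outcome.get(NOT_SPECIFIED, 0) + 1
        else:
            if worst_outcome_only:
                codes = [min(codes, key=severity.index)]
            for o in dict.fromkeys(codes):
                label = OUTCOME_LABELS[o]
                outcome[label] = outcome.get(label, 0) + 1
    return CharacteristicsTable(
        drug=cohort.drug,
        n_cases=len(cohort.cases),
        n_events=len(cohort.events),
        sex=_count(sexes),
        age=_count(ages),
        weight=_count(weights),
        outcome=outcome,
        reporter=_count(reporters),
        report_year=_count(years),
        tto=_count(ttos),
        dose=_count(doses),
    )
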