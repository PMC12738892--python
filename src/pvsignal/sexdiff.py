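"""Sex-stratified adverse-event analysis within one drug cohort.

The modified reporting odds ratio compares, within a single drug's cohort,
female vs male reporting of each preferred term:

                    target event    other events
    female               a               b
    male                 c               d

ROR > 1 with a chi-square p-value < 0.05 marks a female-predominant term;
ROR < 1 with p < 0.05 marks a male-predominant one.  Only terms reported in
both sexes are analysed, and cases of unspecified sex are excluded from
both margins.  No minimum-count floor and no multiple-testing correction
are applied by default.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from scipy import stats as _stats

from .cohort import Cohort
from .meddra import TermDictionary
from .signals import ContingencyTable, prr_chi2, ror as _ror


@dataclass(frozen=True)
class SexContingency:
    """Female/male event counts for one term within a cohort."""

    a: int  # female, target event
    b: int  # female, other events
    c: int  # male, target event
    d: int  # male, other events


@dataclass
class SexSignal:
    pt: str
    soc: str
    female_count: int
    male_count: int
    ror: float
    ror_lo: float
    ror_hi: float
    chi2: float
    p_value: float
    direction: Literal["F", "M", "none"]


def sex_tables(cohort: Cohort) -> dict[str, SexContingency]:
    """Per-PT female/male tables for every PT reported by both sexes.

    b and d are the sex's remaining event counts within the cohort; a
    single-sex cohort yields an empty result.
    """
    sex_of = {c.caseid: c.sex for c in cohort.cases}
    female = Counter()
    male = Counter()
    for caseid, pt in cohort.events:
        s = sex_of.get(caseid)
        if s == "F":
            female[pt] += 1
        elif s == "M":
            male[pt] += 1
    n_f = sum(female.values())
    n_m = sum(male.values())
    tables = {}
    for pt in sorted(set(female) & set(male)):
        a, c = female[pt], male[pt]
        tables[pt] = SexContingency(a, n_f - a, c, n_m - c)
    return tables


def modified_ror(
    pt: str, t: SexContingency, dictionary: TermDictionary | None = None,
    yates: bool = False,
) -> SexSignal:
    """Score one female/male table.

    The ROR and its Wald CI reuse the drug-event formulas on the sex table;
    the p-value is the upper tail of the Pearson chi-square statistic at
    1 df (``yates=True`` switches to the continuity-corrected statistic).
    A zero cell leaves the ROR undefined and the direction "none".
    """
    ct = ContingencyTable(t.a, t.b, t.c, t.d)
    est, lo, hi = _ror(ct)
    if yates:
        n = ct.n
        denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
        chi2 = (
            n * max(0.0, abs(t.a * t.d - t.b * t.c) - n / 2) ** 2 / denom
            if denom > 0
            else math.nan
        )
    else:
        _, chi2 = prr_chi2(ct)
    p = float(_stats.chi2.sf(chi2, df=1)) if not math.isnan(chi2) else math.nan
    direction: Literal["F", "M", "none"] = "none"
    if not math.isnan(est) and not math.isnan(p) and p < 0.05:
        if est > 1:
            direction = "F"
        elif est < 1:
            direction = "M"
    soc = dictionary.soc_of(pt) if dictionary is not None else ""
    return SexSignal(pt, soc, t.a, t.c, est, lo, hi, chi2, p, direction)


def sex_signals(
    cohort: Cohort, dictionary: TermDictionary | None = None, yates: bool = False
) -> list[SexSignal]:
    return [
        modified_ror(pt, t, dictionary, yates)
        for pt, t in sex_tables(cohort).items()
    ]


def volcano_coords(signals: Sequence[SexSignal]) -> tuple[pd.DataFrame, int]:
    """Volcano-plot coordinates (log2 ROR, -log10 p) per PT.

    PTs with an undefined ROR or p-value are dropped; the second return
    value counts them.
    """
    rows = []
    dropped = 0
    for s in signals:
        if math.isnan(s.ror) or math.isnan(s.p_value) or s.ror <= 0:
            dropped += 1
            continue
        rows.append(
            {
                "pt": s.pt,
                "log2_ror": math.log2(s.ror),
                "neg_log10_p": -math.log10(s.p_value) if s.p_value > 0 else math.inf,
                "direction": s.direction,
            }
        )
    return pd.DataFrame(rows, columns=["pt", "log2_ror", "neg_log10_p", "direction"]), dropped


def signals_to_frame(signals: Sequence[SexSignal]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "pt": s.pt,
                "soc": s.soc,
                "F": s.female_count,
                "M": s.male_count,
                "ROR": s.ror,
                "ROR_lo": s.ror_lo,
                "ROR_hi": s.ror_hi,
                "chi2": s.chi2,
                "p": s.p_value,
                "direction": s.direction,
            }
            for s in signals
        ]
    )
    if not df.empty:
        df = df.sort_values(["direction", "p", "pt"]).reset_index(drop=True)
    return df
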