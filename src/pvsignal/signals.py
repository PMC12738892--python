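"""Disproportionality statistics on 2x2 drug-event contingency tables.

For a target drug and an adverse-event term, reports are cross-classified as

                    target event    other events
    target drug          a               b
    other drugs          c               d

and four signal-detection statistics are computed on (a, b, c, d):

* **ROR** — reporting odds ratio ``ad/(bc)`` with a Wald 95% CI on the log
  scale; flagged when ``a >= 3`` and the CI lower bound exceeds 1.
* **PRR / MHRA** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]``
  with the Pearson chi-square (no continuity correction); flagged when
  ``a >= 3``, ``PRR >= 2`` and ``chi2 >= 4``.
* **BCPNN** — the information component, a shrunk log2 observed-to-expected
  ratio with closed-form posterior mean E(IC) and variance V(IC) under the
  standard priors (alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1);
  flagged when ``IC025 = E(IC) - 2*sqrt(V(IC)) > 0``.
* **MGPS** — here the closed-form empirical-Bayes geometric mean
  ``EBGM = aN/[(a+c)(a+b)]`` (the relative reporting ratio) with log-normal
  lower bound ``EBGM05``; flagged when ``EBGM05 > 2``.  This is a deliberate
  closed-form definition, not a gamma-Poisson mixture fit (see docs).

A term is a *consensus* signal only when all four methods flag it
simultaneously.  Zero cells make ROR/PRR/MGPS undefined (encoded as NaN,
flag False — no Haldane correction); the BCPNN priors regularize every
non-negative table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

Z95 = 1.96

#: Standard BCPNN hyperparameters: a flat Dirichlet over the 2x2 cell
#: probabilities (gamma11 = 1) with Beta(1,1) margins inside Beta(2,2) totals.
DEFAULT_PRIORS = {"alpha1": 1.0, "beta1": 1.0, "alpha": 2.0, "beta": 2.0, "gamma11": 1.0}


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def ror(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI; (nan, nan, nan) on any zero cell."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr_chi2(t: ContingencyTable) -> tuple[float, float]:
    """PRR and the Pearson chi-square statistic (1 df, no continuity correction).

    PRR is NaN when a+b = 0 or c = 0; chi-square is NaN when any margin is 0.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    prr = math.nan
    if a + b > 0 and c > 0:
        prr = (a / (a + b)) / (c / (c + d))
    chi2 = math.nan
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom > 0:
        chi2 = (a * d - b * c) ** 2 * n / denom
    return prr, chi2


def bcpnn(
    t: ContingencyTable, priors: Mapping[str, float] = DEFAULT_PRIORS
) -> tuple[float, float, float]:
    """Closed-form BCPNN posterior: returns (E(IC), V(IC), IC025).

    Defined for every non-negative table because the priors keep all
    denominators positive.
    """
    a = float(t.a)
    n = float(t.n)
    ab = float(t.a + t.b)
    ac = float(t.a + t.c)
    a1, b1 = priors["alpha1"], priors["beta1"]
    al, be, g11 = priors["alpha"], priors["beta"], priors["gamma11"]
    gamma = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (ab + a1) * (ac + b1))
    )
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
        + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
    ) / math.log(2) ** 2
    ic025 = e_ic - 2 * math.sqrt(v_ic)
    return e_ic, v_ic, ic025


def mgps(t: ContingencyTable) -> tuple[float, float]:
    """Closed-form EBGM = aN/[(a+c)(a+b)] and its log-normal lower bound EBGM05.

    NaN on any zero cell (the count floors in the decision rules mean a
    continuity correction could never rescue a signal).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return math.nan, math.nan
    ebgm = a * t.n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ebgm05 = math.exp(math.log(ebgm) - Z95 * se)
    return ebgm, ebgm05


@dataclass
class SignalScore:
    """All four statistics plus per-method flags and the consensus call
    for one drug-term pair."""

    term: str
    level: Literal["pt", "soc"]
    table: ContingencyTable
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    e_ic: float
    v_ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_mhra: bool
    flag_bcpnn: bool
    flag_mgps: bool
    consensus: bool


def score_table(
    term: str,
    t: ContingencyTable,
    level: Literal["pt", "soc"] = "pt",
    priors: Mapping[str, float] = DEFAULT_PRIORS,
) -> SignalScore:
    """Compute every statistic and decision flag for one table.

    Flags follow the published thresholds: ROR needs a >= 3 and CI lower
    bound > 1; MHRA needs a >= 3, PRR >= 2 and chi2 >= 4; BCPNN needs
    IC025 > 0; MGPS needs EBGM05 > 2.  NaN statistics never flag.
    """
    r, lo, hi = ror(t)
    prr, chi2 = prr_chi2(t)
    e_ic, v_ic, ic025 = bcpnn(t, priors)
    ebgm, ebgm05 = mgps(t)
    floor = t.a >= 3
    f_ror = bool(floor and lo > 1)
    f_mhra = bool(floor and prr >= 2 and chi2 >= 4)
    f_bcpnn = bool(ic025 > 0)
    f_mgps = bool(ebgm05 > 2)
    return SignalScore(
        term, level, t, r, lo, hi, prr, chi2, e_ic, v_ic, ic025, ebgm, ebgm05,
        f_ror, f_mhra, f_bcpnn, f_mgps, f_ror and f_mhra and f_bcpnn and f_mgps,
    )


def build_tables(
    target_events: Iterable[tuple[str, str]],
    background_events: Iterable[tuple[str, str]],
) -> dict[str, ContingencyTable]:
    """Build per-term 2x2 tables from event streams.

    Events are (caseid, term) pairs counted at the event level: a case
    reporting the same term twice contributes one event to that term (the
    deduplication is the caller's job via :func:`unique_events`).  The
    background is every deduplicated case whose primary-suspect drug is not
    the target; an empty background is a hard error since there is no
    comparator.
    """
    tgt = Counter(term for _, term in target_events)
    bkg = Counter(term for _, term in background_events)
    n_tgt = sum(tgt.values())
    n_bkg = sum(bkg.values())
    if n_bkg == 0:
        raise ValueError("background event set is empty: no comparator")
    tables = {}
    for term in sorted(set(tgt) | set(bkg)):
        a = tgt.get(term, 0)
        c = bkg.get(term, 0)
        tables[term] = ContingencyTable(a, n_tgt - a, c, n_bkg - c)
    return tables


def unique_events(events: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Collapse repeated (caseid, term) pairs so each case counts a term once."""
    seen: dict[tuple[str, str], None] = {}
    for ev in events:
        seen.setdefault(ev, None)
    return list(seen)


def score_all(
    tables: Mapping[str, ContingencyTable],
    level: Literal["pt", "soc"] = "pt",
    priors: Mapping[str, float] = DEFAULT_PRIORS,
) -> list[SignalScore]:
    return [score_table(term, t, level, priors) for term, t in tables.items()]


def call_signals(scores: Iterable[SignalScore]) -> list[SignalScore]:
    """The consensus-significant subset: flagged by all four methods."""
    return [s for s in scores if s.consensus]


def scores_to_frame(scores: Iterable[SignalScore]) -> pd.DataFrame:
    """Tabular view, sorted (consensus desc, a desc, term asc) for stable diffs.

    Statistics are carried unrounded; round only at presentation time.
    """
    rows = [
        {
            "term": s.term,
            "level": s.level,
            "a": s.table.a,
            "b": s.table.b,
            "c": s.table.c,
            "d": s.table.d,
            "ROR": s.ror,
            "ROR_lo": s.ror_lo,
            "ROR_hi": s.ror_hi,
            "PRR": s.prr,
            "chi2": s.chi2,
            "EIC": s.e_ic,
            "VIC": s.v_ic,
            "IC025": s.ic025,
            "EBGM": s.ebgm,
            "EBGM05": s.ebgm05,
            "flag_ror": s.flag_ror,
            "flag_mhra": s.flag_mhra,
            "flag_bcpnn": s.flag_bcpnn,
            "flag_mgps": s.flag_mgps,
            "consensus": s.consensus,
        }
        for s in scores
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["consensus", "a", "term"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df


def vectorized_consensus(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-method flags and consensus over arrays of tables at once.

    Used by the simulation suites where scoring tables one dataclass at a
    time would dominate runtime; must agree exactly with
    :func:`score_table` (a property the tests enforce).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror_lo = np.where(pos, a * d / (b * c) * np.exp(-Z95 * se), np.nan)
        prr = np.where((a + b > 0) & (c > 0), (a / (a + b)) / (c / (c + d)), np.nan)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(denom > 0, (a * d - b * c) ** 2 * n / denom, np.nan)
        p = DEFAULT_PRIORS
        gamma = p["gamma11"] * (n + p["alpha"]) * (n + p["beta"]) / (
            (a + b + p["alpha1"]) * (a + c + p["beta1"])
        )
        e_ic = np.log2(
            (a + p["gamma11"]) * (n + p["alpha"]) * (n + p["beta"])
            / ((n + gamma) * (a + b + p["alpha1"]) * (a + c + p["beta1"]))
        )
        v_ic = (
            (n - a + gamma - p["gamma11"]) / ((a + p["gamma11"]) * (1 + n + gamma))
            + (n - (a + b) + p["alpha"] - p["alpha1"])
            / ((a + b + p["alpha1"]) * (1 + n + p["alpha"]))
            + (n - (a + c) + p["beta"] - p["beta1"])
            / ((a + c + p["beta1"]) * (1 + n + p["beta"]))
        ) / np.log(2) ** 2
        ic025 = e_ic - 2 * np.sqrt(v_ic)
        ebgm = np.where(pos, a * n / ((a + c) * (a + b)), np.nan)
        ebgm05 = np.where(pos, np.exp(np.log(ebgm) - Z95 * se), np.nan)
    floor = a >= 3
    flags = {
        "ror": floor & (ror_lo > 1),
        "mhra": floor & (prr >= 2) & (chi2 >= 4),
        "bcpnn": ic025 > 0,
        "mgps": ebgm05 > 2,
    }
    flags["consensus"] = flags["ror"] & flags["mhra"] & flags["bcpnn"] & flags["mgps"]
    return flags
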