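"""Synthetic FAERS-like data with known ground truth.

The generator emulates the structure of quarterly spontaneous-report
extracts — "$"-delimited DEMO/DRUG/REAC/OUTC/THER/INDI files, CASEIDs
duplicated across quarters with later FDA_DTs, post-2019Q1 deletion lists,
partial dates, free-text doses and demographic missingness — while keeping
a per-case truth table, so every pipeline stage can be validated without
the real database.

Generative model
----------------
Each case has one primary-suspect drug (the target for the first
``n_target_cases`` cases, otherwise one of ``n_background_drugs``
interchangeable background drugs), a sex drawn from ``sex_mix``, and an
event count k from a zero-truncated Poisson(``events_lambda``).  Its k
preferred terms are drawn with replacement from the PT catalog with
probability proportional to

    background_rate[pt] x (signal multiplier m  if target drug and planted)
                        x (female multiplier    if female and sex effect)

and collapsed to the distinct set, matching the event-level counting used
downstream.  Sex effects act inside the target cohort only.  The same
model has a closed-form expectation (:func:`expected_table`) used as the
recovery oracle, and a vectorised count-level path
(:func:`simulate_counts`) for replicate studies where writing files would
dominate runtime.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TARGET_DRUG = "TARGETINE"

_OCCP = ["MD", "PH", "OT", "CN", ""]
_OCCP_P = [0.25, 0.04, 0.12, 0.52, 0.07]
_OUTC = ["DE", "LT", "HO", "DS", "RI", "OT"]
_OUTC_P = [0.02, 0.02, 0.10, 0.015, 0.03, 0.18]


def default_catalog(n_pts: int = 60, n_socs: int = 8) -> pd.DataFrame:
    """A PT catalog with power-law background reporting rates and a
    round-robin SOC assignment, echoing the long-tailed term frequencies of
    real spontaneous-report data."""
    idx = np.arange(1, n_pts + 1)
    rates = 1.0 / (idx + 4.0)
    rates /= rates.sum()
    return pd.DataFrame(
        {
            "pt": [f"PT_{i:03d}" for i in idx],
            "soc": [f"SOC_{(i - 1) % n_socs + 1:02d}" for i in idx],
            "rate": rates,
        }
    )


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Defaults follow the reporting margins typical of SNRI cohorts in
    spontaneous-report data: a 0.65/0.28/0.07 female/male/unspecified mix
    and ~3 distinct events per case.
    """

    seed: int = 0
    n_target_cases: int = 2000
    n_background_cases: int = 50000
    n_background_drugs: int = 40
    catalog: pd.DataFrame = field(default_factory=default_catalog)
    #: (pt, reporting-rate multiplier) applied when the drug is the target.
    planted_signals: tuple[tuple[str, float], ...] = ()
    #: (pt, female multiplier) applied to female target-cohort cases.
    sex_effects: tuple[tuple[str, float], ...] = ()
    sex_mix: tuple[float, float, float] = (0.65, 0.28, 0.07)  # F, M, unspecified
    events_lambda: float = 2.8  # zero-truncated Poisson; mean ~= 3.0
    age_missing: float = 0.4
    weight_missing: float = 0.8
    dose_missing: float = 0.6
    event_dt_missing: float = 0.5
    start_dt_missing: float = 0.3
    date_imprecise: float = 0.05  # truncate day (or month) from a present date
    duplicate_rate: float = 0.0
    deletion_rate: float = 0.0
    quarters: tuple[str, ...] = ("2019Q1", "2019Q2")
    target_drug: str = TARGET_DRUG

    def validate(self) -> None:
        rates = self.catalog["rate"].to_numpy(float)
        if not len(rates) or not np.any(rates > 0):
            raise ValueError("infeasible config: all PT rates are zero")
        for p in (*self.sex_mix, self.age_missing, self.weight_missing,
                  self.dose_missing, self.event_dt_missing,
                  self.start_dt_missing, self.date_imprecise,
                  self.duplicate_rate, self.deletion_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.sex_mix) - 1) > 1e-9:
            raise ValueError("sex_mix must sum to 1")
        for pt, m in (*self.planted_signals, *self.sex_effects):
            if m <= 0:
                raise ValueError(f"multiplier for {pt} must be > 0")
            if pt not in set(self.catalog["pt"]):
                raise ValueError(f"unknown PT {pt!r}")
        if len(self.quarters) < 2:
            raise ValueError("need at least two quarters")


# ------------------------------------------------------------------ weights

def _weights(cfg: SyntheticConfig, target: bool, female: bool) -> np.ndarray:
    w = cfg.catalog["rate"].to_numpy(float).copy()
    pts = list(cfg.catalog["pt"])
    if target:
        for pt, m in cfg.planted_signals:
            w[pts.index(pt)] *= m
        if female:
            for pt, m in cfg.sex_effects:
                w[pts.index(pt)] *= m
    return w / w.sum()


def _p_include(cfg: SyntheticConfig, q: np.ndarray, kmax: int = 80) -> np.ndarray:
    """P(case reports each PT) = E_k[1 - (1-q)^k], k zero-truncated Poisson."""
    lam = cfg.events_lambda
    norm = 1 - math.exp(-lam)
    p = np.zeros_like(q)
    for k in range(1, kmax + 1):
        pk = math.exp(-lam) * lam**k / math.factorial(k) / norm
        p += pk * (1 - (1 - q) ** k)
    return p


def _arm_inclusion(cfg: SyntheticConfig, target: bool) -> np.ndarray:
    """Per-PT inclusion probability for one arm, mixing over sex."""
    f, m, u = cfg.sex_mix
    p_f = _p_include(cfg, _weights(cfg, target, female=True))
    p_other = _p_include(cfg, _weights(cfg, target, female=False))
    return f * p_f + (m + u) * p_other


def expected_table(cfg: SyntheticConfig, pt: str) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) for one PT under the model.

    ``a`` is the expected number of target cases reporting the PT; ``b`` the
    expected remaining target events, and (c, d) likewise for the
    background arm.
    """
    pts = list(cfg.catalog["pt"])
    if pt not in pts:
        raise KeyError(pt)
    i = pts.index(pt)
    p_t = _arm_inclusion(cfg, target=True)
    p_b = _arm_inclusion(cfg, target=False)
    a = cfg.n_target_cases * p_t[i]
    b = cfg.n_target_cases * p_t.sum() - a
    c = cfg.n_background_cases * p_b[i]
    d = cfg.n_background_cases * p_b.sum() - c
    return a, b, c, d


def expected_ror(cfg: SyntheticConfig, pt: str) -> float:
    a, b, c, d = expected_table(cfg, pt)
    return (a * d) / (b * c)


# ------------------------------------------------------------- count path

def _truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    k = rng.poisson(lam, n)
    while True:
        zero = k == 0
        if not zero.any():
            return k
        k[zero] = rng.poisson(lam, int(zero.sum()))


def _draw_distinct(
    rng: np.random.Generator, n_cases: int, lam: float, w: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Distinct-PT draws for n_cases cases; returns per-PT case counts and
    the per-case distinct index arrays."""
    if n_cases == 0:
        return np.zeros(len(w), dtype=np.int64), []
    k = _truncated_poisson(rng, lam, n_cases)
    draws = rng.choice(len(w), size=int(k.sum()), p=w)
    case_idx = np.repeat(np.arange(n_cases), k)
    pairs = np.unique(np.stack([case_idx, draws]), axis=1)
    counts = np.bincount(pairs[1], minlength=len(w))
    per_case = np.split(pairs[1], np.searchsorted(pairs[0], np.arange(1, n_cases)))
    return counts, per_case


def simulate_counts(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One replicate of per-PT contingency counts without materialising
    reports: columns pt, a, b, c, d (event-level counting, sex mixed in).

    Statistically identical to generating files and running the ingest and
    cohort stages, at a small fraction of the cost.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    npt = len(cfg.catalog)
    out = {}
    for arm, n in (("target", cfg.n_target_cases), ("background", cfg.n_background_cases)):
        sexes = rng.choice(3, size=n, p=list(cfg.sex_mix))
        n_f = int((sexes == 0).sum())
        c_f, _ = _draw_distinct(
            rng, n_f, cfg.events_lambda, _weights(cfg, arm == "target", True)
        )
        c_o, _ = _draw_distinct(
            rng, n - n_f, cfg.events_lambda, _weights(cfg, arm == "target", False)
        )
        out[arm] = c_f + c_o
    a = out["target"]
    c = out["background"]
    return pd.DataFrame(
        {
            "pt": list(cfg.catalog["pt"]),
            "a": a,
            "b": int(a.sum()) - a,
            "c": c,
            "d": int(c.sum()) - c,
        }
    )


# ------------------------------------------------------------- file path

def _qstart(q: str) -> _dt.date:
    return _dt.date(int(q[:4]), 3 * (int(q[5]) - 1) + 1, 1)


def _fmt(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _maybe_imprecise(rng: np.random.Generator, s: str, rate: float) -> str:
    if s and rng.random() < rate:
        return s[:6] if rng.random() < 0.7 else s[:4]
    return s


@dataclass
class TruthTable:
    """Ground truth for one generated dataset: every emitted report (incl.
    duplicate re-emissions), the expected surviving case per CASEID, the
    deletion list, and the config for closed-form expectations."""

    config: SyntheticConfig
    reports: pd.DataFrame        # one row per emitted report version
    cases: pd.DataFrame          # expected post-dedup, post-deletion cases
    deleted_caseids: set[str]


def generate(
    cfg: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[Path], TruthTable]:
    """Draw a full dataset and (optionally) write quarterly bundles.

    Returns the quarter directories (empty list when ``out_dir`` is None)
    and the truth table.  Identical configs give byte-identical files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pts = list(cfg.catalog["pt"])
    n_total = cfg.n_target_cases + cfg.n_background_cases
    quarters = list(cfg.quarters)

    sexes_i = rng.choice(3, size=n_total, p=list(cfg.sex_mix))
    sex_code = np.array(["F", "M", ""], dtype=object)[sexes_i]
    is_target = np.arange(n_total) < cfg.n_target_cases

    # event draws per (arm, sex-class) group, preserving per-case identity
    events: list[np.ndarray] = [None] * n_total  # type: ignore[list-item]
    for target in (True, False):
        for female in (True, False):
            mask = (is_target == target) & ((sexes_i == 0) == female)
            ids = np.nonzero(mask)[0]
            _, per_case = _draw_distinct(
                rng, len(ids), cfg.events_lambda, _weights(cfg, target, female)
            )
            for cid, ev in zip(ids, per_case):
                events[cid] = ev

    drug_ids = rng.integers(0, cfg.n_background_drugs, size=n_total)
    qu_idx = rng.integers(0, len(quarters), size=n_total)
    occp = rng.choice(_OCCP, size=n_total, p=_OCCP_P)

    rows = []
    for i in range(n_total):
        caseid = str(10000000 + i)
        primaryid = caseid + "1"
        q = quarters[qu_idx[i]]
        q0 = _qstart(q)
        start = q0 - _dt.timedelta(days=int(rng.integers(0, 180)))
        tto = int(rng.integers(1, 120))
        event = start + _dt.timedelta(days=tto)
        fda = event + _dt.timedelta(days=int(rng.integers(3, 60)))
        start_s = "" if rng.random() < cfg.start_dt_missing else _fmt(start)
        event_s = "" if rng.random() < cfg.event_dt_missing else _fmt(event)
        start_s = _maybe_imprecise(rng, start_s, cfg.date_imprecise)
        event_s = _maybe_imprecise(rng, event_s, cfg.date_imprecise)
        age = "" if rng.random() < cfg.age_missing else str(int(rng.integers(18, 85)))
        wt = "" if rng.random() < cfg.weight_missing else str(int(rng.integers(42, 125)))
        if rng.random() < cfg.dose_missing:
            dose = "UNK" if rng.random() < 0.5 else ""
        else:
            amount = int(rng.choice([10, 20, 25, 40, 50, 100, 120, 200]))
            freq = str(rng.choice(["QD", "BID", "TID"], p=[0.6, 0.3, 0.1]))
            dose = f"{amount} MG, {freq}"
        n_out = int(rng.random() < 0.4)
        outcomes = sorted(rng.choice(_OUTC, size=n_out, replace=False, p=np.array(_OUTC_P) / sum(_OUTC_P))) if n_out else []
        drug = cfg.target_drug if is_target[i] else f"BKGDRUG{drug_ids[i]:03d}"
        rows.append(
            {
                "primaryid": primaryid,
                "caseid": caseid,
                "quarter": q,
                "fda_dt": _fmt(fda),
                "event_dt": event_s,
                "sex": sex_code[i],
                "age": age,
                "age_cod": "YR" if age else "",
                "wt": wt,
                "wt_cod": "KG" if wt else "",
                "occp_cod": occp[i],
                "outcomes": ";".join(outcomes),
                "drug": drug,
                "is_target": bool(is_target[i]),
                "dose": dose,
                "start_dt": start_s,
                "reactions": ";".join(pts[j] for j in sorted(events[i])),
            }
        )

    # duplicate re-emissions: same case content, later FDA_DT, higher
    # PRIMARYID, landed in the last quarter
    n_dup = int(round(cfg.duplicate_rate * n_total))
    dup_idx = sorted(rng.choice(n_total, size=n_dup, replace=False)) if n_dup else []
    dup_rows = []
    for i in dup_idx:
        r = dict(rows[i])
        r["primaryid"] = r["caseid"] + "2"
        fda = _dt.date(int(r["fda_dt"][:4]), int(r["fda_dt"][4:6]), int(r["fda_dt"][6:8]))
        r["fda_dt"] = _fmt(fda + _dt.timedelta(days=int(rng.integers(10, 90))))
        r["quarter"] = quarters[-1]
        dup_rows.append(r)

    n_del = int(round(cfg.deletion_rate * n_total))
    del_idx = sorted(rng.choice(n_total, size=n_del, replace=False)) if n_del else []
    deleted = {rows[i]["caseid"] for i in del_idx}

    reports = pd.DataFrame(rows + dup_rows)
    surviving = {r["caseid"]: r for r in rows}
    surviving.update({r["caseid"]: r for r in dup_rows})  # duplicates win dedup
    cases = pd.DataFrame(
        [r for cid, r in surviving.items() if cid not in deleted]
    ).reset_index(drop=True)
    truth = TruthTable(cfg, reports, cases, deleted)

    quarter_dirs: list[Path] = []
    if out_dir is not None:
        quarter_dirs = write_bundles(truth, Path(out_dir))
    return quarter_dirs, truth


def write_bundles(truth: TruthTable, out_dir: Path) -> list[Path]:
    """Write one directory per quarter in the FAERS ASCII layout; the
    deletion list goes to the first quarter labelled >= 2019Q1."""
    out_dir = Path(out_dir)
    dirs = []
    by_q = dict(tuple(truth.reports.groupby("quarter", sort=True)))
    deletion_quarter = next(
        (q for q in truth.config.quarters if q >= "2019Q1"), None
    )
    for q in truth.config.quarters:
        qdir = out_dir / q
        qdir.mkdir(parents=True, exist_ok=True)
        df = by_q.get(q, pd.DataFrame(columns=truth.reports.columns))
        df = df.sort_values("primaryid")
        demo, drug, reac, outc, ther, indi = [], [], [], [], [], []
        for r in df.itertuples(index=False):
            demo.append(
                f"{r.primaryid}${r.caseid}${r.fda_dt}${r.event_dt}${r.sex}"
                f"${r.age}${r.age_cod}${r.wt}${r.wt_cod}${r.occp_cod}"
            )
            drug.append(
                f"{r.primaryid}${r.caseid}$1$PS${r.drug}${r.drug}${r.dose}"
            )
            ther.append(f"{r.primaryid}${r.caseid}$1${r.start_dt}")
            for pt in r.reactions.split(";"):
                if pt:
                    reac.append(f"{r.primaryid}${r.caseid}${pt}")
            for oc in r.outcomes.split(";"):
                if oc:
                    outc.append(f"{r.primaryid}${r.caseid}${oc}")
            indi.append(f"{r.primaryid}${r.caseid}$1$Product used for unknown indication")
        headers = {
            "DEMO": ("primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occp_cod", demo),
            "DRUG": ("primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$dose_vbm", drug),
            "REAC": ("primaryid$caseid$pt", reac),
            "OUTC": ("primaryid$caseid$outc_cod", outc),
            "THER": ("primaryid$caseid$dsg_drug_seq$start_dt", ther),
            "INDI": ("primaryid$caseid$indi_drug_seq$indi_pt", indi),
        }
        for name, (header, lines) in headers.items():
            (qdir / f"{name}{q}.txt").write_text(
                "\n".join([header, *lines]) + "\n", encoding="latin-1"
            )
        if q == deletion_quarter and truth.deleted_caseids:
            (qdir / f"DELETED{q}.txt").write_text(
                "\n".join(sorted(truth.deleted_caseids)) + "\n", encoding="latin-1"
            )
        dirs.append(qdir)
    return dirs


def null_config(**overrides) -> SyntheticConfig:
    """A config with no planted signals or sex effects (the null model)."""
    return replace(SyntheticConfig(), planted_signals=(), sex_effects=(), **overrides)
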