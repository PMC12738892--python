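"""Reading FAERS-style quarterly ASCII bundles and FDA-style case deduplication.

FAERS quarterly extracts are distributed as "$"-delimited text tables
(DEMO, DRUG, REAC, OUTC, THER, INDI) keyed by PRIMARYID, where several
PRIMARYIDs (report versions) can share one CASEID (the underlying safety
case).  Since 2019Q1 each quarter also ships a list of CASEIDs marked for
removal.  This module parses such bundles into typed records, collapses
report versions to one record per case (most recent FDA_DT, ties broken by
the higher PRIMARYID) and applies the deletion lists.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_TABLES = ("demo", "drug", "reac")
OPTIONAL_TABLES = ("outc", "ther", "indi")
ALL_TABLES = MANDATORY_TABLES + OPTIONAL_TABLES

_DATE_RE = re.compile(r"^\d{8}$")


@dataclass(frozen=True)
class DrugEntry:
    """One DRUG row: free-text name, role code (PS/SS/C/I), dose text, start date."""

    drugname: str
    prod_ai: str = ""
    role_cod: str = ""
    dose_text: str = ""
    start_dt: str = ""


@dataclass
class RawReport:
    """One report version (a PRIMARYID) assembled from all subfiles."""

    primaryid: str
    caseid: str
    fda_dt: str = ""
    event_dt: str = ""
    sex: str = ""
    age: str = ""
    age_cod: str = ""
    wt: str = ""
    wt_cod: str = ""
    occp_cod: str = ""
    outcomes: tuple[str, ...] = ()
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()


#: A deduplicated report: exactly one per CASEID, not on any deletion list.
CaseRecord = RawReport


@dataclass
class QuarterlyBundle:
    """Parsed tables of one quarter plus its deletion list and parse tallies."""

    quarter_id: str
    tables: dict[str, pd.DataFrame]
    deleted_caseids: set[str] = field(default_factory=set)
    malformed_rows: dict[str, int] = field(default_factory=dict)

    def reports(self) -> list[RawReport]:
        return assemble_reports(self.tables)


class MissingTableError(FileNotFoundError):
    """A mandatory table (DEMO, DRUG or REAC) is absent from the bundle."""


def _read_table(path: Path, delimiter: str) -> tuple[pd.DataFrame, int]:
    """Read one "$"-delimited table; rows with the wrong column count are
    dropped and tallied rather than aborting the quarter."""
    bad = 0

    def _on_bad(row: list[str]) -> None:
        nonlocal bad
        bad += 1
        return None

    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        encoding="latin-1",
        encoding_errors="replace",
        engine="python",
        on_bad_lines=_on_bad,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    # rows with too many fields hit the callback above; rows with too few
    # arrive NaN-padded and are dropped here so both count as malformed
    short = df.isna().any(axis=1)
    if short.any():
        bad += int(short.sum())
        df = df.loc[~short].reset_index(drop=True)
    if bad:
        logger.warning("%s: dropped %d malformed row(s)", path.name, bad)
    return df, bad


def read_bundle(
    quarter_dir: str | Path,
    quarter_id: str | None = None,
    delimiter: str = "$",
) -> QuarterlyBundle:
    """Parse one quarter directory of FAERS-style tables.

    Files are located case-insensitively by prefix (``DEMO*``, ``drug*``, ...).
    A ``deleted*`` file, one CASEID per line, is read as the deletion list.
    Missing DEMO/DRUG/REAC is a hard error naming the table; OUTC/THER/INDI
    default to empty tables.
    """
    quarter_dir = Path(quarter_dir)
    if quarter_id is None:
        quarter_id = quarter_dir.name
    files = {p.name.lower(): p for p in quarter_dir.iterdir() if p.is_file()}

    def _find(prefix: str) -> Path | None:
        for name, p in sorted(files.items()):
            if name.startswith(prefix) and "delet" not in name:
                return p
        return None

    tables: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for name in ALL_TABLES:
        path = _find(name)
        if path is None:
            if name in MANDATORY_TABLES:
                raise MissingTableError(
                    f"bundle {quarter_id!r} is missing mandatory table {name.upper()}"
                )
            tables[name] = pd.DataFrame()
            continue
        tables[name], malformed[name] = _read_table(path, delimiter)

    deleted: set[str] = set()
    for name, p in files.items():
        if "delet" in name:
            text = p.read_text(encoding="latin-1")
            deleted |= {
                line.strip() for line in text.splitlines() if line.strip()
            }
            break
    return QuarterlyBundle(quarter_id, tables, deleted, malformed)


def _group_by_primaryid(df: pd.DataFrame) -> Mapping[str, pd.DataFrame]:
    if df.empty or "primaryid" not in df.columns:
        return {}
    return dict(tuple(df.groupby("primaryid", sort=False)))


def assemble_reports(tables: Mapping[str, pd.DataFrame]) -> list[RawReport]:
    """Join the subfiles of one quarter into RawReports keyed by PRIMARYID."""
    demo = tables["demo"]
    drug_g = _group_by_primaryid(tables.get("drug", pd.DataFrame()))
    reac_g = _group_by_primaryid(tables.get("reac", pd.DataFrame()))
    outc_g = _group_by_primaryid(tables.get("outc", pd.DataFrame()))
    ther_g = _group_by_primaryid(tables.get("ther", pd.DataFrame()))

    def col(row, name: str) -> str:
        v = getattr(row, name, "")
        return str(v).strip() if v is not None else ""

    reports = []
    for row in demo.itertuples(index=False):
        pid = col(row, "primaryid")
        if not pid:
            continue
        drugs = []
        ther = ther_g.get(pid)
        start_by_seq: dict[str, str] = {}
        if ther is not None:
            for t in ther.itertuples(index=False):
                start_by_seq[col(t, "dsg_drug_seq")] = col(t, "start_dt")
        d = drug_g.get(pid)
        if d is not None:
            for dr in d.itertuples(index=False):
                drugs.append(
                    DrugEntry(
                        drugname=col(dr, "drugname"),
                        prod_ai=col(dr, "prod_ai"),
                        role_cod=col(dr, "role_cod").upper(),
                        dose_text=col(dr, "dose_vbm"),
                        start_dt=start_by_seq.get(col(dr, "drug_seq"), ""),
                    )
                )
        r = reac_g.get(pid)
        reactions = tuple(col(x, "pt") for x in r.itertuples(index=False)) if r is not None else ()
        o = outc_g.get(pid)
        outcomes = (
            tuple(col(x, "outc_cod").upper() for x in o.itertuples(index=False))
            if o is not None
            else ()
        )
        reports.append(
            RawReport(
                primaryid=pid,
                caseid=col(row, "caseid"),
                fda_dt=col(row, "fda_dt"),
                event_dt=col(row, "event_dt"),
                sex=col(row, "sex").upper(),
                age=col(row, "age"),
                age_cod=col(row, "age_cod").upper(),
                wt=col(row, "wt"),
                wt_cod=col(row, "wt_cod").upper(),
                occp_cod=col(row, "occp_cod").upper(),
                outcomes=outcomes,
                drugs=tuple(drugs),
                reactions=reactions,
            )
        )
    return reports


def _dedup_key(report: RawReport) -> tuple[str, tuple[int, str]]:
    # Valid YYYYMMDD strings order chronologically as text; anything else
    # (empty, truncated) sorts as the minimum so an informative date wins.
    fda = report.fda_dt if _DATE_RE.match(report.fda_dt) else ""
    pid = report.primaryid
    pid_key = (1, pid.zfill(32)) if pid.isdigit() else (0, pid)
    return fda, pid_key


def deduplicate(reports: Iterable[RawReport]) -> list[CaseRecord]:
    """One record per CASEID: keep the report with the most recent FDA_DT,
    ties broken by the higher PRIMARYID.  Output order follows first
    appearance of each CASEID, so the result is stable under input order
    up to the surviving-report rule."""
    best: dict[str, RawReport] = {}
    for rep in reports:
        cur = best.get(rep.caseid)
        if cur is None or _dedup_key(rep) > _dedup_key(cur):
            best[rep.caseid] = rep
    return list(best.values())


def apply_deletions(
    cases: Sequence[CaseRecord], deleted: set[str]
) -> tuple[list[CaseRecord], dict[str, int]]:
    """Drop cases whose CASEID appears on a deletion list.

    Returns the surviving cases and a tally: ``removed`` (matched deletions)
    and ``unmatched`` (listed CASEIDs never seen in the data).
    """
    survivors = [c for c in cases if c.caseid not in deleted]
    removed = len(cases) - len(survivors)
    matched_ids = {c.caseid for c in cases} & deleted
    tally = {"removed": removed, "unmatched": len(deleted - matched_ids)}
    if tally["unmatched"]:
        logger.info("%d deletion-list CASEID(s) not present in data", tally["unmatched"])
    return survivors, tally


def load_cases(
    quarter_dirs: Sequence[str | Path], delimiter: str = "$"
) -> tuple[list[CaseRecord], dict[str, int]]:
    """Full ingest: read every quarter, pool reports across quarters, dedup,
    then apply the union of all deletion lists (deletions follow dedup, as
    in the FDA-recommended procedure)."""
    reports: list[RawReport] = []
    deleted: set[str] = set()
    for qd in quarter_dirs:
        bundle = read_bundle(qd, delimiter=delimiter)
        reports.extend(bundle.reports())
        deleted |= bundle.deleted_caseids
    cases = deduplicate(reports)
    survivors, tally = apply_deletions(cases, deleted)
    stats = {
        "reports": len(reports),
        "cases_after_dedup": len(cases),
        "duplicates_removed": len(reports) - len(cases),
        "deleted": tally["removed"],
        "unmatched_deletions": tally["unmatched"],
        "cases": len(survivors),
    }
    return survivors, stats


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Flatten cases to the normalized one-row-per-case table written by the CLI.

    Drugs and reactions are packed as ``;``-joined columns (drug entries as
    ``name|role|start_dt``) — a documented, lossy-but-greppable TSV schema.
    """
    rows = []
    for c in cases:
        rows.append(
            {
                "caseid": c.caseid,
                "primaryid": c.primaryid,
                "fda_dt": c.fda_dt,
                "event_dt": c.event_dt,
                "sex": c.sex,
                "age": c.age,
                "age_cod": c.age_cod,
                "wt": c.wt,
                "wt_cod": c.wt_cod,
                "occp_cod": c.occp_cod,
                "outcomes": ";".join(c.outcomes),
                "drugs": ";".join(
                    f"{d.drugname}|{d.role_cod}|{d.start_dt}" for d in c.drugs
                ),
                "reactions": ";".join(c.reactions),
            }
        )
    return pd.DataFrame(rows)
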