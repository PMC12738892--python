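"""Shared fixtures: hand-written micro-bundles and a small PT->SOC table.

All fixtures are generated at test time; nothing binary is stored.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from pvsignal.ingest import DrugEntry, RawReport

DEMO_HEADER = "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occp_cod"
DRUG_HEADER = "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$dose_vbm"
REAC_HEADER = "primaryid$caseid$pt"
THER_HEADER = "primaryid$caseid$dsg_drug_seq$start_dt"
OUTC_HEADER = "primaryid$caseid$outc_cod"


def write_quarter(
    tmp_path: Path,
    name: str = "2019Q1",
    demo: list[str] = (),
    drug: list[str] = (),
    reac: list[str] = (),
    ther: list[str] = (),
    outc: list[str] = (),
    deleted: list[str] = (),
) -> Path:
    qdir = tmp_path / name
    qdir.mkdir(parents=True, exist_ok=True)
    (qdir / f"DEMO{name}.txt").write_text("\n".join([DEMO_HEADER, *demo]) + "\n")
    (qdir / f"DRUG{name}.txt").write_text("\n".join([DRUG_HEADER, *drug]) + "\n")
    (qdir / f"REAC{name}.txt").write_text("\n".join([REAC_HEADER, *reac]) + "\n")
    if ther:
        (qdir / f"THER{name}.txt").write_text("\n".join([THER_HEADER, *ther]) + "\n")
    if outc:
        (qdir / f"OUTC{name}.txt").write_text("\n".join([OUTC_HEADER, *outc]) + "\n")
    if deleted:
        (qdir / f"DELETED{name}.txt").write_text("\n".join(deleted) + "\n")
    return qdir


def make_case(
    caseid: str,
    primaryid: str | None = None,
    drugname: str = "TARGETINE",
    role: str = "PS",
    reactions: tuple[str, ...] = ("Nausea",),
    sex: str = "F",
    fda_dt: str = "20200601",
    event_dt: str = "",
    start_dt: str = "",
    dose: str = "",
    **kw,
) -> RawReport:
    return RawReport(
        primaryid=primaryid or caseid + "1",
        caseid=caseid,
        fda_dt=fda_dt,
        event_dt=event_dt,
        sex=sex,
        drugs=(DrugEntry(drugname, drugname, role, dose, start_dt),),
        reactions=reactions,
        **kw,
    )


@pytest.fixture()
def small_dictionary_file(tmp_path: Path) -> Path:
    rows = [
        "pt\tsoc",
        "Nausea\tGastrointestinal disorders",
        "Vomiting\tGastrointestinal disorders",
        "Headache\tNervous system disorders",
        "Dizziness\tNervous system disorders",
        "Insomnia\tPsychiatric disorders",
    ]
    path = tmp_path / "pt_soc.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path
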