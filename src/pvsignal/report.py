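"""One-shot pipeline run: ingest -> cohorts -> signals -> comparison -> sex
analysis -> time to onset, with a provenance manifest.

All output tables are TSV, deterministically sorted, so reruns on identical
inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    DrugQuery,
    background_events,
    compute_tto,
    extract_cohort,
    tabulate_characteristics,
)
from .compare import compare, comparison_frames, venn_regions
from .ingest import cases_to_frame, load_cases
from .meddra import TermDictionary, load_dictionary, rollup
from .sexdiff import sex_signals, signals_to_frame, volcano_coords
from .signals import build_tables, call_signals, score_all, scores_to_frame, unique_events

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    quarter_dirs: list[str]
    drugs: list[dict]            # each: {name, synonyms, [match]}
    dictionary: str | None = None
    levels: tuple[str, ...] = ("pt", "soc")
    out_dir: str = "pvsignal_out"
    exclude_comparator_from_background: bool = False
    seed: int = 0
    delimiter: str = "$"

    def __post_init__(self) -> None:
        if not 1 <= len(self.drugs) <= 2:
            raise ValueError("need one or two target drugs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def queries(self) -> list[DrugQuery]:
        return [
            DrugQuery(
                d["name"],
                tuple(d.get("synonyms", [d["name"]])),
                d.get("match", "substring"),
            )
            for d in self.drugs
        ]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    for p in config.quarter_dirs:
        if not Path(p).is_dir():
            raise StageError(f"startup: quarter directory not found: {p}")
    dictionary: TermDictionary | None = None
    if config.dictionary:
        if not Path(config.dictionary).is_file():
            raise StageError(f"startup: dictionary not found: {config.dictionary}")
        dictionary = load_dictionary(config.dictionary)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "stages": {}}
    # out_dir is excluded so runs into different directories hash alike
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: v for k, v in vars(config).items() if k != "out_dir"},
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()[:16]

    try:
        cases, stats = load_cases(config.quarter_dirs, delimiter=config.delimiter)
    except Exception as e:  # noqa: BLE001 - rewrap with stage name
        raise StageError(f"ingest: {e}") from e
    manifest["stages"]["ingest"] = stats
    _write(cases_to_frame(cases), out / "cases.tsv")

    queries = config.queries()
    cohorts: list[Cohort] = []
    all_signals: dict[str, dict[str, list]] = {}
    for query in queries:
        label = query.name
        try:
            cohort = extract_cohort(cases, query)
            cohorts.append(cohort)
            chars = tabulate_characteristics(cohort)
            tto_records, tto_tally = compute_tto(cohort)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"cohort[{label}]: {e}") from e
        manifest["stages"][f"cohort[{label}]"] = {
            "cases": len(cohort.cases),
            "events": len(cohort.events),
            "tto_records": len(tto_records),
            "tto_excluded": tto_tally,
        }
        rows = []
        for dim in ("sex", "age", "weight", "outcome", "reporter",
                    "report_year", "tto", "dose"):
            pct = chars.percentages(dim)
            for cat in sorted(getattr(chars, dim)):
                rows.append(
                    {"dimension": dim, "category": cat,
                     "count": getattr(chars, dim)[cat], "pct": pct[cat]}
                )
        _write(pd.DataFrame(rows), out / f"characteristics_{label}.tsv")
        _write(
            pd.DataFrame(
                [{"caseid": r.caseid, "start_dt": r.start_dt,
                  "event_dt": r.event_dt, "tto_days": r.tto_days}
                 for r in tto_records]
            ),
            out / f"tto_{label}.tsv",
        )

        bkg_cases = cases
        if config.exclude_comparator_from_background and len(queries) == 2:
            other = queries[1] if query is queries[0] else queries[0]
            bkg_cases = [
                c for c in cases
                if not any(
                    d.role_cod == "PS" and other.matches(d.drugname, d.prod_ai)
                    for d in c.drugs
                )
            ]
        bkg = background_events(bkg_cases, query)
        all_signals[label] = {}
        for level in config.levels:
            try:
                tgt_ev = cohort.events
                bkg_ev = bkg
                if level == "soc":
                    if dictionary is None:
                        logger.warning("no dictionary: skipping SOC level")
                        continue
                    tgt_ev = unique_events(rollup(tgt_ev, dictionary))
                    bkg_ev = unique_events(rollup(bkg_ev, dictionary))
                scores = score_all(build_tables(tgt_ev, bkg_ev), level=level)
            except Exception as e:  # noqa: BLE001
                raise StageError(f"signals[{label}/{level}]: {e}") from e
            all_signals[label][level] = scores
            _write(scores_to_frame(scores), out / f"signals_{label}_{level}.tsv")
            _write(venn_regions(scores), out / f"venn_{label}_{level}.tsv")
            manifest["stages"][f"signals[{label}/{level}]"] = {
                "terms": len(scores),
                "consensus": len(call_signals(scores)),
            }

        try:
            sx = sex_signals(cohort, dictionary)
            volcano, dropped = volcano_coords(sx)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"sexdiff[{label}]: {e}") from e
        _write(signals_to_frame(sx), out / f"sex_signals_{label}.tsv")
        _write(volcano, out / f"volcano_{label}.tsv")
        manifest["stages"][f"sexdiff[{label}]"] = {
            "pts_both_sexes": len(sx),
            "female_predominant": sum(s.direction == "F" for s in sx),
            "male_predominant": sum(s.direction == "M" for s in sx),
            "volcano_dropped": dropped,
        }

    if len(queries) == 2:
        a, b = queries[0].name, queries[1].name
        for level in config.levels:
            if level not in all_signals[a] or level not in all_signals[b]:
                continue
            cmp = compare(all_signals[a][level], all_signals[b][level], a, b)
            frames = comparison_frames(cmp)
            for name, df in frames.items():
                _write(df, out / f"compare_{level}_{name}.tsv")
            manifest["stages"][f"compare[{level}]"] = {
                "shared": len(cmp.shared),
                f"exclusive_{a}": len(cmp.exclusive_a),
                f"exclusive_{b}": len(cmp.exclusive_b),
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
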