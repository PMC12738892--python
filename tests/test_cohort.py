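"""Cohort extraction, characteristics tabulation, TTO and dose parsing."""

from __future__ import annotations

import pytest

from pvsignal.cohort import (
    NOT_SPECIFIED,
    Cohort,
    DrugQuery,
    compute_tto,
    dose_band,
    extract_cohort,
    parse_dose,
    percentage,
    tabulate_characteristics,
    tto_band,
)
from pvsignal.ingest import DrugEntry, RawReport
from pvsignal.synthetic import SyntheticConfig, generate
from pvsignal.ingest import load_cases

from conftest import make_case

QUERY = DrugQuery("targetine", ("targetine", "targbrand"))


class TestExtractCohort:
    def test_role_concomitant_excluded(self):
        case = make_case("1", role="C")
        assert len(extract_cohort([case], QUERY)) == 0

    def test_primary_suspect_included(self):
        case = make_case("1", role="PS")
        cohort = extract_cohort([case], QUERY)
        assert len(cohort) == 1
        assert cohort.events == [("1", "Nausea")]

    def test_two_matching_entries_count_once(self):
        case = RawReport(
            primaryid="11", caseid="1",
            drugs=(
                DrugEntry("TARGETINE", "", "PS"),
                DrugEntry("TargBrand 50mg", "", "SS"),
            ),
            reactions=("Nausea", "Nausea", "Headache"),
        )
        cohort = extract_cohort([case], QUERY)
        assert len(cohort.cases) == 1
        # repeated PT collapses: event-level counting is per distinct PT
        assert cohort.events == [("1", "Nausea"), ("1", "Headache")]

    def test_substring_matching_on_free_text_names(self):
        case = make_case("1", drugname="TARGETINE HCL 25MG TAB")
        assert len(extract_cohort([case], QUERY)) == 1

    def test_synonym_monotonicity(self):
        cases = [
            make_case("1", drugname="TARGETINE"),
            make_case("2", drugname="OTHERBRAND"),
        ]
        small = DrugQuery("t", ("targetine",))
        large = DrugQuery("t", ("targetine", "otherbrand"))
        assert len(extract_cohort(cases, small)) <= len(extract_cohort(cases, large))

    def test_planted_cohort_size_recovered(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_target_cases=120, n_background_cases=280)
        dirs, truth = generate(cfg, tmp_path)
        cases, _ = load_cases(dirs)
        cohort = extract_cohort(cases, DrugQuery(cfg.target_drug, (cfg.target_drug,)))
        assert len(cohort) == 120


class TestPercentages:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (2191, 2752, 79.61),   # female share of a 2,752-case cohort
            (376, 2752, 13.66),
            (185, 2752, 6.72),
            (461, 715, 64.48),
            (202, 715, 28.25),
            (47, 715, 6.57),       # TTO <= 30 d share
            (1367, 2752, 49.67),
            (1606, 2752, 58.36),
        ],
    )
    def test_half_up_two_decimals(self, count, total, expected):
        assert percentage(count, total) == expected

    def test_zero_total(self):
        assert percentage(0, 0) == 0.0


class TestTabulate:
    def test_all_missing_single_case(self):
        case = RawReport(
            primaryid="11", caseid="1",
            drugs=(DrugEntry("TARGETINE", "", "PS"),),
            reactions=("Nausea",),
        )
        chars = tabulate_characteristics(Cohort("t", [case], [("1", "Nausea")]))
        for dim in ("sex", "age", "weight", "outcome", "reporter",
                    "report_year", "tto", "dose"):
            assert getattr(chars, dim) == {NOT_SPECIFIED: 1}
            assert chars.percentages(dim) == {NOT_SPECIFIED: 100.0}

    def test_band_partition(self, tmp_path):
        """Every partitioning dimension's counts sum to the cohort size."""
        cfg = SyntheticConfig(seed=11, n_target_cases=150, n_background_cases=150)
        dirs, _ = generate(cfg, tmp_path)
        cases, _ = load_cases(dirs)
        cohort = extract_cohort(cases, DrugQuery(cfg.target_drug, (cfg.target_drug,)))
        chars = tabulate_characteristics(cohort)
        for dim in ("sex", "age", "weight", "reporter", "report_year", "tto", "dose"):
            assert sum(getattr(chars, dim).values()) == chars.n_cases, dim
        assert chars.n_events == len(cohort.events)

    def test_outcome_codes_mapped(self):
        case = make_case("1", outcomes=("HO", "DE"))
        chars = tabulate_characteristics(Cohort("t", [case], [("1", "Nausea")]))
        assert chars.outcome == {
            "Death": 1,
            "Hospitalization - initial or prolonged": 1,
        }
        worst = tabulate_characteristics(
            Cohort("t", [case], [("1", "Nausea")]), worst_outcome_only=True
        )
        assert worst.outcome == {"Death": 1}


class TestTto:
    def _cohort(self, **kw):
        return Cohort("t", [make_case("1", **kw)], [("1", "Nausea")])

    def test_simple_interval(self):
        recs, tally = compute_tto(self._cohort(start_dt="20200101", event_dt="20200131"))
        assert len(recs) == 1
        assert recs[0].tto_days == 30
        assert tto_band(recs[0].tto_days) == "<=30"
        assert sum(tally.values()) == 0

    def test_imprecise_date_excluded(self):
        recs, tally = compute_tto(self._cohort(start_dt="202001", event_dt="20200131"))
        assert not recs
        assert tally["imprecise date"] == 1

    def test_onset_not_after_initiation_excluded(self):
        recs, tally = compute_tto(self._cohort(start_dt="20200110", event_dt="20200105"))
        assert not recs
        assert tally["onset not after initiation"] == 1

    def test_same_day_onset_excluded_strict_included_relaxed(self):
        cohort = self._cohort(start_dt="20200110", event_dt="20200110")
        assert not compute_tto(cohort, strict=True)[0]
        recs, _ = compute_tto(cohort, strict=False)
        assert recs[0].tto_days == 0

    def test_missing_date_excluded(self):
        recs, tally = compute_tto(self._cohort(start_dt="", event_dt="20200131"))
        assert tally["missing date"] == 1

    def test_earliest_start_used(self):
        case = RawReport(
            primaryid="11", caseid="1", event_dt="20200301",
            drugs=(
                DrugEntry("TARGETINE", "", "PS", "", "20200201"),
                DrugEntry("TARGETINE", "", "PS", "", "20200101"),
            ),
            reactions=("Nausea",),
        )
        recs, _ = compute_tto(Cohort("t", [case], [("1", "Nausea")]))
        assert recs[0].tto_days == 60

    def test_conservation(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_target_cases=200, n_background_cases=100)
        dirs, _ = generate(cfg, tmp_path)
        cases, _ = load_cases(dirs)
        cohort = extract_cohort(cases, DrugQuery(cfg.target_drug, (cfg.target_drug,)))
        recs, tally = compute_tto(cohort)
        assert len(cohort.cases) == len(recs) + sum(tally.values())


class TestDose:
    @pytest.mark.parametrize(
        "text,expected_mg,band",
        [
            ("50 MG, QD", 50.0, "21-50"),
            ("25 MG, BID", 50.0, "21-50"),
            ("100 MG, TID", 300.0, ">=201"),
            ("0.02 G, QD", 20.0, "<=20"),
            ("120 MG", 120.0, "101-200"),
            ("UNK", None, NOT_SPECIFIED),
            ("", None, NOT_SPECIFIED),
            ("ONE TABLET DAILY", None, NOT_SPECIFIED),
        ],
    )
    def test_parse_and_band(self, text, expected_mg, band):
        mg = parse_dose(text)
        assert mg == expected_mg
        assert dose_band(mg) == band
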