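"""Cleaning stages: deduplication, suspect filtering, exposure classification, counting."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from cardiopv.cohort import (
    build_cohorts,
    classify_exposure,
    cohort_summary,
    deduplicate,
    filter_suspect,
    restrict_to_indications,
)
from cardiopv.model import (
    DrugClass,
    DrugMention,
    ExposureGroup,
    RawReport,
    ReportSet,
    Role,
    exposure_group_of,
)
from cardiopv.synthetic import default_archive, default_smq_map


def report(case, rid, day, drugs=(), reactions=(), indications=()):
    return RawReport(
        case_id=case,
        report_id=rid,
        fda_receipt_date=day,
        drugs=[DrugMention(n, r) for n, r in drugs],
        reactions=list(reactions),
        indications=list(indications),
    )


class TestDeduplicate:
    def test_latest_receipt_date_wins(self):
        rs = ReportSet.from_reports(
            [
                report("A", "01", date(2020, 1, 1), [("x", Role.SUSPECT)]),
                report("A", "02", date(2020, 6, 1), [("x", Role.SUSPECT)]),
            ]
        )
        out = deduplicate(rs)
        assert list(out.demo["report_id"]) == ["02"]

    def test_tie_broken_by_larger_report_id(self):
        rs = ReportSet.from_reports(
            [
                report("A", "07", date(2020, 1, 1)),
                report("A", "03", date(2020, 1, 1)),
            ]
        )
        assert list(deduplicate(rs).demo["report_id"]) == ["07"]

    def test_singletons_untouched(self):
        rs = ReportSet.from_reports(
            [report("A", "01", date(2020, 1, 1)), report("B", "02", date(2020, 1, 2))]
        )
        assert deduplicate(rs).n_reports == 2

    def test_idempotent_and_matches_ledger(self, report_set, batch):
        _, truth = batch
        once = deduplicate(report_set)
        twice = deduplicate(once)
        assert once.n_reports == sum(truth.n_cases.values())
        pd.testing.assert_frame_equal(once.demo, twice.demo)


class TestFilterSuspect:
    def test_concomitant_mentions_removed(self):
        rs = ReportSet.from_reports(
            [
                report(
                    "A",
                    "01",
                    date(2020, 1, 1),
                    [("pembrolizumab", Role.SUSPECT), ("aspirin", Role.CONCOMITANT)],
                )
            ]
        )
        out = filter_suspect(rs)
        assert list(out.drugs["verbatim_name"]) == ["pembrolizumab"]

    def test_report_with_no_suspect_drug_dropped(self):
        rs = ReportSet.from_reports(
            [
                report("A", "01", date(2020, 1, 1), [("aspirin", Role.CONCOMITANT)]),
                report("B", "02", date(2020, 1, 1), [("aspirin", Role.INTERACTING)]),
                report("C", "03", date(2020, 1, 1), [("aspirin", Role.SUSPECT)]),
            ]
        )
        out = filter_suspect(rs)
        assert list(out.demo["case_id"]) == ["C"]

    def test_concomitant_class_drug_does_not_classify(self):
        # an ICI mention with concomitant role must not make the case ICI-exposed
        rs = ReportSet.from_reports(
            [
                report(
                    "A",
                    "01",
                    date(2020, 1, 1),
                    [("aspirin", Role.SUSPECT), ("nivolumab", Role.CONCOMITANT)],
                )
            ]
        )
        cohort = classify_exposure(filter_suspect(rs), default_archive())
        assert cohort.cases["exposure_group"].iloc[0] == ExposureGroup.NEITHER.value


class TestClassifyExposure:
    @pytest.mark.parametrize(
        "names, expected",
        [
            (("nivolumab", "cabozantinib"), ExposureGroup.COMBINATION),
            (("atezolizumab",), ExposureGroup.ICI_ALONE),
            (("  KEYTRUDA ",), ExposureGroup.ICI_ALONE),  # brand name, messy
            (("bevacizumab",), ExposureGroup.AGI_ALONE),
            (("aspirin",), ExposureGroup.NEITHER),
            (("aspirin", "unknown research drug"), ExposureGroup.NEITHER),
        ],
    )
    def test_groups(self, names, expected):
        rs = ReportSet.from_reports(
            [report("A", "01", date(2020, 1, 1), [(n, Role.SUSPECT) for n in names])]
        )
        cohort = classify_exposure(rs, default_archive())
        assert cohort.cases["exposure_group"].iloc[0] == expected.value

    def test_pure_rule(self):
        assert exposure_group_of({DrugClass.ICI}) == ExposureGroup.ICI_ALONE
        assert exposure_group_of({DrugClass.AGI}) == ExposureGroup.AGI_ALONE
        assert exposure_group_of({DrugClass.ICI, DrugClass.AGI}) == ExposureGroup.COMBINATION
        assert exposure_group_of(set()) == ExposureGroup.NEITHER

    def test_partition_is_complete(self, clean_cohort):
        sizes = clean_cohort.group_sizes()
        assert sum(sizes.values()) == clean_cohort.n_cases
        assert clean_cohort.cases["case_id"].is_unique


class TestBuildCohorts:
    def make_cohort(self, reactions_by_case):
        reports = [
            report(
                case,
                f"{i:02d}",
                date(2020, 1, 1),
                [("pembrolizumab", Role.SUSPECT)],
                reactions,
            )
            for i, (case, reactions) in enumerate(reactions_by_case.items())
        ]
        return classify_exposure(ReportSet.from_reports(reports), default_archive())

    def test_case_with_multiple_cv_pts_counts_per_report(self):
        cohort = self.make_cohort({"A": ["Myocarditis", "Pericarditis", "Nausea"]})
        counts = build_cohorts(cohort, default_smq_map())
        assert counts.n_cases[ExposureGroup.ICI_ALONE] == 1
        assert counts.n_reports[ExposureGroup.ICI_ALONE] == 2  # two CV PTs

    def test_case_without_cv_pt_not_counted(self):
        cohort = self.make_cohort({"A": ["Nausea", "Fatigue"]})
        counts = build_cohorts(cohort, default_smq_map())
        assert counts.n_cases[ExposureGroup.ICI_ALONE] == 0
        assert counts.n_reports[ExposureGroup.ICI_ALONE] == 0

    def test_counts_match_generator_ledger(self, clean_cohort, smq_map, batch):
        _, truth = batch
        counts = build_cohorts(clean_cohort, smq_map)
        assert {g.value: n for g, n in counts.n_cases.items()} == truth.cv_cases
        assert {g.value: n for g, n in counts.n_reports.items()} == truth.cv_reports

    def test_reports_at_least_cases(self, clean_cohort, smq_map):
        counts = build_cohorts(clean_cohort, smq_map)
        for g in ExposureGroup:
            assert counts.n_reports[g] >= counts.n_cases[g]


class TestSummariesAndRestriction:
    def test_summary_outcome_counts_sum_to_denominator(self, clean_cohort, smq_map):
        summary = cohort_summary(clean_cohort, smq_map)
        counts = build_cohorts(clean_cohort, smq_map)
        for g in ExposureGroup:
            sec = summary[(summary["group"] == g.value) & (summary["section"] == "outcome")]
            assert sec["n"].sum() == counts.n_cases[g]

    def test_indication_restriction_substring_match(self, clean_cohort):
        restricted = restrict_to_indications(clean_cohort, ("renal cell carcinoma",))
        kept = set(restricted.cases["case_id"])
        ind = clean_cohort.indications
        expected = set(
            ind.loc[ind["indication"].str.casefold().str.contains("renal cell carcinoma"), "case_id"]
        )
        assert kept == expected
        assert restricted.n_cases < clean_cohort.n_cases
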