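"""Three-step cleaning of a spontaneous-report batch into analysis cohorts.

The cleaning order is fixed and testable stage by stage:

1. **Deduplication** — a case may have several report versions (follow-ups,
   duplicate submissions); only the most recent version survives, most recent
   meaning maximal under a configurable version key (default: FDA receipt
   date, ties broken by the larger report id).
2. **Suspect-role filtering** — only drug mentions the reporter marked
   *suspect* classify exposure; concomitant and interacting mentions are
   removed, and reports left with no suspect drug are dropped.
3. **Exposure classification** — suspect names are matched against the
   drug-name archive; the set of matched classes determines the exposure
   group: {ICI} -> ICI alone, {AGI} -> AGI alone, {ICI, AGI} -> combination,
   {} -> neither (the comparator background).

A *case* is a cardiovascular AE case iff at least one of its PTs belongs to
one of the nine narrow cardiovascular SMQs; a *report* at the event level is
one (case, cardiovascular PT) pair, so a case may contribute several reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .faers_io import DrugArchive
from .meddra import SmqMap
from .model import (
    ExposureGroup,
    ReportSet,
    Role,
    exposure_group_of,
    normalize_name,
    DrugClass,
)

log = logging.getLogger(__name__)

DEFAULT_VERSION_KEY = ("fda_receipt_date", "report_id")

#: Indication terms (case-insensitive substring match) for the
#: malignant-tumour-restricted analysis.
CANCER_INDICATION_TERMS = (
    "non-small cell lung cancer",
    "renal cell carcinoma",
    "hepatocellular carcinoma",
    "colorectal cancer",
    "endometrial cancer",
    "breast cancer",
    "melanoma",
)


def deduplicate(rs: ReportSet, version_key: tuple[str, ...] = DEFAULT_VERSION_KEY) -> ReportSet:
    """Keep exactly one report version per case: the maximal one under ``version_key``.

    Idempotent; the dropped-version count is logged.
    """
    demo = rs.demo.sort_values(list(version_key), kind="mergesort")
    keep = demo.drop_duplicates("case_id", keep="last")
    dropped = len(demo) - len(keep)
    if dropped:
        log.info("deduplicate: dropped %d duplicate/older report versions (%d cases kept)", dropped, len(keep))
    return rs.restrict(keep["report_id"])


def filter_suspect(rs: ReportSet) -> ReportSet:
    """Remove non-suspect drug mentions; drop reports with no suspect drug."""
    suspect = rs.drugs[rs.drugs["role"] == Role.SUSPECT.value]
    keep_ids = set(suspect["report_id"])
    dropped = rs.n_reports - len(rs.demo[rs.demo["report_id"].isin(keep_ids)])
    out = rs.restrict(keep_ids)
    out.drugs = out.drugs[out.drugs["role"] == Role.SUSPECT.value].reset_index(drop=True)
    if dropped:
        log.info("filter_suspect: dropped %d reports without any suspect drug", dropped)
    return out


@dataclass
class CleanCohort:
    """Classified cases after cleaning, keyed by case_id.

    ``cases`` has one row per case: case_id, report_id, exposure_group,
    fda_receipt_date, year, age_years, sex, reporter_type, country.
    ``reactions`` (case_id, pt), ``outcomes`` (case_id, outcome) and
    ``indications`` (case_id, indication) are child frames.
    """

    cases: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def group_sizes(self) -> dict[ExposureGroup, int]:
        counts = self.cases["exposure_group"].value_counts()
        return {g: int(counts.get(g.value, 0)) for g in ExposureGroup}

    def restrict_cases(self, case_ids) -> "CleanCohort":
        keep = set(case_ids)
        return CleanCohort(
            self.cases[self.cases["case_id"].isin(keep)].reset_index(drop=True),
            self.reactions[self.reactions["case_id"].isin(keep)].reset_index(drop=True),
            self.outcomes[self.outcomes["case_id"].isin(keep)].reset_index(drop=True),
            self.indications[self.indications["case_id"].isin(keep)].reset_index(drop=True),
        )


def classify_exposure(rs: ReportSet, archive: DrugArchive) -> CleanCohort:
    """Resolve suspect drug classes against the archive and assign exposure groups.

    Input must be deduplicated and suspect-filtered.  Unmatched suspect names
    simply contribute no class (they are neither ICI nor AGI).
    """
    drugs = rs.drugs.copy()
    drugs["drug_class"] = drugs["verbatim_name"].map(normalize_name).map(
        lambda n: c.value if (c := archive.classify(n)) else None
    )
    classes_by_report = (
        drugs.dropna(subset=["drug_class"]).groupby("report_id")["drug_class"].agg(set)
    )

    demo = rs.demo.copy()
    class_sets = [
        s if isinstance(s, set) else set()
        for s in demo["report_id"].map(classes_by_report)
    ]
    demo["exposure_group"] = [
        exposure_group_of(DrugClass(c) for c in s).value for s in class_sets
    ]
    demo["suspect_classes"] = [frozenset(s) for s in class_sets]
    demo["year"] = pd.to_datetime(demo["fda_receipt_date"]).dt.year

    rid_to_cid = demo.set_index("report_id")["case_id"]

    def child(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out.insert(0, "case_id", out["report_id"].map(rid_to_cid))
        return out.drop(columns=["report_id"])

    cases = demo[
        [
            "case_id",
            "report_id",
            "exposure_group",
            "suspect_classes",
            "fda_receipt_date",
            "year",
            "age_years",
            "sex",
            "reporter_type",
            "country",
        ]
    ].reset_index(drop=True)
    sizes = {g.value: int((cases["exposure_group"] == g.value).sum()) for g in ExposureGroup}
    log.info("classify_exposure: %s", sizes)
    return CleanCohort(
        cases=cases,
        reactions=child(rs.reactions).drop_duplicates().reset_index(drop=True),
        outcomes=child(rs.outcomes).drop_duplicates().reset_index(drop=True),
        indications=child(rs.indications).reset_index(drop=True),
    )


@dataclass
class CohortCounts:
    """Cardiovascular case and report counts per exposure group."""

    n_cases: dict[ExposureGroup, int] = field(default_factory=dict)
    n_reports: dict[ExposureGroup, int] = field(default_factory=dict)


def cv_reactions(cohort: CleanCohort, smq_map: SmqMap) -> pd.DataFrame:
    """Distinct (case_id, pt) pairs whose PT is cardiovascular, with group."""
    reac = cohort.reactions.copy()
    reac["pt_norm"] = reac["pt"].map(normalize_name)
    reac = reac.drop_duplicates(["case_id", "pt_norm"])
    cv = reac[reac["pt_norm"].isin(set(smq_map.membership_frame()["pt_norm"]))]
    groups = cohort.cases.set_index("case_id")["exposure_group"]
    cv = cv.copy()
    cv["exposure_group"] = cv["case_id"].map(groups)
    return cv.reset_index(drop=True)


def build_cohorts(cohort: CleanCohort, smq_map: SmqMap) -> CohortCounts:
    """Count cardiovascular AE cases and reports per exposure group.

    A case counts once if any of its PTs is in any of the nine SMQs; its
    report count is its number of distinct cardiovascular PTs.
    """
    cv = cv_reactions(cohort, smq_map)
    counts = CohortCounts()
    for g in ExposureGroup:
        sub = cv[cv["exposure_group"] == g.value]
        counts.n_cases[g] = int(sub["case_id"].nunique())
        counts.n_reports[g] = int(len(sub))
    log.info(
        "build_cohorts: CV cases %s / CV reports %s",
        {g.value: n for g, n in counts.n_cases.items()},
        {g.value: n for g, n in counts.n_reports.items()},
    )
    return counts


def restrict_to_indications(cohort: CleanCohort, terms=CANCER_INDICATION_TERMS) -> CleanCohort:
    """Keep cases with at least one indication matching any term (case-insensitive substring)."""
    terms = [t.casefold() for t in terms]
    ind = cohort.indications.copy()
    low = ind["indication"].str.casefold()
    hit = low.map(lambda s: any(t in s for t in terms))
    return cohort.restrict_cases(ind.loc[hit, "case_id"].unique())


AGE_BINS = (("< 18 years", 0, 18), ("18-65 years", 18, 65), (">= 65 years", 65, float("inf")))


def cohort_summary(cohort: CleanCohort, smq_map: SmqMap, outcome_order=None) -> pd.DataFrame:
    """Baseline tabulation of cardiovascular cases per exposure group.

    Sections: age group, sex, reporter type, outcome category (one per case
    by severity precedence), indication, country, year — counts and
    percentages of the group's cardiovascular case total.
    """
    from .outcomes import resolve_case_outcomes  # local import to avoid a cycle

    cv = cv_reactions(cohort, smq_map)
    cv_cases = cohort.restrict_cases(cv["case_id"].unique())
    cases = cv_cases.cases
    resolved = resolve_case_outcomes(cv_cases, order=outcome_order)
    rows = []
    for g in ExposureGroup:
        sub = cases[cases["exposure_group"] == g.value]
        denom = len(sub)

        def add(section: str, label: str, count: int) -> None:
            pct = round(100.0 * count / denom, 1) if denom else float("nan")
            rows.append(
                {"group": g.value, "section": section, "category": label, "n": count, "pct": pct}
            )

        for label, lo, hi in AGE_BINS:
            add("age_group", label, int(((sub["age_years"] >= lo) & (sub["age_years"] < hi)).sum()))
        add("age_group", "Unknown", int(sub["age_years"].isna().sum()))
        for sex in ("male", "female", "unknown"):
            add("sex", sex, int((sub["sex"] == sex).sum()))
        for rep in ("health_professional", "non_health_professional", "unknown"):
            add("reporter", rep, int((sub["reporter_type"] == rep).sum()))
        res = resolved[resolved["case_id"].isin(sub["case_id"])]
        for cat, cnt in res["outcome_category"].value_counts().items():
            add("outcome", cat, int(cnt))
        ind = cv_cases.indications
        ind_sub = ind[ind["case_id"].isin(sub["case_id"])]
        for label, cnt in ind_sub["indication"].value_counts().head(15).items():
            add("indication", label, int(cnt))
        for country, cnt in sub["country"].value_counts().items():
            add("country", country, int(cnt))
        for year, cnt in sub["year"].value_counts().sort_index().items():
            add("year", str(year), int(cnt))
    return pd.DataFrame(rows, columns=["group", "section", "category", "n", "pct"])
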