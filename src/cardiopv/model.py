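"""Internal data model for FAERS-style spontaneous adverse-event reports.

A spontaneous *case* (one patient's adverse-event history with a drug) may be
submitted several times — follow-ups and duplicates — each submission being one
*report* version.  The tabular container :class:`ReportSet` mirrors the FAERS
quarterly layout: one demographics row per report version, plus child tables
for drugs, reactions (MedDRA preferred terms), outcome codes and indications,
all keyed by the version-specific ``report_id``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable

import pandas as pd


class Role(str, enum.Enum):
    """Reporter-assigned role of a drug in a report."""

    SUSPECT = "suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class ReporterType(str, enum.Enum):
    HEALTH_PROFESSIONAL = "health_professional"
    NON_HEALTH_PROFESSIONAL = "non_health_professional"
    UNKNOWN = "unknown"


class OutcomeCode(str, enum.Enum):
    """Seriousness outcome of a report (FAERS OUTC_COD vocabulary)."""

    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    OTHER_SERIOUS = "other_serious"
    UNKNOWN = "unknown"


class DrugClass(str, enum.Enum):
    ICI = "ICI"  # immune checkpoint inhibitor
    AGI = "AGI"  # angiogenesis inhibitor


class ExposureGroup(str, enum.Enum):
    """Exposure classification from the suspect-drug classes of a case."""

    ICI_ALONE = "ici_alone"
    AGI_ALONE = "agi_alone"
    COMBINATION = "combination"
    NEITHER = "neither"


#: The three contrasted exposure groups (the fourth, NEITHER, is the comparator).
EXPOSED_GROUPS = (
    ExposureGroup.ICI_ALONE,
    ExposureGroup.AGI_ALONE,
    ExposureGroup.COMBINATION,
)


def exposure_group_of(classes: Iterable[DrugClass]) -> ExposureGroup:
    """Pure classification rule: suspect drug classes -> exposure group.

    {ICI} -> ICI_ALONE, {AGI} -> AGI_ALONE, {ICI, AGI} -> COMBINATION,
    {} -> NEITHER.
    """
    s = set(classes)
    if s == {DrugClass.ICI}:
        return ExposureGroup.ICI_ALONE
    if s == {DrugClass.AGI}:
        return ExposureGroup.AGI_ALONE
    if s == {DrugClass.ICI, DrugClass.AGI}:
        return ExposureGroup.COMBINATION
    return ExposureGroup.NEITHER


def normalize_name(name: str) -> str:
    """Normalize a verbatim drug or PT name: case-fold, trim, collapse spaces."""
    return " ".join(str(name).casefold().split())


@dataclass(frozen=True)
class DrugMention:
    verbatim_name: str
    role: Role


@dataclass
class RawReport:
    """One version of one spontaneous report."""

    case_id: str
    report_id: str
    fda_receipt_date: date
    reporter_type: ReporterType = ReporterType.UNKNOWN
    country: str = "unknown"
    age_years: float | None = None
    sex: Sex = Sex.UNKNOWN
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: set[OutcomeCode] = field(default_factory=set)
    indications: list[str] = field(default_factory=list)


DEMO_COLUMNS = [
    "report_id",
    "case_id",
    "fda_receipt_date",
    "age_years",
    "sex",
    "reporter_type",
    "country",
]


@dataclass
class ReportSet:
    """Tabular bundle of one batch of report versions.

    Frames
    ------
    demo : one row per report version (``DEMO_COLUMNS``)
    drugs : report_id, verbatim_name, role
    reactions : report_id, pt
    outcomes : report_id, outcome
    indications : report_id, indication
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def report_ids(self) -> pd.Series:
        return self.demo["report_id"]

    def copy(self) -> "ReportSet":
        return ReportSet(
            self.demo.copy(),
            self.drugs.copy(),
            self.reactions.copy(),
            self.outcomes.copy(),
            self.indications.copy(),
        )

    def restrict(self, report_ids: Iterable[str]) -> "ReportSet":
        """Return the subset of the batch belonging to ``report_ids``."""
        keep = set(report_ids)
        return ReportSet(
            self.demo[self.demo["report_id"].isin(keep)].reset_index(drop=True),
            self.drugs[self.drugs["report_id"].isin(keep)].reset_index(drop=True),
            self.reactions[self.reactions["report_id"].isin(keep)].reset_index(drop=True),
            self.outcomes[self.outcomes["report_id"].isin(keep)].reset_index(drop=True),
            self.indications[self.indications["report_id"].isin(keep)].reset_index(drop=True),
        )

    def to_reports(self) -> list[RawReport]:
        """Materialize record objects (convenience for small batches/tests)."""
        drugs = self.drugs.groupby("report_id")
        reacs = self.reactions.groupby("report_id")
        outs = self.outcomes.groupby("report_id")
        inds = self.indications.groupby("report_id")

        def rows(grouped, rid):
            try:
                return grouped.get_group(rid)
            except KeyError:
                return None

        out: list[RawReport] = []
        for row in self.demo.itertuples(index=False):
            rid = row.report_id
            g = rows(drugs, rid)
            mentions = (
                [DrugMention(r.verbatim_name, Role(r.role)) for r in g.itertuples(index=False)]
                if g is not None
                else []
            )
            r = rows(reacs, rid)
            o = rows(outs, rid)
            i = rows(inds, rid)
            age = row.age_years
            out.append(
                RawReport(
                    case_id=row.case_id,
                    report_id=rid,
                    fda_receipt_date=row.fda_receipt_date,
                    reporter_type=ReporterType(row.reporter_type),
                    country=row.country,
                    age_years=None if pd.isna(age) else float(age),
                    sex=Sex(row.sex),
                    drugs=mentions,
                    reactions=list(r["pt"]) if r is not None else [],
                    outcomes={OutcomeCode(x) for x in o["outcome"]} if o is not None else set(),
                    indications=list(i["indication"]) if i is not None else [],
                )
            )
        return out

    @classmethod
    def from_reports(cls, reports: Iterable[RawReport]) -> "ReportSet":
        demo, drugs, reacs, outs, inds = [], [], [], [], []
        for r in reports:
            demo.append(
                {
                    "report_id": r.report_id,
                    "case_id": r.case_id,
                    "fda_receipt_date": r.fda_receipt_date,
                    "age_years": r.age_years,
                    "sex": r.sex.value,
                    "reporter_type": r.reporter_type.value,
                    "country": r.country,
                }
            )
            for m in r.drugs:
                drugs.append(
                    {"report_id": r.report_id, "verbatim_name": m.verbatim_name, "role": m.role.value}
                )
            for pt in r.reactions:
                reacs.append({"report_id": r.report_id, "pt": pt})
            for oc in sorted(r.outcomes, key=lambda o: o.value):
                outs.append({"report_id": r.report_id, "outcome": oc.value})
            for ind in r.indications:
                inds.append({"report_id": r.report_id, "indication": ind})
        return cls(
            demo=pd.DataFrame(demo, columns=DEMO_COLUMNS),
            drugs=pd.DataFrame(drugs, columns=["report_id", "verbatim_name", "role"]),
            reactions=pd.DataFrame(reacs, columns=["report_id", "pt"]),
            outcomes=pd.DataFrame(outs, columns=["report_id", "outcome"]),
            indications=pd.DataFrame(inds, columns=["report_id", "indication"]),
        )
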