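"""Outcome-severity profiles of cardiovascular adverse-event cases.

A FAERS report can carry several seriousness outcome codes (death,
life-threatening, hospitalization, ...).  For tabulation each case is
assigned exactly one outcome category by severity precedence, so category
counts sum to the case denominator.  The default precedence puts fatal
outcomes first:

    death > life_threatening > disability > congenital_anomaly >
    hospitalization > other_serious > unknown

and is overridable.  Summaries are produced per exposure group, overall and
within single SMQ strata, as counts and percentages (one decimal).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CleanCohort, cv_reactions
from .meddra import NARROW_CV_SMQS, SmqMap
from .model import ExposureGroup, EXPOSED_GROUPS, OutcomeCode, normalize_name

DEFAULT_PRECEDENCE: tuple[OutcomeCode, ...] = (
    OutcomeCode.DEATH,
    OutcomeCode.LIFE_THREATENING,
    OutcomeCode.DISABILITY,
    OutcomeCode.CONGENITAL_ANOMALY,
    OutcomeCode.HOSPITALIZATION,
    OutcomeCode.OTHER_SERIOUS,
    OutcomeCode.UNKNOWN,
)


def resolve_outcome(codes, order: tuple[OutcomeCode, ...] = DEFAULT_PRECEDENCE) -> OutcomeCode:
    """Pick the single highest-precedence outcome category of a case."""
    codes = {OutcomeCode(c) for c in codes}
    for cat in order:
        if cat in codes:
            return cat
    return OutcomeCode.UNKNOWN


def resolve_case_outcomes(cohort: CleanCohort, order=None) -> pd.DataFrame:
    """One row per case: case_id, outcome_category (cases without outcome rows -> unknown)."""
    order = tuple(order) if order else DEFAULT_PRECEDENCE
    rank = {c.value: i for i, c in enumerate(order)}
    out = cohort.outcomes.copy()
    out["rank"] = out["outcome"].map(rank)
    best = out.sort_values("rank", kind="mergesort").drop_duplicates("case_id")
    resolved = cohort.cases[["case_id"]].merge(
        best[["case_id", "outcome"]], on="case_id", how="left"
    )
    resolved["outcome"] = resolved["outcome"].fillna(OutcomeCode.UNKNOWN.value)
    return resolved.rename(columns={"outcome": "outcome_category"})


@dataclass
class OutcomeSummary:
    """Outcome-category counts and percentages for one (group, stratum)."""

    group: ExposureGroup
    stratum: str  # "overall" or the SMQ label
    denominator: int
    counts: dict[OutcomeCode, int]
    percentages: dict[OutcomeCode, float]  # 100*count/denominator, 1 decimal

    @property
    def empty(self) -> bool:
        return self.denominator == 0


def summarize_outcomes(
    cohort: CleanCohort,
    smq_map: SmqMap,
    group: ExposureGroup,
    stratum: int | str = "overall",
    order: tuple[OutcomeCode, ...] | None = None,
) -> OutcomeSummary:
    """Outcome profile of a group's cardiovascular cases, overall or within one SMQ.

    ``stratum`` is ``"overall"`` or a narrow SMQ code; the denominator is the
    number of the group's cardiovascular cases in the stratum.  An empty
    stratum yields a zero-denominator summary with NaN percentages.
    """
    cv = cv_reactions(cohort, smq_map)
    cv = cv[cv["exposure_group"] == group.value]
    if stratum == "overall":
        case_ids = cv["case_id"].unique()
        label = "overall"
    else:
        code = int(stratum)
        members = smq_map.category(code).member_pts
        case_ids = cv.loc[cv["pt"].map(normalize_name).isin(members), "case_id"].unique()
        label = f"{NARROW_CV_SMQS.get(code, '?')} ({code})"
    sub = cohort.restrict_cases(case_ids)
    resolved = resolve_case_outcomes(sub, order=order)
    denom = len(resolved)
    counts = {c: int((resolved["outcome_category"] == c.value).sum()) for c in OutcomeCode}
    pcts = {
        c: (round(100.0 * n / denom, 1) if denom else float("nan")) for c, n in counts.items()
    }
    return OutcomeSummary(group=group, stratum=label, denominator=denom, counts=counts, percentages=pcts)


def combined_death_lt(summary: OutcomeSummary) -> float:
    """Death% + life-threatening% on the summary's denominator (the 'most serious' share)."""
    if summary.empty:
        return 0.0
    return summary.percentages[OutcomeCode.DEATH] + summary.percentages[OutcomeCode.LIFE_THREATENING]


def outcome_table(
    cohort: CleanCohort,
    smq_map: SmqMap,
    groups: tuple[ExposureGroup, ...] = EXPOSED_GROUPS,
    strata: list[int | str] | None = None,
    order: tuple[OutcomeCode, ...] | None = None,
) -> pd.DataFrame:
    """Tidy outcome profile: one row per (group, stratum, category)."""
    if strata is None:
        strata = ["overall"] + sorted(smq_map.codes)
    rows = []
    for stratum in strata:
        for g in groups:
            s = summarize_outcomes(cohort, smq_map, g, stratum, order=order)
            for cat in OutcomeCode:
                rows.append(
                    {
                        "group": g.value,
                        "stratum": s.stratum,
                        "outcome": cat.value,
                        "n": s.counts[cat],
                        "pct": s.percentages[cat],
                        "denominator": s.denominator,
                    }
                )
            rows.append(
                {
                    "group": g.value,
                    "stratum": s.stratum,
                    "outcome": "death_or_life_threatening",
                    "n": s.counts[OutcomeCode.DEATH] + s.counts[OutcomeCode.LIFE_THREATENING],
                    "pct": combined_death_lt(s),
                    "denominator": s.denominator,
                }
            )
    return pd.DataFrame(rows)
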