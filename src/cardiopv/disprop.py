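"""Shrinkage-transformed disproportionality statistics and the signal rule.

Case–noncase (disproportionality) analysis compares how often an adverse
event is reported with a target exposure against its reporting rate with all
other exposures, through a 2x2 table:

====================  =================  ============  ==============
..                     target AE          other AEs     total
====================  =================  ============  ==============
target exposure        a (N_observed)     b             N_drug = a+b
other exposures        c                  d             c+d
total                  N_event = a+c      b+d           N_total
====================  =================  ============  ==============

with N_expected = N_drug * N_event / N_total.  Two shrinkage-transformed
statistics are computed from the same shrunk observed-to-expected core:

    ROR = (N_observed + 0.5) / (N_expected + 0.5)
    IC  = log2[(N_observed + 0.5) / (N_expected + 0.5)]

so IC = log2(ROR) identically.  The +0.5 shrinkage stabilizes small counts
and pulls estimates toward the null.  The 95% interval for the ROR is the
Wald odds-ratio interval exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)) centred
on the shrunk point estimate; the IC credibility bounds use the standard
power-series approximation

    IC_025 = IC - 3.3*(a+0.5)^-1/2 - 2.0*(a+0.5)^-3/2
    IC_975 = IC + 2.4*(a+0.5)^-1/2 - 0.5*(a+0.5)^-3/2

A drug–event combination is a potential signal when ROR_025 > 1 or
IC_025 > 0 with at least 3 reports; both criteria are reported separately.
No multiplicity adjustment is applied (per-signal thresholds only).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CleanCohort
from .meddra import NARROW_CV_SMQS, SmqMap
from .model import ExposureGroup, EXPOSED_GROUPS, normalize_name

Z_95 = 1.96
MIN_REPORTS = 3  # minimum report count for a signal


class UndefinedInputError(ValueError):
    """Statistic requested on an empty table or empty comparator."""


class CountingUnit(str, enum.Enum):
    """What one row of the 2x2 table counts at the SMQ level.

    PER_PT: every distinct (case, PT) pair is one report; a case with two
    PTs inside one SMQ contributes two reports to that SMQ.
    PER_SMQ_ONCE: at the SMQ level a case counts once per SMQ regardless of
    how many member PTs it reported (non-CV rows stay per-PT).
    """

    PER_PT = "per_pt"
    PER_SMQ_ONCE = "per_smq_once"


class Comparator(str, enum.Enum):
    """Reference rows for c/d: the unexposed background, or everything else."""

    NEITHER = "neither"  # reports with neither an ICI nor an AGI suspect
    REST = "rest"  # all reports outside the target group


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one (exposure, event) pair.

    Counts may be expectations (floats) when produced by the synthetic
    generator's closed-form oracle.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_drug(self) -> float:
        return self.a + self.b

    @property
    def n_event(self) -> float:
        return self.a + self.c

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n_expected(self) -> float:
        if self.n_total == 0:
            raise UndefinedInputError("empty contingency table (N_total = 0)")
        return self.n_drug * self.n_event / self.n_total


def shrunk_ror(t: ContingencyTable) -> float:
    """Shrinkage-transformed reporting odds ratio (a + 0.5)/(N_expected + 0.5).

    Defined for any table with N_total > 0, including a = 0; equals 1 when
    observed matches expected and when both margins are empty.
    """
    return (t.a + 0.5) / (t.n_expected + 0.5)


def ic(t: ContingencyTable) -> float:
    """Information component in bits: log2 of the shrunk observed/expected ratio."""
    return math.log2(shrunk_ror(t))


def ic_interval(ic_value: float, a: float) -> tuple[float, float]:
    """95% credibility bounds around an information component with a observed reports."""
    if a < 0:
        raise ValueError("report count must be non-negative")
    s = a + 0.5
    lower = ic_value - 3.3 * s**-0.5 - 2.0 * s**-1.5
    upper = ic_value + 2.4 * s**-0.5 - 0.5 * s**-1.5
    return lower, upper


def ror_wald_ci(t: ContingencyTable, ror_value: float) -> tuple[float, float]:
    """Wald 95% interval exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).

    Centred on the supplied (shrunk) point estimate.  Any zero cell leaves
    the bounds undefined (NaN); the point estimate itself stays defined
    through the shrinkage.
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        return (float("nan"), float("nan"))
    half = Z_95 * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror_value * math.exp(-half), ror_value * math.exp(half))


@dataclass(frozen=True)
class SignalResult:
    """All statistics for one (exposure, event) pair."""

    table: ContingencyTable
    ror: float
    ror_025: float
    ror_975: float
    ic: float
    ic_025: float
    ic_975: float

    @property
    def n_reports(self) -> float:
        return self.table.a

    @property
    def signal_by_ror(self) -> bool:
        return bool(self.n_reports >= MIN_REPORTS and self.ror_025 > 1.0)

    @property
    def signal_by_ic(self) -> bool:
        return bool(self.n_reports >= MIN_REPORTS and self.ic_025 > 0.0)


def compute_signal(t: ContingencyTable) -> SignalResult:
    """Compute both shrunk statistics, their intervals and the signal flags."""
    r = shrunk_ror(t)
    i = math.log2(r)
    lo_i, hi_i = ic_interval(i, t.a)
    lo_r, hi_r = ror_wald_ci(t, r)
    return SignalResult(table=t, ror=r, ror_025=lo_r, ror_975=hi_r, ic=i, ic_025=lo_i, ic_975=hi_i)


def classic_ror(t: ContingencyTable) -> float:
    """Cross-product odds ratio (a*d)/(b*c) — for comparison only.

    This is the textbook reporting odds ratio; the primary statistic of this
    package is the shrunk observed/expected ratio above.
    """
    if t.b * t.c == 0:
        return float("nan")
    return (t.a * t.d) / (t.b * t.c)


# ---------------------------------------------------------------------------
# Event descriptors and table assembly from a cleaned cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PtEvent:
    """A single preferred term."""

    name: str


@dataclass(frozen=True)
class SmqEvent:
    """One of the nine narrow cardiovascular SMQs."""

    smq_code: int


@dataclass(frozen=True)
class AllCardiovascular:
    """The union of the nine SMQs (overall cardiovascular analysis)."""


Event = PtEvent | SmqEvent | AllCardiovascular


def unit_frame(cohort: CleanCohort, smq_map: SmqMap, unit: CountingUnit = CountingUnit.PER_PT) -> pd.DataFrame:
    """Report-unit rows for table assembly.

    Columns: case_id, exposure_group, kind ('pt'|'smq'), key, is_cv.
    PER_PT: one row per distinct (case, PT); cardiovascular PTs flagged.
    PER_SMQ_ONCE: cardiovascular rows become distinct (case, SMQ) pairs;
    non-cardiovascular rows stay distinct (case, PT) pairs.
    """
    reac = cohort.reactions.copy()
    reac["pt_norm"] = reac["pt"].map(normalize_name)
    reac = reac.drop_duplicates(["case_id", "pt_norm"])
    groups = cohort.cases.set_index("case_id")["exposure_group"]
    membership = smq_map.membership_frame()
    cv_pts = set(membership["pt_norm"])
    reac["is_cv"] = reac["pt_norm"].isin(cv_pts)

    if unit == CountingUnit.PER_PT:
        out = reac.rename(columns={"pt_norm": "key"})[["case_id", "key", "is_cv"]]
        out.insert(1, "kind", "pt")
    else:
        non_cv = reac[~reac["is_cv"]].rename(columns={"pt_norm": "key"})[["case_id", "key"]]
        non_cv.insert(1, "kind", "pt")
        non_cv["is_cv"] = False
        cv = reac[reac["is_cv"]].merge(membership, on="pt_norm")
        cv = cv.drop_duplicates(["case_id", "smq_code"])
        cv = cv.rename(columns={"smq_code": "key"})[["case_id", "key"]]
        cv.insert(1, "kind", "smq")
        cv["is_cv"] = True
        out = pd.concat([non_cv, cv], ignore_index=True)

    out = out.copy()
    out["exposure_group"] = out["case_id"].map(groups)
    return out.reset_index(drop=True)


def _event_mask(units: pd.DataFrame, event: Event, smq_map: SmqMap, unit: CountingUnit) -> pd.Series:
    if isinstance(event, AllCardiovascular):
        return units["is_cv"]
    if isinstance(event, PtEvent):
        key = normalize_name(event.name)
        return (units["kind"] == "pt") & (units["key"] == key)
    if isinstance(event, SmqEvent):
        if unit == CountingUnit.PER_SMQ_ONCE:
            return (units["kind"] == "smq") & (units["key"] == event.smq_code)
        members = smq_map.category(event.smq_code).member_pts
        return (units["kind"] == "pt") & units["key"].isin(members)
    raise TypeError(f"unknown event type: {event!r}")


def make_table(
    cohort: CleanCohort,
    group: ExposureGroup,
    event: Event,
    smq_map: SmqMap,
    comparator: Comparator = Comparator.NEITHER,
    unit: CountingUnit = CountingUnit.PER_PT,
    units: pd.DataFrame | None = None,
) -> ContingencyTable:
    """Assemble the 2x2 report-count table for one (group, event) pair.

    The table universe is the target group's reports plus the comparator's
    reports; ``units`` may carry a precomputed :func:`unit_frame`.
    """
    if units is None:
        units = unit_frame(cohort, smq_map, unit)
    in_group = units["exposure_group"] == group.value
    if comparator == Comparator.NEITHER:
        in_comp = units["exposure_group"] == ExposureGroup.NEITHER.value
    else:
        in_comp = ~in_group
    if not in_comp.any():
        raise UndefinedInputError(f"empty comparator ({comparator.value})")
    is_event = _event_mask(units, event, smq_map, unit)
    a = int((in_group & is_event).sum())
    b = int((in_group & ~is_event).sum())
    c = int((in_comp & is_event).sum())
    d = int((in_comp & ~is_event).sum())
    return ContingencyTable(a=a, b=b, c=c, d=d)


def analyze(
    cohort: CleanCohort,
    group: ExposureGroup,
    event: Event,
    smq_map: SmqMap,
    comparator: Comparator = Comparator.NEITHER,
    unit: CountingUnit = CountingUnit.PER_PT,
    units: pd.DataFrame | None = None,
) -> SignalResult:
    """Full disproportionality analysis for one (group, event) pair."""
    t = make_table(cohort, group, event, smq_map, comparator=comparator, unit=unit, units=units)
    return compute_signal(t)


def _event_label(event: Event, smq_map: SmqMap) -> tuple[str, str]:
    if isinstance(event, AllCardiovascular):
        return "overall", "all cardiovascular"
    if isinstance(event, SmqEvent):
        return "smq", f"{NARROW_CV_SMQS.get(event.smq_code, '?')} ({event.smq_code})"
    return "pt", event.name


def analyze_all(
    cohort: CleanCohort,
    smq_map: SmqMap,
    comparator: Comparator = Comparator.NEITHER,
    unit: CountingUnit = CountingUnit.PER_PT,
    groups: tuple[ExposureGroup, ...] = EXPOSED_GROUPS,
    pt_events: list[str] | None = None,
) -> pd.DataFrame:
    """Overall, per-SMQ and per-PT analyses for each exposure group.

    ``pt_events`` defaults to every cardiovascular PT observed in the cohort.
    Returns a tidy, forest-plot-ready frame with one row per (level, event,
    group).
    """
    units = unit_frame(cohort, smq_map, unit)
    if pt_events is None:
        pt_units = unit_frame(cohort, smq_map, CountingUnit.PER_PT)
        pt_events = sorted(pt_units.loc[pt_units["is_cv"], "key"].unique())
    events: list[Event] = [AllCardiovascular()]
    events += [SmqEvent(code) for code in sorted(smq_map.codes)]
    events += [PtEvent(name) for name in pt_events]

    # PT-level rows always count per PT; SMQ/overall rows follow `unit`
    pt_frame = units if unit == CountingUnit.PER_PT else unit_frame(cohort, smq_map, CountingUnit.PER_PT)

    rows = []
    for event in events:
        level, label = _event_label(event, smq_map)
        u = pt_frame if isinstance(event, PtEvent) else units
        eff_unit = CountingUnit.PER_PT if isinstance(event, PtEvent) else unit
        for g in groups:
            res = analyze(cohort, g, event, smq_map, comparator=comparator, unit=eff_unit, units=u)
            t = res.table
            rows.append(
                {
                    "level": level,
                    "event": label,
                    "group": g.value,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "n_expected": t.n_expected,
                    "ror": res.ror,
                    "ror_025": res.ror_025,
                    "ror_975": res.ror_975,
                    "ic": res.ic,
                    "ic_025": res.ic_025,
                    "ic_975": res.ic_975,
                    "signal_by_ror": res.signal_by_ror,
                    "signal_by_ic": res.signal_by_ic,
                }
            )
    return pd.DataFrame(rows)


def round_results(df: pd.DataFrame, precision: int = 3) -> pd.DataFrame:
    """Round the statistic columns for display (default 3 decimals)."""
    out = df.copy()
    stat_cols = ["n_expected", "ror", "ror_025", "ror_975", "ic", "ic_025", "ic_975"]
    out[stat_cols] = out[stat_cols].astype(float).round(precision)
    return out
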