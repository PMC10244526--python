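"""Synthetic FAERS-like report streams with exact ground truth.

The generator emulates the features of spontaneous-report data that the
cleaning pipeline and the disproportionality statistics must survive:
duplicate/follow-up report versions, suspect vs. concomitant drug roles,
messy drug-name variants (brand names, research codes, misspellings, case
and whitespace noise), several preferred terms per case, seriousness
outcome codes, indications and demographics — with configurable
per-(exposure-group, event) relative reporting rates so every statistic can
be checked against known truth.

Generative model
----------------
Cases are drawn group-first (ICI alone / AGI alone / combination / neither),
then versioned.  Per case the number of PT mentions is zero-truncated
Poisson: each PT ``e`` receives an independent Poisson(lambda * f_e * rho_ge)
mention count, where ``f_e`` is the baseline frequency, ``rho_ge`` the
group's relative reporting rate for that PT (1 = null) and ``lambda`` the
overall PT intensity; the case is conditioned on having at least one
mention, and its reaction list is the set of distinct PTs mentioned.  This
gives closed-form per-case presence probabilities

    P(PT e present | case in g) = (1 - exp(-lambda*f_e*rho_ge)) / (1 - exp(-Lambda_g))

with Lambda_g the summed intensity, which :func:`expected_table` uses to
return exact expected 2x2 tables for any event and counting unit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .disprop import Comparator, ContingencyTable, CountingUnit, Event, AllCardiovascular, PtEvent, SmqEvent
from .faers_io import Dialect, DrugArchive, write_drug_archive, write_reports, write_smq_map
from .meddra import NARROW_CV_SMQS, SmqMap
from .model import (
    DrugClass,
    ExposureGroup,
    OutcomeCode,
    ReportSet,
    Role,
    normalize_name,
)

log = logging.getLogger(__name__)


class PtSpec(BaseModel):
    """One preferred term of the synthetic universe."""

    name: str
    freq: float = Field(gt=0)  # baseline relative frequency (normalized internally)
    smqs: tuple[int, ...] = ()  # narrow SMQ memberships (empty = non-cardiovascular)


class Multiplier(BaseModel):
    """Relative reporting rate rho for one exposure group and one event.

    Target is a PT name or an SMQ code (applied to every member PT).
    Multipliers matching the same PT multiply together.
    """

    group: ExposureGroup
    rho: float = Field(ge=0)
    pt: str | None = None
    smq: int | None = None

    @model_validator(mode="after")
    def _one_target(self):
        if (self.pt is None) == (self.smq is None):
            raise ValueError("exactly one of pt/smq must be set")
        return self


# Synthetic PT universe: plausible MedDRA-style PT names for each of the nine
# narrow cardiovascular SMQs plus common non-cardiovascular filler terms.
# Baseline frequencies put ~80% of mentions on non-CV terms.
DEFAULT_PT_UNIVERSE: tuple[PtSpec, ...] = (
    PtSpec(name="Atrial fibrillation", freq=0.012, smqs=(20000049,)),
    PtSpec(name="Ventricular tachycardia", freq=0.006, smqs=(20000049,)),
    PtSpec(name="Bradycardia", freq=0.006, smqs=(20000049,)),
    PtSpec(name="Cardiac failure", freq=0.012, smqs=(20000004,)),
    PtSpec(name="Cardiac failure congestive", freq=0.008, smqs=(20000004,)),
    PtSpec(name="Cardiomyopathy", freq=0.007, smqs=(20000150,)),
    PtSpec(name="Stress cardiomyopathy", freq=0.004, smqs=(20000150,)),
    # myocarditis sits in both the cardiomyopathy and the myocarditis/pericarditis SMQs
    PtSpec(name="Myocarditis", freq=0.008, smqs=(20000150, 20000239)),
    PtSpec(name="Immune-mediated myocarditis", freq=0.004, smqs=(20000239,)),
    PtSpec(name="Pericarditis", freq=0.006, smqs=(20000239,)),
    PtSpec(name="Pulmonary embolism", freq=0.014, smqs=(20000081,)),
    PtSpec(name="Deep vein thrombosis", freq=0.010, smqs=(20000081,)),
    PtSpec(name="Embolism", freq=0.005, smqs=(20000081,)),
    PtSpec(name="Portal vein thrombosis", freq=0.004, smqs=(20000081,)),
    PtSpec(name="Hypertension", freq=0.022, smqs=(20000147,)),
    PtSpec(name="Hypertensive crisis", freq=0.005, smqs=(20000147,)),
    PtSpec(name="Myocardial infarction", freq=0.014, smqs=(20000043,)),
    PtSpec(name="Angina pectoris", freq=0.008, smqs=(20000043,)),
    PtSpec(name="Pulmonary hypertension", freq=0.006, smqs=(20000130,)),
    PtSpec(name="Torsade de pointes", freq=0.003, smqs=(20000001,)),
    PtSpec(name="Electrocardiogram QT prolonged", freq=0.006, smqs=(20000001,)),
    PtSpec(name="Nausea", freq=0.10, smqs=()),
    PtSpec(name="Fatigue", freq=0.10, smqs=()),
    PtSpec(name="Diarrhoea", freq=0.09, smqs=()),
    PtSpec(name="Rash", freq=0.08, smqs=()),
    PtSpec(name="Pyrexia", freq=0.08, smqs=()),
    PtSpec(name="Headache", freq=0.07, smqs=()),
    PtSpec(name="Anaemia", freq=0.07, smqs=()),
    PtSpec(name="Decreased appetite", freq=0.07, smqs=()),
    PtSpec(name="Vomiting", freq=0.07, smqs=()),
    PtSpec(name="Dizziness", freq=0.06, smqs=()),
    PtSpec(name="Arthralgia", freq=0.06, smqs=()),
)

# (name_variant, class, canonical): generic names, brand names, research codes
# and a few deliberate misspellings, emulating a curated drug-name archive.
DEFAULT_ARCHIVE_ENTRIES: tuple[tuple[str, str, str], ...] = (
    ("pembrolizumab", "ICI", "pembrolizumab"),
    ("KEYTRUDA", "ICI", "pembrolizumab"),
    ("MK-3475", "ICI", "pembrolizumab"),
    ("pembrolizmab", "ICI", "pembrolizumab"),  # misspelling
    ("nivolumab", "ICI", "nivolumab"),
    ("OPDIVO", "ICI", "nivolumab"),
    ("BMS-936558", "ICI", "nivolumab"),
    ("atezolizumab", "ICI", "atezolizumab"),
    ("TECENTRIQ", "ICI", "atezolizumab"),
    ("MPDL3280A", "ICI", "atezolizumab"),
    ("ipilimumab", "ICI", "ipilimumab"),
    ("YERVOY", "ICI", "ipilimumab"),
    ("durvalumab", "ICI", "durvalumab"),
    ("IMFINZI", "ICI", "durvalumab"),
    ("avelumab", "ICI", "avelumab"),
    ("BAVENCIO", "ICI", "avelumab"),
    ("bevacizumab", "AGI", "bevacizumab"),
    ("AVASTIN", "AGI", "bevacizumab"),
    ("bevacizumb", "AGI", "bevacizumab"),  # misspelling
    ("axitinib", "AGI", "axitinib"),
    ("INLYTA", "AGI", "axitinib"),
    ("AG-013736", "AGI", "axitinib"),
    ("lenvatinib", "AGI", "lenvatinib"),
    ("LENVIMA", "AGI", "lenvatinib"),
    ("E7080", "AGI", "lenvatinib"),
    ("cabozantinib", "AGI", "cabozantinib"),
    ("CABOMETYX", "AGI", "cabozantinib"),
    ("XL184", "AGI", "cabozantinib"),
    ("sunitinib", "AGI", "sunitinib"),
    ("SUTENT", "AGI", "sunitinib"),
    ("ramucirumab", "AGI", "ramucirumab"),
    ("CYRAMZA", "AGI", "ramucirumab"),
    ("aflibercept", "AGI", "aflibercept"),
    ("ZALTRAP", "AGI", "aflibercept"),
)

#: Non-ICI/non-AGI drugs used as filler suspect/concomitant mentions.
FILLER_DRUGS = ("aspirin", "metformin", "atorvastatin", "omeprazole", "lisinopril", "levothyroxine")

ICI_CANONICALS = tuple(sorted({c for v, k, c in DEFAULT_ARCHIVE_ENTRIES if k == "ICI"}))
AGI_CANONICALS = tuple(sorted({c for v, k, c in DEFAULT_ARCHIVE_ENTRIES if k == "AGI"}))

# Outcome-category mixes per exposure group: the exposed groups follow the
# study-population percentages for cardiovascular cases; the background mix
# is skewed toward non-serious outcomes as in a general report stream.
DEFAULT_OUTCOME_MIX: dict[ExposureGroup, dict[OutcomeCode, float]] = {
    ExposureGroup.ICI_ALONE: {
        OutcomeCode.DEATH: 0.271,
        OutcomeCode.LIFE_THREATENING: 0.069,
        OutcomeCode.HOSPITALIZATION: 0.358,
        OutcomeCode.DISABILITY: 0.005,
        OutcomeCode.CONGENITAL_ANOMALY: 0.0,
        OutcomeCode.OTHER_SERIOUS: 0.183,
        OutcomeCode.UNKNOWN: 0.114,
    },
    ExposureGroup.AGI_ALONE: {
        OutcomeCode.DEATH: 0.172,
        OutcomeCode.LIFE_THREATENING: 0.037,
        OutcomeCode.HOSPITALIZATION: 0.314,
        OutcomeCode.DISABILITY: 0.005,
        OutcomeCode.CONGENITAL_ANOMALY: 0.0,
        OutcomeCode.OTHER_SERIOUS: 0.274,
        OutcomeCode.UNKNOWN: 0.198,
    },
    ExposureGroup.COMBINATION: {
        OutcomeCode.DEATH: 0.167,
        OutcomeCode.LIFE_THREATENING: 0.028,
        OutcomeCode.HOSPITALIZATION: 0.330,
        OutcomeCode.DISABILITY: 0.003,
        OutcomeCode.CONGENITAL_ANOMALY: 0.0,
        OutcomeCode.OTHER_SERIOUS: 0.159,
        OutcomeCode.UNKNOWN: 0.313,
    },
    ExposureGroup.NEITHER: {
        OutcomeCode.DEATH: 0.06,
        OutcomeCode.LIFE_THREATENING: 0.03,
        OutcomeCode.HOSPITALIZATION: 0.25,
        OutcomeCode.DISABILITY: 0.01,
        OutcomeCode.CONGENITAL_ANOMALY: 0.001,
        OutcomeCode.OTHER_SERIOUS: 0.30,
        OutcomeCode.UNKNOWN: 0.349,
    },
}

DEFAULT_INDICATION_MIX: dict[ExposureGroup, dict[str, float]] = {
    ExposureGroup.ICI_ALONE: {
        "Non-small cell lung cancer": 0.26,
        "Melanoma": 0.17,
        "Renal cell carcinoma": 0.08,
        "Hepatocellular carcinoma": 0.01,
        "Breast cancer": 0.02,
        "Product used for unknown indication": 0.46,
    },
    ExposureGroup.AGI_ALONE: {
        "Renal cell carcinoma": 0.21,
        "Colorectal cancer": 0.14,
        "Hepatocellular carcinoma": 0.07,
        "Non-small cell lung cancer": 0.03,
        "Breast cancer": 0.03,
        "Product used for unknown indication": 0.52,
    },
    ExposureGroup.COMBINATION: {
        "Renal cell carcinoma": 0.28,
        "Endometrial cancer": 0.17,
        "Hepatocellular carcinoma": 0.12,
        "Non-small cell lung cancer": 0.11,
        "Melanoma": 0.02,
        "Product used for unknown indication": 0.30,
    },
    ExposureGroup.NEITHER: {
        "Hypertension": 0.20,
        "Diabetes mellitus": 0.15,
        "Rheumatoid arthritis": 0.12,
        "Depression": 0.10,
        "Breast cancer": 0.04,
        "Product used for unknown indication": 0.39,
    },
}

# Relative reporting rates mirroring the study conditions: myocarditis-type
# events dominate for ICIs, hypertension/embolic events for AGIs, and the
# combination shifts weight from myocarditis toward embolic events.
DEFAULT_MULTIPLIERS: tuple[Multiplier, ...] = (
    Multiplier(group=ExposureGroup.ICI_ALONE, smq=20000239, rho=6.0),
    Multiplier(group=ExposureGroup.ICI_ALONE, smq=20000150, rho=2.0),
    Multiplier(group=ExposureGroup.ICI_ALONE, smq=20000081, rho=1.3),
    Multiplier(group=ExposureGroup.AGI_ALONE, smq=20000147, rho=5.0),
    Multiplier(group=ExposureGroup.AGI_ALONE, smq=20000081, rho=2.0),
    Multiplier(group=ExposureGroup.AGI_ALONE, smq=20000130, rho=2.0),
    Multiplier(group=ExposureGroup.AGI_ALONE, smq=20000004, rho=1.5),
    Multiplier(group=ExposureGroup.COMBINATION, smq=20000147, rho=5.0),
    Multiplier(group=ExposureGroup.COMBINATION, smq=20000081, rho=3.0),
    Multiplier(group=ExposureGroup.COMBINATION, smq=20000239, rho=3.0),
    Multiplier(group=ExposureGroup.COMBINATION, smq=20000150, rho=2.0),
    Multiplier(group=ExposureGroup.COMBINATION, smq=20000043, rho=1.5),
)


class SyntheticConfig(BaseModel):
    """Full configuration of the synthetic report stream."""

    seed: int = 0
    n_cases: dict[ExposureGroup, int] = Field(
        default_factory=lambda: {
            ExposureGroup.ICI_ALONE: 2000,
            ExposureGroup.AGI_ALONE: 4000,
            ExposureGroup.COMBINATION: 600,
            ExposureGroup.NEITHER: 20000,
        }
    )
    pt_rate_mean: float = Field(default=2.0, gt=0)  # lambda: mean PT mentions per case (pre-truncation)
    pt_universe: tuple[PtSpec, ...] = DEFAULT_PT_UNIVERSE
    multipliers: tuple[Multiplier, ...] = DEFAULT_MULTIPLIERS
    dup_extra_versions_mean: float = Field(default=0.4, ge=0)  # Poisson extra report versions per case
    extra_drugs_mean: float = Field(default=0.8, ge=0)  # Poisson filler drug mentions per case
    p_filler_suspect: float = Field(default=0.3, ge=0, le=1)
    p_concomitant_class_drug: float = Field(default=0.05, ge=0, le=1)  # decoy ICI/AGI with concomitant role
    p_name_noise: float = Field(default=0.3, ge=0, le=1)  # random case/whitespace mangling
    p_age_missing: float = Field(default=0.22, ge=0, le=1)
    outcome_mix: dict[ExposureGroup, dict[OutcomeCode, float]] = Field(
        default_factory=lambda: DEFAULT_OUTCOME_MIX
    )
    p_extra_outcome: float = Field(default=0.2, ge=0, le=1)  # extra lower-precedence outcome code
    indication_mix: dict[ExposureGroup, dict[str, float]] = Field(
        default_factory=lambda: DEFAULT_INDICATION_MIX
    )
    year_range: tuple[int, int] = (2014, 2022)

    @field_validator("pt_universe")
    @classmethod
    def _covers_all_smqs(cls, universe):
        covered = {c for spec in universe for c in spec.smqs}
        missing = set(NARROW_CV_SMQS) - covered
        if missing:
            raise ValueError(f"PT universe misses SMQs: {sorted(missing)}")
        names = [normalize_name(s.name) for s in universe]
        if len(names) != len(set(names)):
            raise ValueError("duplicate PT names in universe")
        return universe

    @model_validator(mode="after")
    def _valid_mixes(self):
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be increasing")
        for g, mix in self.outcome_mix.items():
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"outcome mix for {g} sums to {total}, expected 1")
        for g, mix in self.indication_mix.items():
            if any(p < 0 for p in mix.values()):
                raise ValueError("negative indication probability")
        return self


def default_config(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**overrides)


def default_smq_map(config: SyntheticConfig | None = None) -> SmqMap:
    """SMQ map implied by the synthetic PT universe."""
    universe = config.pt_universe if config else DEFAULT_PT_UNIVERSE
    records = [(spec.name, code) for spec in universe for code in spec.smqs]
    return SmqMap.from_records(records)


def default_archive() -> DrugArchive:
    df = pd.DataFrame(DEFAULT_ARCHIVE_ENTRIES, columns=["name_variant", "drug_class", "canonical_name"])
    df["name_variant"] = df["name_variant"].map(normalize_name)
    df["canonical_name"] = df["canonical_name"].map(normalize_name)
    return DrugArchive(df)


# ---------------------------------------------------------------------------
# Rates and closed-form expectations
# ---------------------------------------------------------------------------


def pt_intensities(config: SyntheticConfig, group: ExposureGroup) -> pd.DataFrame:
    """Per-PT mention intensities for one group.

    Columns: name, freq (normalized baseline), rho (combined multiplier),
    lam (= pt_rate_mean * freq * rho).
    """
    df = pd.DataFrame(
        {
            "name": [s.name for s in config.pt_universe],
            "freq": [s.freq for s in config.pt_universe],
            "smqs": [s.smqs for s in config.pt_universe],
        }
    )
    df["freq"] = df["freq"] / df["freq"].sum()
    rho = np.ones(len(df))
    for m in config.multipliers:
        if m.group != group:
            continue
        if m.pt is not None:
            mask = df["name"].map(normalize_name) == normalize_name(m.pt)
        else:
            mask = df["smqs"].map(lambda s: m.smq in s)
        rho = np.where(mask, rho * m.rho, rho)
    df["rho"] = rho
    df["lam"] = config.pt_rate_mean * df["freq"] * df["rho"]
    return df


def _presence_probs(config: SyntheticConfig, group: ExposureGroup) -> pd.DataFrame:
    """Per-PT presence probabilities q_e = P(PT in case's reaction set)."""
    df = pt_intensities(config, group)
    big_lambda = df["lam"].sum()
    p_any = 1.0 - math.exp(-big_lambda)
    df["q"] = (1.0 - np.exp(-df["lam"])) / p_any
    df.attrs["big_lambda"] = big_lambda
    df.attrs["p_any"] = p_any
    return df


def _expected_margins(
    config: SyntheticConfig, group: ExposureGroup, event: Event, unit: CountingUnit, smq_map: SmqMap
) -> tuple[float, float]:
    """Expected (a, total reports) for one group under the generative model."""
    df = _presence_probs(config, group)
    n = config.n_cases.get(group, 0)
    p_any = df.attrs["p_any"]
    is_cv = df["smqs"].map(bool)

    def q_set(mask: pd.Series) -> float:
        """P(case reports at least one PT of the set) — exact under the model."""
        lam_set = df.loc[mask, "lam"].sum()
        return (1.0 - math.exp(-lam_set)) / p_any

    if unit == CountingUnit.PER_PT:
        total = df["q"].sum()
        if isinstance(event, PtEvent):
            a = df.loc[df["name"].map(normalize_name) == normalize_name(event.name), "q"].sum()
        elif isinstance(event, SmqEvent):
            members = smq_map.category(event.smq_code).member_pts
            a = df.loc[df["name"].map(normalize_name).isin(members), "q"].sum()
        else:
            a = df.loc[is_cv, "q"].sum()
    else:
        smq_qs = {code: q_set(df["smqs"].map(lambda s: code in s)) for code in sorted(smq_map.codes)}
        total = sum(smq_qs.values()) + df.loc[~is_cv, "q"].sum()
        if isinstance(event, PtEvent):
            raise ValueError("PT-level events are always counted per PT")
        if isinstance(event, SmqEvent):
            a = smq_qs[event.smq_code]
        else:
            a = sum(smq_qs.values())
    return n * a, n * total


def expected_table(
    config: SyntheticConfig,
    event: Event,
    group: ExposureGroup,
    comparator: Comparator = Comparator.NEITHER,
    unit: CountingUnit = CountingUnit.PER_PT,
    smq_map: SmqMap | None = None,
) -> ContingencyTable:
    """Exact expected 2x2 table under the generative model (the test oracle)."""
    smq_map = smq_map or default_smq_map(config)
    a, total_g = _expected_margins(config, group, event, unit, smq_map)
    if comparator == Comparator.NEITHER:
        comp_groups = [ExposureGroup.NEITHER]
    else:
        comp_groups = [g for g in ExposureGroup if g != group]
    c = tot_c = 0.0
    for g in comp_groups:
        cg, tg = _expected_margins(config, g, event, unit, smq_map)
        c += cg
        tot_c += tg
    return ContingencyTable(a=a, b=total_g - a, c=c, d=tot_c - c)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    k = rng.poisson(lam, size)
    while (zero := k == 0).any():
        k[zero] = rng.poisson(lam, int(zero.sum()))
    return k


def simulate_event_arrays(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    groups: tuple[ExposureGroup, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the event layer only, as flat arrays (case_idx, group_idx, pt_idx).

    One element per distinct (case, PT) pair; ``group_idx`` indexes into
    ``groups`` and ``pt_idx`` into ``config.pt_universe``.  Same generative
    law as :func:`simulate`, without drugs/versions/demographics — the fast
    path for large calibration studies.
    """
    rng = rng or np.random.default_rng(config.seed)
    groups = groups or tuple(ExposureGroup)
    n_pts = len(config.pt_universe)
    case_parts, pt_parts, group_parts = [], [], []
    offset = 0
    for gi, g in enumerate(groups):
        n = config.n_cases.get(g, 0)
        if n == 0:
            continue
        df = pt_intensities(config, g)
        lam_total = df["lam"].sum()
        p = (df["lam"] / lam_total).to_numpy()
        k = _zero_truncated_poisson(rng, lam_total, n)
        draws = rng.choice(n_pts, size=int(k.sum()), p=p)
        case_idx = np.repeat(np.arange(n, dtype=np.int64), k)
        # distinct (case, pt) pairs via a packed key (sort-based dedup)
        packed = case_idx * n_pts + draws
        if n * n_pts < np.iinfo(np.int32).max:
            packed = packed.astype(np.int32)
        packed.sort(kind="stable")
        if len(packed):
            packed = packed[np.concatenate(([True], packed[1:] != packed[:-1]))]
        case_parts.append(packed // n_pts + offset)
        pt_parts.append((packed % n_pts).astype(np.int16))
        group_parts.append(np.full(len(packed), gi, dtype=np.int8))
        offset += n
    return (
        np.concatenate(case_parts),
        np.concatenate(group_parts),
        np.concatenate(pt_parts),
    )


def simulate_events(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    groups: tuple[ExposureGroup, ...] | None = None,
) -> pd.DataFrame:
    """Event layer as a frame: columns case_id, exposure_group, pt, is_cv."""
    groups = groups or tuple(ExposureGroup)
    case_idx, group_idx, pt_idx = simulate_event_arrays(config, rng, groups)
    names = [s.name for s in config.pt_universe]
    is_cv = np.array([bool(s.smqs) for s in config.pt_universe])
    return pd.DataFrame(
        {
            "case_id": case_idx,
            "exposure_group": pd.Categorical.from_codes(
                group_idx, categories=[g.value for g in groups]
            ),
            "pt": pd.Categorical.from_codes(pt_idx, categories=names),
            "is_cv": is_cv[pt_idx],
        }
    )


@dataclass
class GroundTruth:
    """Generator bookkeeping for end-to-end conservation checks."""

    seed: int
    n_cases: dict[str, int]  # per group
    n_reports_written: int  # report versions across all tables
    cv_cases: dict[str, int]  # per group: cases with >=1 CV PT
    cv_reports: dict[str, int]  # per group: distinct (case, CV PT) pairs
    pt_report_counts: dict[str, dict[str, int]]  # group -> PT -> distinct-case count
    outcome_counts: dict[str, dict[str, int]]  # group -> category -> CV-case count

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path | str) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _mangle(name: str, rng: np.random.Generator) -> str:
    """Normalization-recoverable name noise: casing and stray whitespace."""
    u = rng.random()
    if u < 0.4:
        name = name.upper()
    elif u < 0.6:
        name = name.lower()
    if rng.random() < 0.3:
        name = f"  {name} "
    return name


def simulate(config: SyntheticConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw a full report stream (with duplicate versions) plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    archive = default_archive()
    smq = default_smq_map(config)
    cv_pts = {normalize_name(s.name) for s in config.pt_universe if s.smqs}
    precedence_idx = {c: i for i, c in enumerate(
        (OutcomeCode.DEATH, OutcomeCode.LIFE_THREATENING, OutcomeCode.DISABILITY,
         OutcomeCode.CONGENITAL_ANOMALY, OutcomeCode.HOSPITALIZATION,
         OutcomeCode.OTHER_SERIOUS, OutcomeCode.UNKNOWN)
    )}

    countries = ("US", "JP", "FR", "DE", "CA", "GB", "CN", "IT", "ES", "unknown")
    country_p = (0.45, 0.12, 0.06, 0.05, 0.04, 0.03, 0.03, 0.03, 0.18, 0.01)
    years = list(range(config.year_range[0], config.year_range[1] + 1))
    ramp = np.linspace(1.0, 2.0, len(years))
    year_p = ramp / ramp.sum()

    demo_rows, drug_rows, reac_rows, outc_rows, indi_rows = [], [], [], [], []
    truth_cv_cases: dict[str, int] = {}
    truth_cv_reports: dict[str, int] = {}
    truth_pt_counts: dict[str, dict[str, int]] = {}
    truth_outcomes: dict[str, dict[str, int]] = {}

    case_num = 0
    for g in ExposureGroup:
        n = config.n_cases.get(g, 0)
        truth_pt_counts[g.value] = {}
        truth_outcomes[g.value] = {}
        cv_case_count = cv_report_count = 0
        if n == 0:
            truth_cv_cases[g.value] = truth_cv_reports[g.value] = 0
            continue

        # event layer (same law as simulate_events)
        df = pt_intensities(config, g)
        lam_total = df["lam"].sum()
        p = (df["lam"] / lam_total).to_numpy()
        names = df["name"].to_list()
        k = _zero_truncated_poisson(rng, lam_total, n)
        draws = rng.choice(len(df), size=int(k.sum()), p=p)
        split = np.split(draws, np.cumsum(k)[:-1])

        # demographics / mixes, vectorized per group
        ages = rng.normal(66, 12, n).clip(18, 95).round()
        age_missing = rng.random(n) < config.p_age_missing
        sexes = rng.choice(["male", "female", "unknown"], size=n, p=[0.52, 0.40, 0.08])
        reporters = rng.choice(
            ["health_professional", "non_health_professional", "unknown"],
            size=n,
            p=[0.65, 0.32, 0.03],
        )
        ctry = rng.choice(countries, size=n, p=country_p)
        yrs = rng.choice(years, size=n, p=year_p)
        out_mix = config.outcome_mix[g]
        out_cats = rng.choice([c.value for c in out_mix], size=n, p=list(out_mix.values()))
        ind_mix = config.indication_mix[g]
        ind_p = np.array(list(ind_mix.values()), dtype=float)
        ind_p = ind_p / ind_p.sum()
        indications = rng.choice(list(ind_mix), size=n, p=ind_p)
        extra_versions = np.minimum(rng.poisson(config.dup_extra_versions_mean, n), 3)
        n_fillers = rng.poisson(config.extra_drugs_mean, n)

        for i in range(n):
            case_num += 1
            case_id = f"C{case_num:07d}"
            reactions = list(dict.fromkeys(names[j] for j in split[i]))

            # drug mentions: class drugs (suspect), fillers, optional decoy
            mentions: list[tuple[str, Role]] = []
            if g in (ExposureGroup.ICI_ALONE, ExposureGroup.COMBINATION):
                mentions.append((str(rng.choice(ICI_CANONICALS)), Role.SUSPECT))
            if g in (ExposureGroup.AGI_ALONE, ExposureGroup.COMBINATION):
                mentions.append((str(rng.choice(AGI_CANONICALS)), Role.SUSPECT))
            n_fill = int(n_fillers[i]) + (1 if g == ExposureGroup.NEITHER else 0)
            for _ in range(n_fill):
                role = Role.SUSPECT if rng.random() < config.p_filler_suspect else (
                    Role.INTERACTING if rng.random() < 0.1 else Role.CONCOMITANT
                )
                mentions.append((str(rng.choice(FILLER_DRUGS)), role))
            if g == ExposureGroup.NEITHER and not any(r == Role.SUSPECT for _, r in mentions):
                mentions[0] = (mentions[0][0], Role.SUSPECT)
            if rng.random() < config.p_concomitant_class_drug:
                decoy_pool = AGI_CANONICALS if g == ExposureGroup.ICI_ALONE else ICI_CANONICALS
                mentions.append((str(rng.choice(decoy_pool)), Role.CONCOMITANT))

            # render names through archive variants + cosmetic noise
            rendered: list[tuple[str, Role]] = []
            for name, role in mentions:
                variants = archive.variants_of(name)
                if variants:
                    name = str(rng.choice(variants))
                if rng.random() < config.p_name_noise:
                    name = _mangle(name, rng)
                rendered.append((name, role))

            # outcome codes: the true category plus maybe one lower-precedence code
            cat = OutcomeCode(out_cats[i])
            codes = [] if cat == OutcomeCode.UNKNOWN else [cat]
            if codes and rng.random() < config.p_extra_outcome:
                lower = [c for c in precedence_idx if precedence_idx[c] > precedence_idx[cat] and c != OutcomeCode.UNKNOWN]
                if lower:
                    codes.append(lower[int(rng.integers(len(lower)))])

            # versions: earlier follow-ups carry a reaction-list prefix
            n_versions = 1 + int(extra_versions[i])
            base = date(int(yrs[i]), 1, 1) + timedelta(days=int(rng.integers(0, 330)))
            for v in range(n_versions):
                rid = f"{case_num:07d}{v + 1:02d}"
                is_final = v == n_versions - 1
                n_reac = len(reactions) if is_final else max(1, len(reactions) - (n_versions - 1 - v))
                demo_rows.append(
                    {
                        "report_id": rid,
                        "case_id": case_id,
                        "fda_receipt_date": base + timedelta(days=40 * v),
                        "age_years": float("nan") if age_missing[i] else float(ages[i]),
                        "sex": sexes[i],
                        "reporter_type": reporters[i],
                        "country": ctry[i],
                    }
                )
                for name, role in rendered:
                    drug_rows.append({"report_id": rid, "verbatim_name": name, "role": role.value})
                for pt in reactions[:n_reac]:
                    reac_rows.append({"report_id": rid, "pt": pt})
                for code in codes:
                    outc_rows.append({"report_id": rid, "outcome": code.value})
                indi_rows.append({"report_id": rid, "indication": indications[i]})

            # ground truth bookkeeping (final-version content)
            case_cv = [r for r in reactions if normalize_name(r) in cv_pts]
            if case_cv:
                cv_case_count += 1
                cv_report_count += len(case_cv)
                truth_outcomes[g.value][cat.value] = truth_outcomes[g.value].get(cat.value, 0) + 1
            for r in reactions:
                truth_pt_counts[g.value][r] = truth_pt_counts[g.value].get(r, 0) + 1

        truth_cv_cases[g.value] = cv_case_count
        truth_cv_reports[g.value] = cv_report_count

    rs = ReportSet(
        demo=pd.DataFrame(demo_rows),
        drugs=pd.DataFrame(drug_rows),
        reactions=pd.DataFrame(reac_rows),
        outcomes=pd.DataFrame(outc_rows),
        indications=pd.DataFrame(indi_rows),
    )
    truth = GroundTruth(
        seed=config.seed,
        n_cases={g.value: config.n_cases.get(g, 0) for g in ExposureGroup},
        n_reports_written=len(rs.demo),
        cv_cases=truth_cv_cases,
        cv_reports=truth_cv_reports,
        pt_report_counts=truth_pt_counts,
        outcome_counts=truth_outcomes,
    )
    log.info("simulated %d cases / %d report versions", case_num, truth.n_reports_written)
    return rs, truth


def generate(config: SyntheticConfig, outdir: Path | str, dialect: Dialect | None = None) -> GroundTruth:
    """Write a synthetic batch to disk: quarterly tables, the drug archive,
    the SMQ map, and the ground-truth ledger (``ground_truth.json``)."""
    SyntheticConfig.model_validate(config)  # validate before touching disk
    outdir = Path(outdir)
    rs, truth = simulate(config)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reports(rs, outdir, dialect)
    write_drug_archive(default_archive(), outdir / "drug_archive.tsv")
    write_smq_map(default_smq_map(config), outdir / "smq_map.tsv")
    truth.to_json(outdir / "ground_truth.json")
    return truth
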