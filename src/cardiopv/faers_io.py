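"""Readers and writers for FAERS-style quarterly ASCII tables.

FAERS quarterly extracts ship as ``$``-delimited ASCII tables: demographics
(DEMO), drugs (DRUG), reactions (REAC), outcomes (OUTC) and indications
(INDI), joined by a version-specific report key (``primaryid``).  The dialect
— delimiter, file names, column names — is configurable; tab-delimited files
are accepted with ``delimiter="\\t"``.

Two auxiliary dictionaries are read here as well: the drug-name archive
(generic/brand/research-code name variants -> ICI/AGI class) and the PT->SMQ
map for the nine narrow cardiovascular SMQs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .meddra import NARROW_CV_SMQS, SmqMap
from .model import (
    DEMO_COLUMNS,
    DrugClass,
    OutcomeCode,
    ReporterType,
    ReportSet,
    Role,
    Sex,
    normalize_name,
)

log = logging.getLogger(__name__)

TABLE_KINDS = ("demo", "drug", "reac", "outc", "indi")


class FaersFormatError(ValueError):
    """Malformed input table (bad columns, duplicate keys, unparseable rows)."""


class DataError(ValueError):
    """Inconsistent dictionary content (e.g. conflicting drug-class entries)."""


# FAERS code vocabularies <-> internal enums
ROLE_CODES = {
    "PS": Role.SUSPECT,  # primary suspect
    "SS": Role.SUSPECT,  # secondary suspect
    "C": Role.CONCOMITANT,
    "I": Role.INTERACTING,
    "SUSPECT": Role.SUSPECT,
    "CONCOMITANT": Role.CONCOMITANT,
    "INTERACTING": Role.INTERACTING,
}
ROLE_TO_CODE = {Role.SUSPECT: "PS", Role.CONCOMITANT: "C", Role.INTERACTING: "I"}

OUTCOME_CODES = {
    "DE": OutcomeCode.DEATH,
    "LT": OutcomeCode.LIFE_THREATENING,
    "HO": OutcomeCode.HOSPITALIZATION,
    "DS": OutcomeCode.DISABILITY,
    "CA": OutcomeCode.CONGENITAL_ANOMALY,
    "OT": OutcomeCode.OTHER_SERIOUS,
    "RI": OutcomeCode.OTHER_SERIOUS,  # required intervention: folded into other-serious
}
OUTCOME_TO_CODE = {
    OutcomeCode.DEATH: "DE",
    OutcomeCode.LIFE_THREATENING: "LT",
    OutcomeCode.HOSPITALIZATION: "HO",
    OutcomeCode.DISABILITY: "DS",
    OutcomeCode.CONGENITAL_ANOMALY: "CA",
    OutcomeCode.OTHER_SERIOUS: "OT",
}

REPORTER_CODES = {
    "MD": ReporterType.HEALTH_PROFESSIONAL,
    "PH": ReporterType.HEALTH_PROFESSIONAL,
    "HP": ReporterType.HEALTH_PROFESSIONAL,
    "OT": ReporterType.HEALTH_PROFESSIONAL,  # "other health professional"
    "CN": ReporterType.NON_HEALTH_PROFESSIONAL,
    "LW": ReporterType.NON_HEALTH_PROFESSIONAL,
}
REPORTER_TO_CODE = {
    ReporterType.HEALTH_PROFESSIONAL: "MD",
    ReporterType.NON_HEALTH_PROFESSIONAL: "CN",
    ReporterType.UNKNOWN: "",
}

SEX_CODES = {"M": Sex.MALE, "F": Sex.FEMALE}
SEX_TO_CODE = {Sex.MALE: "M", Sex.FEMALE: "F", Sex.UNKNOWN: "UNK"}


@dataclass(frozen=True)
class Dialect:
    """Parsing dialect for one set of quarterly tables."""

    delimiter: str = "$"
    filenames: Mapping[str, str] = field(
        default_factory=lambda: {
            "demo": "demo.txt",
            "drug": "drug.txt",
            "reac": "reac.txt",
            "outc": "outc.txt",
            "indi": "indi.txt",
        }
    )
    # column names in the physical files, per table kind
    columns: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: {
            "demo": {
                "report_id": "primaryid",
                "case_id": "caseid",
                "fda_receipt_date": "fda_dt",
                "age_years": "age",
                "sex": "sex",
                "reporter_type": "occp_cod",
                "country": "occr_country",
            },
            "drug": {"report_id": "primaryid", "verbatim_name": "drugname", "role": "role_cod"},
            "reac": {"report_id": "primaryid", "pt": "pt"},
            "outc": {"report_id": "primaryid", "outcome": "outc_cod"},
            "indi": {"report_id": "primaryid", "indication": "indi_pt"},
        }
    )

    def with_delimiter(self, delimiter: str) -> "Dialect":
        return replace(self, delimiter=delimiter)


def _table_paths(source: Path | Mapping[str, Path], dialect: Dialect) -> dict[str, Path]:
    if isinstance(source, Mapping):
        paths = {k: Path(v) for k, v in source.items()}
    else:
        root = Path(source)
        paths = {kind: root / dialect.filenames[kind] for kind in TABLE_KINDS}
    unknown = set(paths) - set(TABLE_KINDS)
    if unknown:
        raise FaersFormatError(f"unknown table kinds: {sorted(unknown)}")
    return paths


def _read_table(path: Path, kind: str, dialect: Dialect) -> pd.DataFrame:
    colmap = dialect.columns[kind]
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False, engine="python")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FaersFormatError(f"{path}: cannot parse ({exc})") from exc
    missing = set(colmap.values()) - set(df.columns)
    if missing:
        raise FaersFormatError(f"{path}: missing columns {sorted(missing)} (found {list(df.columns)})")
    df = df[[colmap[k] for k in colmap]]
    df.columns = list(colmap)
    return df


def read_reports(source: Path | str | Mapping[str, Path], dialect: Dialect | None = None) -> ReportSet:
    """Read one batch of quarterly tables into a :class:`ReportSet`.

    ``source`` is either a directory containing the five tables under the
    dialect's file names, or a mapping ``{"demo": path, "drug": path, ...}``.
    Child rows whose report key has no demographics row fail the join and are
    dropped with a logged count.  A report with no reaction rows is kept here
    (it is rejected downstream when events are counted).

    Raises
    ------
    FaersFormatError
        On unparseable files, missing columns, or a duplicate report key
        within the demographics table.
    """
    dialect = dialect or Dialect()
    paths = _table_paths(Path(source) if isinstance(source, (str, Path)) else source, dialect)
    for kind, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"{kind} table not found: {p}")

    demo = _read_table(paths["demo"], "demo", dialect)
    dup = demo["report_id"].duplicated()
    if dup.any():
        first = demo.loc[dup, "report_id"].iloc[0]
        raise FaersFormatError(
            f"{paths['demo']}: duplicate report_id {first!r} "
            f"(row {int(dup.idxmax()) + 2} counting the header)"
        )

    # field coercions; unknown codes degrade to the explicit 'unknown' values
    demo["fda_receipt_date"] = pd.to_datetime(
        demo["fda_receipt_date"], format="%Y%m%d", errors="coerce"
    ).dt.date
    if demo["fda_receipt_date"].isna().any():
        n = int(demo["fda_receipt_date"].isna().sum())
        raise FaersFormatError(f"{paths['demo']}: {n} rows with unparseable fda_dt")
    demo["age_years"] = pd.to_numeric(demo["age_years"], errors="coerce")
    demo.loc[demo["age_years"] < 0, "age_years"] = float("nan")
    demo["sex"] = demo["sex"].str.upper().map(lambda x: SEX_CODES.get(x, Sex.UNKNOWN).value)
    demo["reporter_type"] = demo["reporter_type"].str.upper().map(
        lambda x: REPORTER_CODES.get(x, ReporterType.UNKNOWN).value
    )
    demo["country"] = demo["country"].where(demo["country"].str.strip() != "", "unknown")

    known = set(demo["report_id"])
    frames: dict[str, pd.DataFrame] = {"demo": demo}
    for kind in ("drug", "reac", "outc", "indi"):
        df = _read_table(paths[kind], kind, dialect)
        orphans = ~df["report_id"].isin(known)
        if orphans.any():
            log.warning("%s: dropped %d rows with no matching demographics row", paths[kind], int(orphans.sum()))
        frames[kind] = df[~orphans].reset_index(drop=True)

    drug = frames["drug"]
    bad_role = ~drug["role"].str.upper().isin(ROLE_CODES)
    if bad_role.any():
        raise FaersFormatError(
            f"{paths['drug']}: unknown role code {drug.loc[bad_role, 'role'].iloc[0]!r}"
        )
    drug["role"] = drug["role"].str.upper().map(lambda x: ROLE_CODES[x].value)

    outc = frames["outc"]
    outc["outcome"] = outc["outcome"].str.upper().map(
        lambda x: OUTCOME_CODES.get(x, OutcomeCode.UNKNOWN).value
    )

    rs = ReportSet(
        demo=demo[DEMO_COLUMNS],
        drugs=drug,
        reactions=frames["reac"],
        outcomes=outc,
        indications=frames["indi"],
    )
    log.info(
        "read %d reports (%d drug rows, %d reaction rows, %d outcome rows, %d indication rows)",
        rs.n_reports, len(rs.drugs), len(rs.reactions), len(rs.outcomes), len(rs.indications),
    )
    return rs


def write_reports(rs: ReportSet, outdir: Path | str, dialect: Dialect | None = None) -> dict[str, Path]:
    """Write a :class:`ReportSet` back to quarterly tables (inverse of read)."""
    dialect = dialect or Dialect()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    demo = rs.demo.copy()
    demo["fda_receipt_date"] = pd.to_datetime(demo["fda_receipt_date"]).dt.strftime("%Y%m%d")
    demo["sex"] = demo["sex"].map(lambda x: SEX_TO_CODE[Sex(x)])
    demo["reporter_type"] = demo["reporter_type"].map(lambda x: REPORTER_TO_CODE[ReporterType(x)])
    demo["age_years"] = demo["age_years"].map(lambda a: "" if pd.isna(a) else f"{a:g}")

    drugs = rs.drugs.copy()
    drugs["role"] = drugs["role"].map(lambda x: ROLE_TO_CODE[Role(x)])
    outc = rs.outcomes.copy()
    outc = outc[outc["outcome"] != OutcomeCode.UNKNOWN.value]
    outc["outcome"] = outc["outcome"].map(lambda x: OUTCOME_TO_CODE[OutcomeCode(x)])

    tables = {"demo": demo, "drug": drugs, "reac": rs.reactions, "outc": outc, "indi": rs.indications}
    paths: dict[str, Path] = {}
    for kind, df in tables.items():
        colmap = dialect.columns[kind]
        out = df[list(colmap)].copy()
        out.columns = [colmap[k] for k in colmap]
        path = outdir / dialect.filenames[kind]
        out.to_csv(path, sep=dialect.delimiter, index=False)
        paths[kind] = path
    log.info("wrote %d reports to %s", rs.n_reports, outdir)
    return paths


@dataclass
class DrugArchive:
    """Drug-name dictionary: normalized name variant -> (class, canonical name)."""

    entries: pd.DataFrame  # columns: name_variant, drug_class, canonical_name (normalized)

    def __post_init__(self) -> None:
        self._lookup: dict[str, tuple[DrugClass, str]] = {
            r.name_variant: (DrugClass(r.drug_class), r.canonical_name)
            for r in self.entries.itertuples(index=False)
        }

    def classify(self, verbatim_name: str) -> DrugClass | None:
        hit = self._lookup.get(normalize_name(verbatim_name))
        return hit[0] if hit else None

    def canonical(self, verbatim_name: str) -> str | None:
        hit = self._lookup.get(normalize_name(verbatim_name))
        return hit[1] if hit else None

    def variants_of(self, canonical_name: str) -> list[str]:
        canonical_name = normalize_name(canonical_name)
        return [
            r.name_variant
            for r in self.entries.itertuples(index=False)
            if r.canonical_name == canonical_name
        ]

    def __len__(self) -> int:
        return len(self.entries)


def read_drug_archive(path: Path | str) -> DrugArchive:
    """Read the drug-name archive TSV (columns name_variant, drug_class, canonical_name).

    Name variants are normalized (case-fold, trim, collapse whitespace); a
    normalized variant mapped to conflicting classes or canonical names is a
    :class:`DataError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name_variant", "drug_class", "canonical_name"}
    if missing := required - set(df.columns):
        raise FaersFormatError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["drug_class"].isin([c.value for c in DrugClass])
    if bad.any():
        raise DataError(f"{path}: unknown drug_class {df.loc[bad, 'drug_class'].iloc[0]!r}")
    df["name_variant"] = df["name_variant"].map(normalize_name)
    df["canonical_name"] = df["canonical_name"].map(normalize_name)
    df = df.drop_duplicates()
    conflicts = df[df["name_variant"].duplicated(keep=False)]
    if not conflicts.empty:
        name = conflicts["name_variant"].iloc[0]
        raise DataError(f"{path}: name variant {name!r} maps to conflicting entries")
    classes = set(df["drug_class"])
    if classes != {c.value for c in DrugClass}:
        log.warning("%s: archive covers only drug classes %s", path, sorted(classes))
    log.info("read drug archive: %d name variants", len(df))
    return DrugArchive(df.reset_index(drop=True))


def read_smq_map(path: Path | str) -> SmqMap:
    """Read the PT->SMQ map TSV (columns pt, smq_code, smq_name, scope).

    Only narrow-scope rows within the nine cardiovascular SMQ codes are
    retained; other rows are skipped with a warning.  Missing SMQ codes are
    warned about by :class:`SmqMap`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pt": str, "smq_name": str, "scope": str})
    required = {"pt", "smq_code", "smq_name", "scope"}
    if missing := required - set(df.columns):
        raise FaersFormatError(f"{path}: missing columns {sorted(missing)}")
    df["smq_code"] = pd.to_numeric(df["smq_code"], errors="coerce").astype("Int64")

    non_narrow = df["scope"].str.lower() != "narrow"
    if non_narrow.any():
        log.warning("%s: skipped %d non-narrow-scope rows", path, int(non_narrow.sum()))
    df = df[~non_narrow]
    unknown = ~df["smq_code"].isin(list(NARROW_CV_SMQS))
    if unknown.any():
        log.warning("%s: skipped %d rows with SMQ codes outside the 9 cardiovascular SMQs", path, int(unknown.sum()))
    df = df[~unknown]
    log.info("read SMQ map: %d narrow PT memberships over %d SMQs", len(df), df["smq_code"].nunique())
    return SmqMap(df[["pt", "smq_code", "smq_name"]].reset_index(drop=True))


def write_drug_archive(archive: DrugArchive, path: Path | str) -> None:
    archive.entries.to_csv(path, sep="\t", index=False)


def write_smq_map(smq: SmqMap, path: Path | str) -> None:
    df = smq.entries[["pt", "smq_code", "smq_name"]].copy()
    df["scope"] = "Narrow"
    df.to_csv(path, sep="\t", index=False)
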