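"""Preferred-term membership in the nine narrow cardiovascular SMQs.

Standardized MedDRA Queries (SMQs) are curated sets of preferred terms (PTs)
that define a medical condition of interest; the *narrow* scope keeps only
high-specificity members.  This package groups cardiovascular adverse events
into the nine narrow SMQ categories commonly used in cardio-oncology
pharmacovigilance.  The PT membership lists themselves are licensed MedDRA
content and must be supplied by the user (or by the synthetic generator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import normalize_name

log = logging.getLogger(__name__)

#: The nine narrow cardiovascular SMQ categories (code -> name).
NARROW_CV_SMQS: dict[int, str] = {
    20000049: "Cardiac arrhythmias",
    20000004: "Cardiac failure",
    20000150: "Cardiomyopathy",
    20000081: "Embolic and thrombotic events",
    20000147: "Hypertension",
    20000043: "Ischaemic heart disease",
    20000239: "Noninfectious myocarditis/pericarditis",
    20000130: "Pulmonary hypertension",
    20000001: "Torsade de pointes/QT prolongation",
}


@dataclass(frozen=True)
class SmqCategory:
    """One narrow SMQ with its member preferred terms."""

    smq_code: int
    smq_name: str
    member_pts: frozenset[str]  # normalized PT names

    def __contains__(self, pt: str) -> bool:
        return normalize_name(pt) in self.member_pts


class SmqMap:
    """PT -> narrow cardiovascular SMQ lookup.

    Membership queries are case-insensitive; a PT may belong to several SMQs
    (each SMQ analysis treats its member list independently).
    """

    def __init__(self, entries: pd.DataFrame):
        """``entries``: columns pt, smq_code, smq_name (narrow rows only)."""
        entries = entries.copy()
        entries["pt_norm"] = entries["pt"].map(normalize_name)
        entries["smq_code"] = entries["smq_code"].astype(int)
        self.entries = entries.drop_duplicates(["pt_norm", "smq_code"]).reset_index(drop=True)
        self._pt_to_codes: dict[str, frozenset[int]] = {
            pt: frozenset(g["smq_code"]) for pt, g in self.entries.groupby("pt_norm")
        }
        self._categories: dict[int, SmqCategory] = {}
        for code, g in self.entries.groupby("smq_code"):
            code = int(code)
            self._categories[code] = SmqCategory(
                smq_code=code,
                smq_name=NARROW_CV_SMQS.get(code, str(g["smq_name"].iloc[0])),
                member_pts=frozenset(g["pt_norm"]),
            )
        missing = sorted(set(NARROW_CV_SMQS) - set(self._categories))
        if missing:
            log.warning(
                "SMQ map is missing %d of the 9 narrow cardiovascular SMQs: %s",
                len(missing),
                ", ".join(f"{c} ({NARROW_CV_SMQS[c]})" for c in missing),
            )

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(self._categories)

    def category(self, smq_code: int) -> SmqCategory:
        return self._categories[int(smq_code)]

    def categories(self) -> list[SmqCategory]:
        return [self._categories[c] for c in sorted(self._categories)]

    def smq_codes_of(self, pt: str) -> frozenset[int]:
        return self._pt_to_codes.get(normalize_name(pt), frozenset())

    def smqs_of(self, pt: str) -> frozenset[SmqCategory]:
        """All narrow SMQ categories containing ``pt`` (possibly empty)."""
        return frozenset(self._categories[c] for c in self.smq_codes_of(pt))

    def is_cardiovascular(self, pt: str) -> bool:
        """True iff ``pt`` belongs to at least one of the nine narrow SMQs."""
        return bool(self.smq_codes_of(pt))

    def membership_frame(self) -> pd.DataFrame:
        """Long frame (pt_norm, smq_code) for vectorized joins."""
        return self.entries[["pt_norm", "smq_code"]].copy()

    @classmethod
    def from_records(cls, records: list[tuple[str, int]]) -> "SmqMap":
        """Build from (pt, smq_code) pairs using the canonical SMQ names."""
        df = pd.DataFrame(records, columns=["pt", "smq_code"])
        df["smq_name"] = df["smq_code"].map(NARROW_CV_SMQS)
        return cls(df)
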