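"""Claims data model.

The interchange unit of the whole pipeline is a :class:`ClaimsDatabase`:
four tidy tables mirroring how national health-insurance outpatient extracts
are distributed — one row per beneficiary, per visit, per prescription
line-item, and per reimbursable Chinese-herbal-medicine (CHM) catalog entry.

A CHM item is atomic: a herbal formula (HF) is a fixed multi-herb product
prescribed as one item, a single herb (SH) is one medicinal plant. Formula
ingredients are informational only and never participate in any counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

#: CHM item kinds: herbal formula / single herb.
HF = "HF"
SH = "SH"
ITEM_KINDS = (HF, SH)

#: Treatment-type flags recorded on a visit. CHM marks a visit whose
#: prescription contains at least one catalog item; the other three mark
#: treatment modalities that the cohort extraction excludes.
CHM_FLAG = "CHM"
EXCLUDABLE_FLAGS = ("acupuncture", "massage", "traumatology")
KNOWN_FLAGS = frozenset((CHM_FLAG, *EXCLUDABLE_FLAGS))

PATIENT_COLUMNS = ("patient_id", "birth_date", "sex")
VISIT_COLUMNS = ("visit_id", "patient_id", "date", "dx1", "dx2", "dx3", "flags")
PRESCRIPTION_COLUMNS = ("visit_id", "item_id")
CATALOG_COLUMNS = ("item_id", "name", "kind")


@dataclass(frozen=True)
class ChmItem:
    """One reimbursable CHM catalog entry (the atom of a prescription)."""

    item_id: str
    name: str
    kind: str  # HF or SH
    ingredients: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ITEM_KINDS:
            raise ValidationError(
                f"ChmItem.kind must be one of {ITEM_KINDS}, got {self.kind!r}")


def split_flags(flags: str) -> frozenset[str]:
    """Parse a semicolon-joined flag field into a set of tokens."""
    if not flags:
        return frozenset()
    return frozenset(tok for tok in flags.split(";") if tok)


def join_flags(flags) -> str:
    """Canonical (sorted, semicolon-joined) text form of a flag set."""
    return ";".join(sorted(flags))


@dataclass
class ClaimsDatabase:
    """An in-memory claims extract.

    Attributes
    ----------
    patients
        Columns ``patient_id, birth_date, sex`` (dates ISO-8601 text).
    visits
        Columns ``visit_id, patient_id, date, dx1, dx2, dx3, flags``.
        A visit carries one to three ICD-9 diagnosis codes (``dx2``/``dx3``
        may be empty) and a semicolon-joined flag field.
    prescriptions
        Long table, one row per (visit, item) prescription line.
    catalog
        CHM catalog: ``item_id, name, kind``.

    All columns are text; parsing to dates happens where needed. Tables are
    kept in a canonical sort order so that equality and on-disk round-trips
    are byte-stable.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    prescriptions: pd.DataFrame
    catalog: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.patients = _canonical(self.patients, PATIENT_COLUMNS, ["patient_id"])
        self.visits = _canonical(self.visits, VISIT_COLUMNS, ["visit_id"])
        self.prescriptions = _canonical(
            self.prescriptions, PRESCRIPTION_COLUMNS, ["visit_id", "item_id"])
        self.catalog = _canonical(self.catalog, CATALOG_COLUMNS, ["item_id"])

    # -- derived views ----------------------------------------------------
    def item_kinds(self) -> dict[str, str]:
        """Map item_id -> kind (HF/SH) from the catalog."""
        return dict(zip(self.catalog["item_id"], self.catalog["kind"]))

    def item_names(self) -> dict[str, str]:
        return dict(zip(self.catalog["item_id"], self.catalog["name"]))

    def prescription_sets(self) -> list[frozenset[str]]:
        """One frozenset of item_ids per visit that has any prescription.

        Counting downstream is set-based: an item appears at most once per
        prescription, a pair is counted once per prescription.
        """
        grouped = self.prescriptions.groupby("visit_id", sort=True)["item_id"]
        return [frozenset(items) for _, items in grouped]

    def validate(self) -> None:
        """Check cross-table invariants; raise ValidationError on breach."""
        cat = set(self.catalog["item_id"])
        unknown = sorted(set(self.prescriptions["item_id"]) - cat)
        if unknown:
            raise ValidationError(
                f"prescription items missing from catalog: {unknown}")
        vis = set(self.visits["visit_id"])
        orphan = sorted(set(self.prescriptions["visit_id"]) - vis)
        if orphan:
            raise ValidationError(f"prescriptions reference unknown visits: {orphan}")
        flag_sets = self.visits["flags"].map(split_flags)
        flagged = flag_sets.map(lambda s: CHM_FLAG in s)
        with_items = self.visits["visit_id"].isin(set(self.prescriptions["visit_id"]))
        mismatch = self.visits.loc[flagged != with_items, "visit_id"]
        if len(mismatch):
            raise ValidationError(
                f"visits {sorted(mismatch)[:5]}...: CHM flag and prescription "
                "presence disagree (items nonempty iff CHM flag set)")
        if (self.visits["dx1"] == "").any():
            bad_v = self.visits.loc[self.visits["dx1"] == "", "visit_id"]
            raise ValidationError(f"visits without any diagnosis: {sorted(bad_v)[:5]}")
        unknown_flags = flag_sets.map(lambda s: bool(s - KNOWN_FLAGS))
        if unknown_flags.any():
            bad_v = self.visits.loc[unknown_flags, "visit_id"]
            raise ValidationError(f"unknown flag tokens on visits: {sorted(bad_v)[:5]}")

    def equals(self, other: "ClaimsDatabase") -> bool:
        return (self.patients.equals(other.patients)
                and self.visits.equals(other.visits)
                and self.prescriptions.equals(other.prescriptions)
                and self.catalog.equals(other.catalog))


def _canonical(df: pd.DataFrame, columns, sort_by) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"table missing required columns: {missing}")
    out = df.loc[:, list(columns)].astype(str)
    return out.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
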