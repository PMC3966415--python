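"""Cohort extraction: from a claims database to a prescription database.

Reproduces the standard claims-data funnel for a diagnosis-defined cohort:

1. restrict to visits inside the study window;
2. keep visits carrying at least one diagnosis matching the index ICD-9
   prefix (breast cancer, prefix ``174``, by default);
3. keep TCM visits — those whose prescription contains at least one CHM
   item;
4. drop visits flagged with acupuncture, massage or traumatology, which
   would confound the CHM prescription patterns.

ICD-9 codes arrive with or without the decimal point; :func:`normalize_icd9`
maps both spellings to a canonical dotless uppercase form, so ``174.5`` and
``1745`` match the same prefix.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from ._util import pct
from .claims import CHM_FLAG, ClaimsDatabase, EXCLUDABLE_FLAGS, split_flags
from .errors import ConfigurationError, ValidationError

__all__ = [
    "Chapter", "CohortSpec", "CohortSummary", "ICD9_CHAPTERS",
    "normalize_icd9", "select_cohort", "summarize_age",
    "summarize_comorbidity",
]


@dataclass(frozen=True)
class Chapter:
    """One ICD-9 chapter: a labelled closed range of 3-digit numeric codes."""

    label: str
    lo: int
    hi: int


#: The 13 ICD-9 comorbidity chapters reported for CHM-using cohorts.
ICD9_CHAPTERS: tuple[Chapter, ...] = (
    Chapter("Symptoms, signs, and ill-defined conditions", 780, 799),
    Chapter("Diseases of the digestive system", 520, 579),
    Chapter("Diseases of the musculoskeletal system and connective tissue", 710, 739),
    Chapter("Diseases of the respiratory system", 460, 519),
    Chapter("Diseases of the genitourinary system", 580, 629),
    Chapter("Diseases of the circulatory system", 390, 459),
    Chapter("Endocrine, nutritional and metabolic diseases, and immunity disorders",
            240, 279),
    Chapter("Diseases of the skin and subcutaneous tissue", 680, 709),
    Chapter("Mental disorders", 290, 319),
    Chapter("Diseases of the nervous system and sense organs", 320, 389),
    Chapter("Injury and poisoning", 800, 999),
    Chapter("Diseases of the blood and blood-forming organs", 280, 289),
    Chapter("Infectious and parasitic diseases", 1, 139),
)

#: Demographic age bins: [0, 40), [40, 60), [60, inf) in completed years.
DEFAULT_AGE_EDGES = (40, 60)
AGE_BIN_LABELS = ("<40", "40-59", ">=60")


def normalize_icd9(code: str) -> str:
    """Canonical dotless uppercase ICD-9 code: ``'174.5' -> '1745'``.

    Idempotent; raises :class:`ValidationError` for empty/whitespace input.
    """
    if code is None or not str(code).strip():
        raise ValidationError("ICD-9 code must be nonempty")
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class CohortSpec:
    """What defines the cohort: index diagnosis prefix, window, exclusions."""

    icd9_prefix: str = "174"
    study_start: dt.date = dt.date(2008, 1, 1)
    study_end: dt.date = dt.date(2008, 12, 31)
    excluded_flags: frozenset[str] = frozenset(EXCLUDABLE_FLAGS)
    age_reference_date: dt.date = dt.date(2008, 7, 1)
    age_edges: tuple[int, ...] = DEFAULT_AGE_EDGES

    def __post_init__(self):
        if not str(self.icd9_prefix).strip():
            raise ConfigurationError("icd9_prefix must be nonempty")
        if self.study_start > self.study_end:
            raise ConfigurationError("study window: start must not exceed end")


@dataclass
class CohortSummary:
    """Funnel counts plus the demographic/comorbidity breakdowns.

    Percentages follow the reporting conventions of published claims
    analyses: visit share over visits with the index diagnosis, patient
    share over patients with the index diagnosis, and per-row shares over
    the TCM patient count — all rounded half-up to two decimals.
    """

    n_patients_with_dx: int
    n_visits_with_dx: int
    n_tcm_visits: int
    n_tcm_patients: int
    pct_tcm_visits: float | None
    pct_tcm_patients: float | None
    age_bins: pd.DataFrame        # label, n, pct
    comorbidity: pd.DataFrame     # label, range, n, pct
    funnel: list[tuple[str, int]]

    def to_dict(self) -> dict:
        return {
            "n_patients_with_dx": self.n_patients_with_dx,
            "n_visits_with_dx": self.n_visits_with_dx,
            "n_tcm_visits": self.n_tcm_visits,
            "n_tcm_patients": self.n_tcm_patients,
            "pct_tcm_visits": self.pct_tcm_visits,
            "pct_tcm_patients": self.pct_tcm_patients,
            "age_bins": self.age_bins.to_dict(orient="records"),
            "comorbidity": self.comorbidity.to_dict(orient="records"),
            "funnel": [list(step) for step in self.funnel],
        }


def age_in_years(birth_date: dt.date, reference_date: dt.date) -> int:
    """Completed years of age at the reference date."""
    if birth_date > reference_date:
        raise ValidationError(
            f"birth date {birth_date} is after reference date {reference_date}")
    return (reference_date.year - birth_date.year
            - ((reference_date.month, reference_date.day)
               < (birth_date.month, birth_date.day)))


def summarize_age(birth_dates, reference_date: dt.date,
                  edges: tuple[int, ...] = DEFAULT_AGE_EDGES) -> pd.DataFrame:
    """Bin ages (completed years at ``reference_date``) into half-open bins.

    With the default edges ``(40, 60)`` the bins are [0, 40), [40, 60),
    [60, inf); counts sum to the cohort size, percentages are over the
    cohort size and are omitted (None) for an empty cohort.
    """
    edges = tuple(edges)
    labels = (AGE_BIN_LABELS if edges == DEFAULT_AGE_EDGES else
              tuple([f"<{edges[0]}"]
                    + [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
                    + [f">={edges[-1]}"]))
    counts = [0] * (len(edges) + 1)
    for bd in birth_dates:
        if isinstance(bd, str):
            bd = dt.date.fromisoformat(bd)
        age = age_in_years(bd, reference_date)
        i = sum(age >= e for e in edges)
        counts[i] += 1
    total = sum(counts)
    return pd.DataFrame({
        "label": labels,
        "n": counts,
        "pct": [pct(c, total) if total else None for c in counts],
    })


def _check_chapters(chapters) -> None:
    spans = sorted((c.lo, c.hi, c.label) for c in chapters)
    for c in chapters:
        if c.lo > c.hi:
            raise ConfigurationError(f"chapter {c.label!r}: lo > hi")
    for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ConfigurationError(
                f"chapter ranges overlap: {l1!r} and {l2!r}")


def _chapter_of(code: str, chapters) -> str | None:
    head = code[:3]
    if not head.isdigit() or len(head) < 3:
        return None  # V/E codes and short stubs have no numeric chapter
    value = int(head)
    for c in chapters:
        if c.lo <= value <= c.hi:
            return c.label
    return None


def summarize_comorbidity(visits: pd.DataFrame,
                          chapters=ICD9_CHAPTERS,
                          index_prefix: str = "174",
                          n_patients: int | None = None) -> pd.DataFrame:
    """Per-chapter patient counts over the retained visits.

    A patient is counted in a chapter when any of their retained visits
    carries a non-index diagnosis inside the chapter range — once per
    patient per chapter, however many qualifying visits there are. Codes
    with the index prefix are comorbidities of nothing and are skipped.
    """
    _check_chapters(chapters)
    index_prefix = normalize_icd9(index_prefix)
    patients_by_chapter: dict[str, set[str]] = {c.label: set() for c in chapters}
    for _, row in visits.iterrows():
        for col in ("dx1", "dx2", "dx3"):
            raw = row[col]
            if not str(raw).strip():
                continue
            code = normalize_icd9(raw)
            if code.startswith(index_prefix):
                continue
            label = _chapter_of(code, chapters)
            if label is not None:
                patients_by_chapter[label].add(row["patient_id"])
    denom = n_patients if n_patients is not None else visits["patient_id"].nunique()
    return pd.DataFrame({
        "label": [c.label for c in chapters],
        "range": [f"{c.lo:03d}-{c.hi:03d}" for c in chapters],
        "n": [len(patients_by_chapter[c.label]) for c in chapters],
        "pct": [pct(len(patients_by_chapter[c.label]), denom) if denom else None
                for c in chapters],
    })


def select_cohort(db: ClaimsDatabase, spec: CohortSpec | None = None
                  ) -> tuple[ClaimsDatabase, CohortSummary]:
    """Apply the extraction funnel; return the prescription database and
    its summary.

    The returned database keeps only retained visits, their prescription
    rows, their patients, and the full catalog. An empty input yields an
    empty cohort with zero counts, not an error.
    """
    spec = spec or CohortSpec()
    prefix = normalize_icd9(spec.icd9_prefix)
    v = db.visits
    funnel: list[tuple[str, int]] = [("all visits", len(v))]

    dates = pd.to_datetime(v["date"], format="%Y-%m-%d").dt.date
    in_window = (dates >= spec.study_start) & (dates <= spec.study_end)
    v = v[in_window]
    funnel.append(("in study window", len(v)))

    dx_mask = pd.Series(False, index=v.index)
    for col in ("dx1", "dx2", "dx3"):
        canon = (v[col].str.strip().str.upper()
                 .str.replace(".", "", regex=False))
        dx_mask |= canon.str.startswith(prefix)
    v_dx = v[dx_mask]
    n_visits_with_dx = len(v_dx)
    patients_with_dx = set(v_dx["patient_id"])
    funnel.append((f"with index diagnosis {spec.icd9_prefix}", n_visits_with_dx))

    flag_sets = v_dx["flags"].map(split_flags)
    has_chm = flag_sets.map(lambda s: CHM_FLAG in s).astype(bool)
    v_tcm = v_dx[has_chm]
    funnel.append(("TCM visits (CHM prescribed)", len(v_tcm)))

    excl = frozenset(spec.excluded_flags)
    keep = v_tcm["flags"].map(
        lambda s: not (split_flags(s) & excl)).astype(bool)
    v_kept = v_tcm[keep]
    funnel.append(("after excluding "
                   + "/".join(sorted(excl)) if excl else "no exclusions",
                   len(v_kept)))

    kept_ids = set(v_kept["visit_id"])
    rx = db.prescriptions[db.prescriptions["visit_id"].isin(kept_ids)]
    tcm_patients = sorted(set(v_kept["patient_id"]))
    patients = db.patients[db.patients["patient_id"].isin(tcm_patients)]

    n_tcm_visits = len(v_kept)
    n_tcm_patients = len(tcm_patients)
    summary = CohortSummary(
        n_patients_with_dx=len(patients_with_dx),
        n_visits_with_dx=n_visits_with_dx,
        n_tcm_visits=n_tcm_visits,
        n_tcm_patients=n_tcm_patients,
        pct_tcm_visits=(pct(n_tcm_visits, n_visits_with_dx)
                        if n_visits_with_dx else None),
        pct_tcm_patients=(pct(n_tcm_patients, len(patients_with_dx))
                          if patients_with_dx else None),
        age_bins=summarize_age(patients["birth_date"], spec.age_reference_date,
                               spec.age_edges),
        comorbidity=summarize_comorbidity(v_kept, ICD9_CHAPTERS, prefix,
                                          n_patients=n_tcm_patients),
        funnel=funnel,
    )
    cohort_db = ClaimsDatabase(patients.copy(), v_kept.copy(), rx.copy(),
                               db.catalog.copy(), meta=dict(db.meta))
    return cohort_db, summary
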