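"""Reading and writing the claims interchange format.

Four delimited text files per database directory::

    patients.csv       patient_id, birth_date, sex
    visits.csv         visit_id, patient_id, date, dx1, dx2, dx3, flags
    prescriptions.csv  visit_id, item_id
    catalog.csv        item_id, name, kind

``flags`` is a semicolon-joined token set. Diagnosis codes are accepted with
or without the decimal point; normalization happens in the cohort stage, not
here. Malformed rows raise :class:`~herbnet.errors.ParseError` with file and
line; a duplicate item within one visit's prescription is deduplicated with
a logged warning (counting downstream is set-based).
"""
from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import logging
from pathlib import Path

import pandas as pd
import yaml

from .claims import (CATALOG_COLUMNS, ChmItem, ClaimsDatabase, ITEM_KINDS,
                     KNOWN_FLAGS, PATIENT_COLUMNS, PRESCRIPTION_COLUMNS,
                     VISIT_COLUMNS)
from .errors import ConfigurationError, ParseError
from .synthetic import AgeDistribution, GeneratorConfig, ImplantedPair

logger = logging.getLogger(__name__)

_FILES = {
    "patients.csv": PATIENT_COLUMNS,
    "visits.csv": VISIT_COLUMNS,
    "prescriptions.csv": PRESCRIPTION_COLUMNS,
    "catalog.csv": CATALOG_COLUMNS,
}


def write_claims(db: ClaimsDatabase, directory: str | Path) -> Path:
    """Write the four interchange files; deterministic byte output."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = {"patients.csv": db.patients, "visits.csv": db.visits,
              "prescriptions.csv": db.prescriptions, "catalog.csv": db.catalog}
    for name, frame in frames.items():
        frame.to_csv(directory / name, index=False, lineterminator="\n")
    return directory


def _read_table(path: Path, columns: tuple[str, ...]) -> list[list[str]]:
    if not path.exists():
        raise ParseError("missing claims file", file=str(path))
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(columns):
            raise ParseError(
                f"expected header {','.join(columns)}", file=path.name, line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(columns):
                raise ParseError(
                    f"expected {len(columns)} fields, got {len(row)}",
                    file=path.name, line=lineno)
            rows.append([f.strip() for f in row])
    return rows


def read_claims(directory: str | Path) -> ClaimsDatabase:
    """Read and validate a claims directory written by :func:`write_claims`.

    Validation enforces the visit invariants (1-3 diagnoses, known flag
    tokens, items nonempty iff the CHM flag is set) and deduplicates repeat
    items within one prescription with a warning.
    """
    directory = Path(directory)
    raw = {name: _read_table(directory / name, cols)
           for name, cols in _FILES.items()}

    for lineno, row in enumerate(raw["catalog.csv"], start=2):
        if row[2] not in ITEM_KINDS:
            raise ParseError(f"unknown item kind {row[2]!r}",
                             file="catalog.csv", line=lineno, column="kind")
    for lineno, row in enumerate(raw["visits.csv"], start=2):
        if not row[3]:
            raise ParseError("visit must carry at least one diagnosis (dx1)",
                             file="visits.csv", line=lineno, column="dx1")
        bad = {tok for tok in row[6].split(";") if tok} - KNOWN_FLAGS
        if bad:
            raise ParseError(f"unknown flag tokens {sorted(bad)}",
                             file="visits.csv", line=lineno, column="flags")

    prescriptions = pd.DataFrame(raw["prescriptions.csv"],
                                 columns=list(PRESCRIPTION_COLUMNS))
    n_dup = int(prescriptions.duplicated().sum())
    if n_dup:
        logger.warning(
            "prescriptions.csv: dropped %d duplicate (visit, item) rows "
            "(prescriptions are item sets)", n_dup)
        prescriptions = prescriptions.drop_duplicates()

    db = ClaimsDatabase(
        pd.DataFrame(raw["patients.csv"], columns=list(PATIENT_COLUMNS)),
        pd.DataFrame(raw["visits.csv"], columns=list(VISIT_COLUMNS)),
        prescriptions,
        pd.DataFrame(raw["catalog.csv"], columns=list(CATALOG_COLUMNS)),
    )
    db.validate()
    return db


# -- generator config as YAML ---------------------------------------------

def generator_config_to_dict(config: GeneratorConfig) -> dict:
    """Field-for-field plain-dict form of a GeneratorConfig (YAML-safe)."""
    return {
        "n_patients": config.n_patients,
        "visits_per_patient": config.visits_per_patient,
        "p_breast_cancer_visit": config.p_breast_cancer_visit,
        "p_chm_user": config.p_chm_user,
        "p_chm_visit": config.p_chm_visit,
        "p_excluded_treatment": config.p_excluded_treatment,
        "mean_items_per_prescription": config.mean_items_per_prescription,
        "age_distribution": dataclasses.asdict(config.age_distribution),
        "study_start": config.study_start.isoformat(),
        "study_end": config.study_end.isoformat(),
        "seed": config.seed,
        "catalog": [
            {"item_id": item.item_id, "name": item.name, "kind": item.kind,
             "p": p} for item, p in config.catalog],
        "implanted_pairs": [
            {"item_a": pr.item_a, "item_b": pr.item_b,
             "joint_boost": pr.joint_boost} for pr in config.implanted_pairs],
    }


def generator_config_from_dict(data: dict) -> GeneratorConfig:
    try:
        kwargs = dict(data)
        catalog = [(ChmItem(e["item_id"], e.get("name", e["item_id"]),
                            e["kind"]), float(e["p"]))
                   for e in kwargs.pop("catalog")]
        pairs = [ImplantedPair(e["item_a"], e["item_b"], float(e["joint_boost"]))
                 for e in kwargs.pop("implanted_pairs", [])]
        age = AgeDistribution(**kwargs.pop("age_distribution", {}))
        for key in ("study_start", "study_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        config = GeneratorConfig(catalog=catalog, implanted_pairs=pairs,
                                 age_distribution=age, **kwargs)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid generator config: {exc}") from exc
    config.validate()
    return config


def write_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(generator_config_to_dict(config), fh, sort_keys=False)


def read_generator_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"generator config {path}: expected a mapping")
    return generator_config_from_dict(data)
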