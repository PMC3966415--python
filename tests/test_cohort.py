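"""Cohort extraction: code normalization, funnel, age and comorbidity."""
import datetime as dt

import pandas as pd
import pytest

from herbnet.cohort import (Chapter, CohortSpec, ICD9_CHAPTERS, age_in_years,
                            normalize_icd9, select_cohort, summarize_age,
                            summarize_comorbidity)
from herbnet.errors import ConfigurationError, ValidationError
from herbnet.synthetic import default_config, generate


@pytest.mark.parametrize("raw,canonical", [
    ("174.5", "1745"),
    ("1745", "1745"),       # idempotent
    ("174.50", "17450"),
    (" 533.9 ", "5339"),
    ("v45.1", "V451"),
])
def test_normalize_icd9(raw, canonical):
    assert normalize_icd9(raw) == canonical
    assert normalize_icd9(canonical) == canonical


@pytest.mark.parametrize("bad", ["", "   ", None])
def test_normalize_icd9_rejects_empty(bad):
    with pytest.raises(ValidationError):
        normalize_icd9(bad)


def test_prefix_match_equals_closed_code_set():
    """Prefix matching on '174' is exactly membership in {174.0..174.9} for
    4-digit codes: checked against an enumeration oracle over 170-179."""
    closed_set = {f"174{d}" for d in range(10)}
    for head in range(170, 180):
        for tail in range(10):
            for raw in (f"{head}.{tail}", f"{head}{tail}"):
                assert (normalize_icd9(raw).startswith("174")
                        == (normalize_icd9(raw) in closed_set))
            # 5-digit codes still match by prefix
            raw5 = f"{head}.{tail}0"
            assert (normalize_icd9(raw5).startswith("174")
                    == (head == 174))


def test_toy_funnel_hand_enumeration(toy_db):
    """5 visits: 3 with the index dx, 2 of those with CHM, 1 of those
    acupuncture-flagged -> exactly one retained prescription."""
    cohort_db, summary = select_cohort(toy_db, CohortSpec())
    assert summary.n_visits_with_dx == 3
    assert summary.n_tcm_visits == 1
    assert summary.n_tcm_patients == 1
    assert list(cohort_db.visits["visit_id"]) == ["V1"]
    assert sorted(cohort_db.prescriptions["item_id"]) == ["A", "B"]
    counts = [n for _, n in summary.funnel]
    assert counts == sorted(counts, reverse=True)  # funnel monotonicity


def test_dotted_and_dotless_index_codes_both_match(toy_db):
    # V1 uses '174.5', V2 uses '1742'; both match prefix 174
    _, summary = select_cohort(
        toy_db, CohortSpec(excluded_flags=frozenset()))
    assert summary.n_tcm_visits == 2


def test_excluded_flag_drops_visit(toy_db):
    _, summary = select_cohort(toy_db, CohortSpec())
    dropped = [n for step, n in summary.funnel if step.startswith("after excluding")]
    assert dropped == [1]


def test_empty_database_gives_zero_counts(toy_db):
    empty = toy_db
    empty = type(toy_db)(toy_db.patients.iloc[:0], toy_db.visits.iloc[:0],
                         toy_db.prescriptions.iloc[:0], toy_db.catalog)
    _, summary = select_cohort(empty, CohortSpec())
    assert summary.n_tcm_visits == 0
    assert summary.pct_tcm_visits is None
    assert summary.age_bins["n"].sum() == 0


def test_age_bins_boundaries():
    ref = dt.date(2008, 7, 1)
    births = [dt.date(2008 - age, 1, 1) for age in (39, 40, 59, 60)]
    frame = summarize_age(births, ref)
    assert list(frame["n"]) == [1, 2, 1]  # [0,40), [40,60), [60,inf)


def test_age_percentages_match_published_breakdown():
    ref = dt.date(2008, 7, 1)
    births = ([dt.date(1978, 1, 1)] * 389 + [dt.date(1958, 1, 1)] * 3146
              + [dt.date(1938, 1, 1)] * 901)
    frame = summarize_age(births, ref)
    assert list(frame["n"]) == [389, 3146, 901]
    assert list(frame["pct"]) == [8.77, 70.92, 20.31]


def test_completed_years_and_future_birth_rejected():
    assert age_in_years(dt.date(1968, 7, 2), dt.date(2008, 7, 1)) == 39
    assert age_in_years(dt.date(1968, 7, 1), dt.date(2008, 7, 1)) == 40
    with pytest.raises(ValidationError):
        age_in_years(dt.date(2010, 1, 1), dt.date(2008, 7, 1))


def _visits_frame(rows):
    return pd.DataFrame(rows, columns=["visit_id", "patient_id", "date",
                                       "dx1", "dx2", "dx3", "flags"])


def test_comorbidity_chapter_assignment_and_dedup():
    visits = _visits_frame([
        ("V1", "P1", "2008-01-01", "174.5", "533.9", "", "CHM"),
        ("V2", "P1", "2008-02-01", "1745", "5339", "", "CHM"),
        ("V3", "P1", "2008-03-01", "174.1", "533.1", "", "CHM"),
        ("V4", "P2", "2008-04-01", "174.2", "780.0", "", "CHM"),
    ])
    frame = summarize_comorbidity(visits, n_patients=2)
    by_label = dict(zip(frame["label"], frame["n"]))
    # digestive 520-579: P1 on three visits, counted once
    assert by_label["Diseases of the digestive system"] == 1
    assert by_label["Symptoms, signs, and ill-defined conditions"] == 1
    # the index code itself never counts as a comorbidity
    assert frame["n"].sum() == 2


def test_comorbidity_published_percentage():
    visits = _visits_frame(
        [(f"V{i}", f"P{i}", "2008-01-01", "1740", "780.0", "", "CHM")
         for i in range(478)])
    frame = summarize_comorbidity(visits, n_patients=4436)
    row = frame[frame["range"] == "780-799"].iloc[0]
    assert row["n"] == 478 and row["pct"] == 10.78


def test_overlapping_chapter_ranges_rejected():
    visits = _visits_frame([("V1", "P1", "2008-01-01", "5339", "", "", "CHM")])
    bad = (Chapter("a", 100, 200), Chapter("b", 150, 250))
    with pytest.raises(ConfigurationError, match="overlap"):
        summarize_comorbidity(visits, chapters=bad)


def test_chapters_cover_expected_ranges():
    spans = sorted((c.lo, c.hi) for c in ICD9_CHAPTERS)
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        assert hi1 < lo2  # disjoint


@pytest.mark.parametrize("seed", [0, 1])
def test_funnel_monotone_on_synthetic_databases(seed):
    db = generate(default_config(seed=seed, n_patients=120,
                                 visits_per_patient=5.0, p_chm_user=0.4,
                                 p_chm_visit=0.7))
    _, summary = select_cohort(db, CohortSpec())
    counts = [n for _, n in summary.funnel]
    assert counts == sorted(counts, reverse=True)
    assert summary.n_tcm_visits <= summary.n_visits_with_dx
    assert summary.n_tcm_patients <= summary.n_patients_with_dx
    assert summary.age_bins["n"].sum() == summary.n_tcm_patients
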