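import pandas as pd
import pytest

from herbnet.claims import ChmItem, ClaimsDatabase


@pytest.fixture
def toy_catalog():
    return [ChmItem("A", "Herb A", "SH"), ChmItem("B", "Herb B", "SH"),
            ChmItem("C", "Formula C", "HF")]


@pytest.fixture
def toy_db(toy_catalog):
    """Five hand-built visits: three carry the index diagnosis (174*), two
    of those have CHM, and one of those is acupuncture-flagged — so exactly
    one visit survives the funnel."""
    patients = pd.DataFrame({
        "patient_id": ["P1", "P2"],
        "birth_date": ["1960-01-01", "1950-06-15"],
        "sex": ["F", "F"],
    })
    visits = pd.DataFrame(
        [
            ("V1", "P1", "2008-02-01", "174.5", "5339", "", "CHM"),
            ("V2", "P1", "2008-03-01", "1742", "", "", "CHM;acupuncture"),
            ("V3", "P2", "2008-04-01", "174.9", "", "", ""),
            ("V4", "P2", "2008-05-01", "5339", "", "", "CHM"),
            ("V5", "P2", "2008-06-01", "7800", "", "", ""),
        ],
        columns=["visit_id", "patient_id", "date", "dx1", "dx2", "dx3", "flags"],
    )
    prescriptions = pd.DataFrame(
        [("V1", "A"), ("V1", "B"), ("V2", "A"), ("V4", "B"), ("V4", "C")],
        columns=["visit_id", "item_id"],
    )
    catalog = pd.DataFrame(
        [(i.item_id, i.name, i.kind) for i in toy_catalog],
        columns=["item_id", "name", "kind"],
    )
    return ClaimsDatabase(patients, visits, prescriptions, catalog)


def brute_force_pair_counts(prescriptions):
    """Independent oracle: double loop over prescriptions x item pairs."""
    from itertools import combinations

    pair_counts: dict[tuple[str, str], int] = {}
    item_counts: dict[str, int] = {}
    for items in prescriptions:
        for item in items:
            item_counts[item] = item_counts.get(item, 0) + 1
        for a, b in combinations(sorted(items), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    return pair_counts, item_counts
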