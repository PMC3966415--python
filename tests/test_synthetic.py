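"""Generator behaviour: determinism, forced/implanted dependence, scaling."""
import math

import pytest

from herbnet.claims import ChmItem
from herbnet.errors import ConfigurationError
from herbnet.io import write_claims
from herbnet.synthetic import (ImplantedPair, default_config,
                               generate, generate_prescription_sets,
                               pair_joint_probability)

from conftest import brute_force_pair_counts


def small_config(seed=1, **overrides):
    return default_config(seed=seed, n_patients=150,
                          visits_per_patient=6.0, p_chm_user=0.5,
                          p_chm_visit=0.8, **overrides)


def test_same_seed_is_byte_identical(tmp_path):
    d1 = write_claims(generate(small_config(seed=1)), tmp_path / "a")
    d2 = write_claims(generate(small_config(seed=1)), tmp_path / "b")
    for name in ("patients.csv", "visits.csv", "prescriptions.csv", "catalog.csv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_different_seeds_differ(tmp_path):
    db1 = generate(small_config(seed=1))
    db2 = generate(small_config(seed=2))
    assert not db1.equals(db2)


def test_forced_co_occurrence_with_unit_marginals():
    catalog = [(ChmItem("A", "A", "SH"), 1.0), (ChmItem("B", "B", "SH"), 1.0)]
    sets = generate_prescription_sets(100, catalog=catalog,
                                      implanted_pairs=[], seed=0)
    assert len(sets) == 100
    assert all(s == frozenset({"A", "B"}) for s in sets)  # pair support 100%


def test_implanted_pair_has_dominant_odds_ratio():
    """20-item catalog, one pair boosted 8-fold, 50k prescriptions: the
    implanted pair's 2x2 odds ratio (brute-force contingency count) exceeds
    every other pair's."""
    catalog = [(ChmItem(f"I{k:02d}", f"item {k}", "SH"), 0.15)
               for k in range(20)]
    sets = generate_prescription_sets(
        50_000, catalog=catalog,
        implanted_pairs=[ImplantedPair("I03", "I11", 8.0)], seed=7)
    pair_counts, item_counts = brute_force_pair_counts(sets)
    n = len(sets)

    def odds_ratio(a, b):
        n11 = pair_counts.get((a, b), 0)
        n1_, n_1 = item_counts.get(a, 0), item_counts.get(b, 0)
        n10, n01 = n1_ - n11, n_1 - n11
        n00 = n - n11 - n10 - n01
        return (n11 * n00) / max(n10 * n01, 1)

    ids = sorted(item_counts)
    implanted = odds_ratio("I03", "I11")
    others = [odds_ratio(a, b) for i, a in enumerate(ids)
              for b in ids[i + 1:] if {a, b} != {"I03", "I11"}]
    assert implanted > 1.0
    assert implanted > max(others)
    # the boost is recovered to sampling accuracy
    assert 6.0 < implanted < 10.5


def test_pair_joint_probability_plackett():
    # theta = 1 is independence
    assert pair_joint_probability(0.4, 0.2, 1.0) == pytest.approx(0.08)
    # the returned joint reproduces the requested odds ratio
    pa, pb, theta = 0.4187, 0.1728, 2.84
    p11 = pair_joint_probability(pa, pb, theta)
    p10, p01, p00 = pa - p11, pb - p11, 1 - pa - pb + p11
    assert (p11 * p00) / (p10 * p01) == pytest.approx(theta, rel=1e-9)
    assert 0 < p11 <= min(pa, pb)
    with pytest.raises(ConfigurationError):
        pair_joint_probability(0.4, 0.2, -1.0)
    with pytest.raises(ConfigurationError):
        pair_joint_probability(1.4, 0.2, 2.0)


@pytest.mark.parametrize("field,value,match", [
    ("p_chm_visit", 1.5, "p_chm_visit"),
    ("p_excluded_treatment", -0.1, "p_excluded_treatment"),
    ("n_patients", 0, "n_patients"),
    ("visits_per_patient", -2.0, "visits_per_patient"),
    ("mean_items_per_prescription", 0.0, "mean_items_per_prescription"),
])
def test_invalid_config_names_the_field(field, value, match):
    config = default_config(seed=0, **{field: value})
    with pytest.raises(ConfigurationError, match=match):
        config.validate()


def test_implanted_pair_referencing_unknown_item_rejected():
    config = default_config(seed=0, implanted_pairs=[
        ImplantedPair("SH01", "NOPE", 2.0)])
    with pytest.raises(ConfigurationError, match="NOPE"):
        config.validate()
    config = default_config(seed=0, implanted_pairs=[
        ImplantedPair("SH01", "SH02", 0.5)])
    with pytest.raises(ConfigurationError, match="joint_boost"):
        config.validate()
    config = default_config(seed=0, implanted_pairs=[
        ImplantedPair("SH01", "SH02", 2.0),
        ImplantedPair("SH02", "SH03", 2.0)])
    with pytest.raises(ConfigurationError, match="at most one"):
        config.validate()


def test_mean_items_rescaling():
    catalog = [(ChmItem(f"I{k}", f"item {k}", "SH"), 0.2) for k in range(10)]
    sets = generate_prescription_sets(
        20_000, catalog=catalog, implanted_pairs=[],
        mean_items_per_prescription=4.0, seed=5)
    mean = sum(len(s) for s in sets) / len(sets)
    assert math.isclose(mean, 4.0, abs_tol=0.1)


def test_mean_items_rescaling_cannot_exceed_unit_probability():
    catalog = [(ChmItem("A", "A", "SH"), 0.9), (ChmItem("B", "B", "SH"), 0.1)]
    with pytest.raises(ConfigurationError, match="exceeds 1"):
        generate_prescription_sets(10, catalog=catalog, implanted_pairs=[],
                                   mean_items_per_prescription=1.5, seed=0)


def test_generated_database_is_internally_consistent():
    db = generate(small_config(seed=3))
    db.validate()  # CHM flag iff items; known flags; diagnoses present
    # every CHM prescription is a set with >= 1 item
    sizes = db.prescriptions.groupby("visit_id").size()
    assert (sizes >= 1).all()
    assert not db.prescriptions.duplicated().any()
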