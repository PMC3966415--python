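"""Published summary statistics of the 2008 Taiwan NHIRD breast-cancer
CHM prescription analysis.

The raw claims are not redistributable, but the published aggregate tables
are: the extraction funnel, the age and comorbidity breakdowns of the CHM
cohort, the ten most-prescribed herbal formulae (HF) and single herbs (SH),
and the ten strongest pair rules. They serve two purposes here:

* calibration — the synthetic generator's default marginals and implanted
  pairs are set from these prevalences; and
* worked examples — every percentage whose numerator and denominator are
  both published can be recomputed by this package's counting/formatting
  path and compared digit-for-digit.

All counts are prescription counts over the N = 37,176 retained
prescriptions unless stated otherwise.
"""
from __future__ import annotations

import pandas as pd

from .claims import HF, SH
from .mining import PairRule, build_rules

__all__ = [
    "study_funnel", "age_table", "comorbidity_table",
    "top_formulas", "top_single_herbs", "pair_rule_table",
    "published_rules", "N_PRESCRIPTIONS", "N_PATIENTS",
]

#: Total retained CHM prescriptions / patients in the published cohort.
N_PRESCRIPTIONS = 37176
N_PATIENTS = 4436


def study_funnel() -> dict[str, int]:
    """Cohort funnel counts: beneficiaries and visits with a breast-cancer
    code, and the CHM (TCM) subset."""
    return {
        "n_patients_with_dx": 61214,
        "n_visits_with_dx": 855440,
        "n_tcm_visits": 37176,
        "n_tcm_patients": 4436,
    }


def age_table() -> pd.DataFrame:
    """Age distribution of the 4,436 CHM-using patients (published
    percentages included for cross-checking)."""
    rows = [("<40", 389, 8.77), ("40-59", 3146, 70.92), (">=60", 901, 20.31)]
    return pd.DataFrame(rows, columns=["label", "n", "published_pct"])


def comorbidity_table() -> pd.DataFrame:
    """Per-ICD-9-chapter comorbid patient counts among the 4,436 CHM users."""
    rows = [
        ("Symptoms, signs, and ill-defined conditions", "780-799", 478, 10.78),
        ("Diseases of the digestive system", "520-579", 446, 10.05),
        ("Diseases of the musculoskeletal system and connective tissue",
         "710-739", 330, 7.44),
        ("Diseases of the respiratory system", "460-519", 268, 6.04),
        ("Diseases of the genitourinary system", "580-629", 261, 5.88),
        ("Diseases of the circulatory system", "390-459", 198, 4.46),
        ("Endocrine, nutritional and metabolic diseases, and immunity disorders",
         "240-279", 193, 4.35),
        ("Diseases of the skin and subcutaneous tissue", "680-709", 158, 3.56),
        ("Mental disorders", "290-319", 154, 3.47),
        ("Diseases of the nervous system and sense organs", "320-389", 98, 2.21),
        ("Injury and poisoning", "800-999", 78, 1.76),
        ("Diseases of the blood and blood-forming organs", "280-289", 64, 1.44),
        ("Infectious and parasitic diseases", "001-139", 8, 0.18),
    ]
    return pd.DataFrame(rows, columns=["label", "range", "n", "published_pct"])


def top_formulas() -> pd.DataFrame:
    """The ten most-prescribed herbal formulae (counts over N=37,176)."""
    rows = [
        (1, "Jia-Wei-Xiao-Yao-San", 7303, 19.64),
        (2, "San-Zhong-Kui-Jian-Tang", 2964, 7.97),
        (3, "Xiang-Sha-Liu-Jun-Zi-Tang", 2161, 5.81),
        (4, "Gui-Pi-Tang", 2067, 5.56),
        (5, "Bu-Zhong-Yi-Qi-Tang", 2066, 5.56),
        (6, "Zhen-Ren-Huo-Ming-Yin", 2037, 5.48),
        (7, "Xue-Fu-Zhu-Yu-Tang", 1954, 5.26),
        (8, "Shen-Mai-San", 1870, 5.03),
        (9, "Suan-Zao-Ren-Tang", 1824, 4.91),
        (10, "Zhi-Bai-Di-Huang-Wan", 1610, 4.33),
    ]
    return pd.DataFrame(rows, columns=["rank", "name", "n", "published_pct"])


def top_single_herbs() -> pd.DataFrame:
    """The ten most-prescribed single herbs (counts over N=37,176)."""
    rows = [
        (1, "Hedyotis diffusa", 15565, 41.87),
        (2, "Scutellaria barbata", 6423, 17.28),
        (3, "Taraxacum mongolicum", 5579, 15.01),
        (4, "Salvia miltiorrhiza", 4477, 12.04),
        (5, "Ziziphus spinosa", 4353, 11.71),
        (6, "Millettia dielsiana", 4305, 11.58),
        (7, "Astragalus membranaceus", 3801, 10.22),
        (8, "Scutellaria baicalensis", 3551, 9.55),
        (9, "Fritillaria thunbergii", 3536, 9.51),
        (10, "Rheum palmatum", 3301, 8.88),
    ]
    return pd.DataFrame(rows, columns=["rank", "name", "n", "published_pct"])


def pair_rule_table() -> pd.DataFrame:
    """The ten strongest published pair rules.

    ``published_conf_pct`` is reproduced as printed; for most rows the
    implied denominator matches no published item count exactly (likely a
    sub-cohort denominator in the original processing), so only rows whose
    counts are internally consistent are used in exact cross-checks. The
    last column marks duplex medicinals (SH + SH pairs).
    """
    rows = [
        (1, "Hedyotis diffusa", SH, "Scutellaria barbata", SH,
         4045, 10.88, 77.36, True),
        (2, "Scutellaria barbata", SH, "San-Zhong-Kui-Jian-Tang", HF,
         1492, 4.01, 50.78, False),
        (3, "Hedyotis diffusa", SH, "San-Zhong-Kui-Jian-Tang", HF,
         1396, 3.76, 47.52, False),
        (4, "Taraxacum mongolicum", SH, "Millettia dielsiana", SH,
         1197, 3.22, 33.91, True),
        (5, "Taraxacum mongolicum", SH, "Zhen-Ren-Huo-Ming-Yin", HF,
         960, 2.58, 50.16, False),
        (6, "Hedyotis diffusa", SH, "Fritillaria thunbergii", SH,
         870, 2.34, 31.42, True),
        (7, "Hedyotis diffusa", SH, "Smilax glabra", SH,
         853, 2.29, 76.09, True),
        (8, "Scutellaria barbata", SH, "Smilax glabra", SH,
         766, 2.06, 68.33, True),
        (9, "Hedyotis diffusa", SH, "Wen-Dan-Tang", HF,
         715, 1.92, 49.83, False),
        (10, "Hedyotis diffusa", SH, "Xiang-Sha-Liu-Jun-Zi-Tang", HF,
         677, 1.82, 31.33, False),
    ]
    return pd.DataFrame(rows, columns=[
        "rank", "item_a", "kind_a", "item_b", "kind_b", "n_ab",
        "published_support_pct", "published_conf_pct", "is_duplex"])


def published_item_counts() -> dict[str, int]:
    """Item name -> prescription count, for every published item."""
    counts = {}
    for frame in (top_formulas(), top_single_herbs()):
        counts.update(dict(zip(frame["name"], frame["n"])))
    return counts


def published_rules(policy: str = "condition_on_rarer") -> list[PairRule]:
    """The published pair rules as :class:`PairRule` objects.

    Counts for the two items appearing only inside pair rules (Smilax
    glabra, Wen-Dan-Tang) are not published; they are reconstructed from the
    printed confidence (n_ab / confidence), which affects only those rules'
    own confidence values, not supports, the network, or the core.
    """
    table = pair_rule_table()
    item_counts = published_item_counts()
    # implied by printed confidence: 853 / 0.7609 and 715 / 0.4983
    item_counts.setdefault("Smilax glabra", round(853 / 0.7609))
    item_counts.setdefault("Wen-Dan-Tang", round(715 / 0.4983))
    kinds = {}
    pair_counts = {}
    for row in table.itertuples():
        kinds[row.item_a] = row.kind_a
        kinds[row.item_b] = row.kind_b
        a, b = sorted((row.item_a, row.item_b))
        pair_counts[(a, b)] = row.n_ab
    used = {name: item_counts[name] for name in kinds}
    return build_rules(pair_counts, used, N_PRESCRIPTIONS, kinds, policy)
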