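"""Seed-reproducible synthetic claims generator.

Taiwan's National Health Insurance Research Database (NHIRD) cannot be
redistributed, so this module generates claims databases with the
statistical structure the downstream mining assumes:

* a CHM catalog of herbal formulae (HF) and single herbs (SH), each with a
  configured marginal prescription probability;
* outpatient visits carrying 1-3 ICD-9 diagnoses, a breast-cancer subset
  (codes 174.0-174.9, emitted dotless), and treatment-type flags including
  the acupuncture/massage/traumatology modalities that cohort extraction
  excludes;
* per-visit CHM item sets averaging ~6.5 items, sampled so that each item's
  empirical frequency converges to its configured marginal; and
* one or more *implanted pairs* whose co-occurrence odds are boosted above
  independence — the planted "core treatment" that the rule miner and
  network analysis are expected to recover.

Sampling model
--------------
Items enter a prescription as independent Bernoulli draws with the
configured marginals, so the expected prescription size is the sum of the
marginals and every non-implanted pair has co-occurrence odds ratio exactly
1. Each implanted pair ``(a, b, joint_boost)`` is instead drawn jointly from
the unique 2x2 distribution with the same two marginals and odds ratio
``joint_boost`` (a Plackett construction; see
:func:`pair_joint_probability`), which perturbs dependence without moving
any marginal. Empty prescriptions are redrawn, a negligible correction when
the marginals sum to ~6.5.

One integer seed drives a single named :class:`numpy.random.Generator`
stream; no global RNG state is touched.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .claims import (ChmItem, ClaimsDatabase, CHM_FLAG, EXCLUDABLE_FLAGS,
                     HF, SH, join_flags)
from .errors import ConfigurationError

__all__ = [
    "AgeDistribution", "GeneratorConfig", "ImplantedPair",
    "default_catalog", "default_implanted_pairs", "default_config",
    "generate", "generate_prescription_sets", "pair_joint_probability",
]

# Named catalog entries calibrated to the per-prescription prevalence of the
# ten most-used HF and SH (plus two items that appear only inside published
# pair rules) in the 2008 Taiwan NHIRD breast-cancer prescription database.
_NAMED_ITEMS: list[tuple[str, str, str, float]] = [
    ("HF01", "Jia-Wei-Xiao-Yao-San", HF, 0.1964),
    ("HF02", "San-Zhong-Kui-Jian-Tang", HF, 0.0797),
    ("HF03", "Xiang-Sha-Liu-Jun-Zi-Tang", HF, 0.0581),
    ("HF04", "Gui-Pi-Tang", HF, 0.0556),
    ("HF05", "Bu-Zhong-Yi-Qi-Tang", HF, 0.0556),
    ("HF06", "Zhen-Ren-Huo-Ming-Yin", HF, 0.0548),
    ("HF07", "Xue-Fu-Zhu-Yu-Tang", HF, 0.0526),
    ("HF08", "Shen-Mai-San", HF, 0.0503),
    ("HF09", "Suan-Zao-Ren-Tang", HF, 0.0491),
    ("HF10", "Zhi-Bai-Di-Huang-Wan", HF, 0.0433),
    ("HF11", "Wen-Dan-Tang", HF, 0.0386),
    ("SH01", "Hedyotis diffusa", SH, 0.4187),
    ("SH02", "Scutellaria barbata", SH, 0.1728),
    ("SH03", "Taraxacum mongolicum", SH, 0.1501),
    ("SH04", "Salvia miltiorrhiza", SH, 0.1204),
    ("SH05", "Ziziphus spinosa", SH, 0.1171),
    ("SH06", "Millettia dielsiana", SH, 0.1158),
    ("SH07", "Astragalus membranaceus", SH, 0.1022),
    ("SH08", "Scutellaria baicalensis", SH, 0.0955),
    ("SH09", "Fritillaria thunbergii", SH, 0.0951),
    ("SH10", "Rheum palmatum", SH, 0.0888),
    ("SH11", "Smilax glabra", SH, 0.0302),
]

_MEAN_ITEMS_TARGET = 6.5  # mean CHM items per prescription in the emulated data
_N_FILLER = 30  # synthetic long-tail items carrying the rest of the 6.5 mean

# ICD-9 comorbidity chapters (numeric code ranges) with sampling weights
# proportional to the published per-chapter patient shares; the breast-cancer
# range 140-239 (neoplasms) is deliberately absent so index and comorbidity
# codes never collide.
_COMORBIDITY_CHAPTERS: list[tuple[int, int, float]] = [
    (780, 799, 10.78), (520, 579, 10.05), (710, 739, 7.44),
    (460, 519, 6.04), (580, 629, 5.88), (390, 459, 4.46),
    (240, 279, 4.35), (680, 709, 3.56), (290, 319, 3.47),
    (320, 389, 2.21), (800, 999, 1.76), (280, 289, 1.44), (1, 139, 0.18),
]

# Secondary-diagnosis rates, calibrated so that with ~6-8 retained visits
# per CHM user the per-patient chapter shares land near the published ones
# (top chapter ~11% of patients).
_P_SECOND_DX = 0.08   # chance a visit records a second diagnosis
_P_THIRD_DX = 0.25    # chance a visit with a second diagnosis records a third


@dataclass(frozen=True)
class ImplantedPair:
    """A planted dependence: co-occurrence odds of (item_a, item_b) are
    multiplied by ``joint_boost`` relative to independence, marginals held
    fixed."""

    item_a: str
    item_b: str
    joint_boost: float


@dataclass(frozen=True)
class AgeDistribution:
    """Normal age distribution (years at the study midpoint), truncated."""

    mean: float = 52.0
    sd: float = 9.0
    min_age: float = 20.0
    max_age: float = 95.0


@dataclass
class GeneratorConfig:
    """Everything :func:`generate` needs; one seed, no hidden state.

    The defaults emulate the 2008 breast-cancer study conditions: marginal
    item probabilities equal to the published per-prescription prevalences,
    a mean of 6.5 items per prescription, 7.25% of patients using CHM with
    ~4.35% of eligible visits carrying a CHM prescription (net of the
    excluded-modality rate), and the Hedyotis diffusa / Scutellaria barbata
    core pair implanted at the published joint prevalence.
    """

    n_patients: int = 10_000
    visits_per_patient: float = 14.0
    p_breast_cancer_visit: float = 0.75
    p_chm_user: float = 0.0725
    p_chm_visit: float = 0.69
    p_excluded_treatment: float = 0.13
    catalog: list[tuple[ChmItem, float]] = field(default_factory=lambda: default_catalog())
    implanted_pairs: list[ImplantedPair] = field(
        default_factory=lambda: default_implanted_pairs())
    mean_items_per_prescription: float | None = None
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    study_start: dt.date = dt.date(2008, 1, 1)
    study_end: dt.date = dt.date(2008, 12, 31)
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_breast_cancer_visit", "p_chm_user", "p_chm_visit",
                     "p_excluded_treatment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients <= 0:
            raise ConfigurationError(f"n_patients must be positive, got {self.n_patients}")
        if self.visits_per_patient <= 0:
            raise ConfigurationError(
                f"visits_per_patient must be positive, got {self.visits_per_patient}")
        if not self.catalog:
            raise ConfigurationError("catalog must not be empty")
        ids = [item.item_id for item, _ in self.catalog]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("catalog: item_id values must be unique")
        for item, p in self.catalog:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"catalog: marginal probability of {item.item_id} must be "
                    f"in [0, 1], got {p}")
        if (self.mean_items_per_prescription is not None
                and self.mean_items_per_prescription <= 0):
            raise ConfigurationError(
                "mean_items_per_prescription must be positive, got "
                f"{self.mean_items_per_prescription}")
        known = set(ids)
        seen: set[str] = set()
        for pair in self.implanted_pairs:
            for item_id in (pair.item_a, pair.item_b):
                if item_id not in known:
                    raise ConfigurationError(
                        f"implanted_pairs: unknown item_id {item_id!r}")
            if pair.item_a == pair.item_b:
                raise ConfigurationError(
                    f"implanted_pairs: self-pair {pair.item_a!r}")
            if pair.joint_boost < 1.0:
                raise ConfigurationError(
                    f"implanted_pairs: joint_boost must be >= 1, got {pair.joint_boost}")
            overlap = {pair.item_a, pair.item_b} & seen
            if overlap:
                raise ConfigurationError(
                    "implanted_pairs: each item may appear in at most one "
                    f"pair (reused: {sorted(overlap)})")
            seen |= {pair.item_a, pair.item_b}
        if self.study_start > self.study_end:
            raise ConfigurationError("study_start must not be after study_end")


def default_catalog() -> list[tuple[ChmItem, float]]:
    """The calibrated catalog: 22 named items plus a synthetic long tail.

    Marginals sum to 6.5, the mean CHM item count per prescription in the
    emulated data. Filler entries stand in for the many low-prevalence items
    of a real formulary and are labelled synthetic.
    """
    entries = [(ChmItem(i, n, k), p) for i, n, k, p in _NAMED_ITEMS]
    named_mass = sum(p for _, _, _, p in _NAMED_ITEMS)
    filler_p = (_MEAN_ITEMS_TARGET - named_mass) / _N_FILLER
    for j in range(_N_FILLER):
        kind = HF if j % 2 else SH
        label = "formula" if kind == HF else "herb"
        entries.append(
            (ChmItem(f"X{kind}{j + 1:02d}", f"Synthetic filler {label} {j + 1:02d}",
                     kind), filler_p))
    return entries


def default_implanted_pairs() -> list[ImplantedPair]:
    """Planted dependencies matching the published pair prevalences.

    Boost 2.84 lifts Hedyotis diffusa + Scutellaria barbata from the 7.2%
    joint prevalence independence would give to the published 10.9%; boost
    2.50 lifts Taraxacum mongolicum + Millettia dielsiana to 3.2%.
    """
    return [ImplantedPair("SH01", "SH02", 2.84),
            ImplantedPair("SH03", "SH06", 2.50)]


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The study-condition defaults with a chosen seed."""
    return replace(GeneratorConfig(seed=seed), **overrides)


def pair_joint_probability(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(A and B) for the 2x2 distribution with marginals ``p_a``, ``p_b``
    and the given odds ratio (Plackett construction).

    Solves ``theta (p_a-p11)(p_b-p11) = p11 (1-p_a-p_b+p11)`` for the root
    that keeps all four cells non-negative; ``theta = 1`` returns the
    independent product.
    """
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ConfigurationError("marginals must be in [0, 1]")
    if odds_ratio <= 0:
        raise ConfigurationError(f"odds_ratio must be positive, got {odds_ratio}")
    if math.isclose(odds_ratio, 1.0):
        return p_a * p_b
    theta = odds_ratio
    b = theta * (p_a + p_b) + (1.0 - p_a - p_b)
    disc = b * b - 4.0 * (theta - 1.0) * theta * p_a * p_b
    p11 = (b - math.sqrt(disc)) / (2.0 * (theta - 1.0))
    # guard tiny negative round-off
    return min(max(p11, max(0.0, p_a + p_b - 1.0)), min(p_a, p_b))


def _effective_marginals(config: GeneratorConfig) -> np.ndarray:
    p = np.array([prob for _, prob in config.catalog], dtype=float)
    target = config.mean_items_per_prescription
    if target is not None and p.sum() > 0:
        scale = target / p.sum()
        p = p * scale
        if (p > 1.0).any():
            raise ConfigurationError(
                "mean_items_per_prescription: rescaled marginal exceeds 1 for "
                f"{[config.catalog[i][0].item_id for i in np.flatnonzero(p > 1.0)]}")
    return p


def _pair_cells(config: GeneratorConfig, p: np.ndarray):
    """Per implanted pair: column indices and the 2x2 cell probabilities
    ordered (11, 10, 01, 00)."""
    index = {item.item_id: i for i, (item, _) in enumerate(config.catalog)}
    cells = []
    for pair in config.implanted_pairs:
        ia, ib = index[pair.item_a], index[pair.item_b]
        pa, pb = p[ia], p[ib]
        p11 = pair_joint_probability(pa, pb, pair.joint_boost)
        cells.append((ia, ib,
                      np.array([p11, pa - p11, pb - p11, 1.0 - pa - pb + p11])))
    return cells


def _sample_item_matrix(rng: np.random.Generator, n: int, p: np.ndarray,
                        pair_cells) -> np.ndarray:
    """n x n_items boolean matrix of prescriptions; rows guaranteed nonempty."""

    def draw(m: int) -> np.ndarray:
        X = rng.random((m, p.size)) < p
        for ia, ib, cells in pair_cells:
            u = rng.random(m)
            c = np.minimum(np.searchsorted(np.cumsum(cells), u, side="right"), 3)
            X[:, ia] = c <= 1          # cells 11, 10 -> item a present
            X[:, ib] = (c == 0) | (c == 2)  # cells 11, 01 -> item b present
        return X

    X = draw(n)
    empty = ~X.any(axis=1)
    while empty.any():  # redraw empty prescriptions (a CHM visit has >=1 item)
        X[empty] = draw(int(empty.sum()))
        empty = ~X.any(axis=1)
    return X


def generate_prescription_sets(
    n_prescriptions: int,
    catalog: list[tuple[ChmItem, float]] | None = None,
    implanted_pairs: list[ImplantedPair] | None = None,
    mean_items_per_prescription: float | None = None,
    seed: int = 0,
) -> list[frozenset[str]]:
    """Sample bare prescriptions (no visit/patient scaffolding).

    Convenience entry point for mining experiments where every unit of
    observation is a CHM prescription.
    """
    config = GeneratorConfig(
        n_patients=1, visits_per_patient=1.0,
        catalog=catalog if catalog is not None else default_catalog(),
        implanted_pairs=(implanted_pairs if implanted_pairs is not None
                         else default_implanted_pairs()),
        mean_items_per_prescription=mean_items_per_prescription, seed=seed)
    config.validate()
    if n_prescriptions < 0:
        raise ConfigurationError("n_prescriptions must be non-negative")
    rng = np.random.default_rng(seed)
    p = _effective_marginals(config)
    X = _sample_item_matrix(rng, n_prescriptions, p, _pair_cells(config, p))
    ids = np.array([item.item_id for item, _ in config.catalog])
    return [frozenset(ids[row]) for row in X]


def _sample_comorbidity_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dotless 4-digit ICD-9 codes drawn from the comorbidity chapters."""
    lo = np.array([c[0] for c in _COMORBIDITY_CHAPTERS])
    hi = np.array([c[1] for c in _COMORBIDITY_CHAPTERS])
    w = np.array([c[2] for c in _COMORBIDITY_CHAPTERS])
    chapter = rng.choice(len(lo), size=n, p=w / w.sum())
    code3 = rng.integers(lo[chapter], hi[chapter] + 1)
    digit4 = rng.integers(0, 10, size=n)
    return np.array([f"{c:03d}{d}" for c, d in zip(code3, digit4)])


def generate(config: GeneratorConfig) -> ClaimsDatabase:
    """Generate a full synthetic claims database.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical database (and byte-identical files once written).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients
    window_days = (config.study_end - config.study_start).days + 1
    mid = config.study_start + dt.timedelta(days=window_days // 2)

    # patients: breast-cancer cohort, recorded sex F, ages ~ truncated normal
    age = config.age_distribution
    ages = np.clip(rng.normal(age.mean, age.sd, n_pat), age.min_age, age.max_age)
    birth = (pd.Timestamp(mid)
             - pd.to_timedelta(np.round(ages * 365.25).astype(int), unit="D"))
    patient_ids = np.array([f"P{i + 1:06d}" for i in range(n_pat)])
    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "birth_date": birth.strftime("%Y-%m-%d"),
        "sex": "F",
    })

    # visits: exchangeable within patient, dates uniform over the window
    counts = rng.poisson(config.visits_per_patient, n_pat)
    n_vis = int(counts.sum())
    pat_idx = np.repeat(np.arange(n_pat), counts)
    offsets = rng.integers(0, window_days, n_vis)
    dates = (pd.Timestamp(config.study_start)
             + pd.to_timedelta(offsets, unit="D")).strftime("%Y-%m-%d")

    is_bc = rng.random(n_vis) < config.p_breast_cancer_visit
    bc_codes = np.char.add("174", rng.integers(0, 10, n_vis).astype(str))
    other = _sample_comorbidity_codes(rng, n_vis)
    dx1 = np.where(is_bc, bc_codes, other)
    has2 = rng.random(n_vis) < _P_SECOND_DX
    dx2 = np.where(has2, _sample_comorbidity_codes(rng, n_vis), "")
    has3 = has2 & (rng.random(n_vis) < _P_THIRD_DX)
    dx3 = np.where(has3, _sample_comorbidity_codes(rng, n_vis), "")

    excluded = rng.random(n_vis) < config.p_excluded_treatment
    which_excl = rng.integers(0, len(EXCLUDABLE_FLAGS), n_vis)
    # CHM use is patient-clustered: only a small fraction of patients ever
    # receive CHM, but most of a user's visits do
    chm_user = rng.random(n_pat) < config.p_chm_user
    chm = chm_user[pat_idx] & (rng.random(n_vis) < config.p_chm_visit)
    flags = []
    for i in range(n_vis):
        f = []
        if chm[i]:
            f.append(CHM_FLAG)
        if excluded[i]:
            f.append(EXCLUDABLE_FLAGS[which_excl[i]])
        flags.append(join_flags(f))
    visit_ids = np.array([f"V{i + 1:07d}" for i in range(n_vis)])
    visits = pd.DataFrame({
        "visit_id": visit_ids, "patient_id": patient_ids[pat_idx],
        "date": dates, "dx1": dx1, "dx2": dx2, "dx3": dx3, "flags": flags,
    })

    # prescriptions for CHM visits
    p = _effective_marginals(config)
    chm_rows = np.flatnonzero(chm)
    X = _sample_item_matrix(rng, chm_rows.size, p, _pair_cells(config, p))
    r, c = np.nonzero(X)
    item_ids = np.array([item.item_id for item, _ in config.catalog])
    prescriptions = pd.DataFrame({
        "visit_id": visit_ids[chm_rows[r]],
        "item_id": item_ids[c],
    })

    catalog = pd.DataFrame(
        [(item.item_id, item.name, item.kind) for item, _ in config.catalog],
        columns=["item_id", "name", "kind"])

    db = ClaimsDatabase(patients, visits, prescriptions, catalog,
                        meta={"seed": config.seed})
    return db
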