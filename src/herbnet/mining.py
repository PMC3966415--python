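"""Pairwise association-rule mining over a prescription database.

Given N prescriptions (each a *set* of CHM items), every unordered item
pair {A, B} observed together in at least one prescription yields a rule
with

* ``support``  = n_AB / N — the fraction of all prescriptions containing
  both items;
* ``confidence_a_to_b`` = n_AB / n_A and ``confidence_b_to_a`` = n_AB / n_B
  — the conditional co-prescription rates in each direction;
* a single ``reported_confidence`` chosen by policy (by default the rate
  conditioned on the *rarer* item, the direction that makes the strength of
  the attachment of a minor item to a major one visible).

Rules pass the filter when support >= 0.5% and reported confidence >= 30%
(the conventional thresholds for CHM co-prescription studies, both
configurable), and are ranked by support, then confidence, then pair id.
A rule joining two single herbs is flagged as a *duplex medicinal*.

The pair counting itself is a sparse matrix product (X'X over the binary
prescription-by-item matrix); tests hold it equal to a brute-force
enumeration.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._util import pct
from .claims import SH
from .errors import ConfigurationError, ValidationError

__all__ = [
    "PairRule", "MiningThresholds", "CONFIDENCE_POLICIES",
    "count_items", "count_pairs", "build_rules", "reported_confidence",
    "apply_thresholds", "mine", "frequent_itemsets", "rules_to_frame",
]

CONFIDENCE_POLICIES = ("condition_on_rarer", "condition_on_a", "max_direction")


@dataclass(frozen=True)
class PairRule:
    """One unordered co-prescription rule with its exact counts.

    ``item_a < item_b`` by identifier, so each unordered pair appears once.
    """

    item_a: str
    item_b: str
    n_ab: int
    n_a: int
    n_b: int
    n_total: int
    support: float
    confidence_a_to_b: float
    confidence_b_to_a: float
    reported_confidence: float
    is_duplex: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.item_a, self.item_b)


@dataclass(frozen=True)
class MiningThresholds:
    """Retention thresholds (fractions): support >= 0.5%, confidence >= 30%
    by default."""

    min_support: float = 0.005
    min_confidence: float = 0.30

    def __post_init__(self):
        for name in ("min_support", "min_confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


def _validate_items(prescriptions: Sequence[AbstractSet[str]],
                    catalog_ids: AbstractSet[str] | None) -> None:
    if catalog_ids is None:
        return
    seen = set().union(*prescriptions) if prescriptions else set()
    unknown = sorted(seen - set(catalog_ids))
    if unknown:
        raise ValidationError(f"items absent from catalog: {unknown}")


def count_items(prescriptions: Sequence[AbstractSet[str]],
                catalog_ids: AbstractSet[str] | None = None
                ) -> tuple[dict[str, int], int]:
    """Per-item prescription counts and the total prescription count.

    ``counts[i]`` is the number of prescriptions *containing* item i (not
    line items — a prescription is a set). Prevalence percentages are
    ``pct(counts[i], n_total)``.
    """
    _validate_items(prescriptions, catalog_ids)
    counts: dict[str, int] = {}
    for items in prescriptions:
        for item in items:
            counts[item] = counts.get(item, 0) + 1
    return dict(sorted(counts.items())), len(prescriptions)


def count_pairs(prescriptions: Sequence[AbstractSet[str]],
                catalog_ids: AbstractSet[str] | None = None
                ) -> tuple[dict[tuple[str, str], int], dict[str, int], int]:
    """Exact co-prescription counts for every observed unordered pair.

    Each prescription of k items contributes one observation to each of its
    C(k, 2) pairs, so ``sum(pair_counts.values())`` equals the sum of
    C(k, 2) over prescriptions. Implemented as a sparse X'X product.
    """
    _validate_items(prescriptions, catalog_ids)
    n_total = len(prescriptions)
    if n_total == 0:
        return {}, {}, 0
    vocab = sorted(set().union(*prescriptions))
    index = {item: i for i, item in enumerate(vocab)}
    rows, cols = [], []
    for r, items in enumerate(prescriptions):
        for item in items:
            rows.append(r)
            cols.append(index[item])
    X = sp.csr_matrix((np.ones(len(rows), dtype=np.int64), (rows, cols)),
                      shape=(n_total, len(vocab)))
    C = sp.triu(X.T @ X, k=1).tocoo()
    pair_counts = {(vocab[i], vocab[j]): int(n)
                   for i, j, n in zip(C.row, C.col, C.data)}
    item_counts = {item: int(n) for item, n in
                   zip(vocab, np.asarray(X.sum(axis=0)).ravel())}
    return pair_counts, item_counts, n_total


def reported_confidence(n_ab: int, n_a: int, n_b: int,
                        item_a: str, item_b: str,
                        policy: str = "condition_on_rarer") -> float:
    """The single confidence value a rule reports, by policy.

    ``condition_on_rarer`` (default) divides by the less frequent item's
    count (ties broken toward the lexicographically smaller identifier);
    ``condition_on_a`` always conditions on ``item_a`` (the smaller id);
    ``max_direction`` takes the larger of the two directional confidences.
    """
    if policy not in CONFIDENCE_POLICIES:
        raise ConfigurationError(
            f"unknown confidence policy {policy!r}; choose from {CONFIDENCE_POLICIES}")
    if policy == "condition_on_a":
        denom = n_a
    elif policy == "max_direction":
        denom = min(n_a, n_b)
    else:  # condition_on_rarer
        if n_a < n_b or (n_a == n_b and item_a <= item_b):
            denom = n_a
        else:
            denom = n_b
    if denom == 0:
        raise ValidationError(
            f"confidence undefined for pair ({item_a}, {item_b}): zero denominator")
    return n_ab / denom


def build_rules(pair_counts: Mapping[tuple[str, str], int],
                item_counts: Mapping[str, int], n_total: int,
                kinds: Mapping[str, str] | None = None,
                policy: str = "condition_on_rarer") -> list[PairRule]:
    """Assemble :class:`PairRule` objects from raw counts.

    ``kinds`` maps item_id -> HF/SH for the duplex flag; without it no rule
    is flagged duplex.
    """
    if n_total <= 0:
        raise ValidationError("cannot build rules over zero prescriptions")
    rules = []
    for (a, b), n_ab in pair_counts.items():
        if b < a:
            a, b = b, a
        n_a, n_b = item_counts[a], item_counts[b]
        if n_ab > min(n_a, n_b):
            raise ValidationError(
                f"inconsistent counts for pair ({a}, {b}): n_ab > min(n_a, n_b)")
        rules.append(PairRule(
            item_a=a, item_b=b, n_ab=n_ab, n_a=n_a, n_b=n_b, n_total=n_total,
            support=n_ab / n_total,
            confidence_a_to_b=n_ab / n_a,
            confidence_b_to_a=n_ab / n_b,
            reported_confidence=reported_confidence(n_ab, n_a, n_b, a, b, policy),
            is_duplex=(kinds is not None
                       and kinds.get(a) == SH and kinds.get(b) == SH),
        ))
    return sorted(rules, key=_rank_key)


def _rank_key(rule: PairRule):
    # support desc, reported confidence desc, pair id asc — deterministic
    return (-rule.support, -rule.reported_confidence, rule.item_a, rule.item_b)


def apply_thresholds(rules: Iterable[PairRule],
                     thresholds: MiningThresholds | None = None) -> list[PairRule]:
    """Keep rules with support and reported confidence at or above the
    thresholds, ranked by (support desc, confidence desc, pair id asc)."""
    thresholds = thresholds or MiningThresholds()
    kept = [r for r in rules
            if r.support >= thresholds.min_support
            and r.reported_confidence >= thresholds.min_confidence]
    return sorted(kept, key=_rank_key)


def mine(prescriptions: Sequence[AbstractSet[str]],
         kinds: Mapping[str, str] | None = None,
         thresholds: MiningThresholds | None = None,
         policy: str = "condition_on_rarer",
         catalog_ids: AbstractSet[str] | None = None) -> list[PairRule]:
    """Count, score and filter in one call; returns the retained, ranked rules."""
    pair_counts, item_counts, n_total = count_pairs(prescriptions, catalog_ids)
    if n_total == 0:
        return []
    rules = build_rules(pair_counts, item_counts, n_total, kinds, policy)
    return apply_thresholds(rules, thresholds)


def frequent_itemsets(prescriptions: Sequence[AbstractSet[str]],
                      min_support: float = 0.005,
                      max_size: int = 3) -> dict[frozenset, int]:
    """Apriori frequent itemsets up to ``max_size`` items.

    Exploration helper only: the rule/network path mines pairs, matching
    the analysis this package implements, and nothing downstream consumes
    larger itemsets.
    """
    n = len(prescriptions)
    if n == 0:
        return {}
    if max_size < 1:
        raise ConfigurationError(f"max_size must be >= 1, got {max_size}")
    min_count = min_support * n
    counts, _ = count_items(prescriptions)
    level = {frozenset([item]): c for item, c in counts.items()
             if c >= min_count}
    out = dict(level)
    k = 1
    while level and k < max_size:
        frequent = set(level)
        singles = sorted({i for s in frequent for i in s})
        candidates = set()
        for s in frequent:
            for item in singles:
                if item not in s:
                    cand = s | {item}
                    if all(cand - {x} in frequent for x in cand):
                        candidates.add(cand)
        level = {}
        for cand in candidates:
            c = sum(1 for items in prescriptions if cand <= items)
            if c >= min_count:
                level[cand] = c
        out.update(level)
        k += 1
    return out


def rules_to_frame(rules: Sequence[PairRule],
                   names: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Ranked tabular form with percentages rounded half-up to 2 decimals."""
    names = names or {}
    records = []
    for rank, r in enumerate(rules, start=1):
        # the reported value is one of the two directional confidences; use
        # the matching exact (n, denominator) pair for rounding
        reported_denom = r.n_a if r.reported_confidence == r.confidence_a_to_b else r.n_b
        records.append({
            "rank": rank,
            "item_a": r.item_a, "item_b": r.item_b,
            "name_a": names.get(r.item_a, r.item_a),
            "name_b": names.get(r.item_b, r.item_b),
            "is_duplex": r.is_duplex,
            "n_ab": r.n_ab,
            "support_pct": pct(r.n_ab, r.n_total),
            "conf_ab_pct": pct(r.n_ab, r.n_a),
            "conf_ba_pct": pct(r.n_ab, r.n_b),
            "reported_conf_pct": pct(r.n_ab, reported_denom),
        })
    cols = ["rank", "item_a", "item_b", "name_a", "name_b", "is_duplex",
            "n_ab", "support_pct", "conf_ab_pct", "conf_ba_pct",
            "reported_conf_pct"]
    return pd.DataFrame(records, columns=cols)
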