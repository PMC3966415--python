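"""End-to-end orchestration and report rendering.

``run_pipeline`` chains the stages — generate or load claims, extract the
cohort, mine pair rules, build the network, identify the core — into a
:class:`ReportBundle`: the cohort summary, ranked HF/SH prevalence tables,
the ranked pair-rule table with duplex flags, the core treatment, and a
provenance block (config hash, seed, package version) so any output can be
traced back to its exact inputs.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from ._util import pct
from .claims import HF, SH
from .cohort import CohortSpec, CohortSummary, select_cohort
from .errors import ConfigurationError, HerbnetError
from .io import (generator_config_from_dict, generator_config_to_dict,
                 read_claims)
from .mining import (MiningThresholds, PairRule, apply_thresholds,
                     build_rules, count_pairs, rules_to_frame)
from .network import (CoreTreatment, build_network, identify_core,
                      prevalent_unconnected, write_edgelist_tsv,
                      write_graphml)
from .synthetic import GeneratorConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_tables"]


@dataclass
class PipelineConfig:
    """Pipeline inputs: a claims source plus analysis parameters.

    Exactly one of ``claims_dir`` (a directory in the interchange format)
    or ``generator`` (a synthetic-claims config) must be set.
    """

    claims_dir: str | None = None
    generator: GeneratorConfig | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    confidence_policy: str = "condition_on_rarer"
    top_k: int = 10
    min_unconnected_prevalence: float = 0.05

    def validate(self) -> None:
        if (self.claims_dir is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one of claims_dir / generator must be set")
        if self.top_k <= 0:
            raise ConfigurationError(f"top_k must be positive, got {self.top_k}")

    def to_dict(self) -> dict:
        return {
            "claims_dir": self.claims_dir,
            "generator": (generator_config_to_dict(self.generator)
                          if self.generator else None),
            "cohort": {
                "icd9_prefix": self.cohort.icd9_prefix,
                "study_start": self.cohort.study_start.isoformat(),
                "study_end": self.cohort.study_end.isoformat(),
                "excluded_flags": sorted(self.cohort.excluded_flags),
                "age_reference_date": self.cohort.age_reference_date.isoformat(),
                "age_edges": list(self.cohort.age_edges),
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "confidence_policy": self.confidence_policy,
            "top_k": self.top_k,
            "min_unconnected_prevalence": self.min_unconnected_prevalence,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        gen = kwargs.pop("generator", None)
        coh = kwargs.pop("cohort", {}) or {}
        thr = kwargs.pop("thresholds", {}) or {}
        for key in ("study_start", "study_end", "age_reference_date"):
            if key in coh and isinstance(coh[key], str):
                coh[key] = dt.date.fromisoformat(coh[key])
        if "excluded_flags" in coh:
            coh["excluded_flags"] = frozenset(coh["excluded_flags"])
        if "age_edges" in coh:
            coh["age_edges"] = tuple(coh["age_edges"])
        config = cls(
            generator=generator_config_from_dict(gen) if gen else None,
            cohort=CohortSpec(**coh),
            thresholds=MiningThresholds(**thr),
            **{k: v for k, v in kwargs.items() if v is not None
               or k == "claims_dir"},
        )
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"pipeline config {path}: expected a mapping")
        return cls.from_dict(data)


@dataclass
class ReportBundle:
    """Everything the analysis reports, with provenance."""

    cohort_summary: CohortSummary
    top_hf: pd.DataFrame
    top_sh: pd.DataFrame
    top_pairs: pd.DataFrame
    all_retained_rules: list[PairRule]
    core: CoreTreatment | None
    prevalent_unconnected: pd.DataFrame
    network: "object"  # networkx.Graph
    n_prescriptions: int
    mean_items_per_prescription: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "cohort_summary": self.cohort_summary.to_dict(),
            "top_hf": self.top_hf.to_dict(orient="records"),
            "top_sh": self.top_sh.to_dict(orient="records"),
            "top_pairs": self.top_pairs.to_dict(orient="records"),
            "core": self.core.to_dict() if self.core else None,
            "prevalent_unconnected":
                self.prevalent_unconnected.to_dict(orient="records"),
            "n_prescriptions": self.n_prescriptions,
            "mean_items_per_prescription": self.mean_items_per_prescription,
            "provenance": self.provenance,
        }


def _top_items(item_counts, n_total, names, kinds, kind, top_k) -> pd.DataFrame:
    rows = [(item, n) for item, n in item_counts.items()
            if kinds.get(item) == kind]
    rows.sort(key=lambda r: (-r[1], r[0]))
    records = [{"rank": i + 1, "item_id": item, "name": names.get(item, item),
                "n": n, "pct": pct(n, n_total)}
               for i, (item, n) in enumerate(rows[:top_k])]
    return pd.DataFrame(records,
                        columns=["rank", "item_id", "name", "n", "pct"])


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except HerbnetError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage; deterministic given the config (and its seed)."""
    config.validate()
    if config.generator is not None:
        db = _stage("generate", generate, config.generator)
        source = {"kind": "synthetic", "seed": config.generator.seed}
    else:
        db = _stage("load", read_claims, config.claims_dir)
        source = {"kind": "claims_dir", "path": str(config.claims_dir)}
    logger.info("claims: %d patients, %d visits, %d prescription rows",
                len(db.patients), len(db.visits), len(db.prescriptions))

    cohort_db, summary = _stage("cohort", select_cohort, db, config.cohort)
    for step, n in summary.funnel:
        logger.info("funnel: %-40s %8d", step, n)

    sets = cohort_db.prescription_sets()
    kinds = db.item_kinds()
    names = db.item_names()
    pair_counts, item_counts, n_total = _stage(
        "mine", count_pairs, sets, set(db.catalog["item_id"]))
    retained: list[PairRule] = []
    if n_total:
        rules = build_rules(pair_counts, item_counts, n_total, kinds,
                            config.confidence_policy)
        retained = apply_thresholds(rules, config.thresholds)
    logger.info("mining: %d prescriptions, %d observed pairs, %d retained rules",
                n_total, len(pair_counts), len(retained))

    if retained:
        G = _stage("network", build_network, retained, item_counts, n_total, kinds)
        core = _stage("network", identify_core, G)
    else:
        G, core = nx.Graph(), None
    unconnected = (prevalent_unconnected(item_counts, n_total, G,
                                         config.min_unconnected_prevalence)
                   if n_total else pd.DataFrame(
                       columns=["item_id", "n", "prevalence_pct"]))
    if not unconnected.empty:
        unconnected = unconnected.assign(
            name=[names.get(i, i) for i in unconnected["item_id"]])

    mean_items = (sum(len(s) for s in sets) / n_total) if n_total else None
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    provenance = {
        "tool": "herbnet",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "source": source,
    }
    return ReportBundle(
        cohort_summary=summary,
        top_hf=_top_items(item_counts, n_total, names, kinds, HF, config.top_k)
        if n_total else pd.DataFrame(columns=["rank", "item_id", "name", "n", "pct"]),
        top_sh=_top_items(item_counts, n_total, names, kinds, SH, config.top_k)
        if n_total else pd.DataFrame(columns=["rank", "item_id", "name", "n", "pct"]),
        top_pairs=rules_to_frame(retained[:config.top_k], names),
        all_retained_rules=retained,
        core=core,
        prevalent_unconnected=unconnected,
        network=G,
        n_prescriptions=n_total,
        mean_items_per_prescription=mean_items,
        provenance=provenance,
    )


def _render_pairs_text(top_pairs: pd.DataFrame) -> list[str]:
    lines = ["rank\tcombination\tsupport_pct\tconfidence_pct\tn_ab"]
    for row in top_pairs.itertuples():
        star = "*" if row.is_duplex else ""
        lines.append(f"{star}{row.rank}\t{row.name_a}, {row.name_b}\t"
                     f"{row.support_pct:.2f}\t{row.reported_conf_pct:.2f}\t"
                     f"{row.n_ab}")
    return lines


def render_tables(bundle: ReportBundle, out_dir: str | Path,
                  fmt: str = "tsv") -> dict[str, Path]:
    """Write the report artifacts; returns a name -> path map.

    ``fmt='tsv'`` writes machine-readable tables plus a human-readable
    ``report.txt`` (duplex rows starred); ``fmt='text'`` writes only the
    text report. Anything else is a usage error.
    """
    if fmt not in ("tsv", "text"):
        raise ConfigurationError(f"unknown render format {fmt!r} (tsv|text)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    summary = bundle.cohort_summary
    text: list[str] = []
    text.append("Cohort funnel")
    for step, n in summary.funnel:
        text.append(f"  {step}: {n}")
    text.append(f"TCM visit share: "
                f"{summary.pct_tcm_visits if summary.pct_tcm_visits is not None else 'n/a'}%"
                f" of visits with the index diagnosis")
    text.append(f"TCM patient share: "
                f"{summary.pct_tcm_patients if summary.pct_tcm_patients is not None else 'n/a'}%"
                f" of patients with the index diagnosis")
    if bundle.mean_items_per_prescription is not None:
        text.append(f"Mean CHM items per prescription: "
                    f"{bundle.mean_items_per_prescription:.2f}")
    text.append("")
    text.append("Top herbal formulae (HF)")
    for row in bundle.top_hf.itertuples():
        text.append(f"  {row.rank}. {row.name}: {row.n} ({row.pct:.2f})")
    text.append("")
    text.append("Top single herbs (SH)")
    for row in bundle.top_sh.itertuples():
        text.append(f"  {row.rank}. {row.name}: {row.n} ({row.pct:.2f})")
    text.append("")
    text.append("Top CHM combinations (* = duplex medicinal, two SHs)")
    text.extend("  " + line for line in _render_pairs_text(bundle.top_pairs))
    text.append("")
    if bundle.core is not None:
        a, b = bundle.core.core_edge
        text.append(f"Core treatment edge: {a} + {b} "
                    f"(support {100 * bundle.core.edge_support:.2f}%, "
                    f"confidence {100 * bundle.core.edge_confidence:.2f}%)")
        text.append("Core node(s): " + ", ".join(bundle.core.core_nodes))
    else:
        text.append("No rules survived the thresholds; no core identified.")
    text.append("")
    text.append(f"Provenance: {json.dumps(bundle.provenance, sort_keys=True)}")

    report = out_dir / "report.txt"
    report.write_text("\n".join(text) + "\n")
    written["report"] = report

    if fmt == "tsv":
        for name, frame in (("top_hf", bundle.top_hf),
                            ("top_sh", bundle.top_sh),
                            ("top_pairs", bundle.top_pairs),
                            ("prevalent_unconnected",
                             bundle.prevalent_unconnected),
                            ("age_bins", summary.age_bins),
                            ("comorbidity", summary.comorbidity)):
            path = out_dir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
            written[name] = path
        funnel = out_dir / "funnel.tsv"
        funnel.write_text("stage\tn_visits\n" + "".join(
            f"{step}\t{n}\n" for step, n in summary.funnel))
        written["funnel"] = funnel
        summary_path = out_dir / "summary.json"
        payload = {"cohort_summary": summary.to_dict(),
                   "core": bundle.core.to_dict() if bundle.core else None,
                   "n_prescriptions": bundle.n_prescriptions,
                   "mean_items_per_prescription":
                       bundle.mean_items_per_prescription,
                   "provenance": bundle.provenance}
        summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True)
                                + "\n")
        written["summary"] = summary_path
        if bundle.network.number_of_nodes():
            gpath = out_dir / "network.graphml"
            write_graphml(bundle.network, gpath)
            written["graphml"] = gpath
        epath = out_dir / "edges.tsv"
        write_edgelist_tsv(bundle.network, epath)
        written["edges"] = epath
    return written
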