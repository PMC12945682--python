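"""End-to-end orchestration: candidates -> union -> evidence -> validation.

The pipeline runs four stages from a single config:

1. candidate generation — fit the metapath ranker on a hetnet and/or load
   external model score tables, each truncated to the top-k;
2. pooling — set union of the per-model lists with provenance;
3. evidence triage — judge the per-drug abstract corpus, aggregate rates,
   apply both stratification criteria;
4. validation — per-drug left-truncated Cox fits on the cohort and
   cross-tabulation against registered clinical trials.

Every stochastic component derives its randomness from the single config
seed, and the default judgment backend is the deterministic lexicon mock,
so a run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import evidence as ev
from . import pool as pool_mod
from . import ranker as ranker_mod
from .dwpc import build_feature_table
from .hetnet import SynthKGConfig, generate_synthetic_kg, load_hetnet

log = logging.getLogger("addr.pipeline")


@dataclass
class PipelineConfig:
    """Single-run configuration; every stage block is optional except one
    source of candidates.

    ``hetnet`` is either ``{"nodes": path, "edges": path}`` or
    ``{"synthetic": {...kwargs for SynthKGConfig...}}``; ``corpus`` is
    ``{"path": corpus.jsonl}`` or ``{"synthetic": [[drug, P, U, N], ...]}``;
    ``cohort`` is ``{"path": cohort.tsv}`` or ``{"synthetic": {...kwargs
    for CohortConfig...}}``.
    """

    seed: int = 0
    top_k: int = 30
    damping: float = 0.4
    max_length: int = 4
    neutral_threshold: float = 0.99
    year_floor: int = 2000
    abstract_cap: int = 200
    alphas: Mapping[str, float] = field(
        default_factory=lambda: dict(cohort_mod.DEFAULT_ALPHAS)
    )
    mask: Sequence[str] = ()
    target_disease: Optional[str] = None
    hetnet: Optional[Mapping[str, Any]] = None
    score_tables: Sequence[Mapping[str, str]] = ()
    corpus: Optional[Mapping[str, Any]] = None
    cohort: Optional[Mapping[str, Any]] = None
    trials: Optional[str] = None

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.neutral_threshold <= 1.0:
            raise ValueError("neutral_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class FinalReport:
    """Per-drug rows plus a summary block recomputable from the rows."""

    rows: pd.DataFrame
    summary: dict


def _load_mask(mask) -> tuple[str, ...]:
    if isinstance(mask, (str, Path)):
        return tuple(
            line.strip()
            for line in Path(mask).read_text().splitlines()
            if line.strip()
        )
    return tuple(mask)


def _kg_kwargs(raw: Mapping[str, Any]) -> dict:
    """Normalize YAML-friendly generator kwargs (schema triples may be
    comma-separated strings instead of tuples)."""
    kw = dict(raw)
    densities = kw.get("edge_densities")
    if densities:
        kw["edge_densities"] = {
            (tuple(k.split(",")) if isinstance(k, str) else tuple(k)): v
            for k, v in densities.items()
        }
    return kw


def _candidate_lists(config: PipelineConfig, mask: tuple[str, ...]):
    lists = []
    if config.hetnet is not None and config.target_disease is not None:
        if "synthetic" in config.hetnet:
            kg_conf = SynthKGConfig(
                seed=config.seed, **_kg_kwargs(config.hetnet["synthetic"])
            )
            net, _truth = generate_synthetic_kg(kg_conf)
        else:
            net = load_hetnet(config.hetnet["nodes"], config.hetnet["edges"])
        features = build_feature_table(
            net, damping=config.damping, max_length=config.max_length
        )
        labels = ranker_mod.label_pairs_closed_world(net)
        model = ranker_mod.fit_rlr(features, labels, seed=config.seed)
        lists.append(
            ranker_mod.rank_candidates(
                model, features, config.target_disease, mask, config.top_k
            )
        )
        log.info("stage candidates: RLR list of %d drugs", len(lists[-1].entries))
    for spec in config.score_tables:
        ranked = pool_mod.load_score_table(
            spec["path"], spec["name"], config.top_k
        )
        ranked = ranker_mod.RankedList(
            model_name=ranked.model_name,
            entries=[e for e in ranked.entries if e[0] not in set(mask)],
            masked_drugs=tuple(mask),
        )
        # re-rank after masking so ranks stay 1..n
        ranked = ranker_mod.RankedList(
            model_name=ranked.model_name,
            entries=[
                (d, s, i + 1) for i, (d, s, _r) in enumerate(ranked.entries)
            ],
            masked_drugs=tuple(mask),
        )
        lists.append(ranked)
        log.info(
            "stage candidates: %s list of %d drugs",
            ranked.model_name,
            len(ranked.entries),
        )
    if not lists:
        raise ValueError("no candidate source configured")
    return lists


def _evidence_profiles(
    config: PipelineConfig, pool: pool_mod.CandidatePool
) -> tuple[list[ev.EvidenceProfile], int]:
    if config.corpus is None:
        return [
            ev.EvidenceProfile(d, 0, counts=(0, 0, 0)) for d in pool.drugs
        ], 0
    if "synthetic" in config.corpus:
        planted = [tuple(row) for row in config.corpus["synthetic"]]
        records = ev.generate_synthetic_corpus(
            planted,
            seed=config.seed,
            cap=config.abstract_cap,
            year_floor=config.year_floor,
        )
    else:
        records = ev.load_corpus(config.corpus["path"])
    records = ev.filter_corpus(
        records, year_floor=config.year_floor, cap=config.abstract_cap
    )
    judged, unjudged = ev.judge_corpus(ev.LexiconJudge(), records)
    if unjudged:
        log.info("stage evidence: %d abstracts unjudged (excluded)", unjudged)
    profiles = [
        ev.aggregate_rates(drug, judged.get(drug, [])) for drug in pool.drugs
    ]
    return profiles, len(records)


def run_pipeline(config: PipelineConfig) -> FinalReport:
    """Execute all configured stages and assemble the final report."""
    mask = _load_mask(config.mask)
    lists = _candidate_lists(config, mask)
    pool = pool_mod.union_candidates(lists)
    log.info("stage pool: %d unique drugs from %d lists", pool.size, len(lists))

    profiles, n_abstracts = _evidence_profiles(config, pool)
    threshold = Fraction(str(config.neutral_threshold))
    report = ev.stratify(pool, profiles, neutral_threshold=threshold)
    log.info(
        "stage evidence: %d judged, %d without literature (%.2f%%)",
        report.n_judged,
        report.n_insufficient,
        report.insufficient_pct,
    )

    cox_results: dict[str, cohort_mod.CoxResult] = {}
    if config.cohort is not None:
        if "synthetic" in config.cohort:
            cc = cohort_mod.CohortConfig(
                seed=config.seed, **config.cohort["synthetic"]
            )
            table = cohort_mod.generate_synthetic_cohort(cc)
        else:
            table = cohort_mod.load_cohort(config.cohort["path"])
        for drug in pool.drugs:
            cox_results[drug] = cohort_mod.fit_cox(table, drug)
        n_ok = sum(1 for r in cox_results.values() if r.status == "ok")
        log.info("stage validation: %d/%d drugs estimable", n_ok, pool.size)

    overlaps: list[cohort_mod.TrialOverlap] = []
    if config.trials is not None:
        overlaps = [
            o
            for o in cohort_mod.load_trials(config.trials)
            if o.drug_id in pool.members
        ]
    trial_tab = cohort_mod.tabulate_trials(pool, overlaps, profiles)
    trial_counts = {o.drug_id: o.trial_count for o in overlaps}
    trial_ids = {o.drug_id: ";".join(o.trial_ids) for o in overlaps}

    prof_by_drug = {p.drug_id: p for p in profiles}
    rows = []
    for drug in pool.drugs:
        prof = prof_by_drug[drug]
        if prof.has_evidence:
            rp, ru, rn = prof.rounded_rates()
            c1 = ev.apply_criterion1(prof, threshold)
            c2 = ev.apply_criterion2(prof)
        else:
            rp = ru = rn = None
            c1 = c2 = ev.INSUFFICIENT_KNOWLEDGE
        res = cox_results.get(drug)
        if res is not None and res.status == "ok":
            strict, exploratory = cohort_mod.flag_significance(res, config.alphas)
            hr, pval = res.hazard_ratio, res.p_value
        else:
            strict = exploratory = False
            hr = pval = None
        rows.append(
            {
                "drug_id": drug,
                "models": ";".join(pool.models_for(drug)),
                "T": prof.total,
                "R_p": rp,
                "R_u": ru,
                "R_n": rn,
                "criterion1": c1,
                "criterion2": c2,
                "HR": hr,
                "p": pval,
                "sig_strict": strict,
                "sig_exploratory": exploratory,
                "trial_count": trial_counts.get(drug, 0),
                "trial_ids": trial_ids.get(drug, ""),
            }
        )
    rows_df = pd.DataFrame(rows)

    summary = {
        "n_models": len(lists),
        "n_pool": pool.size,
        "n_abstracts": n_abstracts,
        "n_judged_drugs": report.n_judged,
        "n_insufficient": report.n_insufficient,
        "insufficient_pct": report.insufficient_pct,
        "criterion1_counts": dict(sorted(report.criterion1_counts.items())),
        "criterion2_counts": dict(sorted(report.criterion2_counts.items())),
        "c1_therapeutic_by_model": dict(
            sorted(report.c1_therapeutic_by_model.items())
        ),
        "trial_validation": trial_tab,
        "n_estimable_hr": sum(
            1 for r in cox_results.values() if r.status == "ok"
        ),
    }
    return FinalReport(rows=rows_df, summary=summary)


def recount_summary(report: FinalReport) -> dict:
    """Recompute the stratification counts directly from the report rows."""
    rows = report.rows
    c1 = rows["criterion1"].value_counts().to_dict()
    c2 = rows["criterion2"].value_counts().to_dict()
    return {
        "n_pool": int(len(rows)),
        "criterion1_counts": dict(sorted(c1.items())),
        "criterion2_counts": dict(sorted(c2.items())),
    }


def emit_report(report: FinalReport, outdir) -> dict[str, Path]:
    """Write report.tsv (2-decimal rates, "NA" hazard ratios) + summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rendered = report.rows.copy()
    for col in ("R_p", "R_u", "R_n"):
        rendered[col] = [
            "" if v is None or pd.isna(v) else f"{v:.2f}" for v in rendered[col]
        ]
    rendered["HR"] = [
        "NA" if v is None or pd.isna(v) else f"{v:.2f}" for v in rendered["HR"]
    ]
    rendered["p"] = [
        "NA" if v is None or pd.isna(v) else f"{v:.3g}" for v in rendered["p"]
    ]
    tsv_path = outdir / "report.tsv"
    rendered.to_csv(tsv_path, sep="\t", index=False)
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(report.summary, indent=2, sort_keys=True))
    return {"report": tsv_path, "summary": json_path}
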