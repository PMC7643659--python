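"""End-to-end orchestration of the multi-cohort target-gene workup.

``run_all`` chains validation → effect-size meta-analysis → diagnostic
meta-analysis → survival → co-expression/DE discovery → enrichment over a
cohort registry, writing plot-ready TSVs and one consolidated report.json.
``reproduce_fagan`` re-derives the printed diagnostic arithmetic (post-test
probabilities from a 20% pre-test probability and the pooled likelihood
ratios, and the log-DOR diagnostic score) with match flags.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import core, diagnostic_meta, discovery, effect_meta, enrichment
from . import survival as surv_mod

log = logging.getLogger("metaexpr")


@dataclass
class RunConfig:
    """All thresholds in one place; defaults are the published values."""

    registry: str | Path
    target_gene: str = "MAOA"
    r_min: float = 0.3
    p_max: float = 0.05
    min_ceg_votes: int = 9
    lfc_min: float = 1.0
    adjp_max: float = 0.05
    min_deg_votes: int = 8
    i2_random_rule: float = 0.50
    pretest_prob: float = 0.20
    seed: int = 0
    out_dir: str | Path = "metaexpr_out"
    survival_table: str | Path | None = None
    gmt: str | Path | None = None
    edges: str | Path | None = None
    log2_transform: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0 or not 0.0 < self.p_max <= 1.0:
            raise ValueError("correlation thresholds out of range")
        if not 0.0 < self.adjp_max <= 1.0 or self.lfc_min < 0:
            raise ValueError("DE thresholds out of range")
        if not 0.0 < self.pretest_prob < 1.0:
            raise ValueError("pretest probability must be in (0,1)")
        if self.min_ceg_votes < 1 or self.min_deg_votes < 1:
            raise ValueError("vote floors must be ≥ 1")


@dataclass
class StageTiming:
    stage: str
    seconds: float


def _meta_json(res: effect_meta.MetaResult) -> dict:
    return {
        "model": res.model,
        "pooled": res.pooled,
        "ci95": list(res.ci95),
        "Q": res.Q,
        "df": res.df,
        "p_Q": res.p_Q,
        "i2": res.i2,
        "tau2": res.tau2,
        "fixed": {"pooled": res.fixed.pooled, "ci95": list(res.fixed.ci95)},
        "random": {"pooled": res.random.pooled, "ci95": list(res.random.ci95)},
        "omitted": res.omitted,
    }


def _quantity_json(q: diagnostic_meta.PooledQuantity) -> dict:
    return {"estimate": q.estimate, "ci95": list(q.ci95)}


def run_all(config: RunConfig) -> dict:
    """Run every stage over a registry; returns (and writes) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: str(v) if isinstance(v, Path) else v
                               for k, v in asdict(config).items()
                               if k != "out_dir"},
                    "stages": {}}
    timings: list[StageTiming] = []

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings.append(StageTiming(name, time.perf_counter() - self.t0))
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done", name)
        return _Ctx()

    with stage("load_validate"):
        cohorts = core.load_cohorts(config.registry,
                                    log2_transform=config.log2_transform)
        accepted, excluded = [], []
        for c in cohorts:
            v = core.validate(c, config.target_gene)
            if v.accepted:
                accepted.append(c)
            else:
                excluded.append({"cohort_id": c.cohort_id, "reasons": v.reasons})
        report["stages"]["validate"] = {
            "n_accepted": len(accepted),
            "excluded": excluded,
        }
        if len(accepted) < 2:
            raise ValueError("fewer than 2 cohorts pass validation")

    with stage("effect_meta"):
        effects = [effect_meta.cohort_effect(c, config.target_gene)
                   for c in accepted]
        pooled = effect_meta.pool(effects)
        effect_meta.forest_table(effects, pooled).to_csv(
            out / "forest.tsv", sep="\t", index=False)
        effect_meta.funnel_points(effects).to_csv(
            out / "funnel.tsv", sep="\t", index=False)
        loo_rows = []
        if len(effects) >= 3:
            for res in effect_meta.leave_one_out(effects):
                loo_rows.append({"omitted": res.omitted, "pooled": res.pooled,
                                 "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                                 "i2": res.i2})
        pd.DataFrame(loo_rows).to_csv(out / "loo.tsv", sep="\t", index=False)
        sub = {}
        for label_name, labels in [
            ("platform", {c.cohort_id: c.platform.value for c in accepted}),
            ("ethnicity", {c.cohort_id: c.ethnicity.value for c in accepted}),
        ]:
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                sub[label_name] = {cat: _meta_json(res) for cat, res in
                                   effect_meta.subgroup_pool(effects, labels).items()}
        begg = (effect_meta.beggs_test(effects) if len(effects) >= 3
                else (float("nan"), float("nan"), True))
        meta_block = _meta_json(pooled)
        meta_block["begg"] = {"kendall_tau": begg[0], "p": begg[1],
                              "degenerate": begg[2],
                              "no_publication_bias": (not begg[2]) and begg[1] >= 0.05}
        meta_block["subgroups"] = sub
        (out / "meta.json").write_text(json.dumps(meta_block, indent=1))
        report["stages"]["effect_meta"] = meta_block

    with stage("diagnostic_meta"):
        records = [diagnostic_meta.cohort_record(c, config.target_gene)
                   for c in accepted]
        pd.DataFrame([asdict(r) for r in records]).to_csv(
            out / "records.tsv", sep="\t", index=False)
        dx_block: dict = {"records": [asdict(r) for r in records]}
        if len(records) >= 3:
            dx = diagnostic_meta.pool_diagnostics(records)
            dx.sroc_curve.to_csv(out / "sroc_curve.tsv", sep="\t", index=False)
            fag = diagnostic_meta.fagan(config.pretest_prob,
                                        dx.dlr_pos.estimate,
                                        dx.dlr_neg.estimate)
            dx_block["pooled"] = {
                "sens": _quantity_json(dx.sens),
                "spec": _quantity_json(dx.spec),
                "dlr_pos": _quantity_json(dx.dlr_pos),
                "dlr_neg": _quantity_json(dx.dlr_neg),
                "dor": _quantity_json(dx.dor),
                "diag_score": _quantity_json(dx.diag_score),
                "sroc_auc": dx.sroc_auc,
            }
            dx_block["fagan"] = asdict(fag)
            (out / "pooled.json").write_text(json.dumps(
                {k: dx_block[k] for k in ("pooled", "fagan")}, indent=1))
        report["stages"]["diagnostic_meta"] = dx_block

    with stage("survival"):
        if config.survival_table is not None:
            table = surv_mod.SurvivalTable.read(config.survival_table)
            res = surv_mod.analyze(table)
            res.km_high.to_csv(out / "km_high.tsv", sep="\t", index=False)
            res.km_low.to_csv(out / "km_low.tsv", sep="\t", index=False)
            lr = res.logrank
            block = {"chi2": lr.chi2, "p": lr.p, "hr": lr.hr,
                     "ci95": list(lr.ci95), "n_high": res.n_high,
                     "n_low": res.n_low}
            (out / "logrank.json").write_text(json.dumps(block, indent=1))
            report["stages"]["survival"] = block
        else:
            report["stages"]["survival"] = {"skipped": "no survival table"}

    with stage("discovery"):
        corr_records: list[discovery.CorrelationRecord] = []
        de_records: list[discovery.DERecord] = []
        for c in accepted:
            corr_records.extend(discovery.correlate_target(c, config.target_gene))
            de_records.extend(discovery.de_per_dataset(c))
        pos, neg, ceg_table = discovery.ceg_votes(
            corr_records, r_min=config.r_min, p_max=config.p_max,
            min_votes=config.min_ceg_votes)
        up, down, deg_table = discovery.deg_votes(
            de_records, lfc_min=config.lfc_min, adjp_max=config.adjp_max,
            min_votes=config.min_deg_votes)
        set_a, set_b = discovery.intersect(pos, neg, up, down)
        votes = discovery.merge_vote_tables(ceg_table, deg_table)
        votes.to_csv(out / "votes.tsv", sep="\t")
        for name, genes in [("cegs_pos", pos), ("cegs_neg", neg),
                            ("degs_up", up), ("degs_down", down)]:
            (out / f"{name}.txt").write_text("\n".join(genes) + "\n")
        inter = {"pos_ceg_down_deg": set_a, "neg_ceg_up_deg": set_b}
        (out / "intersections.json").write_text(json.dumps(inter, indent=1))
        universe = sorted(votes.index)
        report["stages"]["discovery"] = {
            "n_pos_cegs": len(pos), "n_neg_cegs": len(neg),
            "n_up_degs": len(up), "n_down_degs": len(down),
            "intersections": inter,
        }

    with stage("enrichment"):
        block = {}
        if config.gmt is not None and set_a:
            collection = core.read_gmt(config.gmt)
            results = enrichment.hypergeom_enrich(set_a, collection, universe)
            pd.DataFrame([{**asdict(r),
                           "overlap_genes": ",".join(r.overlap_genes)}
                          for r in results]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)
            block["top_sets"] = [{"set_id": r.set_id, "p": r.p, "q": r.q,
                                  "overlap": r.overlap}
                                 for r in results[:10]]
        if config.edges is not None and set_a:
            edge_list = core.read_edges(config.edges)
            hubs = enrichment.hub_gene(set_a, edge_list)
            pd.DataFrame([asdict(h) for h in hubs]).to_csv(
                out / "hubs.tsv", sep="\t", index=False)
            block["hub"] = hubs[0].gene if hubs else None
        report["stages"]["enrichment"] = block or {"skipped": "no GMT/edges"}

    with stage("reproduce_fagan"):
        report["stages"]["reproduce_fagan"] = reproduce_fagan()

    report["timings"] = [asdict(t) for t in timings]
    body = {k: v for k, v in report.items() if k != "timings"}
    (out / "report.json").write_text(json.dumps(body, indent=1, sort_keys=True))
    return report


#: Published pooled diagnostic statistics the arithmetic check starts from:
#: positive/negative likelihood ratios, diagnostic odds ratio with its 95% CI,
#: and a 20% pre-test probability.
PUBLISHED_DX = {
    "dlr_pos": 3.74,
    "dlr_neg": 0.51,
    "dor": 7.26,
    "dor_ci": (5.64, 9.34),
    "pretest": 0.20,
    "posttest_pos_pct": 48,
    "posttest_neg_pct": 11,
    "diag_score": 1.98,
    "diag_score_ci": (1.73, 2.23),
}


def reproduce_fagan() -> dict:
    """Re-derive the published diagnostic arithmetic, with match flags.

    Post-test probabilities follow from the Bayes odds update of the 20%
    pre-test probability with the pooled likelihood ratios; the diagnostic
    score is the natural log of the pooled DOR (and of its CI bounds).
    """
    p = PUBLISHED_DX
    fag = diagnostic_meta.fagan(p["pretest"], p["dlr_pos"], p["dlr_neg"])
    score = diagnostic_meta.diagnostic_score(p["dor"])
    score_ci = tuple(diagnostic_meta.diagnostic_score(x) for x in p["dor_ci"])
    rows = [
        {"quantity": "posttest_pos_pct",
         "computed": round(100 * fag.posttest_pos),
         "published": p["posttest_pos_pct"]},
        {"quantity": "posttest_neg_pct",
         "computed": round(100 * fag.posttest_neg),
         "published": p["posttest_neg_pct"]},
        {"quantity": "diag_score", "computed": round(score, 2),
         "published": p["diag_score"]},
        {"quantity": "diag_score_ci_lo", "computed": round(score_ci[0], 2),
         "published": p["diag_score_ci"][0]},
        {"quantity": "diag_score_ci_hi", "computed": round(score_ci[1], 2),
         "published": p["diag_score_ci"][1]},
    ]
    for row in rows:
        row["match"] = bool(row["computed"] == row["published"])
    return {"rows": rows, "all_match": all(r["match"] for r in rows)}
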