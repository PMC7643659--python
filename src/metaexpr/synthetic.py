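"""Synthetic multi-cohort fixtures with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real data: K independent cohorts sharing a target gene whose cohort-level
standardized mean difference δ_i is drawn from Normal(true_smd, τ²);
background genes i.i.d. Normal with gene-specific means and SDs shared
across cohorts; planted co-expressed genes built from a single latent factor
(the standardized target) so one loading parameter controls every planted
correlation; planted differentially expressed genes with a fixed case shift
on the log2 scale; and an exponential proportional-hazards survival cohort
dichotomized by the marker median.

Planted CEGs inherit the target's case/control shift through the latent
factor and additionally receive the explicit ±deg_log2fc case shift
(``couple_ceg_deg``), mirroring the empirical observation that genes
positively co-expressed with a downregulated target are themselves
downregulated. The truth object therefore reports those CEGs as DEGs too,
making the planted cross-screen intersections exactly the CEG lists.

All randomness flows from one integer seed; identical seeds give
bit-identical output. Cohort i uses the substream seeded ``seed + 1 + i``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (EdgeList, ExpressionCohort, GeneSetCollection,
                   write_expression, write_gmt)
from .survival import SurvivalTable

#: Baseline hazard, events per month. 0.03 puts median survival near two
#: years, the scale of the liver-cancer cohorts the pipeline targets.
BASELINE_HAZARD = 0.03


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated multi-cohort experiment.

    Defaults describe a desk-scale study: a dozen cohorts of 30 cases /
    30 controls, a downregulated target (Hedges-g scale SMD −0.5 with
    between-cohort SD τ = 0.2), planted co-expression at loading 0.7, DEGs
    shifted by 1.5 log2 units, and a 300-patient survival cohort with a
    twofold hazard ratio and 20% censoring. A much stronger target SMD makes
    the pooled-sample correlation screen pick up the explicitly planted DEGs
    as well (the case/control split then dominates every pairwise
    correlation), which is realistic but blurs the planted class boundaries.
    """

    n_cohorts: int = 12
    n_case: int | list[int] = 30
    n_control: int | list[int] = 30
    n_genes: int = 200
    target_gene: str = "MAOA"
    true_smd: float = -0.5
    tau: float = 0.2
    n_pos_ceg: int = 15
    n_neg_ceg: int = 10
    ceg_loading: float = 0.7
    n_up_deg: int = 15
    n_down_deg: int = 15
    deg_log2fc: float = 1.5
    survival_n: int = 300
    survival_beta: float = math.log(2.0)
    censor_rate: float = 0.2
    seed: int = 0
    couple_ceg_deg: bool = True

    def per_cohort(self, value: int | list[int]) -> list[int]:
        if isinstance(value, int):
            return [value] * self.n_cohorts
        if len(value) != self.n_cohorts:
            raise ValueError("per-cohort size list must have n_cohorts entries")
        return list(value)

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or self.n_genes < 2 or self.survival_n < 4:
            raise ValueError("counts must be positive (and n_genes ≥ 2)")
        if not 0.0 < self.ceg_loading < 1.0:
            raise ValueError("ceg_loading must lie in (0,1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0,1)")
        planted = self.n_pos_ceg + self.n_neg_ceg + self.n_up_deg + self.n_down_deg
        if planted + 1 > self.n_genes:
            raise ValueError("planted gene classes overlap: too few genes "
                             "for disjoint assignment")


@dataclass
class SyntheticTruth:
    """The planted parameters downstream recovery is tested against."""

    target_gene: str
    cohort_smds: list[float]
    pos_cegs: list[str]
    neg_cegs: list[str]
    up_degs: list[str]
    down_degs: list[str]
    background: list[str]
    all_genes: list[str]
    survival_hr: float

    def intersections(self) -> tuple[list[str], list[str]]:
        """Planted pos-CEG∩down-DEG and neg-CEG∩up-DEG gene lists."""
        set_a = sorted(set(self.pos_cegs) & set(self.down_degs))
        set_b = sorted(set(self.neg_cegs) & set(self.up_degs))
        return set_a, set_b

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _gene_names(config: SyntheticConfig) -> dict[str, list[str]]:
    width = len(str(config.n_genes))
    others = [f"G{i:0{width}d}" for i in range(1, config.n_genes)]
    i = 0
    out = {"target": [config.target_gene]}
    for name, count in [("pos_ceg", config.n_pos_ceg),
                        ("neg_ceg", config.n_neg_ceg),
                        ("up_deg", config.n_up_deg),
                        ("down_deg", config.n_down_deg)]:
        out[name] = others[i:i + count]
        i += count
    out["background"] = others[i:]
    return out


def generate(config: SyntheticConfig) -> tuple[list[ExpressionCohort], SurvivalTable, SyntheticTruth]:
    """Draw the full multi-cohort fixture set for one configuration."""
    master = np.random.default_rng(config.seed)
    names = _gene_names(config)
    genes = (names["target"] + names["pos_ceg"] + names["neg_ceg"]
             + names["up_deg"] + names["down_deg"] + names["background"])
    gene_pos = {g: i for i, g in enumerate(genes)}

    # Gene-level means and SDs are shared across cohorts: heterogeneity
    # enters only through the target gene's per-cohort effect δ_i.
    mu = master.uniform(4.0, 12.0, size=config.n_genes)
    sigma = master.uniform(0.5, 1.5, size=config.n_genes)
    deltas = master.normal(config.true_smd, config.tau, size=config.n_cohorts)

    n_cases = config.per_cohort(config.n_case)
    n_controls = config.per_cohort(config.n_control)
    sign = 0.0 if config.true_smd == 0 else math.copysign(1.0, config.true_smd)
    couple = config.couple_ceg_deg and sign != 0.0

    cohorts = []
    for i in range(config.n_cohorts):
        rng = np.random.default_rng(config.seed + 1 + i)
        n1, n0 = n_cases[i], n_controls[i]
        n = n1 + n0
        case_mask = np.zeros(n, dtype=bool)
        case_mask[:n1] = True

        values = mu[:, None] + sigma[:, None] * rng.standard_normal((config.n_genes, n))

        # Target: case mean shifted by δ_i on the σ_t scale.
        ti = gene_pos[config.target_gene]
        values[ti, case_mask] += deltas[i] * sigma[ti]

        # Planted CEGs: latent-factor construction off the standardized target.
        target_row = values[ti]
        z_t = (target_row - target_row.mean()) / target_row.std()
        for gene_list, rho in [(names["pos_ceg"], config.ceg_loading),
                               (names["neg_ceg"], -config.ceg_loading)]:
            for g in gene_list:
                gi = gene_pos[g]
                eps = rng.standard_normal(n)
                x = rho * z_t + math.sqrt(1.0 - rho**2) * eps
                values[gi] = mu[gi] + sigma[gi] * x
                if couple:
                    shift = sign * config.deg_log2fc if rho > 0 else -sign * config.deg_log2fc
                    values[gi, case_mask] += shift

        # Planted DEGs: explicit case shift.
        for gene_list, shift in [(names["up_deg"], config.deg_log2fc),
                                 (names["down_deg"], -config.deg_log2fc)]:
            for g in gene_list:
                values[gene_pos[g], case_mask] += shift

        cid = f"SYN{i + 1:02d}"
        sample_ids = [f"{cid}_S{j + 1:03d}" for j in range(n)]
        group = pd.Series(np.where(case_mask, "case", "control"), index=sample_ids)
        cohorts.append(ExpressionCohort(
            cohort_id=cid,
            values=pd.DataFrame(values, index=genes, columns=sample_ids),
            group=group,
            platform="rnaseq" if i % 2 else "genechip",
            ethnicity="asian" if i % 2 else "non_asian",
        ))

    surv = _generate_survival(config)

    down = list(names["down_deg"])
    up = list(names["up_deg"])
    if couple:
        if sign < 0:
            down = sorted(down + names["pos_ceg"])
            up = sorted(up + names["neg_ceg"])
        else:
            up = sorted(up + names["pos_ceg"])
            down = sorted(down + names["neg_ceg"])
    truth = SyntheticTruth(
        target_gene=config.target_gene,
        cohort_smds=[float(d) for d in deltas],
        pos_cegs=list(names["pos_ceg"]),
        neg_cegs=list(names["neg_ceg"]),
        up_degs=up,
        down_degs=down,
        background=list(names["background"]),
        all_genes=genes,
        survival_hr=math.exp(config.survival_beta),
    )
    return cohorts, surv, truth


def _generate_survival(config: SyntheticConfig) -> SurvivalTable:
    """Exponential proportional-hazards cohort dichotomized at the median.

    T ~ Exp(h0·exp(β·1[marker ≥ median])); each subject is censored with
    probability censor_rate, at a uniform time before its event.
    """
    rng = np.random.default_rng(config.seed + 1 + config.n_cohorts)
    n = config.survival_n
    marker = rng.normal(8.0, 1.0, size=n)
    med = float(np.sort(marker)[(n - 1) // 2])  # lower-middle median
    high = marker >= med
    rate = BASELINE_HAZARD * np.exp(config.survival_beta * high)
    times = rng.exponential(1.0 / rate)
    censored = rng.random(n) < config.censor_rate
    obs = np.where(censored, rng.uniform(0.0, times), times)
    obs = np.maximum(obs, 1e-6)
    return SurvivalTable(pd.DataFrame({
        "sample_id": [f"P{j + 1:04d}" for j in range(n)],
        "time": obs,
        "event": (~censored).astype(int),
        "marker": marker,
    }))


def emit_gene_sets(truth: SyntheticTruth, n_decoy_sets: int,
                   seed: int, noise_fraction: float = 0.3) -> GeneSetCollection:
    """One truly-enriched set plus size-matched decoys drawn from background.

    The true set is the planted pos-CEG∩down-DEG intersection padded with
    ``noise_fraction`` extra background genes; decoys are uniform background
    draws of the same size, so only the true set should enrich against a
    query recovering the planted intersection.
    """
    rng = np.random.default_rng(seed)
    set_a, _ = truth.intersections()
    if not set_a:
        raise ValueError("truth has an empty planted intersection")
    n_noise = int(round(noise_fraction * len(set_a)))
    background = list(truth.background)
    noise = list(rng.choice(background, size=min(n_noise, len(background)),
                            replace=False))
    size = len(set_a) + len(noise)
    sets = {"PLANTED": ("planted intersection set", sorted(set_a) + sorted(noise))}
    for d in range(n_decoy_sets):
        members = rng.choice(background, size=min(size, len(background)),
                             replace=False)
        sets[f"DECOY{d + 1:03d}"] = ("background decoy set", sorted(members))
    return GeneSetCollection(sets=sets, universe=list(truth.all_genes))


def emit_edges(truth: SyntheticTruth, seed: int,
               n_background_edges: int = 50) -> tuple[EdgeList, str]:
    """A star interaction network with one planted hub plus background edges.

    Returns the edge list and the planted hub gene (the alphabetically first
    member of the planted intersection, wired to every other member).
    """
    rng = np.random.default_rng(seed)
    set_a, _ = truth.intersections()
    if len(set_a) < 2:
        raise ValueError("planted intersection too small for a hub network")
    hub = sorted(set_a)[0]
    pairs = [(hub, g) for g in set_a if g != hub]
    pool = list(truth.background)
    for _ in range(n_background_edges):
        a, b = rng.choice(pool, size=2, replace=False)
        pairs.append((str(a), str(b)))
    return EdgeList.from_pairs(pairs), hub


def write_simulation(config: SyntheticConfig, out_dir: str | Path,
                     n_decoy_sets: int = 20) -> dict:
    """Materialize a full simulated study on disk.

    Writes per-cohort matrix/phenotype TSVs, registry.json, survival.tsv,
    sets.gmt, edges.tsv and truth.json; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts, surv, truth = generate(config)
    registry = []
    for cohort in cohorts:
        m = out / f"{cohort.cohort_id}_matrix.tsv"
        p = out / f"{cohort.cohort_id}_phenotype.tsv"
        write_expression(cohort, m, p)
        registry.append({
            "cohort_id": cohort.cohort_id,
            "matrix": m.name,
            "phenotype": p.name,
            "platform": cohort.platform.value,
            "ethnicity": cohort.ethnicity.value,
        })
    (out / "registry.json").write_text(json.dumps(registry, indent=1))
    surv.write(out / "survival.tsv")
    collection = emit_gene_sets(truth, n_decoy_sets=n_decoy_sets,
                                seed=config.seed + 10_000)
    write_gmt(collection, out / "sets.gmt")
    edges, hub = emit_edges(truth, seed=config.seed + 20_000)
    with open(out / "edges.tsv", "w") as fh:
        for edge in sorted(tuple(sorted(e)) for e in edges.edges):
            fh.write(f"{edge[0]}\t{edge[1]}\n")
    payload = asdict(truth)
    payload["planted_hub"] = hub
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
    return {
        "registry": out / "registry.json",
        "survival": out / "survival.tsv",
        "gmt": out / "sets.gmt",
        "edges": out / "edges.tsv",
        "truth": out / "truth.json",
    }
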