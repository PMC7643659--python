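"""Cross-cohort co-expression and differential-expression screens.

A gene is a co-expressed gene (CEG) of the target when, in at least
``min_votes`` cohorts, its Pearson correlation with the target clears
|r| > 0.3 at p < .05 (strict inequalities, same sign each time). A gene is a
differentially expressed gene (DEG) when |log2FC| > 1 at BH-adjusted p < .05
in at least ``min_votes`` cohorts, same direction. The positively related
CEGs are intersected with the downregulated DEGs (and negative with up) —
the vote-counting screen that replaces a single pooled test across
heterogeneous platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionCohort, _clean_symbol


@dataclass(frozen=True)
class CorrelationRecord:
    gene: str
    cohort_id: str
    r: float
    p: float
    constant: bool = False


@dataclass(frozen=True)
class DERecord:
    gene: str
    cohort_id: str
    log2fc: float
    p: float
    adj_p: float


@dataclass
class VoteTable:
    """Per-gene cross-cohort vote counts."""

    counts: pd.DataFrame  # index gene; columns n_pos, n_neg, n_up, n_down, n_cohorts_tested


def correlate_target(cohort: ExpressionCohort, target: str) -> list[CorrelationRecord]:
    """Pearson r of every other gene with the target over all samples.

    p from the t transform t = r·sqrt((n−2)/(1−r²)) with n−2 df, two-sided.
    Constant genes (or a constant target) get r=0, p=1, flagged.
    """
    target = _clean_symbol(target)
    if target not in set(cohort.values.index):
        raise ValueError(f"target {target} absent from cohort {cohort.cohort_id}")
    x = cohort.values.values.astype(float)
    n = x.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for the correlation screen")
    t_row = cohort.values.loc[target].values.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t_row - t_row.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    st = np.sqrt((tc**2).sum())
    constant = (sx == 0) | (st == 0)
    denom = np.where(constant, 1.0, sx * st)
    r = np.clip((xc @ tc) / denom, -1.0, 1.0)
    r = np.where(constant, 0.0, r)
    with np.errstate(divide="ignore", over="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(constant, 1.0, np.minimum(p, 1.0))
    records = []
    for gene, ri, pi, ci in zip(cohort.values.index, r, p, constant):
        if gene == target:
            continue
        records.append(CorrelationRecord(gene=gene, cohort_id=cohort.cohort_id,
                                         r=float(ri), p=float(pi), constant=bool(ci)))
    return records


def de_per_dataset(cohort: ExpressionCohort) -> list[DERecord]:
    """Per-gene case-vs-control Welch t-test with BH adjustment in-cohort.

    log2FC = mean(case) − mean(control) (matrices are log2 scale, so the
    mean difference is the log fold change). Genes with zero variance in
    both groups and equal means get p = 1.
    """
    if cohort.n_case < 3 or cohort.n_control < 3:
        raise ValueError("need at least 3 samples per group")
    mask = cohort.case_mask()
    case = cohort.values.values[:, mask].astype(float)
    control = cohort.values.values[:, ~mask].astype(float)
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)  # zero variance, different means
    adj_p = multipletests(p, method="fdr_bh")[1]
    return [
        DERecord(gene=g, cohort_id=cohort.cohort_id, log2fc=float(fc),
                 p=float(pi), adj_p=float(qi))
        for g, fc, pi, qi in zip(cohort.values.index, log2fc, p, adj_p)
    ]


def _count_votes(df: pd.DataFrame, pos_flag: str, neg_flag: str,
                 all_cols: list[str]) -> pd.DataFrame:
    agg = df.groupby("gene").agg(**{
        pos_flag: (pos_flag, "sum"),
        neg_flag: (neg_flag, "sum"),
        "n_cohorts_tested": ("gene", "size"),
    })
    counts = pd.DataFrame(0, index=agg.index.sort_values(), columns=all_cols)
    for col in (pos_flag, neg_flag, "n_cohorts_tested"):
        counts[col] = agg[col].astype(int)
    return counts


_VOTE_COLS = ["n_pos", "n_neg", "n_up", "n_down", "n_cohorts_tested"]


def ceg_votes(records: list[CorrelationRecord], r_min: float = 0.3,
              p_max: float = 0.05,
              min_votes: int = 9) -> tuple[list[str], list[str], VoteTable]:
    """Count qualifying-correlation votes per gene and call CEG membership.

    Strict inequalities throughout (r > r_min, p < p_max); opposite-direction
    votes are counted separately, never cancelled. Membership requires
    ``min_votes`` same-direction votes (an absolute floor, not a fraction).
    """
    df = pd.DataFrame({
        "gene": [r.gene for r in records],
        "n_pos": [(r.p < p_max) and (r.r > r_min) for r in records],
        "n_neg": [(r.p < p_max) and (r.r < -r_min) for r in records],
    })
    counts = _count_votes(df, "n_pos", "n_neg", _VOTE_COLS)
    pos = sorted(counts.index[counts["n_pos"] >= min_votes])
    neg = sorted(counts.index[counts["n_neg"] >= min_votes])
    return pos, neg, VoteTable(counts=counts)


def deg_votes(records: list[DERecord], lfc_min: float = 1.0,
              adjp_max: float = 0.05,
              min_votes: int = 8) -> tuple[list[str], list[str], VoteTable]:
    """Count qualifying-DE votes per gene and call up/down DEG membership."""
    df = pd.DataFrame({
        "gene": [r.gene for r in records],
        "n_up": [(r.adj_p < adjp_max) and (r.log2fc > lfc_min) for r in records],
        "n_down": [(r.adj_p < adjp_max) and (r.log2fc < -lfc_min) for r in records],
    })
    counts = _count_votes(df, "n_up", "n_down", _VOTE_COLS)
    up = sorted(counts.index[counts["n_up"] >= min_votes])
    down = sorted(counts.index[counts["n_down"] >= min_votes])
    return up, down, VoteTable(counts=counts)


def intersect(pos_cegs, neg_cegs, up_degs, down_degs) -> tuple[list[str], list[str]]:
    """The two cross-screen intersections: pos-CEG∩down-DEG, neg-CEG∩up-DEG."""
    set_a = sorted(set(pos_cegs) & set(down_degs))
    set_b = sorted(set(neg_cegs) & set(up_degs))
    return set_a, set_b


def merge_vote_tables(ceg: VoteTable, deg: VoteTable) -> pd.DataFrame:
    """One combined per-gene vote table for reporting."""
    c = ceg.counts[["n_pos", "n_neg"]]
    d = deg.counts[["n_up", "n_down"]]
    n = ceg.counts[["n_cohorts_tested"]].combine_first(
        deg.counts[["n_cohorts_tested"]])
    return c.join(d, how="outer").join(n, how="outer").fillna(0).astype(int)
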