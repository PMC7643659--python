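"""Diagnostic-accuracy meta-analysis for a single continuous marker.

Each cohort's marker expression is scored as a diagnostic test: AUC by the
Mann–Whitney statistic (orientation auto-flipped so a downregulated marker is
handled like an upregulated one), a 2×2 table at the Youden-optimal cutoff,
then DerSimonian–Laird pooling on the logit/log scales for sensitivity,
specificity, likelihood ratios and the diagnostic odds ratio, a
Moses–Littenberg summary ROC, and Fagan (Bayes odds) post-test probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionCohort, validate
from .effect_meta import EffectSize, pool

Z95 = 1.96


@dataclass(frozen=True)
class DiagnosticRecord:
    """One cohort's ROC summary and confusion table at the chosen cutoff."""

    cohort_id: str
    auc: float
    se_auc: float
    p_auc: float
    orientation: str  # "low_positive" | "high_positive"
    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sens(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def spec(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class PooledQuantity:
    estimate: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class DiagnosticPool:
    sens: PooledQuantity
    spec: PooledQuantity
    dlr_pos: PooledQuantity
    dlr_neg: PooledQuantity
    dor: PooledQuantity
    diag_score: PooledQuantity
    sroc_auc: float
    sroc_curve: pd.DataFrame  # columns fpr, tpr
    sroc_intercept: float
    sroc_slope: float
    degenerate_sroc: bool


@dataclass(frozen=True)
class FaganResult:
    pretest_prob: float
    posttest_pos: float
    posttest_neg: float


def auc_mann_whitney(case_values, control_values) -> tuple[float, float, float, str]:
    """AUC via the Mann–Whitney statistic with ties counted ½.

    Returns (auc, se, p, orientation). Raw AUC = P(case > control); if it
    falls below 0.5 the marker is treated as low-positive and 1−AUC reported,
    so the reported AUC is always ≥ 0.5. SE by Hanley–McNeil; p is a
    two-sided normal test of AUC against 0.5.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    n1, n0 = len(case), len(control)
    if n1 < 3 or n0 < 3:
        raise ValueError("need at least 3 values per group")
    u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
    auc = float(u) / (n1 * n0)
    orientation = "high_positive"
    if auc < 0.5:
        auc = 1.0 - auc
        orientation = "low_positive"
    if np.ptp(np.concatenate([case, control])) == 0:
        return 0.5, float("nan"), 1.0, orientation
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    if se == 0:
        p = 0.0 if a > 0.5 else 1.0
    else:
        p = 2.0 * stats.norm.sf(abs(a - 0.5) / se)
    return a, se, min(p, 1.0), orientation


def youden_cutoff(case_values, control_values,
                  orientation: str) -> tuple[float, float, float, int, int, int, int]:
    """Choose the cutoff maximizing Youden J = sens + spec − 1.

    Candidate cutoffs are midpoints of adjacent sorted unique values; a
    sample is test-positive when its value is ≤ cutoff (low_positive) or
    ≥ cutoff (high_positive). Ties on J break toward higher sensitivity,
    then toward the cutoff further from the case mean.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    uniq = np.unique(np.concatenate([case, control]))
    if len(uniq) == 1:
        c = float(uniq[0])
        tp, fn = len(case), 0
        fp, tn = len(control), 0
        return c, 1.0, 0.0, tp, fp, fn, tn
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    case_mean = case.mean()
    best = None
    for c in mids:
        if orientation == "low_positive":
            tp = int((case <= c).sum())
            fp = int((control <= c).sum())
        else:
            tp = int((case >= c).sum())
            fp = int((control >= c).sum())
        fn, tn = len(case) - tp, len(control) - fp
        sens, spec = tp / len(case), tn / len(control)
        j = sens + spec - 1.0
        key = (j, sens, abs(c - case_mean))
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec, tp, fp, fn, tn))
    return best[1]


def cohort_record(cohort: ExpressionCohort, target_gene: str) -> DiagnosticRecord:
    """Full per-cohort diagnostic summary for the target gene."""
    result = validate(cohort, target_gene)
    if not result.accepted:
        raise ValueError(f"cohort {cohort.cohort_id} rejected: {result.reasons}")
    case = cohort.case_values(target_gene)
    control = cohort.control_values(target_gene)
    auc, se, p, orientation = auc_mann_whitney(case, control)
    cutoff, sens, spec, tp, fp, fn, tn = youden_cutoff(case, control, orientation)
    return DiagnosticRecord(cohort_id=cohort.cohort_id, auc=auc, se_auc=se,
                            p_auc=p, orientation=orientation, cutoff=cutoff,
                            tp=tp, fp=fp, fn=fn, tn=tn)


def roc_points(case_values, control_values, orientation: str) -> pd.DataFrame:
    """Plot-ready (fpr, tpr) per candidate cutoff for one cohort."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    uniq = np.unique(np.concatenate([case, control]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    rows = []
    for c in mids:
        if orientation == "low_positive":
            tpr = (case <= c).mean()
            fpr = (control <= c).mean()
        else:
            tpr = (case >= c).mean()
            fpr = (control >= c).mean()
        rows.append({"cutoff": float(c), "fpr": float(fpr), "tpr": float(tpr)})
    return pd.DataFrame(rows)


def _cells(rec: DiagnosticRecord) -> tuple[float, float, float, float]:
    """2×2 cells, +0.5 added to every cell of a zero-containing table."""
    cells = (rec.tp, rec.fp, rec.fn, rec.tn)
    if 0 in cells:
        return tuple(c + 0.5 for c in cells)
    return tuple(float(c) for c in cells)


def _dl_pool(values: list[float], variances: list[float]) -> PooledQuantity:
    """DL random-effects pooling of transformed per-study quantities."""
    effects = [EffectSize(cohort_id=str(i), g=v, var_g=var)
               for i, (v, var) in enumerate(zip(values, variances))]
    res = pool(effects)
    fit = res.random
    return PooledQuantity(estimate=fit.pooled, ci95=fit.ci95)


def _expit_q(q: PooledQuantity) -> PooledQuantity:
    lo, hi = q.ci95
    inv = lambda x: 1.0 / (1.0 + math.exp(-x))
    return PooledQuantity(estimate=inv(q.estimate), ci95=(inv(lo), inv(hi)))


def _exp_q(q: PooledQuantity) -> PooledQuantity:
    lo, hi = q.ci95
    return PooledQuantity(estimate=math.exp(q.estimate),
                          ci95=(math.exp(lo), math.exp(hi)))


def pool_diagnostics(records: list[DiagnosticRecord],
                     sroc_grid: int = 2001) -> DiagnosticPool:
    """Pool per-cohort 2×2 tables into summary diagnostic-accuracy measures.

    Sensitivity and specificity are pooled by DL random effects on the logit
    scale; ln DLR+, ln DLR− and ln DOR each on the log scale; the diagnostic
    score is the pooled ln DOR and DOR = exp(score). The summary ROC follows
    Moses–Littenberg: least-squares fit of D = ln DOR against the threshold
    proxy S = logit(sens) + logit(1−spec), traced over fpr ∈ (0,1) and
    integrated by the trapezoid rule.
    """
    if len(records) < 3:
        raise ValueError("pooling requires at least 3 cohorts")
    logit_sens, v_sens = [], []
    logit_spec, v_spec = [], []
    ln_lrp, v_lrp = [], []
    ln_lrn, v_lrn = [], []
    ln_dor, v_dor = [], []
    d_vals, s_vals = [], []
    for rec in records:
        tp, fp, fn, tn = _cells(rec)
        n1, n0 = tp + fn, fp + tn
        sens, spec = tp / n1, tn / n0
        logit_sens.append(math.log(tp / fn))
        v_sens.append(1.0 / tp + 1.0 / fn)
        logit_spec.append(math.log(tn / fp))
        v_spec.append(1.0 / tn + 1.0 / fp)
        ln_lrp.append(math.log((tp / n1) / (fp / n0)))
        v_lrp.append(1.0 / tp - 1.0 / n1 + 1.0 / fp - 1.0 / n0)
        ln_lrn.append(math.log((fn / n1) / (tn / n0)))
        v_lrn.append(1.0 / fn - 1.0 / n1 + 1.0 / tn - 1.0 / n0)
        ln_dor.append(math.log((tp * tn) / (fp * fn)))
        v_dor.append(1.0 / tp + 1.0 / fp + 1.0 / fn + 1.0 / tn)
        d_vals.append(ln_dor[-1])
        s_vals.append(math.log(sens / (1 - sens)) + math.log((1 - spec) / spec))

    sens_q = _expit_q(_dl_pool(logit_sens, v_sens))
    spec_q = _expit_q(_dl_pool(logit_spec, v_spec))
    lrp_q = _exp_q(_dl_pool(ln_lrp, v_lrp))
    lrn_q = _exp_q(_dl_pool(ln_lrn, v_lrn))
    score_q = _dl_pool(ln_dor, v_dor)
    dor_q = _exp_q(score_q)

    d = np.array(d_vals)
    s = np.array(s_vals)
    degenerate = bool(np.allclose(s, s[0]))
    if degenerate:
        b = 0.0
        a = float(d.mean())
    else:
        b, a = np.polyfit(s, d, 1)  # slope, intercept
        b, a = float(b), float(a)
    curve = sroc_curve(a, b, n=sroc_grid)
    auc = float(np.trapezoid(curve["tpr"].values, curve["fpr"].values))
    return DiagnosticPool(sens=sens_q, spec=spec_q, dlr_pos=lrp_q,
                          dlr_neg=lrn_q, dor=dor_q, diag_score=score_q,
                          sroc_auc=auc, sroc_curve=curve,
                          sroc_intercept=a, sroc_slope=b,
                          degenerate_sroc=degenerate)


def sroc_curve(a: float, b: float, n: int = 2001) -> pd.DataFrame:
    """Trace tpr(fpr) from the fitted Moses–Littenberg line D = a + b·S.

    With D = logit(tpr) − logit(fpr) and S = logit(tpr) + logit(fpr):
    logit(tpr) = (a + (1+b)·logit(fpr)) / (1 − b). Endpoints are clamped to
    (0,0) and (1,1).
    """
    if abs(1.0 - b) < 1e-9:
        raise ValueError("degenerate summary line (slope ≈ 1)")
    fpr = np.linspace(0.0, 1.0, n)
    inner = fpr[1:-1]
    logit_fpr = np.log(inner / (1.0 - inner))
    logit_tpr = (a + (1.0 + b) * logit_fpr) / (1.0 - b)
    tpr = 1.0 / (1.0 + np.exp(-logit_tpr))
    tpr_full = np.concatenate([[0.0], np.clip(tpr, 0.0, 1.0), [1.0]])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr_full})


def diagnostic_score(dor: float) -> float:
    """The diagnostic score is the natural log of the diagnostic odds ratio."""
    if dor <= 0:
        raise ValueError("DOR must be positive")
    return math.log(dor)


def fagan(pretest_prob: float, dlr_pos: float, dlr_neg: float) -> FaganResult:
    """Bayes odds update: post-test probabilities for ± test results."""
    if not 0.0 < pretest_prob < 1.0:
        raise ValueError("pretest probability must be in (0,1)")
    if dlr_pos <= 0 or dlr_neg <= 0:
        raise ValueError("likelihood ratios must be positive")
    odds = pretest_prob / (1.0 - pretest_prob)
    pos_odds = odds * dlr_pos
    neg_odds = odds * dlr_neg
    return FaganResult(
        pretest_prob=pretest_prob,
        posttest_pos=pos_odds / (1.0 + pos_odds),
        posttest_neg=neg_odds / (1.0 + neg_odds),
    )
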