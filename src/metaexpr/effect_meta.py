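"""Standardized-mean-difference meta-analysis.

Per-cohort effects are Hedges g (small-sample-corrected SMD, case minus
control over the pooled SD). Pooling follows the classical inverse-variance
fixed-effect model plus the DerSimonian–Laird method-of-moments random-effects
model; Cochran's Q, I² and τ² quantify between-cohort heterogeneity, and the
I² > 0.50 rule selects the reported model. Publication-bias screening uses
the Begg–Mazumdar rank-correlation test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionCohort, GroupStats, group_stats, validate

Z95 = 1.96  # conventional two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectSize:
    """Hedges g for one cohort with its large-sample variance."""

    cohort_id: str
    g: float
    var_g: float

    @property
    def se_g(self) -> float:
        return math.sqrt(self.var_g)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.g - Z95 * self.se_g, self.g + Z95 * self.se_g)


@dataclass(frozen=True)
class ModelFit:
    """One pooled estimate (fixed or random) with CI and normalized weights."""

    pooled: float
    se: float
    weights: tuple[float, ...]

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.pooled - Z95 * self.se, self.pooled + Z95 * self.se)


@dataclass(frozen=True)
class MetaResult:
    """Fixed + DL random pooled results with heterogeneity statistics.

    ``model`` is the one selected by the I² > 0.50 rule; ``pooled``/``ci95``/
    ``weights`` delegate to it. Both fits are always available.
    """

    fixed: ModelFit
    random: ModelFit
    Q: float
    df: int
    p_Q: float
    i2: float
    tau2: float
    cohort_ids: tuple[str, ...] = field(default=())
    omitted: str | None = None

    @property
    def model(self) -> str:
        return "random" if self.i2 > 0.50 else "fixed"

    @property
    def selected(self) -> ModelFit:
        return self.random if self.model == "random" else self.fixed

    @property
    def pooled(self) -> float:
        return self.selected.pooled

    @property
    def ci95(self) -> tuple[float, float]:
        return self.selected.ci95

    @property
    def weights(self) -> tuple[float, ...]:
        return self.selected.weights


def hedges_g(case: GroupStats, control: GroupStats) -> float:
    """Hedges g point estimate (case − control, pooled-SD standardized).

    d = (m1 − m0)/s_p, s_p² = ((n1−1)s1² + (n0−1)s0²)/(n1+n0−2);
    J = 1 − 3/(4(n1+n0−2) − 1); g = J·d.
    """
    n1, n0 = case.n, control.n
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per group")
    sp2 = ((n1 - 1) * case.sd**2 + (n0 - 1) * control.sd**2) / (n1 + n0 - 2)
    if sp2 <= 0:
        raise ValueError("degenerate variance")
    d = (case.mean - control.mean) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (n1 + n0 - 2) - 1.0)
    return j * d


def hedges_g_effect(case: GroupStats, control: GroupStats,
                    cohort_id: str = "") -> EffectSize:
    """Hedges g with variance var_g = (n1+n0)/(n1·n0) + g²/(2(n1+n0))."""
    g = hedges_g(case, control)
    n1, n0 = case.n, control.n
    var_g = (n1 + n0) / (n1 * n0) + g**2 / (2.0 * (n1 + n0))
    return EffectSize(cohort_id=cohort_id, g=g, var_g=var_g)


def cohort_effect(cohort: ExpressionCohort, target_gene: str) -> EffectSize:
    """Hedges g of the target gene for one validated cohort."""
    result = validate(cohort, target_gene)
    if not result.accepted:
        raise ValueError(f"cohort {cohort.cohort_id} rejected: {result.reasons}")
    case, control = group_stats(cohort, target_gene)
    return hedges_g_effect(case, control, cohort_id=cohort.cohort_id)


def pool(effects: list[EffectSize]) -> MetaResult:
    """Inverse-variance fixed-effect and DerSimonian–Laird random-effects pooling.

    Q = Σ w_i (g_i − pooled_FE)² with w_i = 1/var_i; I² = max(0, (Q−df)/Q);
    τ² = max(0, (Q−df)/(Σw − Σw²/Σw)); random weights w*_i = 1/(var_i + τ²).
    """
    if len(effects) < 2:
        raise ValueError("pooling requires at least 2 effects")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    w = 1.0 / v
    sw = w.sum()
    pooled_fe = float((w * g).sum() / sw)
    q = float((w * (g - pooled_fe) ** 2).sum())
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0

    fixed = ModelFit(pooled=pooled_fe, se=math.sqrt(1.0 / sw),
                     weights=tuple(w / sw))
    wr = 1.0 / (v + tau2)
    swr = wr.sum()
    random = ModelFit(pooled=float((wr * g).sum() / swr), se=math.sqrt(1.0 / swr),
                      weights=tuple(wr / swr))
    return MetaResult(fixed=fixed, random=random, Q=q, df=df, p_Q=p_q,
                      i2=i2, tau2=tau2,
                      cohort_ids=tuple(e.cohort_id for e in effects))


def leave_one_out(effects: list[EffectSize]) -> list[MetaResult]:
    """Sensitivity analysis: re-pool k times, omitting one cohort each time."""
    if len(effects) < 3:
        raise ValueError("leave-one-out requires at least 3 effects")
    out = []
    for i, omitted in enumerate(effects):
        rest = effects[:i] + effects[i + 1:]
        res = pool(rest)
        out.append(MetaResult(
            fixed=res.fixed, random=res.random, Q=res.Q, df=res.df, p_Q=res.p_Q,
            i2=res.i2, tau2=res.tau2, cohort_ids=res.cohort_ids,
            omitted=omitted.cohort_id))
    return out


def subgroup_pool(effects: list[EffectSize],
                  labels: dict[str, str]) -> dict[str, MetaResult]:
    """Independent pooling within each category; singletons warned and dropped."""
    by_cat: dict[str, list[EffectSize]] = {}
    for e in effects:
        by_cat.setdefault(labels[e.cohort_id], []).append(e)
    out = {}
    for cat, group in sorted(by_cat.items()):
        if len(group) < 2:
            warnings.warn(f"subgroup {cat!r} has a single cohort; omitted")
            continue
        out[cat] = pool(group)
    return out


def beggs_test(effects: list[EffectSize]) -> tuple[float, float, bool]:
    """Begg–Mazumdar publication-bias test.

    Kendall tau-b between the standardized deviates
    t_i = (g_i − pooled_FE)/sqrt(var_i − 1/Σw) and the variances var_i, with a
    two-sided normal-approximation p. Returns (tau, p, degenerate_flag); all
    variances tied is degenerate (tau=0, p=1).
    """
    if len(effects) < 3:
        raise ValueError("Begg's test requires at least 3 effects")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    if np.allclose(v, v[0]):
        return 0.0, 1.0, True
    w = 1.0 / v
    pooled_fe = (w * g).sum() / w.sum()
    inner = v - 1.0 / w.sum()
    t = (g - pooled_fe) / np.sqrt(np.maximum(inner, np.finfo(float).tiny))
    res = stats.kendalltau(t, v, method="asymptotic")
    tau = float(res.statistic)
    if math.isnan(tau):
        return 0.0, 1.0, True
    return tau, float(res.pvalue), False


def funnel_points(effects: list[EffectSize]) -> pd.DataFrame:
    """Plot-ready funnel table: effect vs its standard error, one row/cohort."""
    return pd.DataFrame({
        "cohort_id": [e.cohort_id for e in effects],
        "g": [e.g for e in effects],
        "se_g": [e.se_g for e in effects],
    })


def forest_table(effects: list[EffectSize], result: MetaResult) -> pd.DataFrame:
    """Plot-ready forest table with per-cohort CIs and selected-model weights."""
    rows = []
    for e, wt in zip(effects, result.weights):
        lo, hi = e.ci95
        rows.append({"cohort_id": e.cohort_id, "g": e.g, "ci_lo": lo,
                     "ci_hi": hi, "weight": wt})
    lo, hi = result.ci95
    rows.append({"cohort_id": f"pooled ({result.model})", "g": result.pooled,
                 "ci_lo": lo, "ci_hi": hi, "weight": 1.0})
    return pd.DataFrame(rows)
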