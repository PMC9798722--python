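"""Effect-size meta-analysis.

Implements the standardized mean difference (Cohen's d, optionally Hedges'
g), Cochran's Q / I-squared heterogeneity, fixed-effect and
DerSimonian-Laird random-effects pooling with the printed model-selection
rule (random iff I2 > 50% or heterogeneity p < 0.05), subgroup and
leave-one-out sensitivity analyses, the Begg-Mazumdar rank-correlation
test for publication bias, and Fisher-z pooling of Pearson correlations.

Conventions: group 1 is the tumor group, effects are tumor minus control,
and pooled confidence intervals use normal quantiles.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import CorrelationStudy, GroupSummary, MetaResult, StudyEffect

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def smd(summary: GroupSummary, correction: str = "cohen", label: str = "") -> StudyEffect:
    """Standardized mean difference of one cohort.

    Cohen's d divides the mean difference by the pooled SD
    ``s_p = sqrt(((n1-1) sd1^2 + (n0-1) sd0^2) / (n1+n0-2))``; Hedges' g
    multiplies d by the small-sample factor ``J = 1 - 3/(4(n1+n0-2) - 1)``.
    The large-sample variance is ``(n1+n0)/(n1 n0) + d^2/(2(n1+n0))`` and the
    95% CI uses normal quantiles.
    """
    if correction not in ("cohen", "hedges"):
        raise ValueError("correction must be 'cohen' or 'hedges'")
    if not summary.usable_for_variance:
        raise ValueError("SMD needs n >= 2 in both groups")
    if summary.sd1 == 0 and summary.sd0 == 0:
        raise ValueError("both group SDs are zero: SMD undefined")
    n1, n0 = summary.n1, summary.n0
    df = n1 + n0 - 2
    s_pooled = math.sqrt(((n1 - 1) * summary.sd1**2 + (n0 - 1) * summary.sd0**2) / df)
    d = (summary.mean1 - summary.mean0) / s_pooled
    if correction == "hedges":
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    n = n1 + n0
    variance = n / (n1 * n0) + d**2 / (2.0 * n)
    half = Z95 * math.sqrt(variance)
    return StudyEffect(estimate=d, variance=variance, ci_low=d - half, ci_high=d + half, label=label)


def heterogeneity(effects: Sequence[StudyEffect]) -> tuple[float, int, float, float]:
    """Cochran's Q, its df, chi-square p-value, and I2 = max(0, (Q-df)/Q)."""
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least 2 studies")
    e = np.array([s.estimate for s in effects])
    w = 1.0 / np.array([s.variance for s in effects])
    mean_w = float(np.sum(w * e) / np.sum(w))
    Q = float(np.sum(w * (e - mean_w) ** 2))
    df = len(effects) - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, p, I2


def _single_study_result(effect: StudyEffect) -> MetaResult:
    """A singleton 'pooled' result: the study's own estimate and CI."""
    return MetaResult(
        pooled=effect.estimate,
        se=math.sqrt(effect.variance),
        ci_low=effect.ci_low,
        ci_high=effect.ci_high,
        Q=0.0,
        df=0,
        I2=0.0,
        tau2=0.0,
        model="fixed",
        k=1,
        het_p=float("nan"),
    )


def pool(effects: Sequence[StudyEffect], model: str = "auto") -> MetaResult:
    """Inverse-variance pooling of study effects.

    ``fixed`` uses weights 1/v_i. ``random`` uses DerSimonian-Laird:
    ``tau2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``
    and weights ``1/(v_i + tau2)``. ``auto`` picks random iff I2 > 0.5 or
    the heterogeneity p-value < 0.05.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError("model must be fixed, random or auto")
    if len(effects) < 2:
        raise ValueError("pooling needs at least 2 studies")
    e = np.array([s.estimate for s in effects])
    v = np.array([s.variance for s in effects])
    Q, df, het_p, I2 = heterogeneity(effects)
    if model == "auto":
        model = "random" if (I2 > 0.5 or het_p < 0.05) else "fixed"

    w_fixed = 1.0 / v
    if model == "random":
        C = float(np.sum(w_fixed) - np.sum(w_fixed**2) / np.sum(w_fixed))
        tau2 = max(0.0, (Q - df) / C)
    else:
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * e) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return MetaResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        Q=Q,
        df=df,
        I2=I2,
        tau2=tau2,
        model=model,
        k=len(effects),
        het_p=het_p,
    )


def subgroup_pool(
    effects: Sequence[StudyEffect],
    subgroups: Sequence[str],
    model: str = "auto",
) -> tuple[dict[str, MetaResult], MetaResult]:
    """Pool within each subgroup label plus an overall pool.

    A singleton subgroup is reported as the study's own effect and CI
    (no pooling), the way a forest plot shows a one-study subgroup.
    """
    if len(effects) != len(subgroups):
        raise ValueError("every effect needs a subgroup label")
    per_label: dict[str, list[StudyEffect]] = {}
    for eff, label in zip(effects, subgroups):
        per_label.setdefault(label, []).append(eff)
    results = {
        label: (_single_study_result(group[0]) if len(group) == 1 else pool(group, model))
        for label, group in per_label.items()
    }
    overall = pool(effects, model) if len(effects) > 1 else _single_study_result(effects[0])
    return results, overall


def leave_one_out(effects: Sequence[StudyEffect], model: str = "auto") -> list[MetaResult]:
    """Sensitivity analysis: re-pool k times, omitting one study each time."""
    if len(effects) < 3:
        raise ValueError("leave-one-out needs at least 3 studies")
    out = []
    for i in range(len(effects)):
        subset = [s for j, s in enumerate(effects) if j != i]
        out.append(pool(subset, model))
    return out


def beggs_test(effects: Sequence[StudyEffect]) -> tuple[float, float, float]:
    """Begg-Mazumdar rank-correlation test for publication bias.

    Standardized deviates ``t_i = (e_i - e_fixed) / sqrt(v_i - 1/sum(w))``
    are rank-correlated (Kendall) with the sampling variances. The z
    statistic is ``(|P - Q| - 1) / sqrt(k(k-1)(2k+5)/18)`` with the
    continuity correction applied when P != Q; tied pairs count toward
    neither P nor Q. Returns ``(tau, z, p_two_sided)``.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Begg's test needs at least 3 studies")
    e = np.array([s.estimate for s in effects])
    v = np.array([s.variance for s in effects])
    w = 1.0 / v
    pooled_fixed = float(np.sum(w * e) / np.sum(w))
    # v_i - 1/sum(w) >= 0 always; clip guards rounding at equality
    denom = np.sqrt(np.clip(v - 1.0 / np.sum(w), 0.0, None))
    if (denom == 0).any():
        raise ValueError("degenerate deviate variance in Begg's test")
    deviates = (e - pooled_fixed) / denom

    P = Qd = 0
    for i in range(k):
        for j in range(i + 1, k):
            dt = deviates[j] - deviates[i]
            dv = v[j] - v[i]
            prod = dt * dv
            if prod > 0:
                P += 1
            elif prod < 0:
                Qd += 1
    diff = P - Qd
    tau = diff / (k * (k - 1) / 2)
    sd = math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    z = 0.0 if diff == 0 else (abs(diff) - 1.0) / sd * (1 if diff > 0 else -1)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return tau, z, p


def pool_correlations(studies: Sequence[CorrelationStudy], model: str = "auto") -> MetaResult:
    """Pool Pearson correlations via the Fisher z transform.

    Each study contributes ``z_i = atanh(r_i)`` with standard error
    ``1/sqrt(n_i - 3)``; pooling happens on the z scale and the pooled value
    and CI are transformed back with tanh. ``se``, ``Q``, ``I2`` and ``tau2``
    remain on the z scale.
    """
    if len(studies) < 1:
        raise ValueError("need at least one correlation study")
    effects = [
        StudyEffect(
            estimate=math.atanh(s.r),
            variance=1.0 / (s.n - 3),
            ci_low=math.atanh(s.r) - Z95 / math.sqrt(s.n - 3),
            ci_high=math.atanh(s.r) + Z95 / math.sqrt(s.n - 3),
            label=s.label,
        )
        for s in studies
    ]
    z_result = _single_study_result(effects[0]) if len(effects) == 1 else pool(effects, model)
    return MetaResult(
        pooled=math.tanh(z_result.pooled),
        se=z_result.se,
        ci_low=math.tanh(z_result.ci_low),
        ci_high=math.tanh(z_result.ci_high),
        Q=z_result.Q,
        df=z_result.df,
        I2=z_result.I2,
        tau2=z_result.tau2,
        model=z_result.model,
        k=z_result.k,
        het_p=z_result.het_p,
    )


def effects_from_summaries(
    summaries: Mapping[str, GroupSummary], correction: str = "cohen"
) -> list[StudyEffect]:
    """Convenience: SMD per labeled cohort summary, preserving order."""
    return [smd(s, correction=correction, label=label) for label, s in summaries.items()]
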