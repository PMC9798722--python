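"""Diagnostic-accuracy analysis: t tests, ROC/AUC, 2x2 pooling, sROC, Fagan.

Per cohort the marker's values are turned into a ROC curve (tumor positive,
higher value more positive), a Youden-optimal cutoff, and a 2x2 table.
Across cohorts sensitivity and specificity are pooled on the logit scale
with the same inverse-variance machinery as the effect-size meta-analysis,
a Moses-Littenberg summary ROC is fitted, and Fagan post-test probabilities
convert a pre-test probability through the pooled likelihood ratios.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import meta_effect
from .types import (
    TUMOR,
    DiagnosticMeta,
    DiagnosticStudy,
    GroupSummary,
    MetaResult,
    StudyEffect,
)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    variant: str


def two_sample_t(summary: GroupSummary, variant: str = "student") -> TTestResult:
    """Independent two-sample t test from group summaries.

    ``student`` pools variances (df = n1+n0-2); ``welch`` uses
    ``t = (mean1-mean0)/sqrt(sd1^2/n1 + sd0^2/n0)`` with Welch-Satterthwaite
    df; ``auto`` runs an F test of variance equality at alpha = 0.05 and
    uses Welch when it rejects. Sign follows mean1 - mean0 (tumor - control).
    """
    if variant not in ("student", "welch", "auto"):
        raise ValueError("variant must be student, welch or auto")
    if not summary.usable_for_variance:
        raise ValueError("t test needs n >= 2 in both groups")
    if summary.sd1 == 0 and summary.sd0 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    n1, n0 = summary.n1, summary.n0
    v1, v0 = summary.sd1**2, summary.sd0**2
    delta = summary.mean1 - summary.mean0

    if variant == "auto":
        if v1 == 0 or v0 == 0:
            variant = "welch"
        else:
            F = max(v1, v0) / min(v1, v0)
            dfn = (n1 - 1) if v1 >= v0 else (n0 - 1)
            dfd = (n0 - 1) if v1 >= v0 else (n1 - 1)
            p_var = 2.0 * stats.f.sf(F, dfn, dfd)
            variant = "welch" if min(p_var, 1.0) < 0.05 else "student"

    if variant == "student":
        df = n1 + n0 - 2
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    else:
        se = math.sqrt(v1 / n1 + v0 / n0)
        df = (v1 / n1 + v0 / n0) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    if se == 0:
        raise ValueError("zero standard error: t undefined")
    t = delta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p=p, variant=variant)


class RocCurve(NamedTuple):
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(values: Sequence[float], labels: Sequence[str]) -> RocCurve:
    """ROC curve of a marker (tumor positive; higher value more positive).

    The trapezoidal area under the full curve equals the Mann-Whitney U
    statistic divided by n1*n0, with ties counted one half.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    y = labels == TUMOR
    if y.all() or not y.any():
        raise ValueError("ROC needs both tumor and control samples")
    fpr, tpr, thresholds = _sk_roc_curve(y, values, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def youden_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sens + spec - 1.

    Ties are broken toward the lower cutoff, i.e. the higher sensitivity.
    Returns (cutoff, sensitivity, specificity) with positivity at
    value >= cutoff.
    """
    J = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValueError("degenerate ROC: no finite thresholds")
    J_best = J[finite].max()
    candidates = np.where(finite & (J >= J_best - 1e-12))[0]
    idx = candidates[np.argmin(roc.thresholds[candidates])]
    return float(roc.thresholds[idx]), float(roc.tpr[idx]), float(1.0 - roc.fpr[idx])


def to_two_by_two(
    values: Sequence[float], labels: Sequence[str], cutoff: float, label: str = ""
) -> DiagnosticStudy:
    """Dichotomize marker values at a cutoff into a 2x2 table (>= positive)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    values = np.asarray(values, dtype=float)
    is_tumor = np.asarray(labels) == TUMOR
    positive = values >= cutoff
    return DiagnosticStudy(
        tp=int((positive & is_tumor).sum()),
        fp=int((positive & ~is_tumor).sum()),
        fn=int((~positive & is_tumor).sum()),
        tn=int((~positive & ~is_tumor).sum()),
        cutoff=float(cutoff),
        label=label,
    )


def _corrected_cells(study: DiagnosticStudy) -> tuple[float, float, float, float]:
    """0.5 continuity correction on all four cells when any cell is zero."""
    cells = (study.tp, study.fp, study.fn, study.tn)
    if 0 in cells:
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def _logit_effects(
    studies: Sequence[DiagnosticStudy], which: str
) -> list[StudyEffect]:
    effects = []
    for s in studies:
        tp, fp, fn, tn = _corrected_cells(s)
        if which == "sens":
            p, var = tp / (tp + fn), 1.0 / tp + 1.0 / fn
        else:
            p, var = tn / (tn + fp), 1.0 / tn + 1.0 / fp
        est = float(logit(p))
        half = meta_effect.Z95 * math.sqrt(var)
        effects.append(
            StudyEffect(estimate=est, variance=var, ci_low=est - half, ci_high=est + half, label=s.label)
        )
    return effects


def pool_accuracy(studies: Sequence[DiagnosticStudy], model: str = "auto") -> DiagnosticMeta:
    """Pool sensitivity and specificity across 2x2 tables on the logit scale.

    Likelihood ratios and the diagnostic odds ratio are derived from the
    pooled (back-transformed) sensitivity and specificity.
    """
    if len(studies) < 2:
        raise ValueError("pooling accuracy needs at least 2 studies")
    sens_meta = _backtransform(meta_effect.pool(_logit_effects(studies, "sens"), model))
    spec_meta = _backtransform(meta_effect.pool(_logit_effects(studies, "spec"), model))
    sens, spec = sens_meta.pooled, spec_meta.pooled
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    return DiagnosticMeta(
        pooled_sens=sens,
        sens_ci=(sens_meta.ci_low, sens_meta.ci_high),
        pooled_spec=spec,
        spec_ci=(spec_meta.ci_low, spec_meta.ci_high),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=lr_pos / lr_neg,
        sens_meta=sens_meta,
        spec_meta=spec_meta,
    )


def _backtransform(result: MetaResult) -> MetaResult:
    """Map a logit-scale MetaResult to the probability scale (se stays logit)."""
    return MetaResult(
        pooled=float(expit(result.pooled)),
        se=result.se,
        ci_low=float(expit(result.ci_low)),
        ci_high=float(expit(result.ci_high)),
        Q=result.Q,
        df=result.df,
        I2=result.I2,
        tau2=result.tau2,
        model=result.model,
        k=result.k,
        het_p=result.het_p,
    )


class SrocResult(NamedTuple):
    fpr: np.ndarray
    sens: np.ndarray
    auc: float
    intercept: float
    slope: float


def sroc(studies: Sequence[DiagnosticStudy], n_points: int = 1001) -> SrocResult:
    """Moses-Littenberg summary ROC curve.

    Per study, D = ln(DOR) and S = logit(sens) + logit(FPR); a least-squares
    line D = a + bS is fitted and back-transformed into a curve over
    FPR in (0, 1): logit(sens) = (a + (1+b) logit(fpr)) / (1 - b). The AUC
    is the trapezoidal area over ``n_points`` grid points. Identical studies
    give S constant, handled as slope 0 (a symmetric curve).
    """
    if len(studies) < 3:
        raise ValueError("sROC needs at least 3 studies")
    D, S = [], []
    for s in studies:
        tp, fp, fn, tn = _corrected_cells(s)
        sens, fprate = tp / (tp + fn), fp / (fp + tn)
        D.append(float(logit(sens) - logit(fprate)))  # ln DOR
        S.append(float(logit(sens) + logit(fprate)))
    D, S = np.array(D), np.array(S)
    if np.ptp(S) < 1e-12:
        slope, intercept = 0.0, float(np.mean(D))
    else:
        slope, intercept = np.polyfit(S, D, 1)
        slope, intercept = float(slope), float(intercept)
    if abs(1.0 - slope) < 1e-8:
        raise ValueError("degenerate sROC fit (slope ~ 1)")

    grid = np.linspace(0.0, 1.0, n_points)
    inner = grid[1:-1]
    sens_curve = expit((intercept + (1.0 + slope) * logit(inner)) / (1.0 - slope))
    fpr = np.concatenate([[0.0], inner, [1.0]])
    sens_full = np.concatenate([[0.0], sens_curve, [1.0]])
    auc = float(np.trapezoid(sens_full, fpr))
    return SrocResult(fpr=fpr, sens=sens_full, auc=auc, intercept=intercept, slope=slope)


def fagan(pretest: float, sens: float, spec: float) -> tuple[float, float]:
    """Fagan nomogram: post-test probabilities after a positive/negative test.

    LR+ = sens/(1-spec), LR- = (1-sens)/spec; pre-test odds are multiplied
    by the likelihood ratio and converted back to a probability.
    """
    for name, p in (("pretest", pretest), ("sens", sens), ("spec", spec)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    odds = pretest / (1.0 - pretest)
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    odds_pos = odds * lr_pos
    odds_neg = odds * lr_neg
    return odds_pos / (1.0 + odds_pos), odds_neg / (1.0 + odds_neg)
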