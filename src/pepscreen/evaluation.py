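"""Validation metrics for the biomarker panel.

ROC AUC as the Mann-Whitney concordance probability (ties count 1/2)
with DeLong confidence intervals (a Clopper-Pearson binomial interval on
concordant pairs is available as an alternative), the paired DeLong test
for comparing correlated AUCs, operating-point sensitivity/specificity
with exact binomial CIs and predictive values at a stated prevalence,
the tie-corrected Kruskal-Wallis test across risk groups, and the
coefficient of variation for replicate classification scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ValidationError

__all__ = [
    "DiagnosticPerformance",
    "roc_auc",
    "delong_variance",
    "delong_compare",
    "operating_point",
    "predictive_values",
    "kruskal_wallis",
    "reproducibility_cv",
]


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must align")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValidationError("both classes must be present")
    return s, y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Per-observation DeLong structural components (V10, V01) and AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance."""
    s, y = _as_arrays(scores, labels)
    auc, v10, v01 = _delong_components(s, y)
    var = sum(
        np.var(v, ddof=1) / len(v) if len(v) > 1 else 0.0 for v in (v10, v01)
    )
    return float(auc), float(var)


def roc_auc(scores, labels, ci: str = "delong", level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a 95% (by default) confidence interval.

    ``ci='delong'`` uses the DeLong normal interval; ``ci='binomial'``
    uses a Clopper-Pearson interval treating concordant pairs as
    binomial successes out of the n1*n0 discordant-pair trials.
    """
    s, y = _as_arrays(scores, labels)
    auc, var = delong_variance(s, y)
    if ci == "delong":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif ci == "binomial":
        n_pairs = int((y == 1).sum()) * int((y == 0).sum())
        k = int(round(auc * n_pairs))
        lo, hi = _clopper_pearson(k, n_pairs, level)
    else:
        raise ValidationError(f"unknown CI method {ci!r}")
    return float(auc), float(max(0.0, lo)), float(min(1.0, hi))


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for two correlated AUCs on identical samples.

    Returns (auc_a - auc_b, two-sided p).  Identical score vectors give
    delta 0 and p = 1.
    """
    a, y = _as_arrays(scores_a, labels)
    b, y2 = _as_arrays(scores_b, labels)
    if not np.array_equal(y, y2):
        raise ValidationError("paired scores must share one label vector")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    delta = auc_a - auc_b
    m, n = len(v10_a), len(v01_a)
    var = 0.0
    for pair, k in (((v10_a, v10_b), m), ((v01_a, v01_b), n)):
        if k > 1:
            s = np.cov(np.stack(pair), ddof=1)
            var += (s[0, 0] + s[1, 1] - 2.0 * s[0, 1]) / k
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2.0 * stats.norm.sf(abs(z)))


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2.0, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


@dataclass
class DiagnosticPerformance:
    """Operating-point summary at a fixed score cutoff."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    prevalence: float
    npv: float
    ppv: float
    n_case: int
    n_control: int


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """(NPV, PPV) at an externally stated prevalence, by Bayes' rule."""
    if not 0.0 < prevalence < 1.0:
        raise ValidationError("prevalence must lie in (0, 1)")
    se, sp, pi = sensitivity, specificity, prevalence
    npv_denom = sp * (1 - pi) + (1 - se) * pi
    ppv_denom = se * pi + (1 - sp) * (1 - pi)
    # degenerate operating points (nobody tests negative/positive)
    npv = sp * (1 - pi) / npv_denom if npv_denom > 0 else float("nan")
    ppv = se * pi / ppv_denom if ppv_denom > 0 else float("nan")
    return float(npv), float(ppv)


def operating_point(scores, labels, cutoff: float, prevalence: float) -> DiagnosticPerformance:
    """Sensitivity/specificity at ``cutoff`` (score >= cutoff is positive)
    with Clopper-Pearson 95% CIs, plus NPV/PPV at ``prevalence``."""
    s, y = _as_arrays(scores, labels)
    if not np.isfinite(cutoff):
        # +/- inf cutoffs are degenerate but well-defined limits
        positive = np.full(s.shape, cutoff < 0)
    else:
        positive = s >= cutoff
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    tp = int((positive & (y == 1)).sum())
    tn = int((~positive & (y == 0)).sum())
    se = tp / n_case
    sp = tn / n_ctrl
    npv, ppv = predictive_values(se, sp, prevalence)
    auc, lo, hi = roc_auc(s, y)
    return DiagnosticPerformance(
        auc=auc,
        auc_ci=(lo, hi),
        cutoff=float(cutoff),
        sensitivity=se,
        sensitivity_ci=_clopper_pearson(tp, n_case),
        specificity=sp,
        specificity_ci=_clopper_pearson(tn, n_ctrl),
        prevalence=float(prevalence),
        npv=npv,
        ppv=ppv,
        n_case=n_case,
        n_control=n_ctrl,
    )


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = pd.Series(group_labels)
    samples = [values[(groups == g).to_numpy()] for g in groups.unique()]
    samples = [g for g in samples if len(g) > 0]
    if len(samples) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 non-empty groups")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def reproducibility_cv(scores) -> float:
    """Coefficient of variation of replicate scores, in percent."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValidationError("need at least 2 replicate scores")
    mean = s.mean()
    if mean == 0:
        raise ValidationError("CV is undefined for zero mean")
    return float(s.std(ddof=1) / abs(mean) * 100.0)
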