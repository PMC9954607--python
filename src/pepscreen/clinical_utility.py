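"""Decision-curve analysis and the integrative logistic nomogram.

Net benefit at a decision threshold t (the risk at which a patient
would accept a biopsy) is NB(t) = TP/n - (FP/n) * t/(1-t), compared
against the treat-all and treat-none strategies.  Raw SVM scores are
mapped to probabilities for DCA by logistic (Platt-style) calibration
fitted on discovery out-of-fold scores.  The nomogram is a
maximum-likelihood logistic regression combining the biomarker score
with clinical covariates (age, PSA density, an external ERSPC-style
risk column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .core_data import ValidationError

__all__ = [
    "NetBenefitCurve",
    "NomogramModel",
    "ScoreCalibrator",
    "net_benefit",
    "treat_all_net_benefit",
    "dca_curves",
    "fit_nomogram",
]

DEFAULT_DCA_GRID = np.round(np.arange(0.01, 0.601, 0.01), 10)


def net_benefit(labels, risk_probabilities, threshold: float) -> float:
    """NB = TP/n - (FP/n) * t/(1-t); positive means probability >= t."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    y = np.asarray(labels, dtype=int)
    p = np.asarray(risk_probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("risk probabilities must lie in [0, 1]")
    n = len(y)
    positive = p >= threshold
    tp = (positive & (y == 1)).sum()
    fp = (positive & (y == 0)).sum()
    return float(tp / n - (fp / n) * threshold / (1.0 - threshold))


def treat_all_net_benefit(prevalence: float, threshold: float) -> float:
    """Closed form for the biopsy-everyone strategy: pi - (1-pi) t/(1-t)."""
    return float(prevalence - (1.0 - prevalence) * threshold / (1.0 - threshold))


@dataclass
class NetBenefitCurve:
    """Net benefit per strategy over a threshold grid.

    ``curves`` is indexed by threshold with one column per strategy,
    always including ``treat_all`` and ``treat_none``.
    """

    curves: pd.DataFrame

    @property
    def thresholds(self) -> np.ndarray:
        return self.curves.index.to_numpy()

    @property
    def strategies(self) -> list[str]:
        return list(self.curves.columns)


def dca_curves(
    labels,
    model_probabilities: dict[str, np.ndarray] | pd.DataFrame,
    grid: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Decision curves for one or more probability models plus baselines."""
    if grid is None:
        grid = DEFAULT_DCA_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValidationError("all grid thresholds must lie in (0, 1)")
    y = np.asarray(labels, dtype=int)
    probs = pd.DataFrame(model_probabilities)
    if probs.shape[1] > 0 and len(probs) != len(y):
        raise ValidationError("all strategies must be scored on identical samples")
    prevalence = y.mean()
    out = {}
    for name in probs.columns:
        out[name] = [net_benefit(y, probs[name].to_numpy(), t) for t in grid]
    out["treat_all"] = [treat_all_net_benefit(prevalence, t) for t in grid]
    out["treat_none"] = [0.0] * len(grid)
    return NetBenefitCurve(pd.DataFrame(out, index=pd.Index(grid, name="threshold")))


@dataclass
class NomogramModel:
    """Fitted logistic nomogram with per-coefficient inference."""

    predictors: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    fitted_probabilities: pd.Series
    converged: bool
    n_used: int
    n_dropped: int

    def predict(self, frame: pd.DataFrame) -> pd.Series:
        x = sm.add_constant(frame.loc[:, self.predictors], has_constant="add")
        eta = x.to_numpy() @ self.coefficients.loc[x.columns].to_numpy()
        return pd.Series(expit(eta), index=frame.index)


def fit_nomogram(
    frame: pd.DataFrame,
    predictors: list[str],
    outcome: str = "outcome",
) -> NomogramModel:
    """Maximum-likelihood logistic fit of ``outcome`` on ``predictors``.

    Samples with any missing predictor are dropped (complete-case) and
    counted in ``n_dropped``.  Quasi-separation is reported as an error
    rather than returning divergent coefficients.
    """
    cols = predictors + [outcome]
    data = frame.loc[:, cols].apply(pd.to_numeric, errors="coerce")
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if len(complete) == 0:
        raise ValidationError("no complete cases for the requested predictors")
    y = complete[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    x = sm.add_constant(complete[predictors], has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is re-raised as an error below
            res = sm.Logit(y, x).fit(disp=False, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and numeric failures
        raise ValidationError(
            f"logistic fit failed ({exc}); check predictors for separation"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise ValidationError("logistic fit did not converge")
    if np.abs(res.params.to_numpy()).max() > 1e3:
        raise ValidationError("separation detected: divergent coefficients")
    return NomogramModel(
        predictors=list(predictors),
        coefficients=res.params,
        std_errors=res.bse,
        p_values=res.pvalues,
        fitted_probabilities=pd.Series(res.predict(x), index=complete.index),
        converged=True,
        n_used=len(complete),
        n_dropped=n_dropped,
    )


@dataclass
class ScoreCalibrator:
    """Logistic mapping from a raw SVM score to a risk probability."""

    intercept: float
    slope: float

    @staticmethod
    def fit(scores, labels) -> "ScoreCalibrator":
        # mild L2 regularization keeps the mapping finite under
        # (quasi-)separated scores, as in classic Platt scaling
        from sklearn.linear_model import LogisticRegression

        s = np.asarray(scores, dtype=float).reshape(-1, 1)
        y = np.asarray(labels, dtype=int)
        lr = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000)
        lr.fit(s, y)
        return ScoreCalibrator(intercept=float(lr.intercept_[0]), slope=float(lr.coef_[0, 0]))

    def __call__(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return expit(self.intercept + self.slope * s)
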