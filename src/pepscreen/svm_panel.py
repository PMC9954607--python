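"""The multi-peptide SVM classifier.

An RBF-kernel support vector machine (default cost C = 16, kernel width
gamma = 0.01) is trained on the z-scored log intensities of the panel
peptides; the continuous classification score is the signed distance to
the decision boundary.  The decision cutoff is fixed on out-of-fold
discovery scores by maximizing the Youden index J = Se + Sp - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .core_data import ValidationError
from .discovery import BiomarkerPanel
from .normalization import TransformedMatrix

__all__ = ["PanelModel", "train_model", "score_samples", "cross_validate", "fix_cutoff"]

DEFAULT_SVM_C = 16.0
DEFAULT_SVM_GAMMA = 0.01
#: Fraction of panel features a sample may miss before being flagged.
MISSING_FLAG_FRACTION = 0.5


@dataclass
class PanelModel:
    """Trained panel classifier: features, standardization, SVM, cutoff."""

    feature_ids: list[str]
    center: pd.Series
    scale: pd.Series
    svm: SVC
    svm_c: float = DEFAULT_SVM_C
    svm_gamma: float = DEFAULT_SVM_GAMMA
    cutoff: float = 0.0
    training_manifest: dict = field(default_factory=dict)

    def standardize(self, design: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in design.columns]
        if missing:
            raise ValidationError(f"panel feature absent from matrix: {missing[0]!r}")
        x = design.loc[:, self.feature_ids]
        return ((x - self.center) / self.scale).to_numpy()

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "PanelModel":
        return joblib.load(path)


def _fit_svm(x: np.ndarray, y: np.ndarray, c: float, gamma: float) -> SVC:
    svm = SVC(C=c, gamma=gamma, kernel="rbf", tol=1e-6, cache_size=256)
    svm.fit(x, y)
    return svm


def _standardization(x: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0).replace(0.0, 1.0)
    return center, scale


def train_model(
    transformed: TransformedMatrix,
    labels: pd.Series,
    panel: BiomarkerPanel | Sequence[str],
    svm_c: float = DEFAULT_SVM_C,
    svm_gamma: float = DEFAULT_SVM_GAMMA,
    seed: int = 0,
) -> PanelModel:
    """Fit the panel SVM on the (discovery) samples in ``labels``.

    ``labels`` maps sample_id -> 1/0 and defines the training set; its
    index must be a subset of the matrix samples.  Standardization
    constants are fitted on the same samples only.
    """
    feature_ids = list(panel.feature_ids) if isinstance(panel, BiomarkerPanel) else list(panel)
    if not feature_ids:
        raise ValidationError("panel is empty")
    labels = pd.Series(labels)
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    missing = [f for f in feature_ids if f not in transformed.values.index]
    if missing:
        raise ValidationError(f"panel feature absent from matrix: {missing[0]!r}")
    design = transformed.samples_design(list(labels.index)).loc[:, feature_ids]
    center, scale = _standardization(design)
    x = ((design - center) / scale).to_numpy()
    svm = _fit_svm(x, y, svm_c, svm_gamma)
    return PanelModel(
        feature_ids=feature_ids,
        center=center,
        scale=scale,
        svm=svm,
        svm_c=svm_c,
        svm_gamma=svm_gamma,
        training_manifest={"n_samples": len(y), "seed": seed,
                           "sample_ids": list(labels.index)},
    )


def score_samples(
    model: PanelModel, transformed: TransformedMatrix,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Continuous classification scores plus a high-missingness flag.

    Returns ``(scores, flagged)``; ``flagged`` marks samples missing
    (not detected) more than half of the panel features — they are
    scored anyway, with absences at the imputed 0.
    """
    ids = list(sample_ids) if sample_ids is not None else transformed.sample_ids
    design = transformed.samples_design(ids)
    x = model.standardize(design)
    scores = pd.Series(model.svm.decision_function(x), index=ids, name="score")
    detected = transformed.detected.loc[model.feature_ids, ids]
    flagged = (1.0 - detected.mean(axis=0)) > MISSING_FLAG_FRACTION
    return scores, flagged.rename("flagged")


def cross_validate(
    transformed: TransformedMatrix,
    labels: pd.Series,
    panel: BiomarkerPanel | Sequence[str],
    scheme: str = "loo",
    n_folds: int = 10,
    svm_c: float = DEFAULT_SVM_C,
    svm_gamma: float = DEFAULT_SVM_GAMMA,
    seed: int = 0,
) -> pd.Series:
    """Out-of-fold scores: every sample scored by a model that never saw it.

    Standardization and the SVM are refitted inside each fold.  Schemes:
    ``'loo'`` (default, leave-one-out) or ``'skf'`` (stratified k-fold).
    """
    feature_ids = list(panel.feature_ids) if isinstance(panel, BiomarkerPanel) else list(panel)
    labels = pd.Series(labels)
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("cross-validation needs both classes")
    design = transformed.samples_design(list(labels.index)).loc[:, feature_ids]
    if scheme == "loo":
        splitter = LeaveOneOut()
    elif scheme == "skf":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        raise ValidationError(f"unknown CV scheme {scheme!r}")

    scores = pd.Series(np.nan, index=labels.index, name="score")
    for train_idx, test_idx in splitter.split(design.to_numpy(), y):
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            if scheme == "loo":
                raise ValidationError("leave-one-out fold lost a class; cohort too small")
            continue  # degenerate k-fold split: skip with out-of-fold NaN
        train = design.iloc[train_idx]
        center, scale = _standardization(train)
        svm = _fit_svm(((train - center) / scale).to_numpy(), y_train, svm_c, svm_gamma)
        test = ((design.iloc[test_idx] - center) / scale).to_numpy()
        scores.iloc[test_idx] = svm.decision_function(test)
    return scores


def fix_cutoff(scores, labels) -> float:
    """Youden-optimal cutoff over midpoints between adjacent distinct scores.

    Maximizes J = Se + Sp - 1 with score >= cutoff classified positive;
    ties are broken toward the smaller cutoff (favoring sensitivity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValidationError("both classes must be present")
    distinct = np.unique(s)
    if distinct.size < 2:
        raise ValidationError("cutoff undefined for constant scores")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n_case = (y == 1).sum()
    n_ctrl = (y == 0).sum()
    best_cutoff, best_j = None, -np.inf
    for c in candidates:  # ascending, so strict improvement keeps the smallest
        positive = s >= c
        j = (positive & (y == 1)).sum() / n_case + (~positive & (y == 0)).sum() / n_ctrl - 1.0
        if j > best_j + 1e-12:
            best_cutoff, best_j = float(c), float(j)
    return best_cutoff
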