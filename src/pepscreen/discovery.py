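"""Case-control biomarker discovery.

Per-feature detection frequencies, two-sided Wilcoxon rank-sum tests on
log intensities (non-detected entries enter as the imputed 0, i.e. the
lowest tied rank, so frequency and abundance effects are jointly
visible), Benjamini-Hochberg multiplicity correction, fold changes, and
selection of the biomarker panel at q < alpha with a detection-frequency
threshold in at least one group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ValidationError
from .normalization import IntensityMatrix, TransformedMatrix, log_transform

__all__ = [
    "BiomarkerPanel",
    "detection_frequency",
    "rank_test",
    "bh_adjust",
    "feature_stats",
    "select_panel",
]

#: Group sizes at or below which the exact rank-sum null is used (ties permitting).
EXACT_TEST_MAX_N = 8


@dataclass
class BiomarkerPanel:
    """Selected features with their discovery statistics.

    ``entries`` columns: feature_id, freq_case, freq_control, p_value,
    q_value, fold_change, direction; ordered by (q_value, feature_id).
    """

    entries: pd.DataFrame
    alpha: float
    freq_threshold: float

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries["feature_id"])

    def __len__(self) -> int:
        return len(self.entries)


def _split_groups(labels: pd.Series) -> tuple[pd.Index, pd.Index]:
    labels = pd.Series(labels)
    cases = labels.index[labels == 1]
    controls = labels.index[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("both groups must be non-empty")
    return cases, controls


def detection_frequency(
    detected: pd.DataFrame | IntensityMatrix, labels: pd.Series
) -> pd.DataFrame:
    """Fraction of each group's samples in which each feature is detected.

    ``labels`` maps sample_id -> 1 (case) / 0 (control).
    """
    if isinstance(detected, IntensityMatrix):
        detected = detected.detected()
    cases, controls = _split_groups(labels)
    return pd.DataFrame(
        {
            "freq_case": detected.loc[:, cases].mean(axis=1),
            "freq_control": detected.loc[:, controls].mean(axis=1),
        }
    )


def rank_test(values_case: np.ndarray, values_control: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null when both groups have <= 8 observations and no
    ties are present, the tie-corrected normal approximation otherwise.
    Identical pooled values give p = 1.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= EXACT_TEST_MAX_N and b.size <= EXACT_TEST_MAX_N
                         and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def feature_stats(
    normalized: IntensityMatrix | TransformedMatrix,
    labels: pd.Series,
    raw_normalized: IntensityMatrix | None = None,
) -> pd.DataFrame:
    """Per-feature discovery statistics on a normalized matrix.

    Accepts the normalized intensity matrix (log transform applied
    internally) or an already-transformed matrix plus the pre-log matrix
    for fold changes.  Fold change is the ratio of group arithmetic
    means of pre-log intensities with non-detected counted as 0.
    """
    if isinstance(normalized, IntensityMatrix):
        raw_normalized = normalized
        transformed = log_transform(normalized)
    else:
        transformed = normalized
        if raw_normalized is None:
            raise ValidationError("raw_normalized is required with a TransformedMatrix")
    labels = pd.Series(labels)
    cases, controls = _split_groups(labels)

    freq = detection_frequency(transformed.detected, labels)
    x_case = transformed.values.loc[:, cases].to_numpy()
    x_ctrl = transformed.values.loc[:, controls].to_numpy()

    if x_case.shape[1] <= EXACT_TEST_MAX_N and x_ctrl.shape[1] <= EXACT_TEST_MAX_N:
        p = np.array([rank_test(a, b) for a, b in zip(x_case, x_ctrl)])
    else:
        constant = np.ptp(np.hstack([x_case, x_ctrl]), axis=1) == 0
        p = stats.mannwhitneyu(
            x_case, x_ctrl, alternative="two-sided", method="asymptotic", axis=1
        ).pvalue
        p = np.where(constant, 1.0, p)

    raw = raw_normalized.values.fillna(0.0)
    mean_case = raw.loc[:, cases].mean(axis=1)
    mean_ctrl = raw.loc[:, controls].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (mean_case / mean_ctrl).to_numpy()
    fold = np.where(np.isnan(fold), 1.0, fold)

    stats_df = pd.DataFrame(
        {
            "feature_id": transformed.feature_ids,
            "freq_case": freq["freq_case"].to_numpy(),
            "freq_control": freq["freq_control"].to_numpy(),
            "p_value": p,
            "q_value": bh_adjust(p),
            "fold_change": fold,
        }
    )
    stats_df["direction"] = np.where(stats_df["fold_change"] >= 1.0, "up", "down")
    return stats_df


def select_panel(
    stats_df: pd.DataFrame, alpha: float = 0.05, freq_threshold: float = 0.90
) -> BiomarkerPanel:
    """Keep features with q < alpha and detection frequency >= threshold
    in at least one group; deterministic (q, feature_id) ordering."""
    keep = (stats_df["q_value"] < alpha) & (
        stats_df[["freq_case", "freq_control"]].max(axis=1) >= freq_threshold
    )
    entries = (
        stats_df.loc[keep]
        .sort_values(["q_value", "feature_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return BiomarkerPanel(entries=entries, alpha=alpha, freq_threshold=freq_threshold)
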