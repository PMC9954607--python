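"""Internal-standard normalization and the log transform.

Urinary peptide intensities vary with urine dilution, so each sample is
rescaled against a panel of reference peptides (29 collagen fragments
that are stably excreted regardless of disease status).  The per-sample
factor is the median over detected panel peptides of
``reference_intensity / observed_intensity`` — a median-of-ratios
estimator robust to individual reference outliers.  After scaling, the
median panel ratio is exactly 1.

Downstream statistics operate on ``log10(1 + x)`` intensities, with
non-detected entries imputed as 0 (the transform's value at x = 0) and
tracked in a separate detection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import IntensityMatrix, PeptideFeature, ValidationError

__all__ = [
    "ReferencePanel",
    "TransformedMatrix",
    "compute_scale_factor",
    "normalize_matrix",
    "log_transform",
]


@dataclass
class ReferencePanel:
    """Reference ("housekeeping") peptides with their target intensities.

    ``minimum_detected`` is the number of panel peptides a sample must
    detect to be normalized; samples below it are excluded and flagged.
    """

    entries: pd.Series  # feature_id -> reference intensity (AU)
    minimum_detected: int = 15

    def __post_init__(self) -> None:
        self.entries = pd.Series(self.entries, dtype=float)
        if len(self.entries) == 0:
            raise ValidationError("reference panel must have at least one entry")
        if self.entries.index.duplicated().any():
            raise ValidationError("duplicate feature_id in reference panel")
        if not (self.entries > 0).all():
            raise ValidationError("reference intensities must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries.index)


def compute_scale_factor(sample_column: pd.Series, panel: ReferencePanel) -> float:
    """Median-of-ratios scale factor for one sample.

    Returns ``median(reference / observed)`` over panel peptides the
    sample detects; multiplying the sample by it makes the median panel
    ratio exactly 1.  Raises if fewer than ``panel.minimum_detected``
    panel peptides are detected.
    """
    observed = sample_column.reindex(panel.feature_ids)
    mask = observed.notna() & (observed > 0)
    n_det = int(mask.sum())
    if n_det < panel.minimum_detected:
        raise ValidationError(
            f"sample detects only {n_det} of {len(panel.entries)} reference peptides "
            f"(minimum {panel.minimum_detected})"
        )
    ratios = panel.entries[mask] / observed[mask]
    return float(np.median(ratios.to_numpy()))


def normalize_matrix(
    matrix: IntensityMatrix, panel: ReferencePanel
) -> tuple[IntensityMatrix, pd.Series, dict[str, str]]:
    """Rescale each sample against the reference panel.

    Returns ``(normalized, factors, flags)`` where ``factors`` maps the
    retained sample ids to their scale factor and ``flags`` maps excluded
    sample ids to the reason for exclusion.  Not-detected entries are
    left not-detected.
    """
    missing = [f for f in panel.feature_ids if f not in matrix.values.index]
    if missing:
        raise ValidationError(f"panel features absent from matrix: {missing[:5]}")
    factors: dict[str, float] = {}
    flags: dict[str, str] = {}
    for s in matrix.sample_ids:
        try:
            factors[s] = compute_scale_factor(matrix.values[s], panel)
        except ValidationError as exc:
            flags[s] = str(exc)
    kept = [s for s in matrix.sample_ids if s in factors]
    if not kept:
        raise ValidationError("no sample passed reference-panel normalization")
    factor_series = pd.Series({s: factors[s] for s in kept})
    values = matrix.values.loc[:, kept].mul(factor_series, axis=1)
    return matrix.with_values(values), factor_series, flags


@dataclass
class TransformedMatrix:
    """Log-scale matrix for statistics: values = log10(1 + intensity).

    ``detected`` marks which entries were measured; non-detected entries
    hold the imputed value 0 and should be interpreted through the mask
    wherever detection itself matters (e.g. frequency thresholds).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    features: list[PeptideFeature] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_design(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples-by-features design matrix (sklearn orientation)."""
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return self.values.loc[:, ids].T


def log_transform(matrix: IntensityMatrix) -> TransformedMatrix:
    """Map detected intensities x -> log10(1 + x); non-detected -> 0."""
    raw = matrix.values.to_numpy(dtype=float)
    if np.isfinite(raw).any() and np.nanmin(raw) < 0:
        raise ValidationError("negative intensity passed to log_transform")
    detected = matrix.detected()
    values = pd.DataFrame(
        np.log10(1.0 + np.nan_to_num(raw, nan=0.0)),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return TransformedMatrix(values=values, detected=detected, features=list(matrix.features))
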