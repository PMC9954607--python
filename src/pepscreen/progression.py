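"""Gleason-progression correlation.

Tumor grade is treated as an ordinal severity scale (non-PCa = 0, then
GS6 < 3+4 < 4+3 < 8 < >=9) under the hypothesis that cancer progresses
as a continuum, so peptides truly tied to progression change gradually
and consistently with grade.  Each feature's log abundance (absences
imputed at 0) is correlated with the ordinal by tie-corrected Spearman
rank correlation; significant features are shortlisted by an overall
detection-frequency floor, and parent proteins are flagged as
consistently regulated when a supermajority of their peptides share the
correlation sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ClinicalRecord, ValidationError
from .normalization import TransformedMatrix

__all__ = [
    "GLEASON_ORDINAL",
    "gleason_ordinals",
    "spearman_per_feature",
    "shortlist",
    "protein_consistency",
]

#: Ordinal encoding of disease severity (non-PCa included at 0).
GLEASON_ORDINAL = {"nonPCa": 0, "6": 1, "3+4": 2, "4+3": 3, "8": 4, ">=9": 5}


def gleason_ordinals(records: dict[str, ClinicalRecord] | list[ClinicalRecord]) -> pd.Series:
    """Map each sample to its severity ordinal."""
    if isinstance(records, dict):
        records = list(records.values())
    out = {}
    for r in records:
        out[r.sample_id] = GLEASON_ORDINAL["nonPCa" if not r.is_case else r.gleason]
    return pd.Series(out, name="gleason_ordinal", dtype=float)


def spearman_per_feature(
    transformed: TransformedMatrix, ordinals: pd.Series
) -> pd.DataFrame:
    """Tie-corrected Spearman rho and two-sided p per feature.

    Columns: feature_id, rho, p_value, frequency (overall detection
    fraction), parent_protein, has_sequence.
    """
    ordinals = pd.Series(ordinals).loc[transformed.sample_ids]
    o = ordinals.to_numpy(dtype=float)
    if np.ptp(o) == 0:
        raise ValidationError("ordinal vector is constant")
    x = transformed.values.loc[:, ordinals.index].to_numpy()
    n = x.shape[1]

    # rank-transform rows and the ordinal, then Pearson on the ranks
    rx = stats.rankdata(x, axis=1)
    ro = stats.rankdata(o)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ro_c = ro - ro.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ro_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ro_c) / denom
    rho = np.where(np.isfinite(rho), rho, 0.0)

    # two-sided p via the t approximation (scipy's default for n > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)

    detected = transformed.detected.loc[:, ordinals.index]
    feats = {f.feature_id: f for f in transformed.features}
    return pd.DataFrame(
        {
            "feature_id": transformed.feature_ids,
            "rho": rho,
            "p_value": p,
            "frequency": detected.mean(axis=1).to_numpy(),
            "parent_protein": [
                feats[fid].parent_protein if fid in feats else None
                for fid in transformed.feature_ids
            ],
            "has_sequence": [
                feats[fid].sequence is not None if fid in feats else False
                for fid in transformed.feature_ids
            ],
        }
    )


def shortlist(
    entries: pd.DataFrame,
    alpha: float = 0.05,
    min_frequency: float = 0.30,
    sequenced_only: bool = False,
) -> pd.DataFrame:
    """Keep significant entries above the detection-frequency floor.

    ``sequenced_only`` additionally requires a sequence annotation
    (mirrors restricting the analysis to sequenced peptides).  Output is
    ordered by (p_value, feature_id).
    """
    if len(entries) == 0:
        return entries.copy()
    keep = (entries["p_value"] < alpha) & (entries["frequency"] >= min_frequency)
    if sequenced_only:
        keep &= entries["has_sequence"].astype(bool)
    return (
        entries.loc[keep]
        .sort_values(["p_value", "feature_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def protein_consistency(entries: pd.DataFrame, min_fraction: float = 0.75) -> pd.DataFrame:
    """Per-parent-protein regulation consistency verdicts.

    For each protein: number of peptides, the majority rho sign, the
    fraction of peptides sharing it, and a pass verdict when that
    fraction is >= ``min_fraction`` (an exact 50/50 tie fails).
    """
    annotated = entries.dropna(subset=["parent_protein"])
    rows = []
    for protein, grp in annotated.groupby("parent_protein", sort=True):
        signs = np.sign(grp["rho"].to_numpy())
        n_pos = int((signs > 0).sum())
        n_neg = int((signs < 0).sum())
        n = len(grp)
        if n_pos == n_neg:
            majority, fraction = 0, 0.5 if n else 0.0
        elif n_pos > n_neg:
            majority, fraction = 1, n_pos / n
        else:
            majority, fraction = -1, n_neg / n
        rows.append(
            {
                "parent_protein": protein,
                "n_peptides": n,
                "majority_sign": majority,
                "consistent_fraction": fraction,
                "passes": bool(fraction >= min_fraction and majority != 0),
            }
        )
    return pd.DataFrame(rows, columns=[
        "parent_protein", "n_peptides", "majority_sign", "consistent_fraction", "passes",
    ])
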