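"""Synthetic cohort generator with ground truth.

Emulates the statistical structure of a urinary CE-MS peptidomics
case-control study so every downstream stage (normalization, discovery,
SVM panel, progression, protease inference) is testable end-to-end:

* log-normal latent peptide intensities with per-feature mean and SD;
* intensity-dependent detection (logistic link on the latent log
  intensity), the realistic hard case for frequency thresholds;
* a set of always-detected reference peptides with small relative
  variation, used as the normalization internal standard;
* planted case-control marker peptides with multiplicative fold changes
  >= 1.2 in either direction, drawn well-detected so a 90% frequency
  threshold can in principle retain them;
* per-marker monotone log-effects across the Gleason ordinal within
  cases (progression signal);
* a per-sample global scale factor emulating urine dilution;
* correlated clinical covariates (age, PSA, prostate volume, DRE, an
  externally supplied ERSPC-style risk probability).

All randomness flows from one seed via named substreams, so edits to one
component do not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_data import (
    ClinicalRecord,
    CohortDataset,
    IntensityMatrix,
    PeptideFeature,
    ValidationError,
    write_clinical,
    write_peptidome,
)
from .normalization import ReferencePanel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_score_replicates",
    "plant_protease_scenario",
    "write_cohort",
]

#: Gleason categories in severity order, with discovery-cohort-style
#: proportions among cases (GS6 46.8%, 3+4 35.3%, 4+3 10.0%, 8 4.3%, >=9 3.6%).
GLEASON_CATEGORIES = ("6", "3+4", "4+3", "8", ">=9")
DEFAULT_GLEASON_PROBS = (0.468, 0.353, 0.100, 0.043, 0.036)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Sample counts per split mirror a two-phase design: a discovery
    case-control split, an independent case-control validation split,
    and a cases-only second validation split.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_cases_validation: int = 150
    n_controls_validation: int = 150
    n_cases_validation2: int = 60
    n_features: int = 2000
    n_markers: int = 181
    n_reference: int = 29
    marker_fold_range: tuple[float, float] = (1.2, 3.0)
    marker_direction_up_fraction: float = 0.8
    base_log_mean: float = 2.0           # mean of per-feature log10 intensity means
    base_log_mean_sd: float = 0.6
    feature_log_sd_range: tuple[float, float] = (0.15, 0.35)
    detection_rate_range: tuple[float, float] = (0.05, 0.99)
    marker_detection_range: tuple[float, float] = (0.90, 0.99)
    detection_slope: float = 1.0         # logit slope per latent SD
    reference_cv: float = 0.05
    sample_scale_sd: float = 0.15        # SD of log10 per-sample scale factor
    progression_slope_range: tuple[float, float] = (0.02, 0.08)  # log10 per GS step
    gleason_probs: tuple[float, ...] = DEFAULT_GLEASON_PROBS
    # clinical covariate shifts (cases vs controls)
    age_mean: float = 63.0
    age_sd: float = 7.0
    age_case_shift: float = 3.0
    psa_median: float = 5.1
    psa_log_sd: float = 0.25
    psa_case_log_shift: float = 0.048    # log10(5.7 / 5.1)
    volume_median: float = 38.0
    volume_log_sd: float = 0.15
    volume_case_log_shift: float = -0.103  # log10(30 / 38)
    dre_suspicious_rate: tuple[float, float] = (0.11, 0.30)  # (controls, cases)
    previous_biopsy_rate: tuple[float, float] = (0.29, 0.18)
    erspc_signal: float = 0.55           # logit shift of ERSPC risk for cases
    seed: int = 0

    def validate(self) -> None:
        if self.n_markers + self.n_reference > self.n_features:
            raise ValidationError("n_markers + n_reference exceeds n_features")
        for p in (self.marker_direction_up_fraction, *self.detection_rate_range,
                  *self.marker_detection_range):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.marker_fold_range[0] < 1.0:
            raise ValidationError("marker fold bounds must be >= 1")
        if abs(sum(self.gleason_probs) - 1.0) > 1e-9:
            raise ValidationError("gleason_probs must sum to 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    markers: pd.DataFrame          # feature_id, direction, fold, progression_slope
    reference_ids: list[str]
    reference_intensities: pd.Series
    sample_scale: pd.Series        # sample_id -> true multiplicative scale
    gleason_ordinal: pd.Series

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["feature_id"])

    def reference_panel(self, minimum_detected: int = 15) -> ReferencePanel:
        return ReferencePanel(self.reference_intensities, minimum_detected=minimum_detected)


def _substream(seed: int, name: str) -> np.random.Generator:
    # crc32 keyed substreams: stable across processes (unlike hash()).
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a cohort with planted structure; deterministic given seed."""
    config.validate()
    n_feat, n_ref, n_mark = config.n_features, config.n_reference, config.n_markers

    width = len(str(n_feat))
    feature_ids = [f"pep_{i + 1:0{width}d}" for i in range(n_feat)]
    ref_ids = feature_ids[:n_ref]
    marker_ids = feature_ids[n_ref:n_ref + n_mark]

    rng_feat = _substream(config.seed, "features")
    mass = np.exp(rng_feat.uniform(np.log(0.8), np.log(15.0), n_feat))
    mig = rng_feat.uniform(10.0, 55.0, n_feat)
    features = [
        PeptideFeature(fid, float(m), float(t)) for fid, m, t in zip(feature_ids, mass, mig)
    ]

    mu = rng_feat.normal(config.base_log_mean, config.base_log_mean_sd, n_feat)
    sigma = rng_feat.uniform(*config.feature_log_sd_range, n_feat)
    base_rate = rng_feat.uniform(*config.detection_rate_range, n_feat)
    base_rate[n_ref:n_ref + n_mark] = rng_feat.uniform(*config.marker_detection_range, n_mark)

    rng_mark = _substream(config.seed, "markers")
    direction = np.where(
        rng_mark.random(n_mark) < config.marker_direction_up_fraction, 1.0, -1.0
    )
    fold = rng_mark.uniform(*config.marker_fold_range, n_mark)
    prog_slope = direction * rng_mark.uniform(*config.progression_slope_range, n_mark)

    # --- samples ---------------------------------------------------------
    splits, outcomes = [], []
    for split, n_case, n_ctrl in [
        ("discovery", config.n_cases, config.n_controls),
        ("validation1", config.n_cases_validation, config.n_controls_validation),
        ("validation2", config.n_cases_validation2, 0),
    ]:
        splits += [split] * (n_case + n_ctrl)
        outcomes += [1] * n_case + [0] * n_ctrl
    n_samp = len(splits)
    sample_ids = [f"s_{i + 1:04d}" for i in range(n_samp)]
    outcome = np.array(outcomes)
    is_case = outcome == 1

    rng_clin = _substream(config.seed, "clinical")
    gleason_idx = np.full(n_samp, -1)
    gleason_idx[is_case] = rng_clin.choice(
        len(GLEASON_CATEGORIES), size=int(is_case.sum()), p=np.array(config.gleason_probs)
    )
    ordinal = np.where(is_case, gleason_idx + 1, 0).astype(float)
    mean_case_ordinal = float(
        np.dot(np.arange(1, len(GLEASON_CATEGORIES) + 1), config.gleason_probs)
    )

    rng_scale = _substream(config.seed, "scale")
    scale = 10.0 ** rng_scale.normal(0.0, config.sample_scale_sd, n_samp)

    # --- latent intensities ---------------------------------------------
    rng_int = _substream(config.seed, "intensity")
    latent_log = mu[:, None] + sigma[:, None] * rng_int.standard_normal((n_feat, n_samp))
    mslice = slice(n_ref, n_ref + n_mark)
    case_shift = direction[:, None] * np.log10(fold)[:, None] * is_case[None, :]
    prog = prog_slope[:, None] * np.where(is_case, ordinal - mean_case_ordinal, 0.0)[None, :]
    latent_log[mslice] += case_shift + prog

    # reference peptides: fixed target intensity with small relative noise
    ref_target = 10.0 ** rng_feat.normal(config.base_log_mean + 0.5, 0.3, n_ref)
    if config.reference_cv > 0:
        ref_sigma = np.sqrt(np.log1p(config.reference_cv**2))
        ref_noise = np.exp(
            rng_int.normal(-0.5 * ref_sigma**2, ref_sigma, (n_ref, n_samp))
        )
    else:
        ref_noise = np.ones((n_ref, n_samp))
    latent = 10.0 ** latent_log
    latent[:n_ref] = ref_target[:, None] * ref_noise

    # --- detection -------------------------------------------------------
    rng_det = _substream(config.seed, "detection")
    z = (latent_log - mu[:, None]) / sigma[:, None]
    logit_rate = logit(np.clip(base_rate, 1e-6, 1 - 1e-6))
    p_det = expit(logit_rate[:, None] + config.detection_slope * z)
    detected = rng_det.random((n_feat, n_samp)) < p_det
    detected[:n_ref] = True

    stored = latent * scale[None, :]
    stored[~detected] = np.nan
    values = pd.DataFrame(stored, index=feature_ids, columns=sample_ids)
    matrix = IntensityMatrix(values, features)

    # --- clinical covariates --------------------------------------------
    age = rng_clin.normal(config.age_mean, config.age_sd, n_samp) + config.age_case_shift * is_case
    age = np.clip(np.round(age, 1), 40.0, 95.0)
    psa = 10.0 ** (
        np.log10(config.psa_median)
        + config.psa_case_log_shift * is_case
        + rng_clin.normal(0.0, config.psa_log_sd, n_samp)
    )
    volume = 10.0 ** (
        np.log10(config.volume_median)
        + config.volume_case_log_shift * is_case
        + rng_clin.normal(0.0, config.volume_log_sd, n_samp)
    )
    dre_rate = np.where(is_case, config.dre_suspicious_rate[1], config.dre_suspicious_rate[0])
    dre = np.where(rng_clin.random(n_samp) < dre_rate, "suspicious", "normal")
    biopsy_rate = np.where(is_case, config.previous_biopsy_rate[1], config.previous_biopsy_rate[0])
    prev_biopsy = rng_clin.random(n_samp) < biopsy_rate
    erspc = expit(
        logit(0.3) + config.erspc_signal * np.where(is_case, 1.0, -1.0)
        + rng_clin.normal(0.0, 1.0, n_samp)
    )
    subtype = rng_clin.choice(["BPH", "PIN", "ASAP"], size=n_samp, p=[0.88, 0.066, 0.054])

    records: dict[str, ClinicalRecord] = {}
    for j, sid in enumerate(sample_ids):
        case = bool(is_case[j])
        gleason = GLEASON_CATEGORIES[gleason_idx[j]] if case else "none"
        records[sid] = ClinicalRecord(
            sample_id=sid,
            age=float(age[j]),
            psa=float(psa[j]),
            prostate_volume=float(volume[j]),
            dre=str(dre[j]),
            previous_biopsy=bool(prev_biopsy[j]),
            outcome="PCa" if case else "nonPCa",
            nonpca_subtype="none" if case else str(subtype[j]),
            gleason=gleason,
            risk_group=_damico(gleason, float(psa[j])) if case else "none",
            erspc_risk=float(erspc[j]),
            center="center2" if splits[j] == "validation2" else "center1",
        )

    dataset = CohortDataset(matrix, records, pd.Series(splits, index=sample_ids))
    truth = GroundTruth(
        markers=pd.DataFrame(
            {
                "feature_id": marker_ids,
                "direction": np.where(direction > 0, "up", "down"),
                "fold": fold,
                "progression_slope": prog_slope,
            }
        ),
        reference_ids=ref_ids,
        reference_intensities=pd.Series(ref_target, index=ref_ids),
        sample_scale=pd.Series(scale, index=sample_ids),
        gleason_ordinal=pd.Series(ordinal, index=sample_ids),
    )
    return dataset, truth


def _damico(gleason: str, psa: float) -> str:
    """Simplified D'Amico risk grouping from Gleason pattern and PSA."""
    if gleason in {"8", ">=9"} or psa > 20.0:
        return "high"
    if gleason == "6" and psa < 10.0:
        return "low"
    return "intermediate"


def simulate_score_replicates(
    n: int,
    mean: float,
    cv: float,
    seed: int = 0,
    score_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Replicate classification scores with a target coefficient of variation.

    Emulates repeated CE-MS acquisitions of one standard urine sample:
    scores are normal with SD = ``|mean| * cv``, optionally truncated to
    ``score_range`` by resampling.
    """
    if n < 2:
        raise ValidationError("need at least 2 replicate scores")
    if mean == 0 and cv > 0:
        raise ValidationError("CV is undefined for mean 0")
    rng = np.random.default_rng(seed)
    sd = abs(mean) * cv
    scores = rng.normal(mean, sd, n)
    if score_range is not None:
        lo, hi = score_range
        for _ in range(1000):
            bad = (scores < lo) | (scores > hi)
            if not bad.any():
                break
            scores[bad] = rng.normal(mean, sd, int(bad.sum()))
        scores = np.clip(scores, lo, hi)
    return scores


def plant_protease_scenario(
    dataset: CohortDataset,
    truth: GroundTruth,
    n_marker_annotated: int = 40,
    n_null_annotated: int = 120,
    peptides_per_protein: int = 5,
    planted_site: str = "GPAGPQGP",
    n_decoys: int = 6,
    decoy_sites_range: tuple[int, int] = (6, 10),
    seed: int = 0,
):
    """Annotate a cohort with sequences so one protease is recoverable.

    A subset of up-regulated marker peptides is embedded in synthetic
    parent proteins such that every one of their N-terminal cleavage
    windows equals ``planted_site`` — the signature of one planted
    protease.  A larger set of null peptides gets random sequences, and
    decoy proteases are built from the actual C-terminal windows of
    null peptides (so they match real events but carry no progression
    signal).  One undersized decoy with only 4 sites exercises the
    minimum-cleavage-site exclusion rule.

    Returns ``(annotated_dataset, parents, spec_records, planted_id)``.
    """
    from .protease import AMINO_ACIDS, ProteaseSpecRecord, extract_cleavage_sites

    if len(planted_site) != 8:
        raise ValidationError("planted_site must be 8 residues")
    rng = np.random.default_rng(seed)

    up_all = [
        fid for fid, d in zip(truth.markers["feature_id"], truth.markers["direction"])
        if d == "up"
    ]
    up_ids = up_all[:min(n_marker_annotated, len(up_all))]
    if len(up_ids) < 5:
        raise ValidationError("not enough up-regulated markers to annotate")
    taken = set(up_ids) | set(truth.reference_ids) | set(truth.marker_ids)
    null_ids = [f for f in dataset.matrix.feature_ids if f not in taken][:n_null_annotated]

    def _random_seq(n: int) -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=n))

    annotations: dict[str, tuple[str, str, int, int]] = {}
    parents: dict[str, str] = {}

    def _build_protein(name: str, fids: list[str], planted: bool) -> None:
        pos = 0
        chunks: list[str] = []
        for fid in fids:
            pep = _random_seq(int(rng.integers(10, 26)))
            if planted:
                pep = planted_site[4:] + pep[4:]
                linker = _random_seq(4) + planted_site[:4]
            else:
                linker = _random_seq(8)
            chunks.append(linker)
            pos += len(linker)
            start = pos + 1
            chunks.append(pep)
            pos += len(pep)
            annotations[fid] = (name, pep, start, pos)
        chunks.append(_random_seq(8))  # tail so the last C-window is full
        parents[name] = "".join(chunks)

    for i in range(0, len(up_ids), peptides_per_protein):
        _build_protein(f"SYN_COLM_{i // peptides_per_protein + 1:02d}",
                       up_ids[i:i + peptides_per_protein], planted=True)
    for i in range(0, len(null_ids), peptides_per_protein):
        _build_protein(f"SYN_PROT_{i // peptides_per_protein + 1:02d}",
                       null_ids[i:i + peptides_per_protein], planted=False)

    new_features = []
    for feat in dataset.matrix.features:
        if feat.feature_id in annotations:
            prot, pep, start, end = annotations[feat.feature_id]
            feat = PeptideFeature(
                feature_id=feat.feature_id, mass=feat.mass,
                migration_time=feat.migration_time, sequence=pep,
                parent_protein=prot, start_pos=start, end_pos=end,
            )
        new_features.append(feat)
    matrix = IntensityMatrix(dataset.matrix.values, new_features)
    annotated = CohortDataset(matrix, dataset.clinical, dataset.split_labels)

    # decoy sites: real C-terminal windows of null peptides
    null_c_sites = []
    for fid in null_ids:
        feat = matrix.feature(fid)
        for e in extract_cleavage_sites(feat, parents[feat.parent_protein]):
            if e.terminus == "C" and not e.truncated:
                null_c_sites.append(e.site)
    rng.shuffle(null_c_sites)

    planted_id = "PLANTED_PROT"
    records = [
        ProteaseSpecRecord(
            protease_id=planted_id, accession="SYN00001", symbol="PLNT1",
            mode="exact", sites=[planted_site],
        )
    ]
    cursor = 0
    for d in range(n_decoys):
        k = int(rng.integers(decoy_sites_range[0], decoy_sites_range[1] + 1))
        sites = null_c_sites[cursor:cursor + k]
        cursor += k
        records.append(
            ProteaseSpecRecord(
                protease_id=f"DECOY_{d + 1:02d}", accession=f"SYN1{d:04d}",
                symbol=f"DEC{d + 1}", mode="exact", sites=sites,
            )
        )
    records.append(
        ProteaseSpecRecord(
            protease_id="DECOY_SMALL", accession="SYN99999", symbol="DECS",
            mode="exact", sites=null_c_sites[cursor:cursor + 4],
        )
    )
    return annotated, parents, records, planted_id


def write_cohort(
    dataset: CohortDataset,
    truth: GroundTruth,
    outdir: str | Path,
    fmt: str = "wide",
) -> dict[str, Path]:
    """Write peptidome, clinical table, splits and ground truth to a directory."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptidome": outdir / ("peptidome.tsv" if fmt == "wide" else "peptidome.csv"),
        "clinical": outdir / "clinical.csv",
        "splits": outdir / "splits.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_peptidome(dataset.matrix, paths["peptidome"], fmt=fmt)
    write_clinical([dataset.clinical[s] for s in dataset.sample_ids], paths["clinical"])
    if dataset.split_labels is not None:
        dataset.split_labels.rename("split").rename_axis("sample_id").to_csv(paths["splits"])
    payload = {
        "markers": truth.markers.to_dict("records"),
        "reference_intensities": truth.reference_intensities.to_dict(),
        "sample_scale": truth.sample_scale.to_dict(),
        "gleason_ordinal": truth.gleason_ordinal.to_dict(),
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=1))
    return paths
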