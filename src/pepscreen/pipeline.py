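"""End-to-end orchestration of the peptidomics analysis.

Stages: simulate or ingest -> reference-panel normalization -> log
transform -> case-control discovery (discovery split only) -> SVM panel
training + cross-validation -> Youden cutoff -> scoring of the
validation splits -> diagnostic evaluation, comparator models, nomogram
and decision-curve analysis -> Gleason-progression correlation ->
protease-activity inference.  A manifest (config, seed, input
checksums) makes runs reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .clinical_utility import NetBenefitCurve, NomogramModel, ScoreCalibrator, dca_curves, fit_nomogram
from .core_data import CohortDataset, ValidationError, join_cohort, read_clinical, read_fasta, read_peptidome
from .discovery import BiomarkerPanel, feature_stats, select_panel
from .evaluation import (
    DiagnosticPerformance,
    delong_compare,
    kruskal_wallis,
    operating_point,
    roc_auc,
)
from .normalization import ReferencePanel, log_transform, normalize_matrix
from .progression import gleason_ordinals, protein_consistency, shortlist, spearman_per_feature
from .protease import (
    ProteaseActivityResult,
    extract_cleavage_sites,
    read_spec_table,
    results_table,
    score_all_proteases,
)
from .svm_panel import PanelModel, cross_validate, fix_cutoff, score_samples, train_model
from .synthetic import GroundTruth, SimulationConfig, plant_protease_scenario, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_models"]

RISK_ORDER = ["nonPCa", "low", "intermediate", "high"]


@dataclass
class RunConfig:
    """All stage parameters with their conventional defaults."""

    simulation: SimulationConfig | None = None
    # file inputs (used when simulation is None)
    peptidome_path: str | None = None
    peptidome_format: str = "wide"
    clinical_path: str | None = None
    splits_path: str | None = None
    reference_panel_path: str | None = None
    parent_fasta_path: str | None = None
    protease_spec_path: str | None = None
    # stage parameters
    alpha: float = 0.05
    freq_threshold: float = 0.90
    min_reference_detected: int = 15
    svm_c: float = 16.0
    svm_gamma: float = 0.01
    cv_scheme: str = "loo"
    cv_folds: int = 10
    cutoff: float | None = None          # None -> Youden on out-of-fold scores
    prevalence: float = 0.40
    dca_grid_stop: float = 0.60
    dca_grid_step: float = 0.01
    progression_alpha: float = 0.05
    progression_min_frequency: float = 0.30
    sequenced_only: bool = False
    consistency_min_fraction: float = 0.75
    protease_min_sites: int = 5
    annotate_proteases: bool = True      # plant sequences when simulating
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = payload.pop("simulation", None)
        config = RunConfig(**payload)
        if sim is not None:
            config.simulation = SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            )
        return config

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    config: RunConfig
    dataset: CohortDataset
    truth: GroundTruth | None
    normalization_factors: pd.Series
    normalization_flags: dict[str, str]
    discovery_stats: pd.DataFrame
    panel: BiomarkerPanel
    model: PanelModel
    cv_scores: pd.Series
    cv_auc: float
    cutoff: float
    validation_scores: pd.Series
    validation_performance: DiagnosticPerformance | None
    comparison: pd.DataFrame | None
    nomogram: NomogramModel | None
    nomogram_auc: float | None
    dca: NetBenefitCurve | None
    validation2_sensitivity: float | None
    validation2_by_risk: pd.DataFrame | None
    validation2_kruskal: tuple[float, float] | None
    progression_entries: pd.DataFrame
    progression_shortlist: pd.DataFrame
    protein_verdicts: pd.DataFrame
    protease_results: list[ProteaseActivityResult]
    manifest: dict[str, Any]


def _sha256_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.simulation.seed or config.seed)
        dataset, truth = simulate_cohort(sim)
        parents: dict[str, str] = {}
        spec_records = []
        if config.annotate_proteases:
            dataset, parents, spec_records, planted = plant_protease_scenario(
                dataset, truth, seed=sim.seed
            )
        ref_panel = truth.reference_panel(config.min_reference_detected)
        return dataset, truth, ref_panel, parents, spec_records
    if not (config.peptidome_path and config.clinical_path and config.reference_panel_path):
        raise ValidationError("file mode requires peptidome, clinical and reference panel paths")
    matrix = read_peptidome(config.peptidome_path, fmt=config.peptidome_format)
    clinical = read_clinical(config.clinical_path)
    splits = None
    if config.splits_path:
        s = pd.read_csv(config.splits_path, dtype=str)
        splits = pd.Series(s["split"].to_numpy(), index=s["sample_id"])
    dataset, _ = join_cohort(matrix, clinical, splits=splits)
    panel_df = pd.read_csv(config.reference_panel_path, sep="\t", dtype={"feature_id": str})
    ref_panel = ReferencePanel(
        pd.Series(panel_df["intensity"].to_numpy(), index=panel_df["feature_id"]),
        minimum_detected=config.min_reference_detected,
    )
    parents = read_fasta(config.parent_fasta_path) if config.parent_fasta_path else {}
    spec_records = read_spec_table(config.protease_spec_path) if config.protease_spec_path else []
    return dataset, None, ref_panel, parents, spec_records


def compare_models(labels: pd.Series, model_scores: pd.DataFrame) -> pd.DataFrame:
    """AUC (with CI) per score column and paired DeLong test vs the first.

    Complete-case: samples with any missing score column are dropped
    (the count is reported in the ``n_dropped`` attribute-free column).
    """
    merged = model_scores.copy()
    for col in merged.columns:
        if col not in merged:
            raise ValidationError(f"comparator column {col!r} absent")
    complete = merged.dropna()
    y = pd.Series(labels).loc[complete.index]
    reference = complete.columns[0]
    rows = []
    for col in complete.columns:
        auc, lo, hi = roc_auc(complete[col], y)
        if col == reference:
            delta, p = 0.0, 1.0
        else:
            delta, p = delong_compare(complete[reference], complete[col], y)
        rows.append(
            {
                "model": col, "auc": auc, "auc_lo": lo, "auc_hi": hi,
                "delong_delta_vs_reference": delta, "delong_p_vs_reference": p,
                "n": len(complete), "n_dropped": len(merged) - len(complete),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; deterministic given config (incl. seed)."""
    dataset, truth, ref_panel, parents, spec_records = _load_inputs(config)

    # --- normalization + transform --------------------------------------
    normalized, factors, flags = normalize_matrix(dataset.matrix, ref_panel)
    kept = normalized.sample_ids
    transformed = log_transform(normalized)

    has_splits = dataset.split_labels is not None
    disc_ids = [s for s in dataset.split("discovery") if s in kept] if has_splits else kept
    val_ids = [s for s in dataset.split("validation1") if s in kept] if has_splits else []
    val2_ids = [s for s in dataset.split("validation2") if s in kept] if has_splits else []

    labels_disc = dataset.outcome_labels(disc_ids)

    # --- discovery (discovery split only) -------------------------------
    disc_matrix = normalized.subset_samples(disc_ids)
    stats_df = feature_stats(disc_matrix, labels_disc)
    panel = select_panel(stats_df, alpha=config.alpha, freq_threshold=config.freq_threshold)
    if len(panel) == 0:
        raise ValidationError("discovery selected an empty biomarker panel")

    # --- SVM panel -------------------------------------------------------
    model = train_model(
        transformed, labels_disc, panel,
        svm_c=config.svm_c, svm_gamma=config.svm_gamma, seed=config.seed,
    )
    cv_scores = cross_validate(
        transformed, labels_disc, panel, scheme=config.cv_scheme,
        n_folds=config.cv_folds, svm_c=config.svm_c, svm_gamma=config.svm_gamma,
        seed=config.seed,
    )
    cv_ok = cv_scores.notna()
    cv_auc, _, _ = roc_auc(cv_scores[cv_ok], labels_disc[cv_ok])
    cutoff = config.cutoff if config.cutoff is not None else fix_cutoff(
        cv_scores[cv_ok], labels_disc[cv_ok]
    )
    model.cutoff = float(cutoff)

    # --- validation 1 ----------------------------------------------------
    validation_performance = None
    comparison = None
    nomogram = None
    nomogram_auc = None
    dca = None
    if val_ids:
        val_scores, _ = score_samples(model, transformed, val_ids)
        labels_val = dataset.outcome_labels(val_ids)
        validation_performance = operating_point(
            val_scores, labels_val, cutoff=cutoff, prevalence=config.prevalence
        )
        clin = dataset.clinical_frame().set_index("sample_id").loc[val_ids]
        scores_frame = pd.DataFrame(
            {
                "panel_score": val_scores,
                "psa": pd.to_numeric(clin["psa"], errors="coerce"),
                "psa_density": pd.to_numeric(clin["psa_density"], errors="coerce"),
                "erspc": pd.to_numeric(clin["erspc_risk"], errors="coerce"),
            }
        )
        comparison = compare_models(labels_val, scores_frame)

        nomo_frame = scores_frame.assign(
            age=pd.to_numeric(clin["age"], errors="coerce"),
            outcome=labels_val,
        )
        try:
            nomogram = fit_nomogram(
                nomo_frame, ["panel_score", "age", "psa_density", "erspc"], outcome="outcome"
            )
            fitted = nomogram.fitted_probabilities
            nomogram_auc, _, _ = roc_auc(fitted, labels_val.loc[fitted.index])
        except ValidationError:
            # (quasi-)separated covariates on a small validation split:
            # report the panel alone rather than divergent coefficients
            nomogram, nomogram_auc = None, None

        calibrator = ScoreCalibrator.fit(cv_scores[cv_ok], labels_disc[cv_ok])
        grid = np.round(
            np.arange(config.dca_grid_step, config.dca_grid_stop + 1e-9, config.dca_grid_step), 10
        )
        strategies = {"panel": calibrator(val_scores.to_numpy())}
        for name in ("psa", "psa_density", "erspc"):
            col = scores_frame[name]
            if col.notna().all():
                cal = ScoreCalibrator.fit(col, labels_val)
                strategies[name] = cal(col.to_numpy())
        if nomogram is not None:
            strategies["nomogram"] = (
                nomogram.predict(nomo_frame.dropna()).reindex(val_ids).to_numpy()
            )
        usable = {k: v for k, v in strategies.items() if not np.isnan(v).any()}
        dca = dca_curves(labels_val, usable, grid=grid)

    # --- validation 2 (cases only) ---------------------------------------
    validation2_sensitivity = None
    validation2_by_risk = None
    validation2_kruskal = None
    if val2_ids:
        v2_scores, _ = score_samples(model, transformed, val2_ids)
        validation2_sensitivity = float((v2_scores >= cutoff).mean())
        risk = pd.Series({s: dataset.clinical[s].risk_group for s in val2_ids})
        validation2_by_risk = (
            pd.DataFrame({"score": v2_scores, "risk_group": risk})
            .groupby("risk_group")["score"]
            .agg(["count", "mean"])
            .reindex([r for r in RISK_ORDER if r != "nonPCa"])
            .dropna()
        )
        if risk.nunique() >= 2:
            validation2_kruskal = kruskal_wallis(v2_scores.to_numpy(), risk)

    # --- progression (full development cohort) ---------------------------
    dev_ids = [s for s in kept if s not in val2_ids] if has_splits else kept
    ordinals = gleason_ordinals({s: dataset.clinical[s] for s in dev_ids})
    dev_transformed = log_transform(normalized.subset_samples(dev_ids))
    progression_entries = spearman_per_feature(dev_transformed, ordinals)
    progression_short = shortlist(
        progression_entries,
        alpha=config.progression_alpha,
        min_frequency=config.progression_min_frequency,
        sequenced_only=config.sequenced_only,
    )
    verdicts = protein_consistency(
        progression_short, min_fraction=config.consistency_min_fraction
    )

    # --- protease activity ------------------------------------------------
    protease_results: list[ProteaseActivityResult] = []
    if parents and spec_records:
        events = []
        for feat in dataset.matrix.features:
            if feat.sequence is None or feat.parent_protein not in parents:
                continue
            events.extend(extract_cleavage_sites(feat, parents[feat.parent_protein]))
        stats_idx = progression_entries.set_index("feature_id")
        protease_results = score_all_proteases(
            events, spec_records, stats_idx, min_sites=config.protease_min_sites
        )

    manifest = {
        "pepscreen_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_samples": dataset.matrix.n_samples,
        "n_features": dataset.matrix.n_features,
        "discovery_samples_sha256": hashlib.sha256(
            ",".join(disc_ids).encode()
        ).hexdigest(),
        "discovery_design_sha256": _sha256_frame(
            transformed.samples_design(disc_ids).loc[:, panel.feature_ids]
        ),
        "panel_size": len(panel),
        "cutoff": float(cutoff),
    }

    result = PipelineResult(
        config=config,
        dataset=dataset,
        truth=truth,
        normalization_factors=factors,
        normalization_flags=flags,
        discovery_stats=stats_df,
        panel=panel,
        model=model,
        cv_scores=cv_scores,
        cv_auc=float(cv_auc),
        cutoff=float(cutoff),
        validation_scores=(
            score_samples(model, transformed, val_ids)[0] if val_ids else pd.Series(dtype=float)
        ),
        validation_performance=validation_performance,
        comparison=comparison,
        nomogram=nomogram,
        nomogram_auc=nomogram_auc,
        dca=dca,
        validation2_sensitivity=validation2_sensitivity,
        validation2_by_risk=validation2_by_risk,
        validation2_kruskal=validation2_kruskal,
        progression_entries=progression_entries,
        progression_shortlist=progression_short,
        protein_verdicts=verdicts,
        protease_results=protease_results,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _panel_table(result: PipelineResult) -> pd.DataFrame:
    """Panel report with the conventional columns (mass, CE time,
    sequence, parent protein, p/q, progression rho)."""
    feats = {f.feature_id: f for f in result.dataset.matrix.features}
    rho = result.progression_entries.set_index("feature_id")["rho"]
    rows = []
    for _, e in result.panel.entries.iterrows():
        f = feats[e["feature_id"]]
        rows.append(
            {
                "feature_id": f.feature_id,
                "mass_da": f.mass * 1000.0,
                "ce_time_min": f.migration_time,
                "sequence": f.sequence or "",
                "parent_protein": f.parent_protein or "",
                "p_value": e["p_value"],
                "q_value": e["q_value"],
                "fold_change": e["fold_change"],
                "direction": e["direction"],
                "rho": rho.get(f.feature_id, np.nan),
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _panel_table(result).to_csv(outdir / "panel.tsv", sep="\t", index=False)
    result.discovery_stats.to_csv(outdir / "discovery_stats.tsv", sep="\t", index=False)
    result.cv_scores.rename("score").rename_axis("sample_id").to_csv(outdir / "cv_scores.csv")
    if len(result.validation_scores):
        result.validation_scores.rename("score").rename_axis("sample_id").to_csv(
            outdir / "validation_scores.csv"
        )
    if result.comparison is not None:
        result.comparison.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
    if result.dca is not None:
        result.dca.curves.to_csv(outdir / "dca.tsv", sep="\t")
    result.progression_shortlist.to_csv(outdir / "progression_shortlist.tsv", sep="\t", index=False)
    result.protein_verdicts.to_csv(outdir / "protein_consistency.tsv", sep="\t", index=False)
    results_table(result.protease_results).to_csv(outdir / "proteases.tsv", sep="\t", index=False)

    summary: dict[str, Any] = {
        "panel_size": len(result.panel),
        "cv_auc": result.cv_auc,
        "cutoff": result.cutoff,
    }
    if result.validation_performance is not None:
        perf = result.validation_performance
        summary["validation"] = {
            "auc": perf.auc, "auc_ci": list(perf.auc_ci),
            "sensitivity": perf.sensitivity, "specificity": perf.specificity,
            "npv": perf.npv, "ppv": perf.ppv, "prevalence": perf.prevalence,
        }
    if result.validation2_sensitivity is not None:
        summary["validation2_sensitivity"] = result.validation2_sensitivity
    if result.nomogram_auc is not None:
        summary["nomogram_auc"] = result.nomogram_auc
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
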