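"""Domain types and file I/O for urinary peptidome cohorts.

The central containers are :class:`IntensityMatrix` (features x samples,
with an explicit "not detected" state kept distinct from an intensity of
zero) and :class:`ClinicalRecord` (per-patient covariates and biopsy
outcome).  Peptidome matrices are exchanged as a wide TSV (one row per
peptide feature, one column per sample; empty cell = not detected) or a
long CSV; clinical tables as CSV.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PeptideFeature",
    "IntensityMatrix",
    "ClinicalRecord",
    "CohortDataset",
    "read_peptidome",
    "write_peptidome",
    "read_clinical",
    "write_clinical",
    "clinical_to_frame",
    "read_fasta",
    "write_fasta",
    "join_cohort",
]

#: Default CE migration-time window (minutes) accepted by validation.
MIGRATION_WINDOW = (10.0, 55.0)

DRE_VALUES = {"normal", "suspicious", "missing"}
OUTCOME_VALUES = {"PCa", "nonPCa"}
NONPCA_SUBTYPES = {"BPH", "PIN", "ASAP", "none"}
GLEASON_VALUES = {"6", "3+4", "4+3", "8", ">=9", "none"}
RISK_GROUPS = {"low", "intermediate", "high", "none"}

_FEATURE_COLUMNS = [
    "feature_id",
    "mass_kda",
    "migration_time_min",
    "sequence",
    "parent_protein",
    "start_pos",
    "end_pos",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class PeptideFeature:
    """One CE-MS-defined peptide.

    ``mass`` is in kDa and ``migration_time`` in normalized minutes.
    ``sequence`` may carry lowercase modification marks (e.g. 'p' for
    hydroxyproline, 'm' for oxidized methionine, 'q' for deamidation);
    the unmodified residue is the uppercase letter.  ``start_pos`` /
    ``end_pos`` are 1-based inclusive coordinates in ``parent_protein``.
    """

    feature_id: str
    mass: float
    migration_time: float
    sequence: str | None = None
    parent_protein: str | None = None
    start_pos: int | None = None
    end_pos: int | None = None

    def unmodified_sequence(self) -> str | None:
        if self.sequence is None:
            return None
        return self.sequence.upper()

    def validate(self, migration_window: tuple[float, float] = MIGRATION_WINDOW) -> None:
        if not self.mass > 0:
            raise ValidationError(f"{self.feature_id}: mass must be > 0, got {self.mass}")
        lo, hi = migration_window
        if not (lo <= self.migration_time <= hi):
            raise ValidationError(
                f"{self.feature_id}: migration time {self.migration_time} outside "
                f"instrument window [{lo}, {hi}]"
            )
        if (self.start_pos is None) != (self.end_pos is None):
            raise ValidationError(f"{self.feature_id}: start_pos/end_pos must be given together")
        if self.sequence is not None and self.start_pos is not None:
            expected = self.end_pos - self.start_pos + 1
            if expected != len(self.sequence):
                raise ValidationError(
                    f"{self.feature_id}: coordinates span {expected} residues but "
                    f"sequence has {len(self.sequence)}"
                )


class IntensityMatrix:
    """Features x samples intensity matrix with explicit non-detection.

    ``values`` is a float DataFrame indexed by feature_id with one column
    per sample; ``NaN`` encodes "not detected" (distinct from a detected
    intensity of exactly 0).
    """

    def __init__(self, values: pd.DataFrame, features: Sequence[PeptideFeature]):
        feature_ids = [f.feature_id for f in features]
        if list(values.index) != feature_ids:
            raise ValidationError("values index must equal the feature_id list, in order")
        if len(set(feature_ids)) != len(feature_ids):
            dup = pd.Index(feature_ids)[pd.Index(feature_ids).duplicated()][0]
            raise FormatError(f"duplicate feature_id {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        with np.errstate(invalid="ignore"):
            neg = values.to_numpy(dtype=float) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative intensity at feature {values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self.values = values.astype(float)
        self.features = list(features)
        self._by_id = {f.feature_id: f for f in self.features}

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature(self, feature_id: str) -> PeptideFeature:
        return self._by_id[feature_id]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (feature, sample) entries."""
        return self.values.notna()

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[:, list(sample_ids)], self.features)

    def with_values(self, values: pd.DataFrame) -> "IntensityMatrix":
        return IntensityMatrix(values, self.features)

    def equals(self, other: "IntensityMatrix") -> bool:
        return (
            self.features == other.features
            and list(self.values.columns) == list(other.values.columns)
            and self.values.equals(other.values)
        )


@dataclass
class ClinicalRecord:
    """Per-patient covariates, biopsy outcome and tumor grading."""

    sample_id: str
    age: float
    psa: float
    outcome: str
    prostate_volume: float | None = None
    psa_density: float | None = None
    dre: str = "missing"
    previous_biopsy: bool = False
    nonpca_subtype: str = "none"
    gleason: str = "none"
    risk_group: str = "none"
    erspc_risk: float | None = None
    center: str = "center1"

    #: |psa/volume - psa_density| tolerance when both are present.
    PSAD_ATOL = 0.011

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_VALUES:
            raise ValidationError(f"{self.sample_id}: unknown outcome {self.outcome!r}")
        if self.dre not in DRE_VALUES:
            raise ValidationError(f"{self.sample_id}: unknown DRE category {self.dre!r}")
        if self.nonpca_subtype not in NONPCA_SUBTYPES:
            raise ValidationError(f"{self.sample_id}: unknown subtype {self.nonpca_subtype!r}")
        if self.gleason not in GLEASON_VALUES:
            raise ValidationError(f"{self.sample_id}: unknown Gleason {self.gleason!r}")
        if self.risk_group not in RISK_GROUPS:
            raise ValidationError(f"{self.sample_id}: unknown risk group {self.risk_group!r}")
        if self.outcome == "PCa":
            if self.gleason == "none":
                raise ValidationError(f"{self.sample_id}: PCa record requires a Gleason score")
        else:
            if self.gleason != "none":
                raise ValidationError(f"{self.sample_id}: Gleason given for non-PCa record")
            if self.risk_group != "none":
                raise ValidationError(f"{self.sample_id}: risk group given for non-PCa record")
        if self.erspc_risk is not None and not (0.0 <= self.erspc_risk <= 1.0):
            raise ValidationError(f"{self.sample_id}: erspc_risk outside [0, 1]")
        if self.psa_density is None and self.prostate_volume:
            self.psa_density = self.psa / self.prostate_volume
        elif self.psa_density is not None and self.prostate_volume:
            derived = self.psa / self.prostate_volume
            if abs(derived - self.psa_density) > self.PSAD_ATOL:
                raise ValidationError(
                    f"{self.sample_id}: psa_density {self.psa_density} inconsistent with "
                    f"psa/volume = {derived:.4f}"
                )

    @property
    def is_case(self) -> bool:
        return self.outcome == "PCa"


@dataclass
class CohortDataset:
    """A peptidome matrix joined with clinical records and split labels."""

    matrix: IntensityMatrix
    clinical: dict[str, ClinicalRecord]
    split_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.matrix.sample_ids if s not in self.clinical]
        if missing:
            raise ValidationError(f"samples without clinical record: {missing[:5]}")
        if self.split_labels is not None:
            unknown = set(self.split_labels.index) - set(self.matrix.sample_ids)
            if unknown:
                raise ValidationError(f"split labels for unknown samples: {sorted(unknown)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    def outcome_labels(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        """1 for PCa, 0 for nonPCa."""
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return pd.Series({s: int(self.clinical[s].is_case) for s in ids}, name="outcome")

    def split(self, label: str) -> list[str]:
        if self.split_labels is None:
            raise ValidationError("dataset carries no split labels")
        return [s for s in self.matrix.sample_ids if self.split_labels.get(s) == label]

    def clinical_frame(self) -> pd.DataFrame:
        return clinical_to_frame([self.clinical[s] for s in self.sample_ids])


# ---------------------------------------------------------------------------
# Peptidome I/O
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, feature_id: str, sample_id: str) -> float:
    if raw == "" or raw.lower() == "nd":
        return math.nan
    try:
        value = float(raw)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity {raw!r} at ({feature_id}, {sample_id})") from exc
    if value < 0:
        raise ValidationError(f"negative intensity at feature {feature_id!r}, sample {sample_id!r}")
    return value


def _feature_from_row(row: Mapping[str, str], mass_unit: str) -> PeptideFeature:
    mass = float(row["mass_kda"])
    if mass_unit == "da":
        mass = mass / 1000.0
    seq = row.get("sequence") or None
    start = row.get("start_pos") or None
    end = row.get("end_pos") or None
    return PeptideFeature(
        feature_id=str(row["feature_id"]),
        mass=mass,
        migration_time=float(row["migration_time_min"]),
        sequence=seq,
        parent_protein=row.get("parent_protein") or None,
        start_pos=int(start) if start else None,
        end_pos=int(end) if end else None,
    )


def read_peptidome(path: str | Path, fmt: str = "wide", mass_unit: str = "kda") -> IntensityMatrix:
    """Read a peptidome matrix from the wide TSV or long CSV dialect.

    Empty cells mean "not detected" and are never coerced to zero; a
    literal 0 is a detected intensity of zero.  ``mass_unit='da'``
    converts input masses from Da to the stored kDa.
    """
    path = Path(path)
    if fmt not in {"wide", "long"}:
        raise FormatError(f"unknown peptidome format {fmt!r}")
    sep = "\t" if fmt == "wide" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = set(_FEATURE_COLUMNS)
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    if fmt == "wide":
        sample_cols = [c for c in df.columns if c not in _FEATURE_COLUMNS]
        if df["feature_id"].duplicated().any():
            dup = df["feature_id"][df["feature_id"].duplicated()].iloc[0]
            raise FormatError(f"{path}: duplicate feature_id {dup!r}")
        features = [_feature_from_row(row, mass_unit) for row in df.to_dict("records")]
        data = {
            s: [_parse_cell(v, fid, s) for fid, v in zip(df["feature_id"], df[s])]
            for s in sample_cols
        }
        values = pd.DataFrame(data, index=list(df["feature_id"]), dtype=float)
        return IntensityMatrix(values, features)

    # long CSV: one row per (feature, sample); intensity "" = not detected.
    if "sample_id" not in df.columns or "intensity" not in df.columns:
        raise FormatError(f"{path}: long format requires sample_id and intensity columns")
    features = []
    seen: dict[str, PeptideFeature] = {}
    for row in df.to_dict("records"):
        fid = str(row["feature_id"])
        if fid not in seen:
            feat = _feature_from_row(row, mass_unit)
            seen[fid] = feat
            features.append(feat)
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    values = pd.DataFrame(
        math.nan, index=[f.feature_id for f in features], columns=sample_ids, dtype=float
    )
    filled: set[tuple[str, str]] = set()
    for row in df.to_dict("records"):
        key = (str(row["feature_id"]), str(row["sample_id"]))
        if key in filled:
            raise FormatError(f"{path}: duplicate entry for {key}")
        filled.add(key)
        values.loc[key[0], key[1]] = _parse_cell(row["intensity"], key[0], key[1])
    return IntensityMatrix(values, features)


def _feature_fields(feat: PeptideFeature) -> dict[str, str]:
    return {
        "feature_id": feat.feature_id,
        "mass_kda": repr(feat.mass),
        "migration_time_min": repr(feat.migration_time),
        "sequence": feat.sequence or "",
        "parent_protein": feat.parent_protein or "",
        "start_pos": str(feat.start_pos) if feat.start_pos is not None else "",
        "end_pos": str(feat.end_pos) if feat.end_pos is not None else "",
    }


def write_peptidome(matrix: IntensityMatrix, path: str | Path, fmt: str = "wide") -> None:
    """Write ``matrix`` in the wide TSV (default) or long CSV dialect.

    Round-trips bit-exactly with :func:`read_peptidome`: floats are
    serialized with ``repr`` and non-detection as the empty string.
    """
    path = Path(path)
    if fmt == "wide":
        rows = []
        for feat in matrix.features:
            row = _feature_fields(feat)
            for s in matrix.sample_ids:
                v = matrix.values.at[feat.feature_id, s]
                row[s] = "" if math.isnan(v) else repr(float(v))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif fmt == "long":
        rows = []
        for feat in matrix.features:
            base = _feature_fields(feat)
            for s in matrix.sample_ids:
                v = matrix.values.at[feat.feature_id, s]
                rows.append({**base, "sample_id": s, "intensity": "" if math.isnan(v) else repr(float(v))})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown peptidome format {fmt!r}")


# ---------------------------------------------------------------------------
# Clinical I/O
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = [
    "sample_id", "age", "psa", "prostate_volume", "psa_density", "dre",
    "previous_biopsy", "outcome", "nonpca_subtype", "gleason", "risk_group",
    "erspc_risk", "center",
]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical CSV, validating every record's invariants."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing clinical columns {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                psa=float(row["psa"]),
                prostate_volume=float(row["prostate_volume"]) if row["prostate_volume"] else None,
                psa_density=float(row["psa_density"]) if row["psa_density"] else None,
                dre=row["dre"] or "missing",
                previous_biopsy=row["previous_biopsy"].strip().lower() in {"1", "true", "y", "yes"},
                outcome=row["outcome"],
                nonpca_subtype=row["nonpca_subtype"] or "none",
                gleason=row["gleason"] or "none",
                risk_group=row["risk_group"] or "none",
                erspc_risk=float(row["erspc_risk"]) if row["erspc_risk"] else None,
                center=row["center"] or "center1",
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample_id in clinical table")
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["previous_biopsy"] = int(r.previous_biopsy)
        rows.append(d)
    return pd.DataFrame(rows, columns=_CLINICAL_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA (parent proteins)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------

def join_cohort(
    matrix: IntensityMatrix,
    clinical: Iterable[ClinicalRecord],
    splits: Mapping[str, str] | pd.Series | None = None,
    rename: Mapping[str, str] | None = None,
) -> tuple[CohortDataset, dict[str, list[str]]]:
    """Join matrix columns with clinical records on sample_id.

    ``rename`` maps matrix sample ids to clinical ids before matching.
    Returns the joined dataset (restricted to the intersection) and a
    report of orphan samples on each side.
    """
    rename = dict(rename or {})
    by_id = {r.sample_id: r for r in clinical}
    mapped = {s: rename.get(s, s) for s in matrix.sample_ids}
    kept = [s for s in matrix.sample_ids if mapped[s] in by_id]
    if not kept:
        raise ValidationError("no overlap between matrix samples and clinical records")
    orphans = {
        "matrix_only": [s for s in matrix.sample_ids if mapped[s] not in by_id],
        "clinical_only": sorted(set(by_id) - {mapped[s] for s in matrix.sample_ids}),
    }
    sub = matrix.subset_samples(kept)
    if rename:
        sub = IntensityMatrix(sub.values.rename(columns=mapped), sub.features)
        kept = [mapped[s] for s in kept]
    clin = {s: by_id[s] for s in kept}
    split_series = None
    if splits is not None:
        split_series = pd.Series(dict(splits))
        split_series = split_series[split_series.index.isin(kept)]
    return CohortDataset(sub, clin, split_series), orphans
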