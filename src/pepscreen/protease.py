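"""In-silico protease-activity inference from endogenous peptide termini.

Every naturally occurring urinary peptide implies up to two proteolytic
events: one at its N-terminus and one at its C-terminus (none where the
peptide reaches the end of its parent protein).  Each event is described
by the eight residues P4-P3-P2-P1 | P1'-P2'-P3'-P4' flanking the
scissile bond.  Events are matched against protease specificity records
(exact literature cleavage sites, or position-specific scoring matrices
with a log-probability threshold), and each protease receives a signed
activity score

    xcorr = 100 * sum over matched events of (rho * detection frequency)

where rho is the feature's progression correlation (or another signed
effect measure): proteases whose products rise with disease score
positive (predicted increased activity), and vice versa.  Proteases
matching fewer than ``min_sites`` events (default 5) are not reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import FormatError, PeptideFeature, ValidationError

__all__ = [
    "CleavageEvent",
    "ProteaseSpecRecord",
    "ProteaseActivityResult",
    "extract_cleavage_sites",
    "match_events",
    "score_protease",
    "score_all_proteases",
    "read_spec_table",
    "write_spec_table",
    "results_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = set("BZX")
WINDOW = 8  # P4..P4'


@dataclass(frozen=True)
class CleavageEvent:
    """One inferred proteolytic event at a peptide terminus."""

    feature_id: str
    terminus: str              # "N" or "C"
    site: str                  # up to 8 residues, unmodified uppercase
    start: int                 # 1-based parent coordinate of the first window residue
    end: int                   # 1-based parent coordinate of the last window residue
    truncated: bool = False    # window clipped at a protein end


def extract_cleavage_sites(feature: PeptideFeature, parent_sequence: str) -> list[CleavageEvent]:
    """Derive the N- and C-terminal cleavage events of one peptide.

    The N-terminal window covers parent residues (start-4 .. start+3),
    the C-terminal window (end-3 .. end+4).  A peptide flush with a
    protein end has no event at that terminus (nothing was cleaved);
    windows partially outside the protein are emitted truncated and
    flagged.  Modification marks are stripped before comparison.
    """
    if feature.sequence is None or feature.start_pos is None:
        raise ValidationError(f"{feature.feature_id}: sequence and coordinates required")
    pep = feature.unmodified_sequence()
    start, end = feature.start_pos, feature.end_pos
    segment = parent_sequence[start - 1:end].upper()
    if segment != pep:
        raise ValidationError(
            f"{feature.feature_id}: sequence mismatch with parent "
            f"{feature.parent_protein!r} at {start}-{end}"
        )
    parent = parent_sequence.upper()
    n_res = len(parent)
    events: list[CleavageEvent] = []
    if start > 1:  # an upstream flank exists, so the N-terminus was cleaved
        lo, hi = max(1, start - 4), min(n_res, start + 3)
        events.append(
            CleavageEvent(
                feature_id=feature.feature_id,
                terminus="N",
                site=parent[lo - 1:hi],
                start=lo,
                end=hi,
                truncated=(hi - lo + 1) != WINDOW,
            )
        )
    if end < n_res:  # a downstream flank exists, so the C-terminus was cleaved
        lo, hi = max(1, end - 3), min(n_res, end + 4)
        events.append(
            CleavageEvent(
                feature_id=feature.feature_id,
                terminus="C",
                site=parent[lo - 1:hi],
                start=lo,
                end=hi,
                truncated=(hi - lo + 1) != WINDOW,
            )
        )
    return events


@dataclass
class ProteaseSpecRecord:
    """One protease's cleavage specificity: exact sites or a PSSM."""

    protease_id: str
    accession: str = ""
    symbol: str = ""
    mode: str = "exact"                      # "exact" | "matrix"
    sites: list[str] = field(default_factory=list)
    matrix: pd.DataFrame | None = None       # 8 positions x 20 residues, rows sum to 1
    threshold: float = 0.0                   # min log10-probability score for a match

    def __post_init__(self) -> None:
        if self.mode == "exact":
            for s in self.sites:
                if len(s) != WINDOW:
                    raise ValidationError(
                        f"{self.protease_id}: exact site {s!r} is not {WINDOW} residues"
                    )
        elif self.mode == "matrix":
            if self.matrix is None or self.matrix.shape[0] != WINDOW:
                raise ValidationError(f"{self.protease_id}: matrix must have {WINDOW} rows")
            sums = self.matrix.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError(f"{self.protease_id}: matrix rows must each sum to 1")
        else:
            raise ValidationError(f"{self.protease_id}: unknown mode {self.mode!r}")

    def matches(self, event: CleavageEvent) -> bool:
        if self.mode == "exact":
            if event.truncated or len(event.site) != WINDOW:
                return False
            if AMBIGUOUS & set(event.site):
                return False
            return event.site in self.sites
        if event.truncated or len(event.site) != WINDOW:
            return False
        return self.matrix_score(event.site) >= self.threshold

    def matrix_score(self, site: str) -> float:
        """Sum of per-position log10 probabilities; ambiguous residues
        score as uniform background (1/20)."""
        total = 0.0
        for pos, aa in enumerate(site):
            if aa in AMBIGUOUS or aa not in self.matrix.columns:
                p = 1.0 / len(AMINO_ACIDS)
            else:
                p = float(self.matrix.iloc[pos][aa])
            total += np.log10(max(p, 1e-12))
        return total


def match_events(
    events: Iterable[CleavageEvent], spec_table: Sequence[ProteaseSpecRecord]
) -> dict[str, list[CleavageEvent]]:
    """Per-protease lists of matching events (one event may match many)."""
    events = list(events)
    return {rec.protease_id: [e for e in events if rec.matches(e)] for rec in spec_table}


@dataclass
class ProteaseActivityResult:
    """Predicted activity change for one protease."""

    protease_id: str
    accession: str
    symbol: str
    n_cleavage_sites: int
    xcorr: float
    contributions: pd.DataFrame  # feature_id, terminus, rho, frequency, weight


def score_protease(
    matched: Sequence[CleavageEvent],
    per_feature_stats: pd.DataFrame,
    min_sites: int = 5,
    record: ProteaseSpecRecord | None = None,
) -> ProteaseActivityResult | None:
    """Score one protease from its matched events; None if below min_sites.

    ``per_feature_stats`` must be indexed by feature_id with ``rho`` and
    ``frequency`` columns.  Events whose feature lacks stats are dropped
    with a warning.
    """
    rows = []
    for e in matched:
        if e.feature_id not in per_feature_stats.index:
            warnings.warn(f"no stats for feature {e.feature_id}; event dropped")
            continue
        s = per_feature_stats.loc[e.feature_id]
        rows.append(
            {
                "feature_id": e.feature_id,
                "terminus": e.terminus,
                "rho": float(s["rho"]),
                "frequency": float(s["frequency"]),
                "weight": float(s["rho"]) * float(s["frequency"]),
            }
        )
    if len(rows) < min_sites:
        return None
    contrib = pd.DataFrame(rows)
    return ProteaseActivityResult(
        protease_id=record.protease_id if record else "",
        accession=record.accession if record else "",
        symbol=record.symbol if record else "",
        n_cleavage_sites=len(contrib),
        xcorr=float(100.0 * contrib["weight"].sum()),
        contributions=contrib,
    )


def score_all_proteases(
    events: Iterable[CleavageEvent],
    spec_table: Sequence[ProteaseSpecRecord],
    per_feature_stats: pd.DataFrame,
    min_sites: int = 5,
) -> list[ProteaseActivityResult]:
    """Match and score every protease; results sorted by |xcorr| descending."""
    matched = match_events(events, spec_table)
    by_id = {rec.protease_id: rec for rec in spec_table}
    results = []
    for pid, evts in matched.items():
        res = score_protease(evts, per_feature_stats, min_sites=min_sites, record=by_id[pid])
        if res is not None:
            results.append(res)
    results.sort(key=lambda r: (-abs(r.xcorr), r.protease_id))
    return results


def results_table(results: Sequence[ProteaseActivityResult]) -> pd.DataFrame:
    """Summary table: Protease, Uniprot ID, Symbol, # CS, Xcorr Score."""
    return pd.DataFrame(
        [
            {
                "protease": r.protease_id,
                "uniprot_id": r.accession,
                "symbol": r.symbol,
                "n_cleavage_sites": r.n_cleavage_sites,
                "xcorr_score": r.xcorr,
            }
            for r in results
        ],
        columns=["protease", "uniprot_id", "symbol", "n_cleavage_sites", "xcorr_score"],
    )


# ---------------------------------------------------------------------------
# Specificity table I/O (TSV: protease_id, accession, symbol, mode,
# specification, threshold).  Exact sites are ';'-joined; matrices are a
# JSON object {position (1-8): {residue: probability}}.
# ---------------------------------------------------------------------------

def read_spec_table(path: str | Path) -> list[ProteaseSpecRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protease_id", "accession", "symbol", "mode", "specification", "threshold"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records = []
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        try:
            if row["mode"] == "exact":
                sites = [s for s in row["specification"].split(";") if s]
                rec = ProteaseSpecRecord(
                    protease_id=row["protease_id"], accession=row["accession"],
                    symbol=row["symbol"], mode="exact", sites=sites,
                )
            else:
                payload = json.loads(row["specification"])
                matrix = pd.DataFrame.from_dict(payload, orient="index").sort_index(
                    key=lambda idx: idx.astype(int)
                )
                rec = ProteaseSpecRecord(
                    protease_id=row["protease_id"], accession=row["accession"],
                    symbol=row["symbol"], mode="matrix", matrix=matrix,
                    threshold=float(row["threshold"] or 0.0),
                )
        except (ValidationError, ValueError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_spec_table(records: Sequence[ProteaseSpecRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if rec.mode == "exact":
            spec = ";".join(rec.sites)
        else:
            spec = json.dumps(
                {str(i + 1): rec.matrix.iloc[i].to_dict() for i in range(WINDOW)}
            )
        rows.append(
            {
                "protease_id": rec.protease_id,
                "accession": rec.accession,
                "symbol": rec.symbol,
                "mode": rec.mode,
                "specification": spec,
                "threshold": repr(rec.threshold),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
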