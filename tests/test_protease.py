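import numpy as np
import pandas as pd
import pytest

from pepscreen.core_data import FormatError, PeptideFeature, ValidationError
from pepscreen.protease import (
    AMINO_ACIDS,
    CleavageEvent,
    ProteaseSpecRecord,
    extract_cleavage_sites,
    match_events,
    read_spec_table,
    score_all_proteases,
    score_protease,
    write_spec_table,
)
from pepscreen.synthetic import SimulationConfig, plant_protease_scenario, simulate_cohort

PARENT = "MKWVTFISLLFLFSSAYS"  # 18 residues


def _feature(seq, start, end, fid="f1"):
    return PeptideFeature(fid, 1.0, 20.0, sequence=seq, parent_protein="P",
                          start_pos=start, end_pos=end)


class TestExtractCleavageSites:
    def test_internal_peptide_has_both_windows(self):
        events = extract_cleavage_sites(_feature("TFISLL", 5, 10), PARENT)
        assert [e.terminus for e in events] == ["N", "C"]
        n, c = events
        assert n.site == "MKWVTFIS" and (n.start, n.end) == (1, 8) and not n.truncated
        assert c.site == "ISLLFLFS" and (c.start, c.end) == (7, 14) and not c.truncated

    def test_protein_start_peptide_has_no_n_event(self):
        events = extract_cleavage_sites(_feature("MKWV", 1, 4), PARENT)
        assert [e.terminus for e in events] == ["C"]

    def test_protein_end_peptide_has_no_c_event(self):
        events = extract_cleavage_sites(_feature("SAYS", 15, 18), PARENT)
        assert [e.terminus for e in events] == ["N"]

    def test_near_boundary_window_truncated_and_flagged(self):
        events = extract_cleavage_sites(_feature("WVTF", 3, 6), PARENT)
        n = events[0]
        assert n.terminus == "N" and n.truncated and n.site == "MKWVTF"

    def test_modification_marks_stripped_before_comparison(self):
        events = extract_cleavage_sites(_feature("tFiSLL", 5, 10), PARENT)
        assert events[0].site == "MKWVTFIS"

    def test_coordinate_mismatch_names_feature(self):
        with pytest.raises(ValidationError, match="f1"):
            extract_cleavage_sites(_feature("AAAAAA", 5, 10), PARENT)


class TestMatching:
    def test_exact_site_matches_by_string_equality(self):
        rec = ProteaseSpecRecord("prot1", mode="exact", sites=["MKWVTFIS"])
        events = extract_cleavage_sites(_feature("TFISLL", 5, 10), PARENT)
        events += extract_cleavage_sites(_feature("TFISLLF", 5, 11, fid="f2"), PARENT)
        matched = match_events(events, [rec])
        assert [e.feature_id for e in matched["prot1"]] == ["f1", "f2"]

    def test_empty_spec_table_matches_nothing(self):
        events = extract_cleavage_sites(_feature("TFISLL", 5, 10), PARENT)
        assert match_events(events, []) == {}

    def test_truncated_events_never_match_exact_sites(self):
        rec = ProteaseSpecRecord("prot1", mode="exact", sites=["MKWVTFXX"])
        events = [e for e in extract_cleavage_sites(_feature("WVTF", 3, 6), PARENT)
                  if e.terminus == "N"]
        assert match_events(events, [rec])["prot1"] == []

    def test_matrix_record_scores_and_thresholds(self):
        site = "MKWVTFIS"
        probs = np.full((8, 20), (1 - 0.9) / 19)
        cols = list(AMINO_ACIDS)
        for i, aa in enumerate(site):
            probs[i, cols.index(aa)] = 0.9
        matrix = pd.DataFrame(probs, columns=cols)
        rec = ProteaseSpecRecord(
            "m1", mode="matrix", matrix=matrix, threshold=8 * np.log10(0.5)
        )
        events = extract_cleavage_sites(_feature("TFISLL", 5, 10), PARENT)
        matched = match_events(events, [rec])
        assert [e.site for e in matched["m1"]] == [site]

    def test_exact_sites_must_be_eight_residues(self):
        with pytest.raises(ValidationError, match="8 residues"):
            ProteaseSpecRecord("p", mode="exact", sites=["SHORT"])


def _stats(rows):
    return pd.DataFrame(rows, columns=["feature_id", "rho", "frequency"]).set_index(
        "feature_id"
    )


def _events(feature_ids):
    # site content is irrelevant once matching has happened
    return [
        CleavageEvent(feature_id=fid, terminus="N", site="AAAAAAAA", start=1, end=8)
        for fid in feature_ids
    ]


class TestScoring:
    def test_five_uniform_events_score_25(self):
        stats = _stats([(f"f{i}", 0.1, 0.5) for i in range(5)])
        res = score_protease(_events(stats.index), stats, min_sites=5)
        assert res.n_cleavage_sites == 5
        assert res.xcorr == pytest.approx(25.0)

    def test_four_events_excluded_at_default_minimum(self):
        stats = _stats([(f"f{i}", 0.5, 0.9) for i in range(4)])
        assert score_protease(_events(stats.index), stats, min_sites=5) is None

    def test_sign_follows_weight_sum(self):
        stats = _stats([(f"f{i}", -0.2, 0.8) for i in range(6)])
        res = score_protease(_events(stats.index), stats, min_sites=5)
        assert res.xcorr < 0

    def test_additive_over_disjoint_event_sets(self):
        rng = np.random.default_rng(8)
        stats = _stats([(f"f{i}", float(rng.uniform(-1, 1)),
                         float(rng.uniform(0, 1))) for i in range(12)])
        all_ids = list(stats.index)
        a, b = all_ids[:5], all_ids[5:]
        whole = score_protease(_events(all_ids), stats, min_sites=1).xcorr
        parts = (score_protease(_events(a), stats, min_sites=1).xcorr
                 + score_protease(_events(b), stats, min_sites=1).xcorr)
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_match_counts_unaffected_by_stat_permutation(self):
        rng = np.random.default_rng(12)
        stats = _stats([(f"f{i}", float(rng.uniform(-1, 1)), 0.5) for i in range(8)])
        permuted = stats.copy()
        permuted["rho"] = rng.permutation(stats["rho"].to_numpy())
        events = _events(stats.index)
        rec = ProteaseSpecRecord("p", mode="exact", sites=["AAAAAAAA"])
        r1 = score_all_proteases(events, [rec], stats, min_sites=1)
        r2 = score_all_proteases(events, [rec], permuted, min_sites=1)
        assert r1[0].n_cleavage_sites == r2[0].n_cleavage_sites

    def test_missing_stats_drop_event_with_warning(self):
        stats = _stats([(f"f{i}", 0.1, 0.5) for i in range(5)])
        events = _events(list(stats.index) + ["unknown"])
        with pytest.warns(UserWarning, match="unknown"):
            res = score_protease(events, stats, min_sites=5)
        assert res.n_cleavage_sites == 5


class TestSpecTableIO:
    def test_roundtrip_exact_and_matrix_records(self, tmp_path):
        probs = np.full((8, 20), 1.0 / 20)
        records = [
            ProteaseSpecRecord("e1", accession="P008", symbol="MMP",
                               mode="exact", sites=["MKWVTFIS", "GPAGPQGP"]),
            ProteaseSpecRecord("m1", mode="matrix",
                               matrix=pd.DataFrame(probs, columns=list(AMINO_ACIDS)),
                               threshold=-11.0),
        ]
        path = tmp_path / "spec.tsv"
        write_spec_table(records, path)
        back = read_spec_table(path)
        assert back[0].sites == records[0].sites
        assert back[0].accession == "P008"
        np.testing.assert_allclose(back[1].matrix.to_numpy(),
                                   records[1].matrix.to_numpy())
        assert back[1].threshold == -11.0

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "spec.tsv"
        path.write_text(
            "protease_id\taccession\tsymbol\tmode\tspecification\tthreshold\n"
            "ok\tA\tS\texact\tMKWVTFIS\t0\n"
            "bad\tA\tS\texact\tTOOSHORT;XX\t0\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            read_spec_table(path)


def test_planted_protease_recovered_end_to_end():
    """A protease whose exact site is seeded into up-regulated marker
    termini tops the |xcorr| ranking against event-matched decoys."""
    from pepscreen.normalization import log_transform, normalize_matrix
    from pepscreen.progression import gleason_ordinals, spearman_per_feature

    config = SimulationConfig(
        n_cases=60, n_controls=60, n_cases_validation=0, n_controls_validation=0,
        n_cases_validation2=0, n_features=400, n_markers=60, seed=19,
    )
    dataset, truth = simulate_cohort(config)
    dataset, parents, records, planted_id = plant_protease_scenario(
        dataset, truth, seed=19
    )
    normalized, _, _ = normalize_matrix(dataset.matrix, truth.reference_panel())
    transformed = log_transform(normalized)
    entries = spearman_per_feature(transformed, gleason_ordinals(dataset.clinical))
    events = []
    for feat in dataset.matrix.features:
        if feat.sequence is not None:
            events.extend(extract_cleavage_sites(feat, parents[feat.parent_protein]))
    results = score_all_proteases(events, records, entries.set_index("feature_id"))
    assert results[0].protease_id == planted_id
    assert results[0].xcorr > 0
    assert all(r.protease_id != "DECOY_SMALL" for r in results)  # only 4 sites
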