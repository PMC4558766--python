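"""Candidate enumeration, single-addition scans, and scan intersection."""

import numpy as np
import pytest

import semnet as sn

from conftest import random_dag_model


class TestEnumerateNewPaths:
    def test_cegs_count_matches_formula(self, cegs_baseline):
        cands = sn.enumerate_new_paths(cegs_baseline)
        assert len(cands) == 104  # 12*11 - 2*14

    def test_dspr_count_matches_formula(self, dspr_baseline):
        assert len(sn.enumerate_new_paths(dspr_baseline)) == 84  # 11*10 - 2*13

    def test_two_gene_model_has_no_candidates(self):
        m = sn.PathModel(("x", "y"), (("x", "y"),))
        assert sn.enumerate_new_paths(m) == []

    def test_excludes_existing_and_reversed(self, cegs_baseline):
        cands = set(sn.enumerate_new_paths(cegs_baseline))
        for s, t in cegs_baseline.paths:
            assert (s, t) not in cands
            assert (t, s) not in cands

    def test_count_identity_on_random_dags(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = random_dag_model(rng, int(rng.integers(3, 12)))
            g, e = len(m.genes), len(m.paths)
            assert len(sn.enumerate_new_paths(m)) == g * (g - 1) - 2 * e


class TestEnumerateGenePlacements:
    def test_cegs_has_37_locations(self, cegs_baseline):
        assert len(sn.enumerate_gene_placements(cegs_baseline)) == 37

    def test_dspr_has_34_locations(self, dspr_baseline):
        assert len(sn.enumerate_gene_placements(dspr_baseline)) == 34

    def test_chain_with_reporter_has_four(self):
        m = sn.PathModel(("x", "y"), (("x", "y"),), reporter="y")
        placements = sn.enumerate_gene_placements(m)
        assert len(placements) == 4  # x->g, g->x, g->y, x->g->y
        assert [p.kind for p in placements] == [
            "downstream", "upstream", "upstream", "insertion"]

    def test_reporter_never_a_downstream_anchor(self, cegs_baseline):
        for p in sn.enumerate_gene_placements(cegs_baseline):
            if p.kind == "downstream":
                assert p.anchor != "Yp2"

    def test_missing_reporter_rejected(self):
        m = sn.PathModel(("x", "y"), (("x", "y"),))
        with pytest.raises(ValueError):
            sn.enumerate_gene_placements(m)

    def test_model_index_is_deterministic_and_one_based(self, cegs_baseline):
        placements = sn.enumerate_gene_placements(cegs_baseline)
        assert [p.model_index for p in placements] == list(range(1, 38))

    def test_count_identity_on_random_dags(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = random_dag_model(rng, int(rng.integers(3, 12)))
            g, e = len(m.genes), len(m.paths)
            assert len(sn.enumerate_gene_placements(m)) == 2 * g - 1 + e


class TestScanNewPaths:
    def test_planted_edge_is_top_ranked_and_accepted(self, cegs_baseline):
        truth_model = cegs_baseline.with_path("vir", "fru")
        theta = sn.default_parameters(truth_model)
        config = sn.SimulationConfig(model=truth_model, parameters=theta,
                                     n=600, seed=31)
        data, _ = sn.generate_grn_dataset(config)
        records = sn.scan_new_paths(
            cegs_baseline, sn.SampleMoments.from_data(data), threshold=0.0)
        top = records[0]
        assert top.candidate == ("vir", "fru")
        assert top.accepted

    def test_null_data_accepts_nothing_at_threshold_12(self, cegs_baseline):
        theta = sn.default_parameters(cegs_baseline)
        clean = 0
        reps = 100
        for rep in range(reps):
            config = sn.SimulationConfig(model=cegs_baseline, parameters=theta,
                                         n=600, seed=1000 + rep)
            data, _ = sn.generate_grn_dataset(config)
            records = sn.scan_new_paths(
                cegs_baseline, sn.SampleMoments.from_data(data), threshold=12.0)
            if not any(r.accepted for r in records):
                clean += 1
        assert clean >= 0.95 * reps

    def test_infinite_threshold_accepts_nothing_but_keeps_records(
            self, cegs_baseline, cegs_moments):
        records = sn.scan_new_paths(cegs_baseline, cegs_moments, float("inf"))
        assert len(records) == 104
        assert not any(r.accepted for r in records)

    def test_cyclic_candidates_recorded_as_skipped(self, cegs_baseline, cegs_moments):
        records = sn.scan_new_paths(cegs_baseline, cegs_moments, threshold=0.0)
        skipped = {r.candidate: r for r in records if r.skipped_reason}
        # fru -> Sxl closes the cycle Sxl -> tra -> fru -> Sxl
        assert ("fru", "Sxl") in skipped
        assert "cycle" in skipped[("fru", "Sxl")].skipped_reason

    def test_baseline_delta_against_itself_is_zero(self, cegs_baseline, cegs_moments):
        fit = sn.fit_model(cegs_baseline, cegs_moments)
        assert fit.stats.bic - fit.stats.bic == 0.0


@pytest.fixture(scope="module")
def planted_scan(cegs_baseline):
    """Baseline data with one planted child of Sxl and null candidates."""
    spec = sn.CandidateSpec("planted", parent="Sxl", coefficient=0.8,
                            noise_variance=0.36)
    data, candidates, _, truth = sn.simulate_population(
        "cegs-like", n=600, n_null_candidates=9,
        true_candidates=(spec,), seed=41)
    return sn.scan_candidate_genes(cegs_baseline, data, candidates,
                                   threshold=12.0)


class TestScanCandidateGenes:
    def test_models_evaluated_bookkeeping(self, planted_scan):
        assert planted_scan.n_models_evaluated == 10 * 37

    def test_planted_gene_accepted_downstream_of_parent(self, planted_scan):
        row = planted_scan.summary.loc["planted"]
        assert row["accepted"]
        assert row["best_kind"] == "downstream"
        assert row["best_anchor"] == "Sxl->gene"

    def test_candidate_overlapping_model_rejected(self, cegs_baseline):
        data, candidates, _, _ = sn.simulate_population(
            "cegs-like", n=75, n_null_candidates=2, seed=4)
        bad = candidates.rename(columns={candidates.columns[0]: "Sxl"})
        with pytest.raises(ValueError):
            sn.scan_candidate_genes(cegs_baseline, data, bad, threshold=12.0)

    def test_noise_genes_rarely_accepted_at_threshold_12(self, cegs_baseline):
        theta = sn.default_parameters(cegs_baseline)
        accepted = 0
        reps = 50
        for rep in range(reps):
            config = sn.SimulationConfig(
                model=cegs_baseline, parameters=theta, n=600,
                n_null_candidates=1, seed=5000 + rep)
            data, _ = sn.generate_grn_dataset(config)
            candidates, _ = sn.generate_candidate_pool(
                config, data, np.random.default_rng(6000 + rep))
            result = sn.scan_candidate_genes(cegs_baseline, data, candidates,
                                             threshold=12.0)
            accepted += int(result.summary["accepted"].any())
        assert accepted <= 0.05 * reps


class TestIntersectScans:
    def test_reciprocal_pair_detected(self):
        report = sn.intersect_scans(
            {("x", "y"), ("y", "x"), ("a", "b")},
            {("x", "y"), ("y", "x"), ("c", "d")})
        assert report.reciprocal_pairs == frozenset({frozenset({"x", "y"})})
        assert report.directed == frozenset()
        assert report.n_shared == 2

    def test_disjoint_sets_empty(self):
        report = sn.intersect_scans({("a", "b")}, {("c", "d")})
        assert report.shared == frozenset()

    def test_identical_sets_identity(self):
        edges = {("a", "b"), ("b", "c")}
        report = sn.intersect_scans(edges, edges)
        assert report.shared == frozenset(edges)
        assert report.directed == frozenset(edges)
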