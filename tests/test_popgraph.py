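"""Population graph: kernel closed forms, phenotype agreement, triple-loop oracle."""

import numpy as np
import pytest

from eegfusion.popgraph import (
    GraphConfig,
    PhenotypeRecord,
    PopGraphError,
    build_adjacency,
    correlation_distance,
    feature_similarity,
    load_graph,
    phenotype_similarity,
    read_phenotypes_csv,
    save_graph,
    write_phenotypes_csv,
)

# orthogonal pair: Pearson r = 0, so correlation distance is exactly 1
X_ORTH = np.array([1.0, -1.0, 1.0, -1.0])
Y_ORTH = np.array([1.0, 1.0, -1.0, -1.0])


def triple_loop_oracle(vecs, phenos, cfg):
    """Independent evaluation: kernel x summed phenotype agreement, per pair."""
    n = len(vecs)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rho = correlation_distance(vecs[i], vecs[j])
            sim = np.exp(-(rho**2) / (2 * cfg.sigma**2))
            gamma = 0
            if phenos[i].gender == phenos[j].gender:
                gamma += 1
            if abs(phenos[i].age - phenos[j].age) < cfg.theta:
                gamma += 1
            W[i, j] = sim * gamma
    return W


class TestFeatureSimilarity:
    def test_identical_vectors_give_similarity_one(self):
        x = np.array([0.3, 0.9, 0.1])
        assert feature_similarity(x, x, sigma=1.0) == pytest.approx(1.0, abs=1e-15)

    def test_distance_equal_to_sigma_gives_exp_minus_half(self):
        assert feature_similarity(X_ORTH, Y_ORTH, sigma=1.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12
        )

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert feature_similarity(x, y) == feature_similarity(y, x)

    def test_zero_variance_vector_is_maximally_dissimilar(self):
        flat = np.ones(5)
        varying = np.arange(5.0)
        assert correlation_distance(flat, varying) == 1.0

    def test_anticorrelation_clipped_to_distance_one(self):
        x = np.arange(5.0)
        assert correlation_distance(x, -x) == 1.0

    def test_similarity_monotone_in_sigma(self):
        s1 = feature_similarity(X_ORTH, Y_ORTH, sigma=0.5)
        s2 = feature_similarity(X_ORTH, Y_ORTH, sigma=1.0)
        s3 = feature_similarity(X_ORTH, Y_ORTH, sigma=2.0)
        assert s1 < s2 < s3


class TestPhenotypeSimilarity:
    CFG = GraphConfig(sigma=1.0, theta=2.0)

    def rec(self, gender="male", age=65.0, sid="a"):
        return PhenotypeRecord(sid, gender, age)

    def test_same_gender_agrees(self):
        assert phenotype_similarity(self.rec(), self.rec(sid="b"), "gender", self.CFG) == 1

    def test_different_gender_disagrees(self):
        b = self.rec(gender="female", sid="b")
        assert phenotype_similarity(self.rec(), b, "gender", self.CFG) == 0

    @pytest.mark.parametrize("age_a, age_b, expected", [(60, 70, 0), (64, 65, 1), (64, 66, 0)])
    def test_age_threshold_is_strict(self, age_a, age_b, expected):
        a, b = self.rec(age=age_a), self.rec(age=age_b, sid="b")
        assert phenotype_similarity(a, b, "age", self.CFG) == expected

    def test_undeclared_phenotype_rejected(self):
        with pytest.raises(PopGraphError, match="not declared"):
            phenotype_similarity(self.rec(), self.rec(sid="b"), "height", self.CFG)


class TestAdjacency:
    def test_identical_twins_edge_equals_phenotype_count(self):
        # identical features (sim = 1), same gender and age (gamma = 2)
        x = np.array([1.0, 2.0, 3.0])
        phenos = [
            PhenotypeRecord("a", "male", 65.0),
            PhenotypeRecord("b", "male", 65.0),
        ]
        g = build_adjacency([x, x.copy()], phenos, GraphConfig())
        assert g.W[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_total_phenotype_disagreement_annihilates_edge(self):
        x = np.array([1.0, 2.0, 3.0])
        phenos = [
            PhenotypeRecord("a", "male", 60.0),
            PhenotypeRecord("b", "female", 80.0),
        ]
        g = build_adjacency([x, x.copy()], phenos, GraphConfig())
        assert g.W[0, 1] == 0.0

    def test_matches_triple_loop_oracle_for_six_subjects(self, rng):
        cfg = GraphConfig(sigma=0.8, theta=3.0)
        vecs = [rng.normal(size=20) for _ in range(6)]
        genders = ["male", "female", "male", "male", "female", "female"]
        ages = [60.0, 61.0, 70.0, 71.5, 62.0, 90.0]
        phenos = [
            PhenotypeRecord(f"s{i}", g, a) for i, (g, a) in enumerate(zip(genders, ages))
        ]
        g = build_adjacency(vecs, phenos, cfg)
        assert np.allclose(g.W, triple_loop_oracle(vecs, phenos, cfg), atol=1e-12)

    def test_entries_bounded_by_phenotype_count_and_symmetric(self, rng):
        vecs = [rng.normal(size=10) for _ in range(5)]
        phenos = [
            PhenotypeRecord(f"s{i}", "male" if i % 2 else "female", 60.0 + i)
            for i in range(5)
        ]
        g = build_adjacency(vecs, phenos, GraphConfig())
        H = 2
        assert np.all(g.W >= 0) and np.all(g.W <= H)
        assert np.array_equal(g.W, g.W.T)
        assert np.all(np.diag(g.W) == 0)

    def test_duplicate_subject_ids_rejected(self):
        phenos = [PhenotypeRecord("a", "male", 60.0)] * 2
        with pytest.raises(PopGraphError, match="duplicate"):
            build_adjacency([np.ones(3), np.ones(3)], phenos, GraphConfig())


def test_phenotype_csv_and_graph_round_trip(tmp_path, rng):
    phenos = [
        PhenotypeRecord("s0", "male", 64.0, "patient"),
        PhenotypeRecord("s1", "female", 66.0, "control"),
        PhenotypeRecord("s2", "male", 65.0, "patient"),
    ]
    csv = tmp_path / "phenos.csv"
    write_phenotypes_csv(phenos, csv)
    assert read_phenotypes_csv(csv) == phenos

    vecs = [rng.normal(size=8) for _ in range(3)]
    g = build_adjacency(vecs, phenos, GraphConfig())
    save_graph(g, tmp_path / "W.txt", tmp_path / "edges.txt")
    back = load_graph(tmp_path / "W.txt")
    assert back.subjects == g.subjects
    assert np.allclose(back.W, g.W, atol=1e-12)
    edge_lines = (tmp_path / "edges.txt").read_text().strip().splitlines()
    assert edge_lines[0] == "v w weight"
    assert len(edge_lines) - 1 == int((g.W > 0).sum() // 2)
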