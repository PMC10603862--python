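"""Built-in microservices: loading, QC, normalization, modelling,
embedding, clustering, and descriptor/callable conformance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from semflow.executor import resolve_invoke_path
from semflow.services import (
    CountMatrix,
    LabeledTable,
    ServiceError,
    ServiceUnavailable,
    svc_classify,
    svc_cluster,
    svc_csv_load,
    svc_embed,
    svc_image_classify,
    svc_load_counts,
    svc_normalize,
    svc_optimize,
    svc_quality_control,
    svc_split,
    svc_text_generate,
)
from semflow.synth import (
    CountsSpec,
    counts_to_csv,
    default_tabular_spec,
    make_classification_table,
    make_count_matrix,
)


@pytest.fixture(scope="module")
def blobs():
    """Three well-separated planted Gaussian blobs in 5 dimensions."""
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0, 0, 0, 0], [12, 12, 0, 0, 0], [0, 12, 12, 0, 0]], float)
    labels = np.repeat([0, 1, 2], 60)
    coords = centers[labels] + rng.normal(0, 0.5, (180, 5))
    from semflow.services import NormalizedMatrix

    matrix = NormalizedMatrix(coords, tuple(f"c{i}" for i in range(180)),
                              tuple(f"g{j}" for j in range(5)))
    return matrix, labels


class TestLoading:
    def test_heart_csv_loads_thirteen_features(self, heart_csv):
        table = svc_csv_load(str(heart_csv))
        assert len(table.feature_names) == 13
        assert table.label == "target"

    def test_missing_label_column_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ServiceError, match="target"):
            svc_csv_load(str(path))

    def test_counts_csv_dimensions(self, counts_csv):
        matrix = svc_load_counts(str(counts_csv))
        assert matrix.counts.shape == (300, 400)
        assert len(matrix.cell_ids) == 300 and len(matrix.gene_ids) == 400


class TestSplit:
    def test_ratio_and_determinism(self):
        table, _ = make_classification_table(default_tabular_spec(n_rows=100, seed=0))
        a = svc_split(table, seed=5, params={"ratio": 0.8})
        b = svc_split(table, seed=5, params={"ratio": 0.8})
        assert len(a.train) == 80 and len(a.test) == 20
        assert a.train.index.tolist() == b.train.index.tolist()

    def test_partitions_disjoint_and_exhaustive(self):
        table, _ = make_classification_table(default_tabular_spec(n_rows=100, seed=1))
        s = svc_split(table, seed=2)
        assert set(s.train.index).isdisjoint(s.test.index)
        assert len(s.train) + len(s.test) == 100

    @pytest.mark.parametrize("seed", range(4))
    def test_stratification_within_one_row(self, seed):
        table, _ = make_classification_table(default_tabular_spec(n_rows=60, seed=seed))
        s = svc_split(table, seed=seed)
        full = table.frame["target"].mean()
        for part in (s.train, s.test):
            expected = full * len(part)
            assert abs(part["target"].sum() - expected) <= 1

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"x": range(10), "target": [1] * 10})
        with pytest.raises(ServiceError, match="single-class"):
            svc_split(LabeledTable(frame), seed=0)


class TestQualityControl:
    def test_rows_with_missing_cells_dropped(self):
        frame = pd.DataFrame({"x": np.r_[np.arange(48.0), np.nan, 1.0],
                              "y": np.arange(50.0),
                              "target": [0, 1] * 25})
        frame.loc[7, "y"] = np.nan
        out = svc_quality_control(LabeledTable(frame))
        assert len(out.frame) == 48

    def test_zero_variance_column_dropped(self):
        frame = pd.DataFrame({"x": np.arange(20.0), "flat": 3.0,
                              "target": [0, 1] * 10})
        out = svc_quality_control(LabeledTable(frame))
        assert "flat" not in out.frame.columns and "x" in out.frame.columns

    def test_planted_lowdepth_cells_are_exactly_the_removed_set(self, counts_fixture):
        matrix, truth = counts_fixture
        out = svc_quality_control(matrix)
        removed = set(matrix.cell_ids) - set(out.cell_ids)
        assert removed == set(truth["lowdepth_cells"])
        assert len(removed) == 15

    def test_all_zero_gene_dropped(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (30, 10))
        counts[:, 4] = 0
        m = CountMatrix(counts, tuple(f"c{i}" for i in range(30)),
                        tuple(f"g{j}" for j in range(10)))
        out = svc_quality_control(m, params={"qc_percentile": 0})
        assert "g0004" not in out.gene_ids or "g4" not in out.gene_ids
        assert len(out.gene_ids) == 9


class TestNormalize:
    def test_tabular_zscore_gives_zero_mean_unit_variance(self):
        frame = pd.DataFrame({"x": np.arange(50.0) + 100.0, "target": [0, 1] * 25})
        out = svc_normalize(LabeledTable(frame))
        assert abs(out.frame["x"].mean()) < 1e-12
        assert abs(out.frame["x"].std(ddof=0) - 1) < 1e-12

    def test_tabular_normalize_is_idempotent(self):
        table, _ = make_classification_table(default_tabular_spec(n_rows=80, seed=3))
        once = svc_normalize(table)
        twice = svc_normalize(once)
        assert np.allclose(once.frame[list(once.feature_names)],
                           twice.frame[list(twice.feature_names)], atol=1e-10)

    def test_counts_row_sums_equal_median_before_log(self, counts_fixture):
        matrix, _ = counts_fixture
        qc = svc_quality_control(matrix)
        out = svc_normalize(qc)
        recovered = np.expm1(out.values).sum(axis=1)
        median = np.median(qc.counts.sum(axis=1))
        assert np.allclose(recovered, median)

    def test_zero_variance_feature_is_a_contract_violation(self):
        frame = pd.DataFrame({"flat": 1.0, "target": [0, 1] * 5}, index=range(10))
        with pytest.raises(ServiceError, match="zero-variance"):
            svc_normalize(LabeledTable(frame))


class TestClassify:
    def test_separable_data_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(-5, 0.3, 100), rng.normal(5, 0.3, 100)]
        frame = pd.DataFrame({"f1": x, "f2": rng.normal(0, 1, 200),
                              "target": np.r_[np.zeros(100), np.ones(100)].astype(int)})
        model = svc_classify(svc_split(LabeledTable(frame), seed=0), seed=0)
        assert model.accuracy == 1.0

    def test_label_shuffled_data_near_chance(self):
        table, _ = make_classification_table(default_tabular_spec(n_rows=200, seed=4))
        rng = np.random.default_rng(4)
        frame = table.frame.copy()
        frame["target"] = rng.permutation(frame["target"].to_numpy())
        model = svc_classify(svc_split(LabeledTable(frame), seed=4), seed=4)
        # binomial null at n=40 test rows: chance within ~3 sigma of 0.5
        assert abs(model.accuracy - 0.5) < 0.25

    def test_fixed_seed_reproduces_coefficients(self):
        table, _ = make_classification_table(default_tabular_spec(n_rows=120, seed=6))
        split = svc_split(table, seed=6)
        a = svc_classify(split, seed=6)
        b = svc_classify(split, seed=6)
        assert np.array_equal(a.pipeline.named_steps["clf"].coef_,
                              b.pipeline.named_steps["clf"].coef_)


class TestOptimize:
    def test_cv_curve_covers_every_subset_size(self):
        table, _ = make_classification_table(
            default_tabular_spec(n_rows=150, n_informative=3, n_noise=4, seed=0))
        opt = svc_optimize(svc_split(table, seed=0), seed=0)
        sizes = [n for n, _ in opt.cv_curve]
        assert sizes == list(range(7, 0, -1))

    def test_two_informative_features_both_retained(self):
        spec = default_tabular_spec(n_rows=300, n_informative=2, n_noise=0,
                                    effect=2.0, seed=1)
        table, truth = make_classification_table(spec)
        opt = svc_optimize(svc_split(table, seed=1), seed=1)
        assert set(opt.selected_features) == set(truth["informative"])

    def test_planted_features_recovered(self):
        table, truth = make_classification_table(default_tabular_spec(seed=7))
        opt = svc_optimize(svc_split(table, seed=7), seed=7)
        assert set(truth["informative"]) <= set(opt.selected_features)


class TestEmbed:
    def test_pca_recovers_exact_low_rank_structure(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        scores = rng.normal(size=(40, 2))
        from semflow.services import NormalizedMatrix

        m = NormalizedMatrix(scores @ basis, tuple(map(str, range(40))),
                             tuple(map(str, range(6))))
        emb = svc_embed(m, params={"method": "pca", "dims": 2})
        from sklearn.decomposition import PCA

        reconstructed = PCA(2).fit(m.values).inverse_transform(
            PCA(2).fit_transform(m.values))
        assert np.allclose(reconstructed, m.values, atol=1e-8)
        assert emb.coords.shape == (40, 2)

    def test_pca_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        from semflow.services import NormalizedMatrix

        x = rng.normal(size=(10, 4))
        m = NormalizedMatrix(x, tuple(map(str, range(10))), tuple(map(str, range(4))))
        emb = svc_embed(m, params={"method": "pca", "dims": 2})
        centered = x - x.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered / 10)
        order = np.argsort(w)[::-1][:2]
        expected = centered @ v[:, order]
        for j in range(2):  # eigenvectors are defined up to sign
            assert (np.allclose(emb.coords[:, j], expected[:, j], atol=1e-8)
                    or np.allclose(emb.coords[:, j], -expected[:, j], atol=1e-8))

    def test_explained_variance_non_increasing(self, blobs):
        matrix, _ = blobs
        from sklearn.decomposition import PCA

        model = PCA(4).fit(matrix.values)
        assert all(np.diff(model.explained_variance_) <= 1e-9)

    def test_dims_must_be_below_feature_count(self, blobs):
        matrix, _ = blobs
        with pytest.raises(ServiceError, match="dims"):
            svc_embed(matrix, params={"method": "pca", "dims": 5})


class TestCluster:
    def test_kmeans_recovers_planted_blobs(self, blobs):
        matrix, truth = blobs
        emb = svc_embed(matrix, seed=0, params={"method": "pca", "dims": 2})
        out = svc_cluster(emb, seed=0, params={"method": "kmeans", "k": 3})
        assert adjusted_rand_score(truth, out.labels) >= 0.99

    def test_graph_clustering_recovers_planted_blobs(self, blobs):
        matrix, truth = blobs
        emb = svc_embed(matrix, seed=0, params={"method": "pca", "dims": 2})
        out = svc_cluster(emb, seed=0, params={"method": "graph"})
        assert adjusted_rand_score(truth, out.labels) >= 0.9

    def test_duplicated_points_get_identical_labels(self):
        rng = np.random.default_rng(1)
        base = np.r_[rng.normal(0, 0.1, (20, 2)), rng.normal(8, 0.1, (20, 2))]
        coords = np.vstack([base, base])
        from semflow.services import Embedding

        emb = Embedding(coords, tuple(map(str, range(80))), "pca")
        out = svc_cluster(emb, seed=0, params={"method": "kmeans", "k": 2})
        assert np.array_equal(out.labels[:40], out.labels[40:])

    def test_k_larger_than_points_rejected(self):
        from semflow.services import Embedding

        emb = Embedding(np.zeros((3, 2)), ("a", "b", "c"), "pca")
        with pytest.raises(ServiceError, match="k="):
            svc_cluster(emb, params={"method": "kmeans", "k": 5})


class TestConformance:
    def test_every_descriptor_resolves_to_a_callable(self, scrna_env):
        _, registry = scrna_env
        for d in registry.descriptors():
            assert callable(resolve_invoke_path(d.invoke_path))

    def test_descriptor_only_services_raise_unavailable(self):
        with pytest.raises(ServiceUnavailable):
            svc_text_generate("hello")
        with pytest.raises(ServiceUnavailable):
            svc_image_classify(None)

    def test_qc_preserves_label_classes(self, heart_table):
        table, _ = heart_table
        before = set(table.frame["target"].unique())
        out = svc_quality_control(table)
        assert set(out.frame["target"].unique()) == before
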