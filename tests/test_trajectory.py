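import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from statedecon.matrix import ExpressionMatrix
from statedecon.pair_encoding import BinaryRelativeMatrix, encode_relative, enumerate_pairs, fit_encoding
from statedecon.syndata import SyntheticConfig, simulate_bulk, simulate_states
from statedecon.trajectory import (
    cluster_cells,
    crosstab_state_proportions,
    de_one_vs_rest,
    fit_pca,
    pc_gene_correlation,
    project,
)


def _binary(values, pairs=None):
    values = np.asarray(values, dtype=np.uint8)
    if pairs is None:
        n = values.shape[1]
        # any pair list with the right width
        genes = tuple(f"g{i}" for i in range(n + 1))
        idx = np.array([[0, i + 1] for i in range(n)])
        from statedecon.pair_encoding import PairList

        pairs = PairList(genes, idx)
    return BinaryRelativeMatrix(values, [f"c{i}" for i in range(values.shape[0])], pairs)


def _expr(values, genes=None, obs=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    obs = obs or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=obs))


class TestClusterCells:
    def test_disjoint_patterns_recovered(self, rng):
        block = np.zeros((20, 10), dtype=np.uint8)
        block[:10, :5] = 1
        block[10:, 5:] = 1
        noise = (rng.random((20, 10)) < 0.05).astype(np.uint8)
        labels = cluster_cells(_binary(block ^ noise), 2)
        first, second = set(labels.iloc[:10]), set(labels.iloc[10:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_singleton_clusters(self, rng):
        values = rng.integers(0, 2, size=(6, 8)).astype(np.uint8)
        labels = cluster_cells(_binary(values), 6)
        assert labels.nunique() == 6

    def test_duplicate_rows_same_cluster(self, rng):
        values = rng.integers(0, 2, size=(8, 10)).astype(np.uint8)
        values[5] = values[2]
        labels = cluster_cells(_binary(values), 3)
        assert labels.iloc[5] == labels.iloc[2]

    def test_too_many_clusters_rejected(self, rng):
        values = rng.integers(0, 2, size=(4, 5)).astype(np.uint8)
        with pytest.raises(ValueError, match="n_clusters"):
            cluster_cells(_binary(values), 5)


class TestFitPca:
    def test_fit_transform_consistency(self, rng):
        values = rng.integers(0, 2, size=(30, 12)).astype(np.uint8)
        binary = _binary(values)
        model = fit_pca(binary, 4)
        reproj = project(model, binary)
        np.testing.assert_allclose(
            reproj.to_numpy(), model.training_coordinates.to_numpy(), atol=1e-8
        )

    def test_explained_variance_ratio_bounded(self, rng):
        values = rng.integers(0, 2, size=(25, 10)).astype(np.uint8)
        model = fit_pca(_binary(values), 5)
        assert model.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_rank_two_matrix_against_eigendecomposition(self, rng):
        # three binary prototypes span a rank-2 space after centering
        protos = [rng.integers(0, 2, size=20) for _ in range(3)]
        rows = [protos[i % 3] for i in range(42)]
        X = np.array(rows, dtype=float)
        model = fit_pca(_binary(X.astype(np.uint8)), 3)
        assert model.explained_variance_ratio[:2].sum() > 0.999
        # independent oracle: eigendecomposition of the covariance matrix
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            model.explained_variance[:2], eigvals[:2], rtol=1e-8
        )

    def test_constant_matrix_rejected(self):
        values = np.ones((10, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="variance"):
            fit_pca(_binary(values), 2)


class TestProject:
    def test_training_mean_maps_to_origin(self, rng):
        values = rng.integers(0, 2, size=(30, 8)).astype(np.uint8)
        binary = _binary(values)
        model = fit_pca(binary, 3)
        coords = (values.astype(float) - model.training_means) @ model.components.T
        centered = np.zeros((1, 8)) + model.training_means
        origin = (centered - model.training_means) @ model.components.T
        np.testing.assert_allclose(origin, 0.0, atol=1e-12)
        assert coords.shape == (30, 3)

    def test_pair_mismatch_rejected(self, rng):
        values = rng.integers(0, 2, size=(10, 6)).astype(np.uint8)
        binary = _binary(values)
        model = fit_pca(binary, 2)
        other = _binary(values[:, :5])
        with pytest.raises(ValueError, match="mismatch"):
            project(model, other)

    def test_bulk_mixtures_fall_between_state_centroids(self):
        cfg = SyntheticConfig(
            n_states=2, n_genes=200, markers_per_state=40, n_cells_per_state=50,
            noise_sd=0.2, dropout_rate=0.0, batch_sd=0.1, seed=21,
        )
        sc, truth = simulate_states(cfg)
        ref_bulk, _ = simulate_bulk(truth, 60, 0.1, seed=22)
        enc = fit_encoding(sc, ref_bulk, n_top=200)
        sc_binary = encode_relative(sc, enc.pairs)
        model = fit_pca(sc_binary, 2)
        labels = truth.state_of_cell
        coords = model.training_coordinates
        centroids = coords.groupby(labels).mean()["PC1"]
        lo, hi = centroids.min(), centroids.max()
        mixtures = np.array([[0.5, 0.5]] * 5)
        bulk, _ = simulate_bulk(truth, 5, 0.0, seed=23, proportions=mixtures)
        proj = project(model, encode_relative(bulk, enc.pairs))
        assert ((proj["PC1"] > lo) & (proj["PC1"] < hi)).all()


def _rank_sum_oracle(x, y):
    """U statistic of x via exhaustive pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestDeOneVsRest:
    def test_constant_gene_not_significant(self):
        vals = np.vstack([np.ones(12), np.random.default_rng(0).normal(size=12)])
        m = _expr(vals)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.observations)
        table = de_one_vs_rest(m, labels)
        const_rows = table[table["gene"] == "g0"]
        assert (const_rows["p"] == 1.0).all()
        assert not const_rows["significant"].any()

    def test_statistic_matches_exhaustive_rank_oracle(self, rng):
        vals = rng.normal(size=(4, 10))
        vals[1, :5] += 3.0
        m = _expr(vals)
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=m.observations)
        table = de_one_vs_rest(m, labels)
        for gene in m.genes:
            x = m.values.loc[gene, labels == "a"].to_numpy()
            y = m.values.loc[gene, labels == "b"].to_numpy()
            row = table[(table["gene"] == gene) & (table["state"] == "a")].iloc[0]
            assert row["statistic"] == _rank_sum_oracle(x, y)

    def test_bonferroni_definition(self, rng):
        m = _expr(rng.normal(size=(6, 14)))
        labels = pd.Series(["a"] * 7 + ["b"] * 7, index=m.observations)
        table = de_one_vs_rest(m, labels)
        n_tests = 6 * 2
        np.testing.assert_allclose(
            table["p_adj"], np.minimum(1.0, table["p"] * n_tests)
        )
        assert (table["p_adj"] >= table["p"]).all()

    def test_direction_symmetry_two_states(self, rng):
        m = _expr(rng.normal(size=(5, 16)))
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=m.observations)
        table = de_one_vs_rest(m, labels)
        a = table[table["state"] == "a"].set_index("gene")
        b = table[table["state"] == "b"].set_index("gene")
        np.testing.assert_allclose(a["location"], -b["location"])
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-10)

    def test_small_state_rejected(self, rng):
        m = _expr(rng.normal(size=(3, 5)))
        labels = pd.Series(["a"] * 4 + ["b"], index=m.observations)
        with pytest.raises(ValueError, match="b"):
            de_one_vs_rest(m, labels)

    def test_ttest_variant_runs(self, rng):
        m = _expr(rng.normal(size=(4, 12)))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.observations)
        table = de_one_vs_rest(m, labels, test="ttest")
        assert set(table["state"]) == {"a", "b"}
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()


class TestPcGeneCorrelation:
    def test_gene_equal_to_pc_has_rho_one(self, rng):
        pc = rng.normal(size=20)
        vals = rng.normal(size=(5, 20))
        vals[0] = pc
        vals[1] = -pc
        m = _expr(vals)
        coords = pd.DataFrame({"PC1": pc}, index=m.observations)
        table = pc_gene_correlation(m, coords, "PC1").set_index("gene")
        assert table.loc["g0", "rho"] == pytest.approx(1.0)
        assert table.loc["g1", "rho"] == pytest.approx(-1.0)
        assert table.index[-1] == "g1"

    def test_matches_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        vals = rng.normal(size=(8, 20))
        pc = rng.normal(size=20)
        m = _expr(vals)
        coords = pd.DataFrame({"PC1": pc}, index=m.observations)
        # oracle on unfiltered rho values via direct spearman per gene
        table = pc_gene_correlation(m, coords, "PC1")
        rp = rankdata(pc)
        for _, row in table.iterrows():
            rx = rankdata(m.values.loc[row["gene"]].to_numpy())
            expected = np.corrcoef(rx, rp)[0, 1]
            assert row["rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_pc_rejected(self, rng):
        m = _expr(rng.normal(size=(3, 10)))
        coords = pd.DataFrame({"PC1": np.ones(10)}, index=m.observations)
        with pytest.raises(ValueError, match="constant"):
            pc_gene_correlation(m, coords, "PC1")


class TestCrosstab:
    def test_identical_labels_identity_pattern(self):
        labels = pd.Series(["a", "b", "c", "a", "b"])
        table = crosstab_state_proportions(labels, labels)
        np.testing.assert_allclose(table.to_numpy(), np.eye(3))

    def test_rows_sum_to_one(self, rng):
        a = pd.Series(rng.choice(list("abcde"), size=200))
        b = pd.Series(rng.choice(list("uvwxyz"), size=200))
        table = crosstab_state_proportions(a, b)
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_counting(self, rng):
        a = pd.Series(rng.choice([f"s{i}" for i in range(5)], size=300))
        b = pd.Series(rng.choice([f"j{i}" for i in range(6)], size=300))
        table = crosstab_state_proportions(a, b)
        for s in table.index:
            total = (a == s).sum()
            for j in table.columns:
                count = ((a == s) & (b == j)).sum()
                assert table.loc[s, j] == pytest.approx(count / total)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            crosstab_state_proportions(pd.Series(["a"]), pd.Series(["a", "b"]))


class TestEndToEndRecovery:
    def test_encode_cluster_recovers_states(self):
        cfg = SyntheticConfig(
            n_states=4, n_genes=800, markers_per_state=50, n_cells_per_state=80,
            marker_effect=4.0, noise_sd=0.4, dropout_rate=0.2, batch_sd=0.3, seed=0,
        )
        sc, truth = simulate_states(cfg)
        bulk, _ = simulate_bulk(truth, 100, 0.1, seed=200)
        # n_top spans all shared genes: state markers are mostly zero outside
        # their own state, so the MAD filter at small n_top would drop them
        enc = fit_encoding(sc, bulk, n_top=800)
        labels = cluster_cells(encode_relative(sc, enc.pairs), 4)
        ari = adjusted_rand_score(truth.state_of_cell[labels.index], labels)
        assert ari > 0.9
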