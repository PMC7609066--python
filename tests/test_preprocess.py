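import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from scvasc.preprocess import (CountMatrix, embed_cluster, flag_mito, lognormalize,
                               qc_filter, read_mtx_triplet, regress_covariate,
                               variable_genes)


def _count_matrix(X, genotypes=None, mito=None):
    X = np.asarray(X)
    n_cells, n_genes = X.shape
    genotypes = genotypes or ["wt"] * (n_cells // 2) + ["ko"] * (n_cells - n_cells // 2)
    cell_meta = pd.DataFrame(
        {"sample": [f"{g}_s1" for g in genotypes], "genotype": genotypes},
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"))
    gene_meta = pd.DataFrame(
        {"mito": mito if mito is not None else [False] * n_genes},
        index=pd.Index([f"g{j}" for j in range(n_genes)], name="gene"))
    return CountMatrix(X=sp.csr_matrix(X), cell_meta=cell_meta, gene_meta=gene_meta)


class TestReadMtx:
    def _write_triplet(self, tmp_path, entries, n_genes, n_cells, barcodes=None):
        lines = [f"{g} {c} {v}" for g, c, v in entries]
        body = "\n".join(lines)
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            f"{n_genes} {n_cells} {len(entries)}\n" + body + ("\n" if body else ""))
        bcs = barcodes if barcodes is not None else [f"bc{i}" for i in range(n_cells)]
        (tmp_path / "barcodes.tsv").write_text("\n".join(bcs) + "\n")
        (tmp_path / "features.tsv").write_text(
            "\n".join(f"gene{j}" for j in range(n_genes)) + "\n")
        meta = pd.DataFrame({"cell_id": [f"bc{i}" for i in range(n_cells)],
                             "sample": "s1", "genotype": "wt"})
        meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        return (tmp_path / "matrix.mtx", tmp_path / "barcodes.tsv",
                tmp_path / "features.tsv", tmp_path / "meta.tsv")

    def test_hand_fixture_exact_entries(self, tmp_path):
        # 3 cells x 4 genes, 5 nonzeros (MTX is genes x cells, 1-based)
        entries = [(1, 1, 5), (2, 1, 3), (4, 2, 7), (3, 3, 1), (1, 3, 2)]
        paths = self._write_triplet(tmp_path, entries, n_genes=4, n_cells=3)
        matrix = read_mtx_triplet(*paths)
        expected = np.zeros((3, 4))
        for g, c, v in entries:
            expected[c - 1, g - 1] = v
        assert np.array_equal(np.asarray(matrix.X.todense()), expected)

    def test_empty_body(self, tmp_path):
        paths = self._write_triplet(tmp_path, [], n_genes=4, n_cells=3)
        matrix = read_mtx_triplet(*paths)
        assert matrix.X.nnz == 0
        assert matrix.X.shape == (3, 4)

    def test_barcode_count_mismatch(self, tmp_path):
        paths = self._write_triplet(tmp_path, [(1, 1, 1)], n_genes=4, n_cells=3,
                                    barcodes=["bc0", "bc1"])
        with pytest.raises(ValueError, match="barcodes"):
            read_mtx_triplet(*paths)


class TestFlagMito:
    @pytest.mark.parametrize("symbol,expected", [
        ("mt-Co1", True),
        ("Mt-Nd1", True),
        ("Mterf1", False),  # prefix requires the hyphen
        ("Atp5a1", False),
    ])
    def test_examples(self, symbol, expected):
        assert flag_mito([symbol])[0] == expected


class TestQCFilter:
    def test_degenerate_sd_no_removal(self):
        X = np.tile([1, 2, 3], (10, 1))
        matrix = _count_matrix(X, genotypes=["wt"] * 10)
        filtered, report = qc_filter(matrix)
        assert report.n_removed == 0
        assert filtered.n_cells == 10

    def test_mito_above_threshold_removed(self):
        X = np.array([[94, 6], [100, 0], [100, 0], [97, 3]])
        matrix = _count_matrix(X, genotypes=["wt"] * 4, mito=[False, True])
        filtered, report = qc_filter(matrix)
        removed = report.per_cell[~report.per_cell["passed"]]
        assert list(removed.index) == ["c0"]
        assert removed.loc["c0", "reasons"] == "mito"

    def test_mito_exactly_at_threshold_retained(self):
        X = np.array([[95, 5], [100, 0], [100, 0]])
        matrix = _count_matrix(X, genotypes=["wt"] * 3, mito=[False, True])
        _, report = qc_filter(matrix)
        assert report.n_removed == 0

    def test_sd_rule_matches_brute_force_oracle(self):
        detected = [100, 200, 300, 400, 2000]
        # one gene per detected count: cell i expresses `detected[i]` genes
        X = np.zeros((5, 2000), dtype=int)
        for i, d in enumerate(detected):
            X[i, :d] = 1
        matrix = _count_matrix(X, genotypes=["wt"] * 5)
        _, report = qc_filter(matrix)
        arr = np.array(detected, float)
        lo, hi = arr.mean() - 2 * arr.std(ddof=1), arr.mean() + 2 * arr.std(ddof=1)
        expected_removed = {f"c{i}" for i, d in enumerate(detected)
                            if d < lo or d > hi}
        got = set(report.per_cell.index[~report.per_cell["passed"]])
        assert got == expected_removed

    def test_grouping_is_per_genotype(self):
        # wt cells all identical; ko cells contain one clear outlier
        ko_detected = [100, 110, 90, 105, 95, 100, 110, 280]
        X = np.zeros((4 + len(ko_detected), 300), dtype=int)
        for i in range(4):
            X[i, :100] = 1
        for i, d in enumerate(ko_detected):
            X[4 + i, :d] = 1
        matrix = _count_matrix(X, genotypes=["wt"] * 4 + ["ko"] * len(ko_detected))
        _, report = qc_filter(matrix)
        # oracle: ko bounds from the ko group alone
        arr = np.array(ko_detected, float)
        hi = arr.mean() + 2 * arr.std(ddof=1)
        assert 280 > hi  # the outlier really is outside its group bounds
        failed = set(report.per_cell.index[~report.per_cell["passed"]])
        assert failed == {"c11"}

    def test_totals_consistent(self, small_sim):
        counts, _ = small_sim
        _, report = qc_filter(counts)
        assert report.n_removed + report.n_retained == report.n_input
        failed = report.per_cell[~report.per_cell["passed"]]
        assert (failed["reasons"].str.len() > 0).all()

    def test_small_group_errors(self):
        matrix = _count_matrix(np.eye(3, dtype=int), genotypes=["wt", "wt", "ko"])
        with pytest.raises(ValueError, match="fewer than 2"):
            qc_filter(matrix)


class TestLognormalize:
    def test_zero_count_zero_value(self):
        matrix = _count_matrix([[0, 5], [3, 2]], genotypes=["wt", "wt"])
        norm = lognormalize(matrix)
        assert norm.values[0, 0] == 0.0

    def test_closed_form_value(self):
        X = np.zeros((2, 2), dtype=int)
        X[0] = [5, 4995]
        X[1] = [10, 90]
        norm = lognormalize(_count_matrix(X, genotypes=["wt", "wt"]), scale=10000)
        assert norm.values[0, 0] == pytest.approx(np.log(11))

    def test_default_scale_is_10000(self):
        matrix = _count_matrix([[1, 1], [2, 2]], genotypes=["wt", "wt"])
        assert lognormalize(matrix).scale == 10000

    def test_zero_total_cell_errors(self):
        matrix = _count_matrix([[0, 0], [1, 1]], genotypes=["wt", "wt"])
        with pytest.raises(ValueError, match="zero total"):
            lognormalize(matrix)

    def test_roundtrip_invariant(self, small_norm):
        norm, _, _ = small_norm
        values = np.asarray(norm.values.todense())
        reconstructed = np.expm1(values).sum(axis=1) * norm.n_umi / norm.scale
        assert np.allclose(reconstructed, norm.n_umi, rtol=1e-6)

    def test_monotone_in_count(self):
        X = np.array([[0, 1, 2, 3, 94]])
        matrix = _count_matrix(X, genotypes=["wt"] * 1)
        # need >=1 cell only for normalization; construct 2 rows to satisfy meta
        X2 = np.vstack([X, X])
        norm = lognormalize(_count_matrix(X2, genotypes=["wt", "wt"]))
        row = np.asarray(norm.values[0].todense()).ravel()
        assert np.all(np.diff(row) > 0)


class TestRegressCovariate:
    def test_constant_covariate_gives_zscores(self, small_norm):
        norm, _, _ = small_norm
        out = regress_covariate(norm, covariate=np.ones(norm.values.shape[0]))
        Y = np.asarray(norm.values.todense())
        sd = Y.std(axis=0, ddof=1)
        expected = np.zeros_like(Y)
        ok = sd > 0
        expected[:, ok] = (Y[:, ok] - Y[:, ok].mean(axis=0)) / sd[ok]
        assert np.allclose(out, expected, atol=1e-10)

    def test_perfectly_linear_gene_zeroed(self):
        n = 20
        covariate = np.linspace(1, 2, n)
        X = np.ones((n, 3), dtype=int)
        norm = lognormalize(_count_matrix(X))
        norm.values = sp.csr_matrix(np.column_stack([
            3.0 * covariate + 1.0, np.random.default_rng(0).normal(size=n),
            np.zeros(n)]))
        out = regress_covariate(norm, covariate=covariate)
        assert np.allclose(out[:, 0], 0.0, atol=1e-10)
        assert np.allclose(out[:, 2], 0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(20, 5))
        covariate = rng.normal(size=20)
        X = np.ones((20, 5), dtype=int)
        norm = lognormalize(_count_matrix(X))
        norm.values = sp.csr_matrix(Y)
        out = regress_covariate(norm, covariate=covariate)
        design = np.column_stack([np.ones(20), covariate])
        for j in range(5):
            beta, *_ = np.linalg.lstsq(design, Y[:, j], rcond=None)
            resid = Y[:, j] - design @ beta
            expected = resid / resid.std(ddof=1)
            assert np.allclose(out[:, j], expected, atol=1e-8)


class TestVariableGenes:
    def test_constant_genes_never_selected(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.poisson(2, size=100) for _ in range(10)]
                            + [np.full(100, 3)] * 5)
        norm = lognormalize(_count_matrix(X.astype(int),
                                          genotypes=["wt"] * 100))
        top = variable_genes(norm, n_top=10)
        constant = {f"g{j}" for j in range(10, 15)}
        assert not (set(top) & constant)

    def test_planted_high_variance_recovered(self):
        rng = np.random.default_rng(6)
        n, flat, hot = 400, 150, 50
        # flat genes span a range of means so they anchor the variance trend
        flat_means = rng.uniform(0.2, 6.0, size=flat)
        base = rng.poisson(flat_means, size=(n, flat))
        labels = rng.integers(0, 2, size=n)
        planted = np.where(labels[:, None] == 1,
                           rng.poisson(8.0, size=(n, hot)),
                           rng.poisson(0.5, size=(n, hot)))
        X = np.hstack([base, planted])
        norm = lognormalize(_count_matrix(X.astype(int), genotypes=["wt"] * n))
        top = variable_genes(norm, n_top=100)
        planted_names = {f"g{j}" for j in range(flat, flat + hot)}
        assert planted_names <= set(top)

    def test_n_top_exceeds_gene_count(self, small_norm):
        norm, _, _ = small_norm
        with pytest.raises(ValueError, match="n_top"):
            variable_genes(norm, n_top=norm.values.shape[1] + 1)


class TestEmbedCluster:
    def _blobs(self, seed=0, n=200, sep=10.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 10))
        b = rng.normal(sep, 1, size=(n, 10))
        return np.vstack([a, b]), np.array([0] * n + [1] * n)

    def test_two_separated_blobs(self):
        data, truth = self._blobs()
        labels = embed_cluster(data, n_pcs=5, resolution=0.1, neighbors_k=15, seed=0)
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_default_n_pcs_is_30(self):
        import inspect

        assert inspect.signature(embed_cluster).parameters["n_pcs"].default == 30

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(50, 5))
        b = rng.normal(12, 1, size=(150, 5))
        labels = embed_cluster(np.vstack([a, b]), n_pcs=3, resolution=0.1,
                               neighbors_k=10, seed=0)
        sizes = pd.Series(labels).value_counts()
        assert sizes.loc[0] >= sizes.loc[1]

    def test_permutation_invariance(self):
        data, truth = self._blobs(seed=2)
        labels = embed_cluster(data, n_pcs=5, resolution=0.1, neighbors_k=15, seed=0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(data))
        labels_perm = embed_cluster(data[perm], n_pcs=5, resolution=0.1,
                                    neighbors_k=15, seed=0)
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_neighbors_exceeds_cells_errors(self):
        data, _ = self._blobs(n=10)
        with pytest.raises(ValueError, match="neighbors_k"):
            embed_cluster(data, n_pcs=3, resolution=0.5, neighbors_k=50, seed=0)

    def test_n_pcs_exceeds_dims_errors(self):
        data, _ = self._blobs()
        with pytest.raises(ValueError, match="n_pcs"):
            embed_cluster(data, n_pcs=100, resolution=0.5, neighbors_k=10, seed=0)
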