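"""Count-matrix I/O, quality control, normalization and graph clustering.

The entry substrate is a cells x genes integer :class:`CountMatrix` with
per-cell sample/genotype metadata.  QC removes cells whose detected-gene
count falls strictly outside mean +/- k*SD within their genotype group or
whose mitochondrial count fraction strictly exceeds a threshold.  Expression
is log-normalized to a fixed scale factor, optionally regressed on total
molecule counts, reduced to principal components and clustered on a
shared-nearest-neighbor graph by modularity optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CountMatrix",
    "QCReport",
    "NormalizedMatrix",
    "read_mtx_triplet",
    "flag_mito",
    "qc_filter",
    "lognormalize",
    "regress_covariate",
    "variable_genes",
    "pca_embed",
    "snn_graph",
    "cluster_graph",
    "embed_cluster",
]

VALID_GENOTYPES = ("wt", "ko")


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer counts with cell and gene metadata."""

    X: sp.csr_matrix
    cell_meta: pd.DataFrame  # index: cell_id; columns: sample, genotype
    gene_meta: pd.DataFrame  # index: gene symbol; columns: mito (bool)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match metadata "
                f"({len(self.cell_meta)} cells, {len(self.gene_meta)} genes)"
            )
        if self.cell_meta.index.duplicated().any():
            dup = self.cell_meta.index[self.cell_meta.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate cell ids: {dup}")
        if self.gene_meta.index.duplicated().any():
            dup = self.gene_meta.index[self.gene_meta.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene symbols: {dup}")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def cells(self) -> pd.Index:
        return self.cell_meta.index


@dataclass
class QCReport:
    per_cell: pd.DataFrame  # detected, mito_frac, group, passed, reasons
    group_stats: pd.DataFrame  # per group: n, detected mean/sd, bounds
    removed_by_rule: dict[str, int]
    n_input: int
    n_removed: int
    n_retained: int


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the raw counts kept for variance ranking."""

    values: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    n_umi: np.ndarray
    scale: float
    counts: sp.csr_matrix | None = None
    regression_covariate: str | None = None

    @property
    def genes(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def cells(self) -> pd.Index:
        return self.cell_meta.index

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense per-cell values for a single gene symbol."""
        if gene not in self.gene_meta.index:
            raise KeyError(f"gene not present in matrix: {gene!r}")
        j = self.gene_meta.index.get_loc(gene)
        return np.asarray(self.values[:, j].todense()).ravel()


def flag_mito(gene_symbols, prefix: str = "mt-") -> np.ndarray:
    """Case-insensitive prefix match marking mitochondrial gene symbols."""
    prefix = prefix.lower()
    return np.array([str(s).lower().startswith(prefix) for s in gene_symbols])


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(matrix_path, barcodes_path, features_path, cell_meta,
                     mito_prefix: str = "mt-") -> CountMatrix:
    """Read a Cell-Ranger-style triplet (genes x cells MTX + TSVs) into a CountMatrix.

    ``cell_meta`` is a TSV path or DataFrame with columns cell_id, sample,
    genotype; it is joined onto the barcodes.
    """
    mat = mmread(str(matrix_path))
    barcodes = _read_lines(barcodes_path)
    features = _read_lines(features_path)
    n_feat, n_bc = mat.shape
    if n_feat != len(features):
        raise ValueError(
            f"{features_path}: matrix declares {n_feat} features but file has {len(features)}"
        )
    if n_bc != len(barcodes):
        raise ValueError(
            f"{barcodes_path}: matrix declares {n_bc} barcodes but file has {len(barcodes)}"
        )
    data = np.asarray(mat.todense() if sp.issparse(mat) else mat)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{matrix_path}: non-integer entries in count matrix")
    X = sp.csr_matrix(data.T.astype(np.int64))

    if not isinstance(cell_meta, pd.DataFrame):
        cell_meta = pd.read_csv(cell_meta, sep="\t")
    meta = cell_meta.set_index("cell_id").reindex(barcodes)
    if meta["genotype"].isna().any():
        missing = meta.index[meta["genotype"].isna()][:5].tolist()
        raise ValueError(f"cell metadata missing for barcodes: {missing}")
    bad = set(meta["genotype"]) - set(VALID_GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotypes {sorted(bad)}; expected {VALID_GENOTYPES}")
    gene_meta = pd.DataFrame({"mito": flag_mito(features, mito_prefix)},
                             index=pd.Index(features, name="gene"))
    return CountMatrix(X=X, cell_meta=meta[["sample", "genotype"]], gene_meta=gene_meta)


def qc_filter(matrix: CountMatrix, sd_k: float = 2.0, mito_max: float = 0.05,
              group_by: str = "genotype") -> tuple[CountMatrix, QCReport]:
    """Remove cells outside mean +/- sd_k*SD detected genes (within group) or
    with mito fraction strictly above ``mito_max``.

    Both rules are evaluated on the input matrix in a single pass; a removed
    cell carries every reason that applies.
    """
    X = matrix.X
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(np.float64)
    mito_mask = matrix.gene_meta["mito"].to_numpy()
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)

    groups = matrix.cell_meta[group_by]
    stats_rows = []
    lo = np.empty(matrix.n_cells)
    hi = np.empty(matrix.n_cells)
    for g, idx in groups.groupby(groups).groups.items():
        pos = matrix.cell_meta.index.get_indexer(idx)
        if len(pos) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells; SD undefined")
        mean = detected[pos].mean()
        sd = detected[pos].std(ddof=1)
        lo[pos] = mean - sd_k * sd
        hi[pos] = mean + sd_k * sd
        stats_rows.append({"group": g, "n": len(pos), "detected_mean": mean,
                           "detected_sd": sd, "lower": mean - sd_k * sd,
                           "upper": mean + sd_k * sd})
    fail_sd = (detected < lo) | (detected > hi)
    fail_mito = mito_frac > mito_max
    failed = fail_sd | fail_mito
    reasons = [
        ",".join(r for r, f in (("detected_sd", fail_sd[i]), ("mito", fail_mito[i])) if f)
        for i in range(matrix.n_cells)
    ]
    per_cell = pd.DataFrame({
        "group": groups.to_numpy(),
        "detected": detected,
        "mito_frac": mito_frac,
        "passed": ~failed,
        "reasons": reasons,
    }, index=matrix.cells)

    keep = ~failed
    filtered = CountMatrix(
        X=matrix.X[keep],
        cell_meta=matrix.cell_meta.loc[keep],
        gene_meta=matrix.gene_meta,
    )
    report = QCReport(
        per_cell=per_cell,
        group_stats=pd.DataFrame(stats_rows).set_index("group"),
        removed_by_rule={"detected_sd": int(fail_sd.sum()), "mito": int(fail_mito.sum())},
        n_input=matrix.n_cells,
        n_removed=int(failed.sum()),
        n_retained=int(keep.sum()),
    )
    return filtered, report


def lognormalize(matrix: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """value = ln(1 + count * scale / cell_total); keeps sparsity."""
    totals = np.asarray(matrix.X.sum(axis=1)).ravel().astype(np.float64)
    if np.any(totals == 0):
        zero = matrix.cells[totals == 0][:5].tolist()
        raise ValueError(f"cells with zero total counts: {zero}")
    values = matrix.X.astype(np.float64).tocsr(copy=True)
    row_rep = np.repeat(np.arange(matrix.n_cells), np.diff(values.indptr))
    values.data = np.log1p(values.data * scale / totals[row_rep])
    return NormalizedMatrix(
        values=values,
        cell_meta=matrix.cell_meta,
        gene_meta=matrix.gene_meta,
        n_umi=totals,
        scale=scale,
        counts=matrix.X,
    )


def regress_covariate(norm: NormalizedMatrix, covariate: np.ndarray | None = None) -> np.ndarray:
    """Per-gene residuals of a linear fit on the covariate, then z-scaled.

    Default covariate is the per-cell total molecule count.  Genes with zero
    residual variance map to all-zero columns.  Returns a dense cells x genes
    array.
    """
    c = norm.n_umi if covariate is None else np.asarray(covariate, dtype=np.float64)
    if not np.all(np.isfinite(c)):
        raise ValueError("covariate contains non-finite values")
    Y = np.asarray(norm.values.todense(), dtype=np.float64)
    c_centered = c - c.mean()
    c_var = float(c_centered @ c_centered)
    if c_var > 0:
        beta = (c_centered @ Y) / c_var
    else:
        beta = np.zeros(Y.shape[1])
    resid = Y - Y.mean(axis=0) - np.outer(c_centered, beta)
    sd = resid.std(axis=0, ddof=1)
    # residual SDs at floating-point noise level count as zero variance
    eps = 1e-10 * (np.abs(Y).max(axis=0) + 1.0)
    out = np.zeros_like(resid)
    ok = sd > eps
    out[:, ok] = resid[:, ok] / sd[ok]
    return out


def variable_genes(norm: NormalizedMatrix, n_top: int = 2000) -> list[str]:
    """Top genes by standardized variance of trend-standardized raw counts.

    The expected SD of each gene is taken from a degree-2 polynomial fit of
    log10(variance) on log10(mean) over genes with positive mean and variance;
    counts are standardized against it, clipped at sqrt(n_cells), and ranked
    by the variance of the clipped values.  Ties break by gene symbol.
    """
    if norm.counts is None:
        raise ValueError("raw counts not available on this NormalizedMatrix")
    if n_top > norm.counts.shape[1]:
        raise ValueError(f"n_top={n_top} exceeds gene count {norm.counts.shape[1]}")
    X = np.asarray(norm.counts.todense(), dtype=np.float64)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    std_var = np.zeros(X.shape[1])
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 3:
        coeffs = np.polyfit(np.log10(mean[fit_mask]), np.log10(var[fit_mask]), deg=2)
        expected_sd = np.sqrt(10 ** np.polyval(coeffs, np.log10(mean[fit_mask])))
        Z = (X[:, fit_mask] - mean[fit_mask]) / expected_sd
        np.clip(Z, -np.sqrt(n), np.sqrt(n), out=Z)
        std_var[fit_mask] = Z.var(axis=0, ddof=1)
    else:  # too few genes for a trend; fall back to raw variance
        std_var = var
    order = sorted(range(X.shape[1]), key=lambda j: (-std_var[j], norm.genes[j]))
    return [norm.genes[j] for j in order[:n_top]]


def pca_embed(scaled: np.ndarray, n_pcs: int = 30, seed: int = 0) -> np.ndarray:
    if n_pcs > min(scaled.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min matrix dimension {min(scaled.shape)}")
    pca = PCA(n_components=n_pcs, random_state=seed)
    return pca.fit_transform(scaled)


def snn_graph(embedding: np.ndarray, neighbors_k: int = 20,
              prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets (self included),
    restricted to kNN pairs and pruned below ``prune``."""
    n = embedding.shape[0]
    if neighbors_k >= n:
        raise ValueError(f"neighbors_k={neighbors_k} must be < number of cells {n}")
    nn = NearestNeighbors(n_neighbors=neighbors_k).fit(embedding)
    knn = nn.kneighbors(return_distance=False)
    # neighbor sets including self
    sets = sp.lil_matrix((n, n), dtype=np.float64)
    rows = np.repeat(np.arange(n), neighbors_k)
    adj = sp.csr_matrix((np.ones(n * neighbors_k), (rows, knn.ravel())), shape=(n, n))
    adj = adj + sp.identity(n, format="csr")
    adj.data = np.minimum(adj.data, 1.0)
    shared = adj @ adj.T  # |intersection| of neighbor sets
    shared = shared.multiply(adj.maximum(adj.T))  # keep only kNN pairs
    shared = shared.tocoo()
    k1 = neighbors_k + 1
    jacc = shared.data / (2 * k1 - shared.data)
    keep = (jacc >= prune) & (shared.row != shared.col)
    g = sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return g.maximum(g.T)


def cluster_graph(graph: sp.csr_matrix, resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Modularity-based community detection; labels 0..k-1 by decreasing size."""
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(n=graph.shape[0], edges=list(zip(coo.row, coo.col)),
                 edge_attrs={"weight": coo.data})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    order = pd.Series(labels).value_counts(sort=True).index  # size desc, label asc ties
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels])


def embed_cluster(scaled: np.ndarray, n_pcs: int = 30, resolution: float = 0.8,
                  neighbors_k: int = 20, seed: int = 0) -> np.ndarray:
    """PCA -> SNN graph -> modularity clustering; deterministic under fixed seed."""
    emb = pca_embed(scaled, n_pcs=n_pcs, seed=seed)
    graph = snn_graph(emb, neighbors_k=neighbors_k)
    return cluster_graph(graph, resolution=resolution, seed=seed)
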