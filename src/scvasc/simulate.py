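"""Synthetic single-cell and spatial count data with known ground truth.

Cells are drawn per cluster and genotype from a negative binomial
(mean, inverse-dispersion) model with cluster-specific marker genes,
genotype-specific differential effects, a Beta-distributed mitochondrial
count share, and zero-inflated positivity-profile genes.  Cell counts per
cluster/genotype are set deterministically from the configuration so that
expansion factors are exact.  Spots are mixtures of cluster mean profiles
with optional lesion / proliferation / tip signal genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .preprocess import CountMatrix, flag_mito
from .spatial import SpotMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cells", "simulate_spots",
           "write_cells_mtx", "write_spots_tsv"]


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    n_clusters: int
    cells_per_cluster_wt: list[int]
    expansion_factor_ko: list[float]
    n_genes: int
    baseline_mean: float = 0.5
    mean_shape: float = 1.0  # gamma shape for per-gene baseline mean spread
    dispersion: float = 2.0  # NB inverse-dispersion ("size")
    markers_per_cluster: int = 5
    marker_fold: float = 8.0
    de_genes_ko: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    mito_gene_count: int = 0
    mito_fraction_mean: float = 0.02
    mito_fraction_sd: float = 0.0
    # gene -> cluster -> genotype -> target positive fraction
    positivity_profiles: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)
    gene_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters <= 0:
            raise SimulationConfigError("n_clusters must be positive")
        if len(self.cells_per_cluster_wt) != self.n_clusters:
            raise SimulationConfigError("cells_per_cluster_wt must have length n_clusters")
        if any(c < 0 for c in self.cells_per_cluster_wt):
            raise SimulationConfigError("cells_per_cluster_wt entries must be >= 0")
        if len(self.expansion_factor_ko) != self.n_clusters:
            raise SimulationConfigError("expansion_factor_ko must have length n_clusters")
        if any(f <= 0 for f in self.expansion_factor_ko):
            raise SimulationConfigError("expansion_factor_ko entries must be > 0")
        if self.n_genes <= 0:
            raise SimulationConfigError("n_genes must be positive")
        if self.baseline_mean <= 0:
            raise SimulationConfigError("baseline_mean must be positive")
        if self.mean_shape <= 0:
            raise SimulationConfigError("mean_shape must be positive")
        if self.dispersion <= 0:
            raise SimulationConfigError("dispersion must be positive")
        if self.marker_fold < 1:
            raise SimulationConfigError("marker_fold must be >= 1")
        if self.mito_gene_count < 0 or self.mito_gene_count > self.n_genes:
            raise SimulationConfigError("mito_gene_count out of range")
        if not 0 <= self.mito_fraction_mean < 1:
            raise SimulationConfigError("mito_fraction_mean must be in [0, 1)")
        if self.mito_fraction_sd < 0:
            raise SimulationConfigError("mito_fraction_sd must be >= 0")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise SimulationConfigError("gene_names must have length n_genes")
        for gene, per_cluster in self.positivity_profiles.items():
            for cl, per_gt in per_cluster.items():
                for gt, frac in per_gt.items():
                    if not 0 <= frac <= 1:
                        raise SimulationConfigError(
                            f"positivity_profiles[{gene!r}][{cl}][{gt!r}] must be in [0, 1]"
                        )

    def names(self) -> list[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        names = [f"mt-G{i:04d}" for i in range(self.mito_gene_count)]
        names += [f"G{i:04d}" for i in range(self.mito_gene_count, self.n_genes)]
        return names


@dataclass
class GroundTruth:
    cells: pd.DataFrame  # index cell_id; columns: cluster, genotype, sample
    genes: pd.DataFrame  # index gene; columns: marker_of, mito, profile
    spots: pd.DataFrame | None = None  # index spot_id; dominant_class, ec_fraction, lesion, proliferating, tip


def _cluster_mean_matrix(config: SimulationConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-gene per-cluster NB means (wt), plus gene truth metadata.

    Per-gene baseline means are gamma-distributed around ``baseline_mean`` so
    that the mean-variance trend is anchored by null genes at every mean.
    Marker genes are taken from the non-mito, non-profile pool in blocks of
    ``markers_per_cluster`` per cluster; positivity-profile genes are handled
    separately (zero-inflated) and get mean 0 here.
    """
    names = config.names()
    mito = flag_mito(names)
    profile = np.array([n in config.positivity_profiles for n in names])
    base = rng.gamma(config.mean_shape,
                     config.baseline_mean / config.mean_shape,
                     size=config.n_genes)
    base = np.maximum(base, 0.02 * config.baseline_mean)
    means = np.tile(base[:, None], (1, config.n_clusters))

    marker_of = np.full(config.n_genes, -1)
    pool = [i for i in range(config.n_genes) if not mito[i] and not profile[i]]
    need = config.markers_per_cluster * config.n_clusters
    if need > len(pool):
        raise SimulationConfigError(
            f"markers_per_cluster: need {need} marker genes but only {len(pool)} available"
        )
    for c in range(config.n_clusters):
        block = pool[c * config.markers_per_cluster:(c + 1) * config.markers_per_cluster]
        for i in block:
            marker_of[i] = c
            # markers sit at the configured baseline so every cluster gets
            # equally strong signal regardless of the gamma draw
            means[i, :] = config.baseline_mean
            means[i, c] = config.baseline_mean * config.marker_fold
    means[profile, :] = 0.0
    genes = pd.DataFrame(
        {"marker_of": marker_of, "mito": mito, "profile": profile},
        index=pd.Index(names, name="gene"),
    )
    return means, genes


def _beta_share(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    var = sd ** 2
    nu = mean * (1 - mean) / var - 1
    if nu <= 0:
        raise SimulationConfigError("mito_fraction_sd too large for the given mean")
    return rng.beta(mean * nu, (1 - mean) * nu, size=size)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial draws with mean mu and inverse-dispersion size_param."""
    mu = np.asarray(mu, dtype=np.float64)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = size_param / (size_param + mu[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_cells(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a cells x genes count matrix with the configured structure."""
    rng = np.random.default_rng(config.seed)
    means, gene_truth = _cluster_mean_matrix(config, rng)
    names = gene_truth.index
    mito_idx = np.where(gene_truth["mito"].to_numpy())[0]
    name_to_idx = {n: i for i, n in enumerate(names)}

    n_ko = [int(round(w * f)) for w, f in
            zip(config.cells_per_cluster_wt, config.expansion_factor_ko)]

    rows, cell_ids, cell_cluster, cell_geno = [], [], [], []
    for gt, counts_per_cluster in (("wt", config.cells_per_cluster_wt), ("ko", n_ko)):
        for c in range(config.n_clusters):
            n_cells = counts_per_cluster[c]
            if n_cells == 0:
                continue
            mu = means[:, c].copy()
            if gt == "ko":
                for gene, effect in config.de_genes_ko.get(c, []):
                    if gene not in name_to_idx:
                        raise SimulationConfigError(f"de_genes_ko: unknown gene {gene!r}")
                    mu[name_to_idx[gene]] *= np.exp(effect)
            # allocate a Beta share of the expected depth to mito genes
            block_mu = np.tile(mu, (n_cells, 1))
            if len(mito_idx) and config.mito_fraction_mean > 0:
                share = _beta_share(rng, config.mito_fraction_mean,
                                    config.mito_fraction_sd, n_cells)
                nonmito_total = mu.sum() - mu[mito_idx].sum()
                block_mu *= (1 - share)[:, None]
                mito_mu = share * nonmito_total / (1 - share) / len(mito_idx)
                block_mu[:, mito_idx] = mito_mu[:, None]
            block = _nb_draw(rng, block_mu, config.dispersion)
            # zero-inflated positivity-profile genes: positive cells get 1 + NB
            for gene, per_cluster in config.positivity_profiles.items():
                frac = per_cluster.get(c, {}).get(gt, 0.0)
                j = name_to_idx[gene]
                mask = rng.random(n_cells) < frac
                block[:, j] = mask * (1 + _nb_draw(
                    rng, np.full(n_cells, config.baseline_mean), config.dispersion))
            rows.append(block)
            start = len(cell_ids)
            cell_ids += [f"{gt}_c{c}_{start + i}" for i in range(n_cells)]
            cell_cluster += [c] * n_cells
            cell_geno += [gt] * n_cells

    X = sp.csr_matrix(np.vstack(rows))
    cell_meta = pd.DataFrame({
        "sample": [f"{g}_s1" for g in cell_geno],
        "genotype": cell_geno,
    }, index=pd.Index(cell_ids, name="cell_id"))
    truth_cells = pd.DataFrame({
        "cluster": cell_cluster,
        "genotype": cell_geno,
        "sample": cell_meta["sample"].to_numpy(),
    }, index=cell_meta.index)
    matrix = CountMatrix(X=X, cell_meta=cell_meta,
                         gene_meta=gene_truth[["mito"]].copy())
    return matrix, GroundTruth(cells=truth_cells, genes=gene_truth)


def simulate_spots(config: SimulationConfig, n_spots: int, mixing: np.ndarray, *,
                   ec_clusters: list[int] | None = None,
                   lesion_flags: np.ndarray | None = None,
                   proliferating_flags: np.ndarray | None = None,
                   tip_flags: np.ndarray | None = None,
                   ec_genes: tuple[str, ...] = ("Cldn5", "Cdh5", "Pecam1"),
                   lesion_genes: tuple[str, ...] = ("Klf4", "Klf2", "Ly6a", "Thbd"),
                   tip_genes: tuple[str, ...] = ("Apln", "Plaur"),
                   proliferation_gene: str = "Mki67",
                   depth: float = 20000.0,
                   on_count: float = 15.0,
                   off_count: float = 0.1,
                   seed: int | None = None) -> tuple[SpotMatrix, GroundTruth]:
    """Spot counts as Poisson mixtures of cluster mean profiles on a grid.

    Signal genes (EC identity, lesion, tip, proliferation) must exist in the
    configured gene names; their expected counts interpolate between
    ``off_count`` and ``on_count`` driven by the spot's EC fraction or its
    lesion / proliferation / tip flag.
    """
    mixing = np.asarray(mixing, dtype=np.float64)
    if mixing.shape != (n_spots, config.n_clusters):
        raise ValueError(f"mixing must be {n_spots} x {config.n_clusters}")
    row_sums = mixing.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"mixing row {bad} sums to {row_sums[bad]}, expected 1")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    means, gene_truth = _cluster_mean_matrix(config, rng)
    names = list(gene_truth.index)
    name_to_idx = {n: i for i, n in enumerate(names)}

    signal = {g: "ec" for g in ec_genes}
    signal.update({g: "lesion" for g in lesion_genes})
    signal.update({g: "tip" for g in tip_genes})
    signal[proliferation_gene] = "proliferation"
    missing = [g for g in signal if g not in name_to_idx]
    if missing:
        raise ValueError(f"signal genes absent from configured gene names: {missing}")

    if ec_clusters is None:
        ec_clusters = list(range(config.n_clusters))
    ec_fraction = mixing[:, ec_clusters].sum(axis=1)
    zeros = np.zeros(n_spots, dtype=bool)
    lesion = zeros if lesion_flags is None else np.asarray(lesion_flags, dtype=bool)
    prolif = zeros if proliferating_flags is None else np.asarray(proliferating_flags, dtype=bool)
    tip = zeros if tip_flags is None else np.asarray(tip_flags, dtype=bool)

    profiles = means / means.sum(axis=0, keepdims=True)  # genes x clusters
    mu = depth * (mixing @ profiles.T)  # spots x genes
    drivers = {"ec": ec_fraction, "lesion": lesion.astype(float),
               "tip": tip.astype(float), "proliferation": prolif.astype(float)}
    for gene, kind in signal.items():
        mu[:, name_to_idx[gene]] = off_count + (on_count - off_count) * drivers[kind]
    counts = rng.poisson(mu).astype(np.int64)

    side = int(np.ceil(np.sqrt(n_spots)))
    xy = np.array([(i % side, i // side) for i in range(n_spots)])
    spot_ids = pd.Index([f"spot_{i:04d}" for i in range(n_spots)], name="spot_id")
    positions = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1],
                              "sample": "ko_sp1", "genotype": "ko"}, index=spot_ids)
    spot_matrix = SpotMatrix(X=sp.csr_matrix(counts), spot_meta=positions,
                             gene_meta=gene_truth[["mito"]].copy())
    truth_spots = pd.DataFrame({
        "dominant_class": mixing.argmax(axis=1),
        "ec_fraction": ec_fraction,
        "lesion": lesion,
        "proliferating": prolif,
        "tip": tip,
    }, index=spot_ids)
    truth = GroundTruth(cells=pd.DataFrame(), genes=gene_truth, spots=truth_spots)
    return spot_matrix, truth


def write_cells_mtx(matrix: CountMatrix, truth: GroundTruth, outdir) -> None:
    """Write Cell-Ranger-style triplet plus metadata and truth tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(matrix.X.T), field="integer")
    (outdir / "barcodes.tsv").write_text("\n".join(matrix.cells) + "\n")
    (outdir / "features.tsv").write_text("\n".join(matrix.genes) + "\n")
    matrix.cell_meta.reset_index().to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    truth.cells.reset_index().to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.reset_index().to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


def write_spots_tsv(spots: SpotMatrix, truth: GroundTruth, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dense = pd.DataFrame(np.asarray(spots.X.todense()),
                         index=spots.spot_meta.index, columns=spots.gene_meta.index)
    table = pd.concat([spots.spot_meta[["x", "y"]], dense], axis=1)
    table.reset_index().to_csv(outdir / "spots.tsv", sep="\t", index=False)
    if truth.spots is not None:
        truth.spots.reset_index().to_csv(outdir / "truth_spots.tsv", sep="\t", index=False)
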