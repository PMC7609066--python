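"""Spot classification by conjunctive co-expression thresholds.

Spots are classified on their log-normalized values: an endothelial (EC)
spot must exceed the identity threshold on every EC identity gene; lesion
and tip classes add their own gene panels; proliferating classes additionally
require the proliferation gene above its (higher) threshold.  Proliferation
proportions between two spot classes are compared with a two-sided Fisher
exact test after merging samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = ["SpotMatrix", "SpotRules", "classify_spots", "proliferation_fisher",
           "spot_gene_overlay", "read_spots_tsv"]

FLAG_COLUMNS = [
    "ec", "proliferating_ec", "lesion_ec", "proliferating_lesion_ec",
    "tip_ec", "tip_lesion_ec", "proliferating_tip_ec", "proliferating_tip_lesion_ec",
]


@dataclass
class SpotMatrix:
    """Spots x genes counts with positions and sample/genotype metadata."""

    X: sp.csr_matrix
    spot_meta: pd.DataFrame  # index spot_id; columns x, y, sample, genotype
    gene_meta: pd.DataFrame  # index gene symbol

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.spot_meta), len(self.gene_meta)):
            raise ValueError("matrix shape does not match spot/gene metadata")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")
        dup = self.spot_meta.groupby("sample").apply(
            lambda d: d.duplicated(subset=["x", "y"]).any(), include_groups=False)
        if dup.any():
            raise ValueError(f"duplicate positions within sample(s): {list(dup[dup].index)}")

    @property
    def genes(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def spots(self) -> pd.Index:
        return self.spot_meta.index

    def lognormalized(self, scale: float = 1e4) -> sp.csr_matrix:
        """Same log-normalization as cells: ln(1 + count * scale / spot_total).

        All-zero spots have no entries to rescale and simply stay zero.
        """
        totals = np.asarray(self.X.sum(axis=1)).ravel().astype(np.float64)
        totals[totals == 0] = 1.0
        values = self.X.astype(np.float64).tocsr(copy=True)
        row_rep = np.repeat(np.arange(self.X.shape[0]), np.diff(values.indptr))
        values.data = np.log1p(values.data * scale / totals[row_rep])
        return values


@dataclass
class SpotRules:
    """Gene panels and thresholds for the co-expression classification."""

    ec_genes: tuple[str, ...] = ("Cldn5", "Cdh5", "Pecam1")
    lesion_genes: tuple[str, ...] = ("Klf4", "Klf2", "Ly6a", "Thbd")
    tip_genes: tuple[str, ...] = ("Apln", "Plaur")
    proliferation_gene: str = "Mki67"
    identity_threshold: float = 0.5
    proliferation_threshold: float = 1.0
    scale: float = 1e4


def classify_spots(spots: SpotMatrix | None, rules: SpotRules | None = None,
                   values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Boolean flags per spot under the conjunctive threshold rules.

    The implication hierarchy (every derived flag implies ``ec``;
    ``proliferating_lesion_ec`` implies ``lesion_ec`` etc.) holds by
    construction.  ``values`` may supply pre-normalized per-spot expression
    (spots x genes DataFrame) directly; otherwise the spot counts are
    log-normalized with the rule's scale factor.
    """
    rules = rules or SpotRules()
    all_genes = (list(rules.ec_genes) + list(rules.lesion_genes)
                 + list(rules.tip_genes) + [rules.proliferation_gene])
    if values is not None:
        missing = [g for g in all_genes if g not in values.columns]
        if missing:
            raise ValueError(f"rule genes missing from value table: {missing}")
        dense = values[all_genes]
    else:
        missing = [g for g in all_genes if g not in spots.genes]
        if missing:
            raise ValueError(f"rule genes missing from spot matrix: {missing}")
        norm = spots.lognormalized(rules.scale)
        dense = pd.DataFrame(
            np.asarray(norm[:, spots.genes.get_indexer(all_genes)].todense()),
            index=spots.spots, columns=all_genes,
        )

    def _all_above(genes, threshold):
        return (dense[list(genes)] > threshold).all(axis=1)

    ec = _all_above(rules.ec_genes, rules.identity_threshold)
    lesion = _all_above(rules.lesion_genes, rules.identity_threshold)
    tip = _all_above(rules.tip_genes, rules.identity_threshold)
    prolif = dense[rules.proliferation_gene] > rules.proliferation_threshold

    flags = pd.DataFrame(index=dense.index)
    flags["ec"] = ec
    flags["proliferating_ec"] = ec & prolif
    flags["lesion_ec"] = ec & lesion
    flags["proliferating_lesion_ec"] = ec & lesion & prolif
    flags["tip_ec"] = ec & tip
    flags["tip_lesion_ec"] = ec & lesion & tip
    flags["proliferating_tip_ec"] = ec & tip & prolif
    flags["proliferating_tip_lesion_ec"] = ec & lesion & tip & prolif
    return flags


def proliferation_fisher(flags: pd.DataFrame, class_a: str = "ec",
                         class_b: str = "lesion_ec",
                         event: str = "proliferating_ec",
                         genotypes: pd.Series | None = None,
                         genotype: str = "ko") -> tuple[np.ndarray, float]:
    """Two-sided Fisher exact test comparing event proportions between
    class_a-only spots (class_a but not class_b) and class_b spots.

    If ``genotypes`` is given, only spots of the requested genotype enter the
    table; samples are merged before counting.
    """
    if genotypes is not None:
        flags = flags.loc[genotypes.reindex(flags.index) == genotype]
    in_a = flags[class_a] & ~flags[class_b]
    in_b = flags[class_b]
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"empty class: {class_a}-only n={int(in_a.sum())}, "
                         f"{class_b} n={int(in_b.sum())}")
    ev = flags[event]
    table = np.array([
        [int((in_a & ev).sum()), int((in_a & ~ev).sum())],
        [int((in_b & ev).sum()), int((in_b & ~ev).sum())],
    ])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def spot_gene_overlay(spots: SpotMatrix, gene: str, scale: float = 1e4) -> pd.DataFrame:
    """Per-spot normalized value of one gene with positions, for mapping."""
    if gene not in spots.genes:
        raise KeyError(f"gene not present in spot matrix: {gene!r}")
    values = spots.lognormalized(scale)
    j = spots.genes.get_loc(gene)
    out = spots.spot_meta[["x", "y"]].copy()
    out["value"] = np.asarray(values[:, j].todense()).ravel()
    return out


def read_spots_tsv(path, sample: str = "s1", genotype: str = "ko") -> SpotMatrix:
    """Read a spot table: columns spot_id, x, y, then one column per gene."""
    table = pd.read_csv(path, sep="\t").set_index("spot_id")
    meta_cols = [c for c in ("x", "y", "sample", "genotype") if c in table.columns]
    meta = table[meta_cols].copy()
    if "sample" not in meta:
        meta["sample"] = sample
    if "genotype" not in meta:
        meta["genotype"] = genotype
    gene_cols = [c for c in table.columns if c not in meta_cols]
    X = sp.csr_matrix(table[gene_cols].to_numpy())
    return SpotMatrix(X=X, spot_meta=meta,
                      gene_meta=pd.DataFrame(index=pd.Index(gene_cols, name="gene")))
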