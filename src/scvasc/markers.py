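"""Per-cluster marker statistics, annotation and genotype comparisons.

Marker detection is one-vs-rest on log-normalized values: a two-sided
Wilcoxon rank-sum p per gene, with the log fold change computed on de-logged
means with a +1 pseudocount.  Conserved markers are tested per genotype and
combined with the Tippett minimum-p method; clusters are annotated by a cell
type when at least a configurable share of its key genes pass.  Genotype
comparisons (ko vs wt) per cluster use the same test, with per-cluster
Bonferroni adjustment by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import RankSumScan, adjust_pvalues, rank_sum_test, tippett_combine
from .preprocess import NormalizedMatrix

__all__ = [
    "rank_markers_one_vs_rest",
    "combine_min_p",
    "conserved_markers",
    "annotate_clusters",
    "deg_ko_vs_wt",
    "unique_markers",
    "unique_degs",
    "read_key_gene_panel",
]

EXACT_MAX = 10


def _log_fold_change(values_in: np.ndarray, values_out: np.ndarray) -> np.ndarray:
    """ln((mean(e^x - 1)_in + 1) / (mean(e^x - 1)_out + 1)) per gene."""
    mean_in = np.expm1(values_in).mean(axis=0)
    mean_out = np.expm1(values_out).mean(axis=0)
    return np.log((mean_in + 1.0) / (mean_out + 1.0))


def rank_markers_one_vs_rest(values: np.ndarray, in_mask: np.ndarray,
                             genes, scan: RankSumScan | None = None) -> pd.DataFrame:
    """Per-gene (logFC, p, pct_in, pct_out) for group-in vs group-out cells.

    ``values`` is a dense cells x genes array of log-normalized expression.
    Groups with fewer than 3 cells on either side are flagged untestable
    (p = NaN).  Both groups at most 10 cells use exact enumeration.
    """
    in_mask = np.asarray(in_mask, dtype=bool)
    n_in = int(in_mask.sum())
    n_out = int((~in_mask).sum())
    v_in = values[in_mask]
    v_out = values[~in_mask]
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["logFC"] = _log_fold_change(v_in, v_out)
    out["pct_in"] = (v_in > 0).mean(axis=0)
    out["pct_out"] = (v_out > 0).mean(axis=0)
    if n_in < 3 or n_out < 3:
        out["p"] = np.nan
        out["untestable"] = True
        return out
    if n_in <= EXACT_MAX and n_out <= EXACT_MAX:
        out["p"] = [rank_sum_test(v_in[:, j], v_out[:, j]) for j in range(values.shape[1])]
    else:
        scan = scan or RankSumScan(values)
        out["p"] = scan.pvalues(in_mask)
    out["untestable"] = False
    return out


def combine_min_p(p_values) -> float:
    """Tippett minimum-p combination across genotypes: 1 - (1 - min p)^k."""
    return tippett_combine(p_values)


def conserved_markers(norm: NormalizedMatrix, clusters: pd.Series,
                      min_fraction: float = 0.1,
                      p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Markers per cluster conserved across genotypes.

    Per genotype, each cluster is tested one-vs-rest within that genotype's
    cells; per-genotype p-values are combined by minimum-p and the logFCs
    averaged.  Genes expressed in less than ``min_fraction`` of the cluster's
    cells in either genotype are dropped.  Adjusted p is a per-cluster
    correction of the combined p across retained genes.
    """
    clusters = clusters.reindex(norm.cells)
    genotype = norm.cell_meta["genotype"]
    genotypes = sorted(genotype.unique())
    values = np.asarray(norm.values.todense())
    scans = {}
    for gt in genotypes:
        scans[gt] = RankSumScan(values[(genotype == gt).to_numpy()])

    records = []
    for cluster in sorted(clusters.unique()):
        in_cluster = (clusters == cluster).to_numpy()
        present = [gt for gt in genotypes
                   if (in_cluster & (genotype == gt).to_numpy()).any()]
        if len(present) < len(genotypes):
            warnings.warn(f"cluster {cluster} present in only one genotype; skipped")
            continue
        per_gt = {}
        for gt in present:
            gt_mask = (genotype == gt).to_numpy()
            sub = rank_markers_one_vs_rest(
                values[gt_mask], in_cluster[gt_mask], norm.genes, scan=scans[gt])
            per_gt[gt] = sub
        table = pd.DataFrame(index=norm.genes)
        table["cluster"] = cluster
        for gt in present:
            table[f"{gt}_logFC"] = per_gt[gt]["logFC"]
            table[f"{gt}_p"] = per_gt[gt]["p"]
            table[f"{gt}_pct_in"] = per_gt[gt]["pct_in"]
            table[f"{gt}_pct_out"] = per_gt[gt]["pct_out"]
        keep = np.ones(len(table), dtype=bool)
        for gt in present:
            keep &= (table[f"{gt}_pct_in"] >= min_fraction).to_numpy()
        table = table.loc[keep]
        table["avg_logFC"] = table[[f"{gt}_logFC" for gt in present]].mean(axis=1)
        pmat = table[[f"{gt}_p" for gt in present]].to_numpy()
        table["combined_p"] = 1.0 - (1.0 - pmat.min(axis=1)) ** pmat.shape[1]
        table["adj_p"] = adjust_pvalues(table["combined_p"].to_numpy(), p_adjust)
        records.append(table.reset_index())
    if not records:
        return pd.DataFrame(columns=["gene", "cluster", "avg_logFC", "combined_p", "adj_p"])
    return pd.concat(records, ignore_index=True)


def annotate_clusters(markers: pd.DataFrame, panel: dict[str, list[str]],
                      logfc_min: float = 0.0, p_max: float = 0.05,
                      share: float = 0.5,
                      all_genes=None) -> pd.DataFrame:
    """Cell-type labels per cluster from the key-gene hit fraction.

    A key gene "hits" in a cluster when it passes avg_logFC > logfc_min and
    combined p < p_max among that cluster's markers; the cluster is annotated
    by every cell type whose hit fraction is at least ``share``.  Key genes
    absent from the gene universe count as misses and are reported.
    """
    if not panel:
        raise ValueError("key-gene panel is empty")
    for cell_type, genes in panel.items():
        if not genes:
            raise ValueError(f"cell type {cell_type!r} has an empty key-gene list")
    universe = set(all_genes) if all_genes is not None else None
    passing = markers[(markers["avg_logFC"] > logfc_min)
                      & (markers["combined_p"] < p_max)]
    by_cluster = {c: set(sub["gene"]) for c, sub in passing.groupby("cluster")}
    rows = []
    for cluster in sorted(markers["cluster"].unique()):
        hits = by_cluster.get(cluster, set())
        for cell_type, genes in panel.items():
            missing = sorted(set(genes) - universe) if universe is not None else []
            n_hit = sum(g in hits for g in genes)
            fraction = n_hit / len(genes)
            rows.append({
                "cluster": cluster, "cell_type": cell_type,
                "n_key_genes": len(genes), "n_hits": n_hit,
                "hit_fraction": fraction, "annotated": fraction >= share,
                "missing_genes": ",".join(missing),
            })
    return pd.DataFrame(rows)


def deg_ko_vs_wt(norm: NormalizedMatrix, clusters: pd.Series,
                 p_adjust: str = "bonferroni",
                 p_max: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster ko-vs-wt differential expression with per-cluster adjustment.

    Returns the full DEG table and a per-cluster summary of significant
    up/down gene counts (significant = adjusted p < ``p_max``; direction by
    the sign of the ko-vs-wt logFC).
    """
    clusters = clusters.reindex(norm.cells)
    genotype = norm.cell_meta["genotype"].to_numpy()
    values = np.asarray(norm.values.todense())
    records, summary = [], []
    for cluster in sorted(clusters.unique()):
        cl_mask = (clusters == cluster).to_numpy()
        ko = cl_mask & (genotype == "ko")
        wt = cl_mask & (genotype == "wt")
        if ko.sum() < 3 or wt.sum() < 3:
            warnings.warn(f"cluster {cluster}: fewer than 3 cells in a genotype; skipped")
            continue
        sub_values = values[cl_mask]
        sub_ko = ko[cl_mask]
        table = rank_markers_one_vs_rest(sub_values, sub_ko, norm.genes)
        table = table.rename(columns={"pct_in": "pct_ko", "pct_out": "pct_wt"})
        table["cluster"] = cluster
        table["adj_p"] = adjust_pvalues(table["p"].to_numpy(), p_adjust)
        table["significant"] = table["adj_p"] < p_max
        table["direction"] = np.sign(table["logFC"]).astype(int)
        records.append(table.reset_index())
        sig = table[table["significant"]]
        summary.append({"cluster": cluster,
                        "n_up": int((sig["logFC"] > 0).sum()),
                        "n_down": int((sig["logFC"] < 0).sum())})
    if not records:
        return (pd.DataFrame(columns=["gene", "cluster", "logFC", "p", "adj_p"]),
                pd.DataFrame(columns=["cluster", "n_up", "n_down"]))
    return pd.concat(records, ignore_index=True), pd.DataFrame(summary)


def unique_markers(markers: pd.DataFrame, logfc_min: float = 0.25,
                   p_max: float = 0.05) -> dict:
    """Genes passing (avg_logFC > logfc_min, adjusted p < p_max) in exactly
    one cluster, keyed by that cluster."""
    passing = markers[(markers["avg_logFC"] > logfc_min) & (markers["adj_p"] < p_max)]
    cluster_count = passing.groupby("gene")["cluster"].nunique()
    unique_genes = set(cluster_count[cluster_count == 1].index)
    out: dict = {c: [] for c in sorted(markers["cluster"].unique())}
    for _, row in passing.iterrows():
        if row["gene"] in unique_genes:
            out[row["cluster"]].append(row["gene"])
    return {c: sorted(g) for c, g in out.items()}


def unique_degs(degs: pd.DataFrame, logfc_min_abs: float = 0.2,
                p_max: float = 0.05) -> dict:
    """DEGs significant (|logFC| > logfc_min_abs, adjusted p < p_max) in
    exactly one cluster, keyed by that cluster."""
    passing = degs[(degs["logFC"].abs() > logfc_min_abs) & (degs["adj_p"] < p_max)]
    cluster_count = passing.groupby("gene")["cluster"].nunique()
    unique_genes = set(cluster_count[cluster_count == 1].index)
    out: dict = {c: [] for c in sorted(degs["cluster"].unique())}
    for _, row in passing.iterrows():
        if row["gene"] in unique_genes:
            out[row["cluster"]].append(row["gene"])
    return {c: sorted(g) for c, g in out.items()}


def read_key_gene_panel(path) -> dict[str, list[str]]:
    """Read a TSV with columns cell_type, gene into a panel mapping."""
    table = pd.read_csv(path, sep="\t")
    panel = {ct: sub["gene"].tolist() for ct, sub in table.groupby("cell_type")}
    for ct, genes in panel.items():
        if not genes:
            raise ValueError(f"cell type {ct!r} has no key genes")
    return panel
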