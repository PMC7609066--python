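"""Gene-set over-representation with hypergeometric and Fisher exact tests.

Query gene lists are tested against named gene-set collections over a fixed
universe (the genes detectable in the expression matrix).  The upper-tail
hypergeometric p is combined with a Benjamini-Hochberg q across the
collection, a fold-enrichment odds ratio (k/n)/(K/N), and configurable pass
filters on p, q, odds and overlap size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = ["GeneSetCollection", "OverlapFilters", "read_gmt",
           "overlap_enrichment", "disease_geneset_overlap"]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a gene universe."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("gene universe is empty")
        self.universe = set(self.universe)
        self.sets = {name: set(genes) & self.universe
                     for name, genes in self.sets.items()}


@dataclass
class OverlapFilters:
    p_max: float = 0.05
    q_max: float = 0.25
    q_direction: str = "le"  # 'le' (q <= q_max) or 'gt' (q > q_max, as printed upstream)
    odds_min: float = 4.0
    min_overlap: int = 2  # pass requires overlap strictly greater than this
    odds_kind: str = "fold"  # 'fold' = (k/n)/(K/N); 'set_share' = k/K


def read_gmt(path, universe) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...) into a collection."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets, universe=set(universe))


def _odds(k: int, n: int, K: int, N: int, kind: str) -> float:
    if kind == "fold":
        if n == 0 or K == 0:
            return np.nan
        return (k / n) / (K / N)
    if kind == "set_share":
        return k / K if K else np.nan
    raise ValueError(f"unknown odds kind: {kind!r}")


def overlap_enrichment(query, collection: GeneSetCollection,
                       filters: OverlapFilters | None = None) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of a query per gene set.

    p = P(X >= k) for X ~ Hypergeom(N, K, n); q = BH across the collection;
    odds defaults to fold enrichment (k/n)/(K/N).  The pass flag applies
    p < p_max, the q filter in the configured direction, odds >= odds_min
    and overlap > min_overlap.
    """
    filters = filters or OverlapFilters()
    query = set(query)
    if not query:
        raise ValueError("query gene list is empty")
    dropped = query - collection.universe
    if dropped:
        import warnings
        warnings.warn(f"{len(dropped)} query genes outside the universe dropped")
    query &= collection.universe
    if not query:
        raise ValueError("no query genes remain inside the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "set_size": K, "query_size": n,
                     "universe_size": N, "overlap": k, "p": min(p, 1.0),
                     "odds": _odds(k, n, K, N, filters.odds_kind)})
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    q_ok = (result["q"] <= filters.q_max if filters.q_direction == "le"
            else result["q"] > filters.q_max)
    result["passed"] = ((result["p"] < filters.p_max) & q_ok
                        & (result["odds"] >= filters.odds_min)
                        & (result["overlap"] > filters.min_overlap))
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def disease_geneset_overlap(cluster_queries: dict, disease_set,
                            universe) -> pd.DataFrame:
    """Per-cluster overlap with one disease gene set plus two-sided Fisher p.

    The 2x2 table counts universe genes by query membership x set membership;
    BH q is computed across clusters and significance stars mirror the
    0.05 / 0.01 display thresholds.
    """
    universe = set(universe)
    disease = set(disease_set) & universe
    if not disease:
        raise ValueError("disease gene set is empty (after harmonization)")
    N = len(universe)
    K = len(disease)
    rows = []
    for cluster, query in cluster_queries.items():
        query = set(query) & universe
        n = len(query)
        k = len(query & disease)
        table = np.array([[k, n - k], [K - k, N - n - (K - k)]])
        if n == 0:
            p = 1.0
        else:
            _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"cluster": cluster, "overlap": k, "query_size": n,
                     "set_size": K, "universe_size": N, "p": float(p)})
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["stars"] = np.select(
        [result["p"] < 0.01, result["p"] < 0.05], ["**", "*"], default="")
    return result
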