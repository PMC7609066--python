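"""Multi-resolution clustering tree and resolution selection.

The tree cross-tabulates cluster assignments at consecutive resolutions;
each edge carries the in-proportion: the fraction of the child cluster's
cells that came from the parent.  A stable region is a maximal run of
resolutions with a constant cluster count and a one-to-one parent/child
mapping; over-clustering begins where a new cluster draws a non-trivial
share of its cells from multiple parents.  The selected resolution is the
highest one inside a stable region entirely below the over-clustering onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClusterTree", "RegionReport", "build_cluster_tree",
           "find_stable_regions", "find_overclustered_onset", "select_resolution"]

IDENTITY_THRESHOLD = 0.9


@dataclass
class ClusterTree:
    resolutions: list[float]
    assignments: pd.DataFrame  # cells x resolutions (column per resolution)
    edges: pd.DataFrame  # step, parent, child, n_cells, in_proportion

    def cluster_counts(self) -> list[int]:
        return [self.assignments[r].nunique() for r in self.assignments.columns]


@dataclass
class RegionReport:
    stable_regions: list[tuple[float, float]]
    overclustered_onset: float | None
    selected_resolution: float


def build_cluster_tree(assignments: dict[float, pd.Series] | pd.DataFrame) -> ClusterTree:
    """Cross-tabulate consecutive resolutions into an in-proportion edge list."""
    if isinstance(assignments, pd.DataFrame):
        table = assignments.copy()
        table.columns = [float(c) for c in table.columns]
    else:
        resolutions = sorted(assignments)
        first = assignments[resolutions[0]]
        for r in resolutions[1:]:
            s = assignments[r]
            if not first.index.equals(s.index):
                missing = sorted(set(first.index).symmetric_difference(s.index))[:10]
                raise ValueError(
                    f"cell sets differ between resolutions {resolutions[0]} and {r}; "
                    f"mismatched ids include {missing}"
                )
        table = pd.DataFrame({r: assignments[r] for r in resolutions})
    table = table[sorted(table.columns)]
    if table.shape[1] < 2:
        raise ValueError("need assignments at >= 2 resolutions")

    resolutions = list(table.columns)
    rows = []
    for step in range(len(resolutions) - 1):
        r_lo, r_hi = resolutions[step], resolutions[step + 1]
        crosstab = pd.crosstab(table[r_lo], table[r_hi])
        child_sizes = crosstab.sum(axis=0)
        for parent in crosstab.index:
            for child in crosstab.columns:
                n = int(crosstab.loc[parent, child])
                if n:
                    rows.append({
                        "step": step, "resolution_parent": r_lo,
                        "resolution_child": r_hi, "parent": parent, "child": child,
                        "n_cells": n,
                        "in_proportion": n / int(child_sizes[child]),
                    })
    return ClusterTree(resolutions=resolutions, assignments=table,
                       edges=pd.DataFrame(rows))


def _step_stable(tree: ClusterTree, step: int,
                 identity_threshold: float = IDENTITY_THRESHOLD) -> bool:
    """A step is stable if cluster counts match and parents map one-to-one
    onto children (each child has a dominant parent, all distinct)."""
    r_lo = tree.resolutions[step]
    r_hi = tree.resolutions[step + 1]
    if tree.assignments[r_lo].nunique() != tree.assignments[r_hi].nunique():
        return False
    edges = tree.edges[tree.edges["step"] == step]
    dominant = edges.loc[edges.groupby("child")["in_proportion"].idxmax()]
    if (dominant["in_proportion"] < identity_threshold).any():
        return False
    return dominant["parent"].is_unique


def find_stable_regions(tree: ClusterTree,
                        identity_threshold: float = IDENTITY_THRESHOLD
                        ) -> list[tuple[float, float]]:
    """Maximal runs of consecutive resolutions joined by stable steps.

    A resolution not joined to its neighbors forms a degenerate [r, r] region,
    so every resolution belongs to exactly one region.
    """
    res = tree.resolutions
    regions = []
    start = 0
    for step in range(len(res) - 1):
        if not _step_stable(tree, step, identity_threshold):
            regions.append((res[start], res[step]))
            start = step + 1
    regions.append((res[start], res[-1]))
    return regions


def find_overclustered_onset(tree: ClusterTree, low_inprop: float = 0.1,
                             min_parents: int = 2) -> float | None:
    """Smallest resolution at which a new cluster forms from multiple parents.

    A child is "new" when it is not the majority continuation of any parent
    (i.e. it receives the largest share of no parent's cells); the onset
    triggers when such a child draws at least ``low_inprop`` of its cells
    from each of ``min_parents`` or more distinct parents.
    """
    for step in range(len(tree.resolutions) - 1):
        edges = tree.edges[tree.edges["step"] == step]
        # parent's main child = child receiving the largest share of the parent
        main_children = set(
            edges.loc[edges.groupby("parent")["n_cells"].idxmax(), "child"]
        )
        for child, sub in edges.groupby("child"):
            if child in main_children:
                continue
            qualifying = (sub["in_proportion"] >= low_inprop).sum()
            if qualifying >= min_parents:
                return tree.resolutions[step + 1]
    return None


def select_resolution(tree: ClusterTree, low_inprop: float = 0.1,
                      min_parents: int = 2,
                      identity_threshold: float = IDENTITY_THRESHOLD) -> RegionReport:
    """Highest resolution inside a stable region strictly below the onset."""
    regions = find_stable_regions(tree, identity_threshold)
    onset = find_overclustered_onset(tree, low_inprop, min_parents)
    if onset is None:
        candidates = regions
    else:
        candidates = [(lo, hi) for lo, hi in regions if hi < onset]
    if not candidates:
        raise ValueError(
            "no stable region below the over-clustering onset; widen the resolution grid"
        )
    selected = max(hi for _, hi in candidates)
    return RegionReport(stable_regions=regions, overclustered_onset=onset,
                        selected_resolution=selected)
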