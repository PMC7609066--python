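"""Cluster-expansion confidence-interval statistic and positivity rules.

The expansion statistic computes ko/wt cell-count fold changes per group
(cluster or trajectory branch) and flags groups whose fold strictly exceeds
the upper limit of the t-based confidence interval over the mean fold.
Positivity rules mark cells above zero, above the first quartile of a
reference population, or above an arbitrary threshold; fractions of positive
cells feed the same confidence-interval machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import t_upper_limit
from .preprocess import NormalizedMatrix

__all__ = [
    "PositivityRule",
    "ExpansionTable",
    "expansion_fold",
    "positive_cells",
    "positivity_fraction_fold",
    "double_positive_counts",
    "load_branches",
]


@dataclass
class PositivityRule:
    """kind: 'gt_zero', 'gt_q1' (Q1 over a reference population) or 'gt_threshold'."""

    kind: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gt_zero", "gt_q1", "gt_threshold"):
            raise ValueError(f"unknown positivity rule kind: {self.kind!r}")
        if self.kind == "gt_threshold" and self.threshold is None:
            raise ValueError("gt_threshold rule requires a threshold")


@dataclass
class ExpansionTable:
    per_group: pd.DataFrame  # wt, ko, fold, flagged
    mean_fold: float
    sd_fold: float
    ci_upper: float
    level: float
    excluded: list


def _fold_table(wt: pd.Series, ko: pd.Series, level: float) -> ExpansionTable:
    groups = wt.index
    excluded = [g for g in groups if wt[g] == 0]
    if excluded:
        warnings.warn(f"groups with zero wt denominator excluded: {excluded}")
    kept = [g for g in groups if g not in excluded]
    if len(kept) < 2:
        raise ValueError("need at least two groups with non-zero wt denominators")
    folds = (ko[kept] / wt[kept]).astype(float)
    upper = t_upper_limit(folds.to_numpy(), level)
    per_group = pd.DataFrame({
        "wt": wt[kept], "ko": ko[kept], "fold": folds,
        "flagged": folds > upper,
    })
    return ExpansionTable(per_group=per_group,
                          mean_fold=float(folds.mean()),
                          sd_fold=float(folds.std(ddof=1)),
                          ci_upper=float(upper), level=level, excluded=excluded)


def expansion_fold(counts: pd.DataFrame, level: float = 0.95) -> ExpansionTable:
    """Fold change of ko over wt cell counts per group, with CI flagging.

    ``counts`` has one row per group and columns 'wt' and 'ko'.  The upper
    limit is mean(folds) + t * SD(folds)/sqrt(n) over the included groups;
    a group is flagged when its fold strictly exceeds that limit.  Groups
    with zero wt cells are excluded with a warning.
    """
    if not {"wt", "ko"}.issubset(counts.columns):
        raise ValueError("counts must have 'wt' and 'ko' columns")
    return _fold_table(counts["wt"], counts["ko"], level)


def positive_cells(norm: NormalizedMatrix, gene: str, rule: PositivityRule,
                   reference_mask: np.ndarray | None = None) -> np.ndarray:
    """Boolean per cell under the positivity rule.

    For 'gt_q1' the first quartile is the linearly interpolated 25th
    percentile of the gene's values (zeros included) over the reference
    population (all cells when no mask is given); positivity is strict.
    """
    values = norm.gene_values(gene)
    if rule.kind == "gt_zero":
        return values > 0
    if rule.kind == "gt_threshold":
        return values > rule.threshold
    ref = values if reference_mask is None else values[np.asarray(reference_mask, bool)]
    if ref.size == 0:
        raise ValueError("reference population for Q1 is empty")
    q1 = np.percentile(ref, 25)
    return values > q1


def positivity_fraction_fold(positives: np.ndarray, groups: pd.Series,
                             genotypes: pd.Series,
                             level: float = 0.95) -> tuple[pd.DataFrame, ExpansionTable]:
    """Positive-cell fractions per group/genotype and their ko/wt fold with CI flags.

    Groups where the wt fraction is zero (or a genotype is absent) are
    excluded from the CI family with a warning.
    """
    positives = np.asarray(positives, dtype=bool)
    frame = pd.DataFrame({"positive": positives,
                          "group": groups.to_numpy(),
                          "genotype": genotypes.to_numpy()})
    fractions = (frame.groupby(["group", "genotype"])["positive"]
                 .mean().unstack("genotype"))
    counts = (frame.groupby(["group", "genotype"])["positive"]
              .agg(["sum", "count"]))
    missing = fractions.index[fractions.isna().any(axis=1)].tolist()
    if missing:
        warnings.warn(f"groups missing a genotype excluded: {missing}")
        fractions = fractions.drop(index=missing)
    table = _fold_table(fractions["wt"], fractions["ko"], level)
    per_gt = counts.rename(columns={"sum": "n_positive", "count": "n_cells"})
    return per_gt.reset_index(), table


def double_positive_counts(norm: NormalizedMatrix, gene_a: str, rule_a: PositivityRule,
                           gene_b: str, rule_b: PositivityRule,
                           groups: pd.Series, genotypes: pd.Series,
                           reference_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Counts of cells positive under both rules, per group and genotype."""
    pos = (positive_cells(norm, gene_a, rule_a, reference_mask)
           & positive_cells(norm, gene_b, rule_b, reference_mask))
    frame = pd.DataFrame({"positive": pos,
                          "group": groups.to_numpy(),
                          "genotype": genotypes.to_numpy()})
    out = (frame.groupby(["group", "genotype"])["positive"].sum()
           .unstack("genotype", fill_value=0))
    out.columns.name = None
    return out


def load_branches(table) -> pd.Series:
    """Cell -> branch mapping from a TSV (cell_id, branch) or DataFrame."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    if table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].tolist()[:5]
        raise ValueError(f"duplicate cell ids in branch table: {dup}")
    return table.set_index("cell_id")["branch"]
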