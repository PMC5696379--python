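"""Luminal-intermediate trend statistics and cell-cycle cluster flagging.

The monotone-trend statistic asks, among genes differentially expressed
across the LP / intermediate / ML clusters, what fraction have the
intermediate group mean lying between the LP and ML means -- the pattern
expected of a transit population.  Means are taken on the linear CPM
scale by default (the elevated-intermediate criterion is multiplicative);
a log-scale mode is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de_nb
from .iofmt import CountMatrix, GeneSetCollection
from .normalize import ExpressionMatrix


@dataclass
class MonotoneTrendResult:
    n_de_genes: int
    n_monotone: int
    fraction_monotone: float
    per_gene: pd.DataFrame


@dataclass
class ElevatedIntermediateResult:
    genes: pd.DataFrame          # gene_id, ratio_vs_a, ratio_vs_b
    threshold: float


def _group_means_linear(cm: CountMatrix, groups, levels, scale: str = "linear") -> np.ndarray:
    """Library-normalized (CPM) group means, genes x levels."""
    libs = cm.library_sizes()
    cpm = cm.counts / libs[None, :] * 1e6
    groups = np.asarray(groups)
    cols = []
    for lev in levels:
        mask = groups == lev
        if not np.any(mask):
            raise ValueError(f"group {lev!r} has no samples")
        if scale == "linear":
            cols.append(cpm[:, mask].mean(axis=1))
        elif scale == "log":
            cols.append(2.0 ** np.log2(cpm[:, mask] + 0.5).mean(axis=1) - 0.5)
        else:
            raise ValueError("scale must be 'linear' or 'log'")
    return np.column_stack(cols)


def monotone_fraction(cm: CountMatrix, groups=None,
                      order: tuple = ("LP", "LumInt", "ML"),
                      fdr_cut: float = 0.01, eps: float = 0.0,
                      disp: de_nb.DispersionModel | None = None,
                      mean_scale: str = "linear",
                      de_table: pd.DataFrame | None = None) -> MonotoneTrendResult:
    """Fraction of DE genes whose intermediate mean lies between its parents.

    A one-way NB LRT across the three groups defines the DE gene set at
    ``fdr_cut``; a gene is monotone when the middle group's mean falls
    within [min(parents) - eps, max(parents) + eps].  A precomputed
    ``de_table`` (from ``de_nb.lrt_de`` on the same matrix) may be passed
    to skip refitting.
    """
    if groups is None:
        groups = cm.groups()
    groups = np.asarray(groups)
    a, mid, b = order
    for lev in order:
        if not np.any(groups == lev):
            raise ValueError(f"group {lev!r} has no samples")
    keep = np.isin(groups, list(order))
    sub = cm.subset_samples(keep)
    sub_groups = groups[keep]

    if de_table is None:
        de_table = de_nb.lrt_de(sub, sub_groups, disp)
    de_table = de_table.set_index("gene_id").loc[sub.gene_ids]

    means = _group_means_linear(sub, sub_groups, order, scale=mean_scale)
    lo = np.minimum(means[:, 0], means[:, 2]) - eps
    hi = np.maximum(means[:, 0], means[:, 2]) + eps
    monotone = (means[:, 1] >= lo) & (means[:, 1] <= hi)
    direction = np.where(~monotone, "non-monotone",
                         np.where(means[:, 2] >= means[:, 0], "up", "down"))

    is_de = (de_table["fdr"] < fdr_cut).to_numpy()
    n_de = int(is_de.sum())
    n_mono = int((monotone & is_de).sum())
    per_gene = pd.DataFrame({
        "gene_id": sub.gene_ids,
        f"mean_{a}": means[:, 0],
        f"mean_{mid}": means[:, 1],
        f"mean_{b}": means[:, 2],
        "fdr": de_table["fdr"].to_numpy(),
        "is_de": is_de,
        "monotone": monotone,
        "direction": direction,
    })
    frac = n_mono / n_de if n_de > 0 else float("nan")
    return MonotoneTrendResult(n_de, n_mono, frac, per_gene)


def elevated_intermediate_genes(cm: CountMatrix, groups=None,
                                order: tuple = ("LP", "LumInt", "ML"),
                                ratio: float = 1.2,
                                mean_scale: str = "linear",
                                restrict_to: list[str] | None = None) -> ElevatedIntermediateResult:
    """Genes whose intermediate mean is at least ``ratio`` times both parents."""
    if groups is None:
        groups = cm.groups()
    groups = np.asarray(groups)
    a, mid, b = order
    means = _group_means_linear(cm, groups, order, scale=mean_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_a = np.divide(means[:, 1], means[:, 0])
        r_b = np.divide(means[:, 1], means[:, 2])
    sel = (means[:, 1] >= ratio * means[:, 0]) & (means[:, 1] >= ratio * means[:, 2])
    tab = pd.DataFrame({"gene_id": cm.gene_ids,
                        f"ratio_vs_{a}": r_a, f"ratio_vs_{b}": r_b})[sel]
    if restrict_to is not None:
        tab = tab[tab["gene_id"].isin(set(restrict_to))]
    return ElevatedIntermediateResult(genes=tab.reset_index(drop=True), threshold=ratio)


def cell_cycle_flag(expr: ExpressionMatrix, cycle_genes: GeneSetCollection | list[str],
                    cluster_labels, z_margin: float = 0.5) -> tuple[pd.Series, pd.Series]:
    """Flag clusters with elevated mean cell-cycle expression.

    ``expr`` should be per-gene standardized.  The per-cell score is the
    mean standardized expression over the cycle genes; a cluster is
    flagged when its mean score exceeds the all-cell mean score by
    ``z_margin`` standard deviations of the cluster means.

    Returns (per-cluster flag Series, per-cell score Series).
    """
    genes = cycle_genes if isinstance(cycle_genes, list) else next(iter(cycle_genes.sets.values()))
    idx = expr.gene_index()
    rows = [idx[g] for g in genes if g in idx]
    if not rows:
        raise ValueError("no cell-cycle genes present in the expression matrix")
    score = expr.values[rows, :].mean(axis=0)
    cells = pd.Series(score, index=expr.sample_ids, name="cycle_score")
    labels = pd.Series(np.asarray(cluster_labels), index=expr.sample_ids)
    cluster_means = cells.groupby(labels).mean()
    spread = cluster_means.std(ddof=1) if len(cluster_means) > 1 else 0.0
    if spread == 0 or not np.isfinite(spread):
        flags = pd.Series(False, index=cluster_means.index, name="cycle_flag")
    else:
        flags = (cluster_means > cells.mean() + z_margin * spread).rename("cycle_flag")
    return flags, cells
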