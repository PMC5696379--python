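"""Per-cell lineage composition and mixed-lineage detection.

A cell's ternary score over three lineage signatures is, for each
signature set, the mean positive excess of (quantile-normalized log2-CPM)
expression above a floor, normalized across the three sets to proportions
summing to one.  The per-set mean removes set-size bias; the floor
defaults to the matrix-wide median of the expression values supplied.
A count-of-detected-genes scoring mode is available as an alternative.

Mixed-lineage cells are host-lineage cells (e.g. sorted basal) that
express at least ``min_foreign_genes`` genes of the foreign signature
above an absolute detection level while remaining host-dominant in their
overall signature scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de_nb import SignatureSet
from .normalize import ExpressionMatrix

CLASS_ORDER_FALLBACK = ("basal", "LP", "ML")


@dataclass
class TernaryScore:
    sample_id: str
    class_names: tuple[str, str, str]
    raw_scores: np.ndarray
    proportions: np.ndarray
    label: str
    degenerate: bool


@dataclass
class MixedLineageCall:
    sample_id: str
    host_class: str
    n_foreign_detected: int
    foreign_genes: list[str]
    host_score: float
    foreign_score: float
    is_mixed: bool


def _set_rows(expr: ExpressionMatrix, sigs: SignatureSet):
    idx = expr.gene_index()
    rows = {}
    for name in sigs.names():
        present = [idx[g] for g in sigs.genes(name) if g in idx]
        if not present:
            raise ValueError(f"signature set {name!r} has no genes in the expression matrix")
        rows[name] = np.asarray(present)
    return rows


def _raw_scores(expr: ExpressionMatrix, rows: dict, floor: float,
                mode: str = "mean_positive") -> np.ndarray:
    """Per-set per-cell raw scores, shape (n_sets, n_cells)."""
    out = np.empty((len(rows), expr.n_samples))
    for k, (_, rr) in enumerate(rows.items()):
        sub = expr.values[rr, :]
        if mode == "mean_positive":
            out[k] = np.maximum(sub - floor, 0.0).mean(axis=0)
        elif mode == "count_detected":
            out[k] = (sub > floor).mean(axis=0)
        else:
            raise ValueError(f"unknown score mode {mode!r}")
    return out


def resolve_floor(expr: ExpressionMatrix, floor: float | str = "median") -> float:
    if floor == "median":
        return float(np.median(expr.values))
    return float(floor)


def ternary_cell_scores(expr: ExpressionMatrix, sigs: SignatureSet,
                        floor: float | str = "median",
                        mode: str = "mean_positive") -> list[TernaryScore]:
    """Relative proportions of the three lineage signatures per cell.

    A cell with no signature expression above the floor is degenerate and
    gets proportions (1/3, 1/3, 1/3) with label "unclassified".
    """
    if len(sigs.names()) != 3:
        raise ValueError("ternary scoring requires exactly 3 signature sets")
    names = tuple(sigs.names())
    rows = _set_rows(expr, sigs)
    fl = resolve_floor(expr, floor)
    raw = _raw_scores(expr, rows, fl, mode)
    totals = raw.sum(axis=0)
    out = []
    for j, sid in enumerate(expr.sample_ids):
        if totals[j] <= 0:
            props = np.full(3, 1.0 / 3.0)
            out.append(TernaryScore(sid, names, raw[:, j].copy(), props,
                                    "unclassified", True))
        else:
            props = raw[:, j] / totals[j]
            label = names[int(np.argmax(props))]     # argmax takes first on ties
            out.append(TernaryScore(sid, names, raw[:, j].copy(), props, label, False))
    return out


def classify_cells(scores: list[TernaryScore],
                   intermediate_band: float | None = None,
                   lp_name: str = "LP", ml_name: str = "ML",
                   intermediate_name: str = "LumInt") -> list[str]:
    """Argmax labels, optionally carving out a luminal-intermediate band.

    With a band b, a cell whose LP and ML proportions differ by less than b
    while both exceed the remaining (basal) proportion is labeled as the
    intermediate class.
    """
    labels = []
    for s in scores:
        lab = s.label
        if intermediate_band is not None and not s.degenerate:
            pos = {n: p for n, p in zip(s.class_names, s.proportions)}
            if lp_name in pos and ml_name in pos:
                other = [n for n in s.class_names if n not in (lp_name, ml_name)][0]
                lp, ml, rest = pos[lp_name], pos[ml_name], pos[other]
                if abs(lp - ml) < intermediate_band and min(lp, ml) > rest:
                    lab = intermediate_name
        labels.append(lab)
    return labels


def ternary_gene_composition(expr: ExpressionMatrix, groups) -> pd.DataFrame:
    """Per-gene relative expression across 3 stages (linear-scale means).

    Log-scale input (log2cpm / log2rpkm, quantile-normalized or not) is
    de-logged before averaging; cpm input is averaged as is.
    """
    groups = np.asarray(groups)
    levels = []
    for g in groups:
        if g not in levels:
            levels.append(g)
    if len(levels) != 3:
        raise ValueError("gene composition requires exactly 3 stages")
    linear = expr.values if expr.normalization == "cpm" else 2.0 ** expr.values
    means = np.column_stack([
        linear[:, groups == lev].mean(axis=1) if np.any(groups == lev)
        else _raise_empty(lev)
        for lev in levels
    ])
    tot = means.sum(axis=1)
    degen = tot <= 0
    props = np.divide(means, np.where(degen, 1.0, tot)[:, None])
    props[degen] = 1.0 / 3.0
    out = pd.DataFrame(props, columns=[f"prop_{lev}" for lev in levels])
    out.insert(0, "gene_id", expr.gene_ids)
    out["degenerate"] = degen
    return out


def _raise_empty(lev):
    raise ValueError(f"stage {lev!r} has no cells")


def detect_mixed_lineage(expr: ExpressionMatrix, host_class: str, sigs: SignatureSet,
                         min_foreign_genes: int = 3,
                         detect_level: float = np.log2(5.0),
                         host_dominance: float = 1.0,
                         floor: float | str = "median") -> list[MixedLineageCall]:
    """Flag host cells co-expressing foreign-lineage signature genes.

    ``expr`` should be log2-RPKM (or log2-CPM) of sorted host cells.  A
    cell is mixed when at least ``min_foreign_genes`` foreign-signature
    genes exceed ``detect_level`` (log2 scale) and its host raw signature
    score stays above ``host_dominance`` times the foreign score.
    """
    names = sigs.names()
    if host_class not in names:
        raise ValueError(f"host class {host_class!r} not among signatures {names}")
    if len(names) != 2:
        raise ValueError("mixed-lineage detection expects host + foreign signature sets")
    foreign_class = [n for n in names if n != host_class][0]
    if set(sigs.genes(host_class)) == set(sigs.genes(foreign_class)):
        raise ValueError("host and foreign signature sets are identical")

    rows = _set_rows(expr, sigs)
    fl = resolve_floor(expr, floor)
    raw = _raw_scores(expr, rows, fl)
    host_raw = raw[names.index(host_class)]
    foreign_raw = raw[names.index(foreign_class)]

    fr_rows = rows[foreign_class]
    fr_ids = [expr.gene_ids[i] for i in fr_rows]
    detected = expr.values[fr_rows, :] > detect_level

    calls = []
    for j, sid in enumerate(expr.sample_ids):
        genes = [g for g, d in zip(fr_ids, detected[:, j]) if d]
        is_mixed = (len(genes) >= min_foreign_genes
                    and host_raw[j] > host_dominance * foreign_raw[j])
        calls.append(MixedLineageCall(sid, host_class, len(genes), genes,
                                      float(host_raw[j]), float(foreign_raw[j]), is_mixed))
    return calls


def flag_marker_positive(expr: ExpressionMatrix, gene: str,
                         threshold_linear: float) -> pd.Series:
    """Per-cell flag for linear-scale expression strictly above a threshold.

    For log-scale normalizations the stored values are de-logged before
    comparison (e.g. RPKM > 40 on log2-RPKM input).
    """
    idx = expr.gene_index()
    if gene not in idx:
        raise ValueError(f"gene {gene!r} absent from expression matrix")
    vals = expr.values[idx[gene], :]
    if expr.normalization == "cpm":
        flags = vals > threshold_linear
    else:
        # compare on the log scale so a value storing exactly the threshold
        # is not flagged by de-logging round-off
        flags = vals > np.log2(threshold_linear) if threshold_linear > 0 \
            else np.isfinite(vals)
    return pd.Series(flags, index=expr.sample_ids, name=gene)


def ternary_table(scores: list[TernaryScore], labels: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for k, s in enumerate(scores):
        row = {"sample_id": s.sample_id}
        for n, p, r in zip(s.class_names, s.proportions, s.raw_scores):
            row[f"prop_{n}"] = p
            row[f"raw_{n}"] = r
        row["label"] = labels[k] if labels is not None else s.label
        row["degenerate"] = s.degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def mixed_table(calls: list[MixedLineageCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample_id": c.sample_id, "host_class": c.host_class,
         "n_foreign_detected": c.n_foreign_detected,
         "foreign_genes": ",".join(c.foreign_genes),
         "host_score": c.host_score, "foreign_score": c.foreign_score,
         "is_mixed": c.is_mixed}
        for c in calls
    ])
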