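"""Cell- and gene-level quality filters.

The filter order is fixed: strip mitochondrial/ribosomal/unannotated genes,
then drop shallow cells (assigned total and detected-gene thresholds, with a
relaxed pair for sorted basal / pregnancy samples), then drop genes below
1 CPM in fewer than 3 cells.  "Fewer than X" drops strictly below X;
"detected" means raw count >= 1.  A separate housekeeping filter removes
multiplex-qPCR cells in which ACTB or GAPDH is undetected (Ct >= 40).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iofmt import CountMatrix

DEFAULT_MITO_PREFIXES = ("mt-",)
DEFAULT_RIBO_PREFIXES = ("Rps", "Rpl", "Mrps", "Mrpl")


@dataclass
class QCThresholds:
    min_read_pairs: int = 100_000
    min_detected_genes: int = 1500
    relaxed_min_read_pairs: int = 50_000
    relaxed_min_detected_genes: int = 1000
    min_cpm: float = 1.0
    min_cells_at_cpm: int = 3

    def __post_init__(self) -> None:
        vals = [self.min_read_pairs, self.min_detected_genes,
                self.relaxed_min_read_pairs, self.relaxed_min_detected_genes,
                self.min_cpm, self.min_cells_at_cpm]
        if any(v <= 0 for v in vals):
            raise ValueError("all QC thresholds must be positive")
        if (self.relaxed_min_read_pairs > self.min_read_pairs
                or self.relaxed_min_detected_genes > self.min_detected_genes):
            raise ValueError("relaxed thresholds must not exceed strict ones")


@dataclass
class QCReport:
    removed_cells: dict[str, str] = field(default_factory=dict)   # id -> reason
    removed_genes: dict[str, str] = field(default_factory=dict)
    kept_dims: tuple[int, int] = (0, 0)


def strip_gene_classes(cm: CountMatrix,
                       mito_prefixes=DEFAULT_MITO_PREFIXES,
                       ribo_prefixes=DEFAULT_RIBO_PREFIXES) -> tuple[CountMatrix, QCReport]:
    """Remove mitochondrial genes, ribosomal genes, and unannotated genes.

    Identification is by case-sensitive symbol prefix; an empty symbol marks
    a gene without current annotation.
    """
    report = QCReport()
    keep = np.ones(cm.n_genes, dtype=bool)
    for i, sym in enumerate(cm.gene_symbols):
        if not sym or sym in (".", "nan", "NA"):
            keep[i] = False
            report.removed_genes[cm.gene_ids[i]] = "unannotated"
        elif any(sym.startswith(p) for p in mito_prefixes):
            keep[i] = False
            report.removed_genes[cm.gene_ids[i]] = "mitochondrial"
        elif any(sym.startswith(p) for p in ribo_prefixes):
            keep[i] = False
            report.removed_genes[cm.gene_ids[i]] = "ribosomal"
    out = cm.subset_genes(keep)
    report.kept_dims = (out.n_genes, out.n_samples)
    return out, report


def filter_cells(cm: CountMatrix, th: QCThresholds | None = None,
                 relaxed: bool = False) -> tuple[CountMatrix, QCReport]:
    """Drop cells with fewer assigned read pairs or detected genes than required.

    Totals are column sums over the (already class-stripped) count matrix.
    Thresholds are inclusive: a cell at exactly the minimum is kept.
    """
    th = th or QCThresholds()
    min_pairs = th.relaxed_min_read_pairs if relaxed else th.min_read_pairs
    min_genes = th.relaxed_min_detected_genes if relaxed else th.min_detected_genes
    report = QCReport()
    totals = cm.counts.sum(axis=0)
    detected = (cm.counts >= 1).sum(axis=0)
    keep = np.ones(cm.n_samples, dtype=bool)
    for j, sid in enumerate(cm.sample_ids):
        reasons = []
        if totals[j] < min_pairs:
            reasons.append(f"assigned_total<{min_pairs}")
        if detected[j] < min_genes:
            reasons.append(f"detected_genes<{min_genes}")
        if reasons:
            keep[j] = False
            report.removed_cells[sid] = ";".join(reasons)
    out = cm.subset_samples(keep)
    report.kept_dims = (out.n_genes, out.n_samples)
    return out, report


def filter_genes_cpm(cm: CountMatrix, th: QCThresholds | None = None) -> tuple[CountMatrix, QCReport]:
    """Keep genes reaching ``min_cpm`` CPM in at least ``min_cells_at_cpm`` cells.

    CPM uses the post-cell-filter library sizes; a zero-library cell means
    filter_cells has not run and is an error.
    """
    th = th or QCThresholds()
    if cm.n_samples == 0:
        return cm, QCReport(kept_dims=(cm.n_genes, 0))
    libs = cm.library_sizes()
    if np.any(libs == 0):
        raise ValueError("zero library size present; run filter_cells first")
    cpm = cm.counts / libs[None, :] * 1e6
    n_ok = (cpm >= th.min_cpm).sum(axis=1)
    keep = n_ok >= th.min_cells_at_cpm
    report = QCReport()
    for i in np.flatnonzero(~keep):
        report.removed_genes[cm.gene_ids[i]] = (
            f"cpm>={th.min_cpm}_in<{th.min_cells_at_cpm}_cells")
    out = cm.subset_genes(keep)
    report.kept_dims = (out.n_genes, out.n_samples)
    return out, report


def run_qc(cm: CountMatrix, th: QCThresholds | None = None, relaxed: bool = False,
           mito_prefixes=DEFAULT_MITO_PREFIXES,
           ribo_prefixes=DEFAULT_RIBO_PREFIXES) -> tuple[CountMatrix, QCReport]:
    """Full QC chain: strip gene classes -> filter cells -> filter genes."""
    th = th or QCThresholds()
    out, r1 = strip_gene_classes(cm, mito_prefixes, ribo_prefixes)
    out, r2 = filter_cells(out, th, relaxed)
    out, r3 = filter_genes_cpm(out, th)
    merged = QCReport(
        removed_cells=r2.removed_cells,
        removed_genes={**r1.removed_genes, **r3.removed_genes},
        kept_dims=(out.n_genes, out.n_samples),
    )
    return out, merged


def filter_cells_housekeeping(ct: pd.DataFrame, housekeeping: list[str],
                              undetected_ct: float = 40.0) -> tuple[pd.DataFrame, QCReport]:
    """Remove qPCR cells in which any housekeeping gene is undetected.

    ``ct`` is a gene x cell table of Ct values; Ct >= ``undetected_ct``
    means no expression.
    """
    missing = [g for g in housekeeping if g not in ct.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from Ct table: {missing}")
    report = QCReport()
    bad = (ct.loc[housekeeping] >= undetected_ct).any(axis=0)
    for cell in ct.columns[bad]:
        report.removed_cells[str(cell)] = "housekeeping_undetected"
    out = ct.loc[:, ~bad.to_numpy()]
    report.kept_dims = (out.shape[0], out.shape[1])
    return out, report


def qc_report_table(report: QCReport) -> pd.DataFrame:
    rows = [{"item": k, "axis": "cell", "reason": v} for k, v in report.removed_cells.items()]
    rows += [{"item": k, "axis": "gene", "reason": v} for k, v in report.removed_genes.items()]
    return pd.DataFrame(rows, columns=["item", "axis", "reason"])
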