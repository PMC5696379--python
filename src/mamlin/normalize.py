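"""Expression transforms: CPM, log2-CPM, log2-RPKM, quantile normalization,
per-gene standardization.

log2-RPKM follows the offset convention of scaling the prior count per
column in proportion to library size (so equal libraries get the plain
prior), with the library size inflated by twice the scaled prior; a plain
unscaled mode is available.  Standardization uses the n-1 denominator and
flags constant rows instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iofmt import CountMatrix


@dataclass
class ExpressionMatrix:
    values: np.ndarray                  # genes x samples, float
    gene_ids: list[str]
    sample_ids: list[str]
    normalization: str                  # cpm | log2cpm | log2rpkm | quantile_log2cpm | standardized
    prior_count: float = 0.0
    constant_rows: np.ndarray | None = None   # flagged by standardize_genes
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ids")
        if self.gene_symbols is None:
            self.gene_symbols = list(self.gene_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows, :], list(gene_ids), list(self.sample_ids),
                                self.normalization, self.prior_count,
                                gene_symbols=[self.gene_symbols[r] for r in rows])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(sample_ids),
                                self.normalization, self.prior_count,
                                gene_symbols=list(self.gene_symbols))


def _libsizes(cm: CountMatrix) -> np.ndarray:
    libs = cm.library_sizes()
    if np.any(libs <= 0):
        raise ValueError("zero library size; filter cells first")
    return libs


def to_cpm(cm: CountMatrix) -> ExpressionMatrix:
    libs = _libsizes(cm)
    vals = cm.counts / libs[None, :] * 1e6
    return ExpressionMatrix(vals, list(cm.gene_ids), list(cm.sample_ids), "cpm",
                            gene_symbols=list(cm.gene_symbols))


def to_log2cpm(cm: CountMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """log2((count + prior) / (libsize + 2 prior) * 1e6)."""
    if prior <= 0:
        raise ValueError("prior count must be positive")
    libs = _libsizes(cm)
    vals = np.log2((cm.counts + prior) / (libs[None, :] + 2 * prior) * 1e6)
    return ExpressionMatrix(vals, list(cm.gene_ids), list(cm.sample_ids), "log2cpm",
                            prior_count=prior, gene_symbols=list(cm.gene_symbols))


def to_log2rpkm(cm: CountMatrix, prior: float = 5.0,
                scale_prior_by_libsize: bool = True) -> ExpressionMatrix:
    """log2 reads-per-kilobase-per-million with an offset prior count.

    The prior for column j is ``prior * libsize_j / mean(libsize)`` when
    scaling is on (equal libraries then receive the plain prior), and the
    effective library is ``libsize + 2 * scaled_prior``.
    """
    if prior <= 0:
        raise ValueError("prior count must be positive")
    if cm.gene_lengths_bp is None:
        raise ValueError("gene lengths required for RPKM")
    libs = _libsizes(cm)
    scaled = prior * libs / libs.mean() if scale_prior_by_libsize else np.full_like(libs, prior)
    eff_lib = libs + 2 * scaled
    vals = np.log2((cm.counts + scaled[None, :]) / eff_lib[None, :] * 1e9
                   / cm.gene_lengths_bp[:, None])
    return ExpressionMatrix(vals, list(cm.gene_ids), list(cm.sample_ids), "log2rpkm",
                            prior_count=prior, gene_symbols=list(cm.gene_symbols))


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to the across-column mean of sorted values.

    Ties within a column receive the mean of the reference values over
    their rank span, so permutation-equivalent columns normalize
    identically.
    """
    if expr.n_samples < 2:
        raise ValueError("quantile normalization needs >=2 columns")
    x = expr.values
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = ref
        # average reference values over spans of tied inputs
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[order[i:k + 1]] = ref[i:k + 1].mean()
            i = k + 1
        out[:, j] = ranked
    tag = "quantile_log2cpm" if expr.normalization == "log2cpm" else f"quantile_{expr.normalization}"
    return ExpressionMatrix(out, list(expr.gene_ids), list(expr.sample_ids), tag,
                            prior_count=expr.prior_count, gene_symbols=list(expr.gene_symbols))


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to SD 1 (n-1 denominator).

    Constant genes become all-zero rows and are flagged in
    ``constant_rows`` rather than standardized.
    """
    if expr.n_samples < 2:
        raise ValueError("standardization needs >=2 samples")
    x = expr.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (x - mean) / sd_safe
    out[const, :] = 0.0
    em = ExpressionMatrix(out, list(expr.gene_ids), list(expr.sample_ids), "standardized",
                          prior_count=expr.prior_count, gene_symbols=list(expr.gene_symbols))
    em.constant_rows = const
    return em
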