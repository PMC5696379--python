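"""Readers and writers for the external formats the pipeline touches.

Count matrices come in either as a 10X-style Matrix Market directory
(``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``) or as a
dense TSV with gene IDs in the first column.  Gene sets are GMT lines,
interaction/ortholog/function tables are plain TSV, and configuration is a
single YAML (or JSON) file with per-stage blocks.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml


class FormatError(ValueError):
    """Malformed input file (bad MTX header, bad schema)."""


class ConsistencyError(ValueError):
    """Internally inconsistent inputs (dimension mismatch, duplicate IDs)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with gene/sample annotation.

    ``counts`` has shape (n_genes, n_samples).  ``sample_meta`` is a DataFrame
    indexed by sample id; a ``group`` column carries stage / cell-type /
    population labels where known.  ``gene_lengths_bp`` is optional: RPKM
    operations refuse to run without it rather than guessing lengths.
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    gene_symbols: list[str] | None = None
    gene_lengths_bp: np.ndarray | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ConsistencyError("counts must be 2-D (genes x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ConsistencyError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConsistencyError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConsistencyError("duplicate sample IDs")
        if self.gene_symbols is None:
            self.gene_symbols = list(self.gene_ids)
        else:
            self.gene_symbols = [str(s) for s in self.gene_symbols]
            if len(self.gene_symbols) != len(self.gene_ids):
                raise ConsistencyError("gene_symbols length mismatch")
        if self.gene_lengths_bp is not None:
            self.gene_lengths_bp = np.asarray(self.gene_lengths_bp, dtype=float)
            if self.gene_lengths_bp.shape != (len(self.gene_ids),):
                raise ConsistencyError("gene_lengths_bp length mismatch")
            if np.any(self.gene_lengths_bp <= 0):
                raise ValueError("gene lengths must be positive")
        if self.sample_meta is not None:
            missing = set(self.sample_ids) - set(map(str, self.sample_meta.index))
            if missing:
                raise ConsistencyError(f"sample_meta missing samples: {sorted(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[self.sample_ids]

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def groups(self) -> np.ndarray:
        if self.sample_meta is None or "group" not in self.sample_meta.columns:
            raise ValueError("no group labels in sample_meta")
        return self.sample_meta["group"].to_numpy()

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[keep, :],
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            gene_symbols=[self.gene_symbols[i] for i in keep],
            gene_lengths_bp=None if self.gene_lengths_bp is None else self.gene_lengths_bp[keep],
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.sample_ids[i] for i in keep]
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=list(self.gene_ids),
            sample_ids=ids,
            gene_symbols=list(self.gene_symbols),
            gene_lengths_bp=None if self.gene_lengths_bp is None else self.gene_lengths_bp.copy(),
            sample_meta=None if self.sample_meta is None else self.sample_meta.loc[ids],
        )


@dataclass
class GeneSetCollection:
    """Named ordered gene lists (lineage signatures, cell-cycle genes, ...)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ConsistencyError(f"duplicate members in gene set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path: str, format_hint: str = "auto") -> CountMatrix:
    """Read a count matrix from a 10X-style MTX directory or dense TSV.

    ``format_hint`` may be ``mtx_dir``, ``tsv`` or ``auto`` (directory =>
    MTX, file => TSV).  MTX triplets place genes on rows and cells on
    columns; missing entries are zero.
    """
    if format_hint == "auto":
        format_hint = "mtx_dir" if os.path.isdir(path) else "tsv"
    if format_hint == "mtx_dir":
        return _read_mtx_dir(path)
    if format_hint == "tsv":
        return _read_tsv_counts(path)
    raise ValueError(f"unknown format_hint {format_hint!r}")


def _find(dirname: str, names: list[str]) -> str:
    for n in names:
        p = os.path.join(dirname, n)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"none of {names} found in {dirname}")


def _read_mtx_dir(dirname: str) -> CountMatrix:
    mtx_path = _find(dirname, ["matrix.mtx", "matrix.mtx.gz"])
    feat_path = _find(dirname, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"])
    bc_path = _find(dirname, ["barcodes.tsv", "barcodes.tsv.gz"])
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"malformed MTX file {mtx_path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    dense = np.asarray(mat.todense())
    if dense.size and not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ValueError(f"non-integer entries in {mtx_path}")
    dense = dense.astype(np.int64)

    try:
        feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        feats = pd.DataFrame(columns=[0])
    if feats.shape[1] < 1 or feats.shape[1] > 3:
        # an empty features file reads as 0 rows, 1 col; allow that
        raise FormatError(f"features file must have 1-3 columns, got {feats.shape[1]}")
    gene_ids = feats.iloc[:, 0].tolist() if len(feats) else []
    symbols = feats.iloc[:, 1].tolist() if feats.shape[1] >= 2 and len(feats) else None
    try:
        bcs = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        bcs = pd.DataFrame(columns=[0])
    barcodes = bcs.iloc[:, 0].tolist() if len(bcs) else []

    if dense.shape != (len(gene_ids), len(barcodes)):
        raise ConsistencyError(
            f"MTX dims {dense.shape} do not match features ({len(gene_ids)}) "
            f"x barcodes ({len(barcodes)})"
        )
    return CountMatrix(counts=dense, gene_ids=gene_ids, sample_ids=barcodes,
                       gene_symbols=symbols)


def _read_tsv_counts(path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if vals.size and not np.all(np.equal(np.mod(vals, 1), 0)):
        raise ValueError(f"non-integer entries in {path}")
    return CountMatrix(counts=vals.astype(np.int64),
                       gene_ids=[str(g) for g in df.index],
                       sample_ids=[str(c) for c in df.columns])


def write_counts(cm: CountMatrix, dirname: str) -> None:
    """Write a CountMatrix as a 10X-style MTX directory."""
    os.makedirs(dirname, exist_ok=True)
    sp = scipy.sparse.coo_matrix(cm.counts)
    scipy.io.mmwrite(os.path.join(dirname, "matrix.mtx"), sp, field="integer")
    pd.DataFrame({"id": cm.gene_ids, "symbol": cm.gene_symbols}).to_csv(
        os.path.join(dirname, "features.tsv"), sep="\t", header=False, index=False)
    with open(os.path.join(dirname, "barcodes.tsv"), "w") as fh:
        for s in cm.sample_ids:
            fh.write(s + "\n")
    if cm.gene_lengths_bp is not None:
        pd.DataFrame({"id": cm.gene_ids, "length_bp": cm.gene_lengths_bp.astype(int)}).to_csv(
            os.path.join(dirname, "lengths.tsv"), sep="\t", header=False, index=False)
    if cm.sample_meta is not None:
        cm.sample_meta.to_csv(os.path.join(dirname, "sample_meta.tsv"), sep="\t")


def read_gene_lengths(path: str) -> pd.Series:
    """Two-column TSV (gene id, length in bp) -> Series indexed by id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "length_bp"], dtype={0: str})
    s = pd.Series(df["length_bp"].to_numpy(dtype=float), index=df["id"])
    if (s <= 0).any():
        raise ValueError("gene lengths must be positive")
    return s


def attach_lengths(cm: CountMatrix, lengths: pd.Series) -> CountMatrix:
    missing = [g for g in cm.gene_ids if g not in lengths.index]
    if missing:
        raise ConsistencyError(f"lengths missing for {len(missing)} genes, e.g. {missing[:3]}")
    cm.gene_lengths_bp = lengths.loc[cm.gene_ids].to_numpy(dtype=float)
    return cm


def attach_meta(cm: CountMatrix, meta_path: str) -> CountMatrix:
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    cm.sample_meta = meta.loc[cm.sample_ids]
    return cm


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(rows, path: str, columns: list[str] | None = None) -> None:
    """Write records (list of dicts or DataFrame) to UTF-8 TSV.

    Floats are rendered with 6 significant digits so repeated runs diff
    cleanly.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
        if df.empty and columns is not None:
            df = pd.DataFrame(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name <tab> description <tab> members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
            name = parts[0]
            if name in sets:
                raise ConsistencyError(f"duplicate gene set name {name!r}")
            sets[name] = [p for p in parts[2:] if p]
    return GeneSetCollection(sets=sets, provenance=path)


def write_gene_sets(gsc: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, "."] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# network side inputs
# ---------------------------------------------------------------------------

VALID_FUNCTION_TOKENS = {"ST", "TF"}


def read_network_tables(edges_path: str, orthologs_path: str, functions_path: str):
    """Load interaction edges, mouse->human ortholog map, and function classes.

    Edges are deduplicated as unordered pairs and self-loops dropped.  The
    ortholog map may be one-to-many.  Function tokens must be ST or TF.
    """
    edf = pd.read_csv(edges_path, sep="\t", header=None, dtype=str, comment="#")
    edges: list[tuple[str, str]] = []
    seen = set()
    for a, b in edf.iloc[:, :2].itertuples(index=False):
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            edges.append(key)

    odf = pd.read_csv(orthologs_path, sep="\t", header=None, dtype=str, comment="#")
    orth: dict[str, list[str]] = {}
    for m, h in odf.iloc[:, :2].itertuples(index=False):
        orth.setdefault(m, [])
        if h not in orth[m]:
            orth[m].append(h)

    fdf = pd.read_csv(functions_path, sep="\t", header=None, dtype=str, comment="#")
    func: dict[str, set[str]] = {}
    for h, tok in fdf.iloc[:, :2].itertuples(index=False):
        if tok not in VALID_FUNCTION_TOKENS:
            raise ValueError(f"unknown function token {tok!r} (expected ST or TF)")
        func.setdefault(h, set()).add(tok)
    return edges, orth, func


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "results",
    "qc": {
        "min_read_pairs": 100_000,
        "min_detected_genes": 1500,
        "relaxed_min_read_pairs": 50_000,
        "relaxed_min_detected_genes": 1000,
        "min_cpm": 1.0,
        "min_cells_at_cpm": 3,
        "mito_prefixes": ["mt-"],
        "ribo_prefixes": ["Rps", "Rpl", "Mrps", "Mrpl"],
        "undetected_ct": 40.0,
    },
    "normalize": {
        "log2cpm_prior": 0.5,
        "log2rpkm_prior": 5.0,
        "scale_prior_by_libsize": True,
    },
    "de": {
        "fdr_cut": 0.05,
        "dispersion_grid_min": 1e-3,
        "dispersion_grid_max": 10.0,
        "dispersion_grid_points": 21,
        "shrink_weight": 10.0,
        "tau_basal_vs_luminal": 2.0,
        "tau_lp_vs_ml": 1.3,
        "tau_lineage_panels": 3.0,
        "n_top_panel": 200,
    },
    "lineage": {
        "ternary_floor": "median",
        "score_mode": "mean_positive",
        "intermediate_band": None,
        "min_foreign_genes": 3,
        "detect_rpkm": 5.0,
        "host_dominance": 1.0,
        "marker_rpkm_threshold": 40.0,
    },
    "structure": {
        "k_top": 500,
        "mds_dims": 2,
        "linkage": "complete",
    },
    "trend": {
        "fdr_cut": 0.01,
        "eps": 0.0,
        "elevated_ratio": 1.2,
        "mean_scale": "linear",
        "z_margin": 0.5,
    },
    "network": {
        "fdr_cut": 0.001,
    },
}


def _merge_config(base: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in user.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge_config(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: str | None = None) -> dict:
    """Load a YAML/JSON config, validated against the default schema.

    Unknown keys are rejected; omitted keys take the documented defaults.
    """
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        if path.endswith(".json"):
            user = json.load(fh)
        else:
            user = yaml.safe_load(fh) or {}
    return _merge_config(DEFAULT_CONFIG, user)


def dump_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
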