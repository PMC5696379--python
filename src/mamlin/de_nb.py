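"""Negative-binomial differential expression.

Each gene is modeled as NB(mean mu_ij, dispersion phi_g) with a log link
and log library-size offset, so for a one-way group layout the coefficient
of group g is the log of its library-normalized mean rate.  Because the
design is a group indicator, the IRLS fit separates into independent
per-group one-dimensional Fisher-scoring problems, which we solve
vectorized across genes.

Provided tests:

* ``lrt_de`` -- likelihood-ratio test of equal means across 2+ groups,
  chi-square reference with (n_groups - 1) df.
* ``treat_test`` -- fold-change-threshold test of H0: |log2FC| <= log2(tau)
  against |log2FC| > log2(tau), built from signed-root likelihood-ratio
  statistics at the two shifted-null boundaries with the two one-sided
  tails summed; at tau = 1 it reduces exactly to the two-group LRT.
* ``estimate_dispersions`` -- common dispersion by maximizing the summed
  Cox-Reid adjusted profile likelihood (APL) over a log grid with
  golden-section refinement; tagwise dispersions by weighted-likelihood
  shrinkage of the per-gene APL toward the common curve.

Multiple testing uses Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from .iofmt import CountMatrix, GeneSetCollection

_LN2 = np.log(2.0)
_RATE_FLOOR = 1e-12      # lower bound on the fitted per-read rate (all-zero groups)


# ---------------------------------------------------------------------------
# NB likelihood and one-way fits
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Elementwise NB log-likelihood, parameterized by mean and dispersion."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + xlogy(y, phi * mu) - (y + r) * np.log1p(phi * mu))


def _fit_rate(y: np.ndarray, libs: np.ndarray, phi: np.ndarray,
              max_iter: int = 50, tol: float = 1e-10):
    """MLE of a common rate for each gene: mu_ij = exp(beta_g) * libs_j.

    ``y`` is genes x samples, ``libs`` length-samples, ``phi`` length-genes.
    Returns (beta, loglik, fisher_info) per gene.  Fisher scoring on beta;
    concave in beta so convergence is monotone in practice.
    """
    y = np.asarray(y, dtype=float)
    libs = np.asarray(libs, dtype=float)
    phi = np.asarray(phi, dtype=float)
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.1) / libs.sum())
    beta_floor = np.log(_RATE_FLOOR)
    for _ in range(max_iter):
        mu = np.exp(beta)[:, None] * libs[None, :]
        denom = 1.0 + phi[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = np.maximum(beta + step, beta_floor)
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(beta)[:, None] * libs[None, :]
    ll = nb_loglik(y, mu, phi[:, None]).sum(axis=1)
    info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)
    return beta, ll, info


def _group_levels(groups) -> list:
    levels = []
    for g in groups:
        if g not in levels:
            levels.append(g)
    return levels


def _fit_oneway(counts: np.ndarray, libs: np.ndarray, phi: np.ndarray, groups):
    """Per-group rate fits; returns dict level -> (beta, ll, info)."""
    groups = np.asarray(groups)
    out = {}
    for lev in _group_levels(groups):
        cols = np.flatnonzero(groups == lev)
        out[lev] = _fit_rate(counts[:, cols], libs[cols], phi)
    return out


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    common_phi: float
    tagwise_phi: np.ndarray
    shrink_weight: float = 10.0

    def __post_init__(self) -> None:
        self.tagwise_phi = np.asarray(self.tagwise_phi, dtype=float)
        if self.common_phi <= 0 or np.any(self.tagwise_phi <= 0):
            raise ValueError("dispersions must be positive")

    @classmethod
    def fixed(cls, phi: float, n_genes: int) -> "DispersionModel":
        """A known, shared dispersion (used for calibration studies)."""
        return cls(common_phi=phi, tagwise_phi=np.full(n_genes, phi))


def _apl(counts, libs, groups, phi_scalar) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at one dispersion."""
    phi = np.full(counts.shape[0], phi_scalar)
    apl = np.zeros(counts.shape[0])
    for _, (beta, ll, info) in _fit_oneway(counts, libs, phi, groups).items():
        apl += ll - 0.5 * np.log(np.maximum(info, 1e-300))
    return apl


def estimate_dispersions(cm: CountMatrix, groups=None, shrink_weight: float = 10.0,
                         grid_min: float = 1e-3, grid_max: float = 10.0,
                         grid_points: int = 21) -> DispersionModel:
    """Common + tagwise NB dispersions from the adjusted profile likelihood.

    The common dispersion maximizes the summed APL over a log-spaced grid,
    refined by golden-section search.  Tagwise values maximize
    ``APL_g + shrink_weight * mean_APL`` over the grid (plus the refined
    common point), shrinking each gene toward the common value with the
    weight of ``shrink_weight`` prior genes.
    """
    if groups is None:
        groups = cm.groups()
    counts = cm.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    libs = cm.library_sizes()

    grid = np.exp(np.linspace(np.log(grid_min), np.log(grid_max), grid_points))
    apl_mat = np.column_stack([_apl(counts, libs, groups, p) for p in grid])
    total = apl_mat.sum(axis=0)

    # golden-section refinement around the grid argmax of the summed APL
    k = int(np.argmax(total))
    lo = np.log(grid[max(k - 1, 0)])
    hi = np.log(grid[min(k + 1, grid_points - 1)])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc = _apl(counts, libs, groups, np.exp(c)).sum()
    fd = _apl(counts, libs, groups, np.exp(d)).sum()
    for _ in range(20):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _apl(counts, libs, groups, np.exp(c)).sum()
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _apl(counts, libs, groups, np.exp(d)).sum()
    common = float(np.exp((a + b) / 2.0))

    cand = np.append(grid, common)
    apl_common = _apl(counts, libs, groups, common)
    apl_all = np.column_stack([apl_mat, apl_common])
    mean_apl = apl_all.mean(axis=0)
    weighted = apl_all + shrink_weight * mean_apl[None, :]
    tagwise = cand[np.argmax(weighted, axis=1)]
    return DispersionModel(common_phi=common, tagwise_phi=tagwise,
                           shrink_weight=shrink_weight)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def lrt_de(cm: CountMatrix, groups=None, disp: DispersionModel | None = None,
           contrast_label: str | None = None) -> pd.DataFrame:
    """One-way NB likelihood-ratio test across 2+ groups.

    Returns a DataFrame with gene_id, per-group log2FC relative to the
    grand mean (columns ``log2fc_<group>``), a summary ``log2fc`` (signed
    second-vs-first for two groups, max-minus-min spread otherwise),
    ``lr_stat``, ``p`` and BH ``fdr``.
    """
    if groups is None:
        groups = cm.groups()
    groups = np.asarray(groups)
    levels = _group_levels(groups)
    if len(levels) < 2:
        raise ValueError("need >=2 groups")
    if disp is None:
        disp = estimate_dispersions(cm, groups)
    phi = disp.tagwise_phi
    counts = cm.counts.astype(float)
    libs = cm.library_sizes()

    fits = _fit_oneway(counts, libs, phi, groups)
    ll_full = sum(f[1] for f in fits.values())
    beta_null, ll_null, _ = _fit_rate(counts, libs, phi)
    lr = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    df = len(levels) - 1
    p = stats.chi2.sf(lr, df)

    out = pd.DataFrame({"gene_id": cm.gene_ids})
    betas = np.column_stack([fits[lev][0] for lev in levels])
    grand = betas.mean(axis=1)
    for i, lev in enumerate(levels):
        out[f"log2fc_{lev}"] = (betas[:, i] - grand) / _LN2
    if len(levels) == 2:
        out["log2fc"] = (betas[:, 1] - betas[:, 0]) / _LN2
    else:
        out["log2fc"] = (betas.max(axis=1) - betas.min(axis=1)) / _LN2
    out["lr_stat"] = lr
    out["p"] = p
    out["fdr"] = bh_adjust(p)
    out["contrast"] = contrast_label or "-vs-".join(str(x) for x in levels)
    return out


def treat_test(cm: CountMatrix, groups=None, disp: DispersionModel | None = None,
               tau: float = 2.0, contrast_label: str | None = None) -> pd.DataFrame:
    """Threshold test of H0: |log2FC| <= log2(tau) between exactly two groups.

    The p-value combines the one-sided signed-root LR tails at the nearer
    and farther boundary of the null interval, so the test is conservative
    on the boundary and reduces to the ordinary LRT at tau = 1.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if groups is None:
        groups = cm.groups()
    groups = np.asarray(groups)
    levels = _group_levels(groups)
    if len(levels) != 2:
        raise ValueError("treat_test requires exactly 2 groups")
    if disp is None:
        disp = estimate_dispersions(cm, groups)
    phi = disp.tagwise_phi
    counts = cm.counts.astype(float)
    libs = cm.library_sizes()
    x = (groups == levels[1]).astype(float)     # indicator of second group

    fits = _fit_oneway(counts, libs, phi, groups)
    ll_full = sum(f[1] for f in fits.values())
    beta_hat = fits[levels[1]][0] - fits[levels[0]][0]   # natural-log FC

    t = np.log(tau)

    def _constrained_ll(delta: float) -> np.ndarray:
        # fix the group effect at delta by folding it into the exposure
        _, ll, _ = _fit_rate(counts, libs * np.exp(delta * x), phi)
        return ll

    ll_up = _constrained_ll(t)
    ll_dn = _constrained_ll(-t) if t > 0 else ll_up
    near_is_up = beta_hat >= 0
    ll_near = np.where(near_is_up, ll_up, ll_dn)
    ll_far = np.where(near_is_up, ll_dn, ll_up)
    z_near = np.sign(np.abs(beta_hat) - t) * np.sqrt(np.maximum(2.0 * (ll_full - ll_near), 0.0))
    z_far = np.sqrt(np.maximum(2.0 * (ll_full - ll_far), 0.0))
    p = np.minimum(stats.norm.sf(z_near) + stats.norm.sf(z_far), 1.0)

    out = pd.DataFrame({
        "gene_id": cm.gene_ids,
        "log2fc": beta_hat / _LN2,
        "lr_stat": np.maximum(2.0 * (ll_full - ll_near), 0.0),
        "p": p,
    })
    out["fdr"] = bh_adjust(p)
    out["contrast"] = contrast_label or f"{levels[1]}-vs-{levels[0]}"
    out["threshold_tau"] = tau
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagated)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any(~ok):
        warnings.warn("NaN p-values propagated through BH adjustment")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Named lineage gene lists with derivation log2FC and FDR per gene."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: str = ""

    def genes(self, name: str) -> list[str]:
        return self.tables[name]["gene_id"].tolist()

    def names(self) -> list[str]:
        return list(self.tables)

    def to_gene_sets(self) -> GeneSetCollection:
        return GeneSetCollection({n: self.genes(n) for n in self.tables},
                                 provenance=self.provenance)

    @classmethod
    def from_gene_sets(cls, gsc: GeneSetCollection) -> "SignatureSet":
        tables = {
            name: pd.DataFrame({"gene_id": members,
                                "log2fc": np.nan, "fdr": np.nan})
            for name, members in gsc.sets.items()
        }
        return cls(tables=tables, provenance=gsc.provenance)


def derive_signatures(bulk: CountMatrix, celltypes=None,
                      tau_map: dict | None = None, fdr_cut: float = 0.05,
                      disp: DispersionModel | None = None,
                      biotypes=None) -> SignatureSet:
    """Cell-type-specific genes: up in one type vs BOTH other types.

    Each pairwise contrast is a fold-change-threshold test at the tau given
    by ``tau_map`` (keys are frozensets of the two type names), filtered at
    ``fdr_cut``.  With ``biotypes`` provided, only protein_coding genes are
    considered.
    """
    groups = np.asarray(celltypes if celltypes is not None else bulk.groups())
    levels = _group_levels(groups)
    if len(levels) != 3:
        raise ValueError("signature derivation expects exactly 3 cell types")
    tau_map = {frozenset(k): v for k, v in (tau_map or {}).items()}
    for a in levels:
        for b in levels:
            if a < b and frozenset((a, b)) not in tau_map:
                raise ValueError(f"no fold-change threshold for contrast {a} vs {b}")

    if biotypes is not None:
        keep = np.asarray([bt == "protein_coding" for bt in biotypes])
        bulk = bulk.subset_genes(keep)
    if disp is None:
        disp = estimate_dispersions(bulk, groups)

    # one threshold test per unordered pair, reused for both directions
    pair_res: dict[frozenset, pd.DataFrame] = {}
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = levels[i], levels[j]
            cols = np.flatnonzero((groups == a) | (groups == b))
            sub = bulk.subset_samples(cols)
            sub_disp = DispersionModel(disp.common_phi, disp.tagwise_phi,
                                       disp.shrink_weight)
            res = treat_test(sub, groups[cols], sub_disp,
                             tau=tau_map[frozenset((a, b))],
                             contrast_label=f"{b}-vs-{a}")
            res = res.set_index("gene_id")
            res["second"] = b            # log2fc is second-level over first
            pair_res[frozenset((a, b))] = res

    tables = {}
    for s in levels:
        others = [o for o in levels if o != s]
        masks, lfcs, fdrs = [], [], []
        for o in others:
            res = pair_res[frozenset((s, o))]
            sign = 1.0 if (res["second"] == s).all() else -1.0
            lfc = sign * res["log2fc"]
            masks.append((res["fdr"] < fdr_cut) & (lfc > 0))
            lfcs.append(lfc)
            fdrs.append(res["fdr"])
        sel = masks[0] & masks[1]
        tab = pd.DataFrame({
            "gene_id": sel.index[sel],
            "log2fc": np.minimum(lfcs[0][sel], lfcs[1][sel]).to_numpy(),
            "fdr": np.maximum(fdrs[0][sel], fdrs[1][sel]).to_numpy(),
        })
        tables[s] = tab.sort_values(
            ["fdr", "log2fc", "gene_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return SignatureSet(tables=tables, provenance="derive_signatures")


def _rank_panel(tab: pd.DataFrame, n_top: int) -> pd.DataFrame:
    tab = tab.copy()
    tab["abs_lfc"] = tab["log2fc"].abs()
    tab = tab.sort_values(["fdr", "abs_lfc", "gene_id"],
                          ascending=[True, False, True]).drop(columns="abs_lfc")
    return tab.head(n_top).reset_index(drop=True)


def top_lineage_panels(bulk: CountMatrix, two_types=None, tau: float = 3.0,
                       n_top: int = 200, fdr_cut: float = 0.05,
                       disp: DispersionModel | None = None) -> SignatureSet:
    """Top-N panels per lineage from a two-group threshold test.

    Significant genes split by log2FC sign; each side ranked by ascending
    FDR (ties: larger |log2FC|, then gene id) and truncated to ``n_top``.
    """
    groups = np.asarray(two_types if two_types is not None else bulk.groups())
    levels = _group_levels(groups)
    if len(levels) != 2:
        raise ValueError("top_lineage_panels expects exactly 2 groups")
    res = treat_test(bulk, groups, disp, tau=tau)
    sig = res[res["fdr"] < fdr_cut]
    up_b = sig[sig["log2fc"] > 0]       # up in second level
    up_a = sig[sig["log2fc"] < 0]
    if len(up_a) < n_top or len(up_b) < n_top:
        warnings.warn("fewer significant genes than requested panel size")
    tables = {
        levels[0]: _rank_panel(up_a[["gene_id", "log2fc", "fdr"]], n_top),
        levels[1]: _rank_panel(up_b[["gene_id", "log2fc", "fdr"]], n_top),
    }
    return SignatureSet(tables=tables, provenance=f"top_lineage_panels tau={tau}")


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def hypergeom_enrichment(hits: list[str], universe: list[str],
                         sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    ``hits`` must be a subset of ``universe``; sets are intersected with
    the universe first and sets disjoint from it are skipped with a
    warning.  BH adjustment is across the tested sets.
    """
    uni = set(universe)
    stray = [h for h in hits if h not in uni]
    if stray:
        raise ValueError(f"hit genes outside universe: {stray[:5]}")
    hit_set = set(hits)
    n_uni, n_hits = len(uni), len(hit_set)
    rows = []
    for name, members in sets.sets.items():
        in_uni = [m for m in members if m in uni]
        if not in_uni:
            warnings.warn(f"gene set {name!r} disjoint from universe; skipped")
            continue
        k = len(hit_set.intersection(in_uni))
        p = stats.hypergeom.sf(k - 1, n_uni, len(in_uni), n_hits)
        rows.append({"set": name, "set_size": len(in_uni), "overlap": k, "p": p})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["fdr"] = bh_adjust(out["p"]) if len(out) else np.nan
    return out
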