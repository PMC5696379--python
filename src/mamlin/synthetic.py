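"""Synthetic bulk and single-cell count generators with planted lineage truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial counts with gene-wise dispersion, lognormal
library sizes, optional mean-dependent dropout, and planted structure --
cell-type-specific marker genes, a luminal-intermediate population whose
gene means linearly interpolate its two parents, and a rare mixed-lineage
subset of basal cells whose randomly chosen donor-marker genes take donor
means.

Marker (cell-type-specific) genes are drawn at a low off-lineage baseline
and raised by the planted log2 fold change in their own lineage; background
genes share one mean across all populations.  A small block of constant
high-abundance "housekeeping" filler genes absorbs the remaining library
mass so that the drawn mean values are true counts-per-million.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iofmt import CountMatrix
import pandas as pd


@dataclass
class GroupSpec:
    name: str
    n_samples: int


@dataclass
class SignaturePlan:
    n_specific_genes: int
    log2fc: float = 3.0


@dataclass
class IntermediatePlan:
    """A population whose gene means interpolate two parents on linear scale."""
    name: str
    parent_a: str
    parent_b: str
    n_samples: int
    alpha: float | str = 0.5  # weight on parent_a, or "uniform" per cell


@dataclass
class MixedPlan:
    """Rare host-population cells co-expressing donor marker genes."""
    host_group: str
    donor_group: str
    fraction: float = 0.05
    n_swapped_genes: int = 12


@dataclass
class DropoutPlan:
    midpoint_log2cpm: float = 1.0
    slope: float = 1.0


@dataclass
class SimulationDesign:
    n_genes: int = 2000                      # background (non-marker) genes
    groups: list[GroupSpec] = field(default_factory=list)
    signature_plan: dict[str, SignaturePlan] = field(default_factory=dict)
    dispersion_median: float = 0.1
    dispersion_sigma: float = 0.3
    libsize_target: float = 2e6
    libsize_lognormal_sigma: float = 0.3
    dropout: DropoutPlan | None = None
    intermediate_plan: IntermediatePlan | None = None
    mixed_plan: MixedPlan | None = None
    background_cpm_range: tuple[float, float] = (1.0, 500.0)
    marker_off_cpm_range: tuple[float, float] = (0.25, 1.0)
    n_filler_genes: int = 10
    gene_length_bp: float = 1000.0
    seed: int = 1

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        for gname in self.signature_plan:
            if gname not in names:
                raise ValueError(f"signature_plan group {gname!r} not in groups")
        if self.dispersion_median <= 0 or self.libsize_target <= 0:
            raise ValueError("dispersion and library size must be positive")
        if self.mixed_plan is not None:
            mp = self.mixed_plan
            if not 0.0 <= mp.fraction <= 1.0:
                raise ValueError("mixed fraction must be in [0,1]")
            if mp.host_group not in names or mp.donor_group not in self.signature_plan:
                raise ValueError("mixed_plan host must be a group and donor must have markers")
        if self.intermediate_plan is not None:
            ip = self.intermediate_plan
            if ip.parent_a not in names or ip.parent_b not in names:
                raise ValueError("intermediate parents must be existing groups")
            if isinstance(ip.alpha, (int, float)) and not 0.0 <= float(ip.alpha) <= 1.0:
                raise ValueError("alpha must be in [0,1] or 'uniform'")


@dataclass
class Truth:
    cell_labels: dict[str, str]
    specific_genes: dict[str, list[str]]
    mixed_cells: list[str]
    swapped_genes_per_cell: dict[str, list[str]]
    intermediate_alpha: dict[str, float]
    gene_mean_cpm: pd.DataFrame | None = None  # genes x populations, linear CPM


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    # one master sequence, children per stage: adding a stage never
    # perturbs the draws of earlier stages
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _build_mean_table(design: SimulationDesign, rng: np.random.Generator):
    """Gene ids, symbols, and a genes x populations table of true mean CPM."""
    group_names = [g.name for g in design.groups]
    specific: dict[str, list[str]] = {}
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []

    gidx = 0
    for gname in group_names:
        plan = design.signature_plan.get(gname)
        if plan is None or plan.n_specific_genes == 0:
            specific[gname] = []
            continue
        lo, hi = design.marker_off_cpm_range
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), plan.n_specific_genes))
        ids = [f"MK{gname}{i:04d}" for i in range(plan.n_specific_genes)]
        specific[gname] = ids
        for b, gid in zip(base, ids):
            mean = np.full(len(group_names), b)
            mean[group_names.index(gname)] = b * 2.0 ** plan.log2fc
            gene_ids.append(gid)
            rows.append(mean)
            gidx += 1

    lo, hi = design.background_cpm_range
    bg = np.exp(rng.uniform(np.log(lo), np.log(hi), design.n_genes))
    for i, b in enumerate(bg):
        gene_ids.append(f"BG{i:05d}")
        rows.append(np.full(len(group_names), b))

    table = np.vstack(rows) if rows else np.zeros((0, len(group_names)))
    total = table.sum(axis=0).max() if len(rows) else 0.0
    if total >= 0.95e6:
        raise ValueError("drawn mean CPMs exceed the library budget; reduce n_genes or ranges")
    if design.n_filler_genes > 0:
        fill = (1e6 - table.sum(axis=0)) / design.n_filler_genes
        for i in range(design.n_filler_genes):
            gene_ids.append(f"HK{i:03d}")
        table = np.vstack([table, np.tile(fill, (design.n_filler_genes, 1))])
    means = pd.DataFrame(table, index=gene_ids, columns=group_names)
    return gene_ids, specific, means


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2); phi broadcast over columns."""
    phi = np.broadcast_to(np.asarray(phi)[:, None], mu.shape)
    r = 1.0 / phi
    p = r / (r + np.maximum(mu, 1e-300))
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r[pos], p[pos])
    return out


def _simulate(design: SimulationDesign, platform: str) -> tuple[CountMatrix, Truth]:
    design.validate()
    (rng_means, rng_disp, rng_lib, rng_counts,
     rng_mixed, rng_drop, rng_alpha) = _rngs(design.seed, 7)

    gene_ids, specific, means = _build_mean_table(design, rng_means)
    n_genes_total = len(gene_ids)
    phi = np.exp(rng_disp.normal(np.log(design.dispersion_median),
                                 design.dispersion_sigma, n_genes_total))

    # per-population mean CPM columns, including the intermediate population
    pop_of_sample: list[str] = []
    sample_ids: list[str] = []
    for g in design.groups:
        for i in range(g.n_samples):
            sample_ids.append(f"{g.name}_{i:03d}")
            pop_of_sample.append(g.name)
    alpha_map: dict[str, float] = {}
    if design.intermediate_plan is not None:
        ip = design.intermediate_plan
        for i in range(ip.n_samples):
            sid = f"{ip.name}_{i:03d}"
            sample_ids.append(sid)
            pop_of_sample.append(ip.name)
            alpha_map[sid] = (float(rng_alpha.uniform())
                              if ip.alpha == "uniform" else float(ip.alpha))

    n_samples = len(sample_ids)
    libsizes = np.exp(rng_lib.normal(np.log(design.libsize_target),
                                     design.libsize_lognormal_sigma, n_samples))

    # expected counts per cell
    mu = np.empty((n_genes_total, n_samples))
    for j, (sid, pop) in enumerate(zip(sample_ids, pop_of_sample)):
        if design.intermediate_plan is not None and pop == design.intermediate_plan.name:
            ip = design.intermediate_plan
            a = alpha_map[sid]
            cpm = a * means[ip.parent_a].to_numpy() + (1 - a) * means[ip.parent_b].to_numpy()
        else:
            cpm = means[pop].to_numpy()
        mu[:, j] = cpm / 1e6 * libsizes[j]

    # mixed-lineage cells: host cells whose chosen donor markers take donor means
    mixed_cells: list[str] = []
    swapped: dict[str, list[str]] = {}
    if design.mixed_plan is not None:
        mp = design.mixed_plan
        host_idx = [j for j, p in enumerate(pop_of_sample) if p == mp.host_group]
        n_mixed = int(round(mp.fraction * len(host_idx)))
        if mp.fraction > 0 and n_mixed == 0:
            import warnings
            warnings.warn("mixed fraction too small for host population; zero mixed cells")
        chosen = sorted(rng_mixed.choice(host_idx, size=n_mixed, replace=False).tolist())
        donor_markers = specific[mp.donor_group]
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for j in chosen:
            sid = sample_ids[j]
            genes = sorted(rng_mixed.choice(donor_markers,
                                            size=min(mp.n_swapped_genes, len(donor_markers)),
                                            replace=False).tolist())
            mixed_cells.append(sid)
            swapped[sid] = genes
            rowix = [gene_pos[g] for g in genes]
            mu[rowix, j] = means.loc[genes, mp.donor_group].to_numpy() / 1e6 * libsizes[j]

    counts = _nb_draw(rng_counts, mu, phi)

    if design.dropout is not None:
        from scipy.special import expit
        log2cpm_mean = np.log2(np.maximum(mu / libsizes[None, :] * 1e6, 1e-8))
        p_drop = expit(-design.dropout.slope * (log2cpm_mean - design.dropout.midpoint_log2cpm))
        counts = np.where(rng_drop.uniform(size=counts.shape) < p_drop, 0, counts)

    meta = pd.DataFrame({"group": pop_of_sample, "platform": platform}, index=sample_ids)
    cm = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        gene_symbols=list(gene_ids),
        gene_lengths_bp=np.full(n_genes_total, design.gene_length_bp),
        sample_meta=meta,
    )
    truth = Truth(
        cell_labels={s: p for s, p in zip(sample_ids, pop_of_sample)},
        specific_genes=specific,
        mixed_cells=mixed_cells,
        swapped_genes_per_cell=swapped,
        intermediate_alpha=alpha_map,
        gene_mean_cpm=means,
    )
    return cm, truth


def simulate_bulk(design: SimulationDesign) -> tuple[CountMatrix, Truth]:
    """Bulk replicate counts: NB around libsize-scaled group means."""
    for g in design.groups:
        if g.n_samples < 2:
            raise ValueError(f"group {g.name!r} needs >=2 replicates for bulk simulation")
    if design.intermediate_plan is not None or design.mixed_plan is not None:
        raise ValueError("intermediate/mixed plans are single-cell features")
    return _simulate(design, platform="bulk")


def simulate_cells(design: SimulationDesign) -> tuple[CountMatrix, Truth]:
    """Single-cell counts with optional intermediate and mixed populations."""
    return _simulate(design, platform="C1")


# ---------------------------------------------------------------------------
# canned study designs (the default conditions exercised by the pipeline)
# ---------------------------------------------------------------------------

def bulk_three_type_design(seed: int = 1, n_reps: int = 5,
                           n_specific: int = 100, log2fc: float = 3.0) -> SimulationDesign:
    """Bulk basal/LP/ML replicates with planted type-specific genes (FC 8)."""
    return SimulationDesign(
        n_genes=2000,
        groups=[GroupSpec("basal", n_reps), GroupSpec("LP", n_reps), GroupSpec("ML", n_reps)],
        signature_plan={
            "basal": SignaturePlan(n_specific, log2fc),
            "LP": SignaturePlan(n_specific, log2fc),
            "ML": SignaturePlan(n_specific, log2fc),
        },
        dispersion_median=0.05,
        dispersion_sigma=0.3,
        libsize_target=2e7,
        seed=seed,
    )


def cells_three_population_design(seed: int = 1, n_cells: int = 200,
                                  n_specific: int = 100, log2fc: float = 3.0) -> SimulationDesign:
    """Deep C1-like basal/LP/ML cells, no dropout."""
    return SimulationDesign(
        n_genes=2000,
        groups=[GroupSpec("basal", n_cells), GroupSpec("LP", n_cells), GroupSpec("ML", n_cells)],
        signature_plan={
            "basal": SignaturePlan(n_specific, log2fc),
            "LP": SignaturePlan(n_specific, log2fc),
            "ML": SignaturePlan(n_specific, log2fc),
        },
        seed=seed,
    )


def cells_luminal_design(seed: int = 1, n_cells: int = 150, n_intermediate: int = 100,
                         alpha: float | str = 0.5) -> SimulationDesign:
    """Basal/LP/ML plus a Lum Int population interpolating LP and ML."""
    d = cells_three_population_design(seed=seed, n_cells=n_cells)
    d.intermediate_plan = IntermediatePlan("LumInt", "LP", "ML", n_intermediate, alpha)
    return d


def cells_basal_compartment_design(seed: int = 1, n_cells: int = 200,
                                   fraction: float = 0.05,
                                   n_swapped: int = 12) -> SimulationDesign:
    """Sorted basal cells harboring a rare mixed-lineage subset.

    A zero-cell luminal group supplies the donor marker means, matching the
    study design of profiling a purified basal compartment against known
    luminal signature genes.  Libraries are deeper than the mixed-stage
    designs (median 3M read pairs): resolving co-expression of individual
    foreign marker genes at an absolute detection level needs enough depth
    that baseline leakage counts sit well below the threshold.
    """
    return SimulationDesign(
        n_genes=2000,
        groups=[GroupSpec("basal", n_cells), GroupSpec("luminal", 0)],
        libsize_target=3e6,
        signature_plan={
            "basal": SignaturePlan(100, 3.0),
            "luminal": SignaturePlan(100, 3.0),
        },
        mixed_plan=MixedPlan("basal", "luminal", fraction, n_swapped),
        seed=seed,
    )
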