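"""End-to-end workflows wiring the modules together.

Three workflows mirror the study's analyses, run on the synthetic
designs with planted truth:

* ``stages``  -- developmental-stage comparison: QC, leading-logFC MDS,
  one-way DE across three stages, top-500 gene heatmap clustering, and
  per-gene stage composition.
* ``luminal`` -- ternary lineage scoring of basal/LP/ML(+Lum Int) cells
  against bulk-derived signatures, monotone-trend and
  elevated-intermediate statistics, and MDS.
* ``basal``   -- sorted-basal mixed-lineage detection against top-200
  lineage panels.
* ``network`` -- DE-overlaid interaction subnetwork on synthetic ortholog
  and edge tables.

Each workflow writes deterministic TSV outputs plus the resolved
configuration into its output directory and returns the key objects for
programmatic use.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import de_nb, lineage, netview, normalize, qc, structure, synthetic, trend
from .iofmt import dump_config, load_config, write_table


def _outpath(outdir: str, name: str) -> str:
    os.makedirs(outdir, exist_ok=True)
    return os.path.join(outdir, name)


def _derive_default_signatures(seed: int, cfg: dict) -> de_nb.SignatureSet:
    """Basal/LP/ML signatures from the default synthetic bulk experiment."""
    bulk, _ = synthetic.simulate_bulk(synthetic.bulk_three_type_design(seed=seed))
    de_cfg = cfg["de"]
    tau_map = {
        frozenset(("basal", "LP")): de_cfg["tau_basal_vs_luminal"],
        frozenset(("basal", "ML")): de_cfg["tau_basal_vs_luminal"],
        frozenset(("LP", "ML")): de_cfg["tau_lp_vs_ml"],
    }
    return de_nb.derive_signatures(bulk, tau_map=tau_map, fdr_cut=de_cfg["fdr_cut"])


def run_luminal_workflow(cfg: dict | None = None, outdir: str = "results/luminal",
                         seed: int | None = None) -> dict:
    cfg = cfg or load_config()
    seed = cfg["seed"] if seed is None else seed
    qc_cfg, li_cfg = cfg["qc"], cfg["lineage"]

    sigs = _derive_default_signatures(seed, cfg)
    cells, truth = synthetic.simulate_cells(synthetic.cells_luminal_design(seed=seed))

    th = qc.QCThresholds(qc_cfg["min_read_pairs"], qc_cfg["min_detected_genes"],
                         qc_cfg["relaxed_min_read_pairs"], qc_cfg["relaxed_min_detected_genes"],
                         qc_cfg["min_cpm"], qc_cfg["min_cells_at_cpm"])
    filtered, report = qc.run_qc(cells, th)

    log2cpm = normalize.to_log2cpm(filtered, cfg["normalize"]["log2cpm_prior"])
    sig_genes = [g for name in sigs.names() for g in sigs.genes(name)
                 if g in set(filtered.gene_ids)]
    qn = normalize.quantile_normalize(log2cpm.subset_genes(sig_genes))

    scores = lineage.ternary_cell_scores(qn, sigs, floor=li_cfg["ternary_floor"],
                                         mode=li_cfg["score_mode"])
    labels = lineage.classify_cells(scores, intermediate_band=li_cfg["intermediate_band"])
    tern = lineage.ternary_table(scores, labels)
    tern["true_label"] = [truth.cell_labels[s] for s in tern["sample_id"]]
    write_table(tern, _outpath(outdir, "ternary_cells.tsv"))

    groups = filtered.groups()
    mono = trend.monotone_fraction(filtered, groups, fdr_cut=cfg["trend"]["fdr_cut"],
                                   eps=cfg["trend"]["eps"],
                                   mean_scale=cfg["trend"]["mean_scale"])
    write_table(mono.per_gene, _outpath(outdir, "lumint_trend.tsv"))
    elev = trend.elevated_intermediate_genes(
        filtered.subset_samples(np.isin(groups, ["LP", "LumInt", "ML"])),
        ratio=cfg["trend"]["elevated_ratio"], mean_scale=cfg["trend"]["mean_scale"],
        restrict_to=mono.per_gene.loc[mono.per_gene["is_de"], "gene_id"].tolist())
    write_table(elev.genes, _outpath(outdir, "lumint_elevated_genes.tsv"))

    dist = structure.leading_logfc_distances(log2cpm, k_top=cfg["structure"]["k_top"])
    coords = structure.classical_mds(dist, dims=cfg["structure"]["mds_dims"])
    mds_tab = pd.DataFrame(coords, columns=[f"dim{k+1}" for k in range(coords.shape[1])])
    mds_tab.insert(0, "sample_id", dist.ids)
    write_table(mds_tab, _outpath(outdir, "mds_coordinates.tsv"))

    write_table(qc.qc_report_table(report), _outpath(outdir, "qc_report.tsv"))
    dump_config(cfg, _outpath(outdir, "resolved_config.yaml"))
    return {"signatures": sigs, "cells": filtered, "truth": truth, "ternary": tern,
            "labels": labels, "monotone": mono, "elevated": elev, "mds": mds_tab}


def run_stages_workflow(cfg: dict | None = None, outdir: str = "results/stages",
                        seed: int | None = None) -> dict:
    cfg = cfg or load_config()
    seed = cfg["seed"] if seed is None else seed

    design = synthetic.cells_three_population_design(seed=seed, n_cells=100)
    for g, stage in zip(design.groups, ("wk2", "wk5", "wk10")):
        g.name = stage
    design.signature_plan = {stage: plan for stage, plan in
                             zip(("wk2", "wk5", "wk10"), design.signature_plan.values())}
    cells, truth = synthetic.simulate_cells(design)
    filtered, report = qc.run_qc(cells)
    groups = filtered.groups()

    log2cpm = normalize.to_log2cpm(filtered, cfg["normalize"]["log2cpm_prior"])
    dist = structure.leading_logfc_distances(log2cpm, k_top=cfg["structure"]["k_top"])
    coords = structure.classical_mds(dist, dims=cfg["structure"]["mds_dims"])
    mds_tab = pd.DataFrame(coords, columns=[f"dim{k+1}" for k in range(coords.shape[1])])
    mds_tab.insert(0, "sample_id", dist.ids)
    mds_tab["stage"] = [truth.cell_labels[s] for s in dist.ids]
    write_table(mds_tab, _outpath(outdir, "mds_coordinates.tsv"))

    de = de_nb.lrt_de(filtered, groups)
    de = de.sort_values(["fdr", "log2fc", "gene_id"],
                        ascending=[True, False, True]).reset_index(drop=True)
    write_table(de, _outpath(outdir, "stage_de.tsv"))
    top500 = de.head(500)["gene_id"].tolist()

    log2rpkm = normalize.to_log2rpkm(filtered, cfg["normalize"]["log2rpkm_prior"])
    standardized = normalize.standardize_genes(log2rpkm.subset_genes(top500))
    gene_tree = structure.hcluster(standardized, axis="genes",
                                   linkage=cfg["structure"]["linkage"])
    cell_tree = structure.hcluster(standardized, axis="cells",
                                   linkage=cfg["structure"]["linkage"])
    write_table(pd.DataFrame({"gene_id": [gene_tree.ids[i] for i in gene_tree.leaf_order]}),
                _outpath(outdir, "heatmap_gene_order.tsv"))
    write_table(pd.DataFrame({"sample_id": [cell_tree.ids[i] for i in cell_tree.leaf_order]}),
                _outpath(outdir, "heatmap_cell_order.tsv"))

    comp = lineage.ternary_gene_composition(normalize.to_cpm(filtered), groups)
    write_table(comp, _outpath(outdir, "gene_stage_composition.tsv"))
    write_table(qc.qc_report_table(report), _outpath(outdir, "qc_report.tsv"))
    dump_config(cfg, _outpath(outdir, "resolved_config.yaml"))
    return {"cells": filtered, "truth": truth, "de": de, "mds": mds_tab,
            "gene_tree": gene_tree, "cell_tree": cell_tree, "composition": comp}


def run_basal_workflow(cfg: dict | None = None, outdir: str = "results/basal",
                       seed: int | None = None) -> dict:
    cfg = cfg or load_config()
    seed = cfg["seed"] if seed is None else seed
    li_cfg = cfg["lineage"]

    # top-200 basal / luminal panels from a two-type bulk comparison; group
    # names match the sorted-basal design so marker gene ids line up
    bulk_design = synthetic.bulk_three_type_design(seed=seed)
    bulk_design.groups = [g for g in bulk_design.groups if g.name == "basal"]
    bulk_design.groups.append(synthetic.GroupSpec("luminal", 5))
    bulk_design.signature_plan = {"basal": bulk_design.signature_plan["basal"],
                                  "luminal": bulk_design.signature_plan["LP"]}
    bulk, _ = synthetic.simulate_bulk(bulk_design)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")   # planted panels are smaller than 200
        panels = de_nb.top_lineage_panels(bulk, tau=cfg["de"]["tau_lineage_panels"],
                                          n_top=cfg["de"]["n_top_panel"])

    cells, truth = synthetic.simulate_cells(
        synthetic.cells_basal_compartment_design(seed=seed))
    filtered, report = qc.run_qc(cells, relaxed=True)
    log2rpkm = normalize.to_log2rpkm(filtered, cfg["normalize"]["log2rpkm_prior"])

    sig_genes = [g for name in panels.names() for g in panels.genes(name)
                 if g in set(filtered.gene_ids)]
    calls = lineage.detect_mixed_lineage(
        log2rpkm.subset_genes(sig_genes), "basal", panels,
        min_foreign_genes=li_cfg["min_foreign_genes"],
        detect_level=float(np.log2(li_cfg["detect_rpkm"])),
        host_dominance=li_cfg["host_dominance"])
    tab = lineage.mixed_table(calls)
    tab["true_mixed"] = tab["sample_id"].isin(set(truth.mixed_cells))
    write_table(tab, _outpath(outdir, "mixed_lineage_calls.tsv"))
    write_table(qc.qc_report_table(report), _outpath(outdir, "qc_report.tsv"))
    dump_config(cfg, _outpath(outdir, "resolved_config.yaml"))
    return {"panels": panels, "cells": filtered, "truth": truth,
            "calls": calls, "table": tab}


def synthetic_network_tables(de: pd.DataFrame, seed: int, fdr_cut: float = 0.001,
                             edge_prob: float = 0.02):
    """Synthetic ortholog/edge/function tables over the DE gene space.

    Stand-in for curated ortholog, interaction and GO resources: every
    mouse gene maps to one human id (a deterministic rename, with a small
    ambiguous minority mapping to two), edges are Bernoulli among the DE
    orthologs, and ST/TF classes are assigned at random.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7919)))
    genes = de["gene_id"].tolist()
    orth = {}
    for i, g in enumerate(genes):
        orth[g] = [f"H_{g}"] if i % 97 else [f"H_{g}", f"H_{g}_B"]
    human = sorted({h for hs in orth.values() for h in hs})
    de_human = sorted({h for g in de.loc[de["fdr"] < fdr_cut, "gene_id"]
                       for h in orth[g]})
    edges = []
    for i in range(len(de_human)):
        for j in range(i + 1, len(de_human)):
            if rng.uniform() < edge_prob:
                edges.append((de_human[i], de_human[j]))
    func = {}
    for h in human:
        u = rng.uniform()
        if u < 0.2:
            func[h] = {"ST"}
        elif u < 0.35:
            func[h] = {"TF"}
        elif u < 0.4:
            func[h] = {"ST", "TF"}
    return edges, orth, func


def run_network_workflow(cfg: dict | None = None, outdir: str = "results/network",
                         seed: int | None = None,
                         network_tables=None) -> dict:
    cfg = cfg or load_config()
    seed = cfg["seed"] if seed is None else seed
    fdr_cut = cfg["network"]["fdr_cut"]

    bulk, _ = synthetic.simulate_bulk(synthetic.bulk_three_type_design(seed=seed))
    groups = bulk.groups()
    keep = np.isin(groups, ["basal", "LP"])
    de = de_nb.lrt_de(bulk.subset_samples(keep), groups[keep])

    if network_tables is None:
        network_tables = synthetic_network_tables(de, seed, fdr_cut)
    edges, orth, func = network_tables

    mapped = netview.map_orthologs(de, orth, fdr_cut=fdr_cut)
    net = netview.build_de_subnetwork(mapped, edges)
    net = netview.classify_node_function(net, func)
    view = netview.st_tf_view(net)
    netview.export_network(net, _outpath(outdir, "de_network"))
    netview.export_network(view, _outpath(outdir, "de_network_st_tf"))
    dump_config(cfg, _outpath(outdir, "resolved_config.yaml"))
    return {"de": de, "mapped": mapped, "network": net, "st_tf": view}


WORKFLOWS = {
    "stages": run_stages_workflow,
    "luminal": run_luminal_workflow,
    "basal": run_basal_workflow,
    "network": run_network_workflow,
}


def run_pipeline(workflow: str, cfg: dict | None = None,
                 outdir: str | None = None, seed: int | None = None) -> dict:
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {sorted(WORKFLOWS)}")
    kwargs = {"cfg": cfg, "seed": seed}
    if outdir is not None:
        kwargs["outdir"] = outdir
    return WORKFLOWS[workflow](**kwargs)
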