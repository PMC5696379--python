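# mamlin — lineage heterogeneity in mammary epithelial scRNA-seq

`mamlin` is a tested re-implementation of a single-cell RNA-seq analysis
pipeline for dissecting epithelial lineage heterogeneity in the post-natal
mouse mammary gland: how basal, luminal progenitor (LP) and mature luminal
(ML) cells diversify through puberty, whether a luminal-intermediate
("Lum Int") cluster behaves like a transit population between LP and ML,
and whether the sorted basal compartment harbors rare mixed-lineage
(lineage-primed) cells co-expressing luminal genes.

It is written for computational biologists who want the statistical
machinery of that style of analysis as a reusable, seedable library, and it
ships a synthetic-data generator with planted ground truth so every stage
can be exercised and validated without any external download.

## What it computes

* **QC** (`mamlin.qc`) — removal of mitochondrial/ribosomal/unannotated
  genes; cell filters at ≥100,000 assigned read pairs and ≥1,500 detected
  genes (relaxed: 50,000 / 1,000); gene filter at ≥1 CPM in ≥3 cells; the
  multiplex-qPCR housekeeping filter (ACTB/GAPDH, Ct ≥ 40 = undetected).
* **Normalization** (`mamlin.normalize`) — CPM, log2-CPM, log2-RPKM with a
  library-scaled prior count of 5, quantile normalization, per-gene
  standardization.
* **NB differential expression** (`mamlin.de_nb`) — per-gene negative
  binomial GLMs with log link and library-size offsets. For gene *g* in
  group *j*, counts are NB with mean μ = exp(β_gj)·L_i and variance
  μ + φ_g μ². Dispersions φ are estimated by maximizing the Cox–Reid
  adjusted profile likelihood (common via grid + golden-section search;
  tagwise by weighted-likelihood shrinkage toward the common curve).
  Likelihood-ratio tests across 2+ groups, and a fold-change-threshold
  (TREAT-style) test of H₀: |log2FC| ≤ log2(τ) built from signed-root LR
  statistics at the shifted-null boundaries. BH FDR throughout.
* **Signatures** — cell-type-specific genes: up in one type versus *both*
  other types under threshold tests (τ = 2 for basal-vs-luminal contrasts,
  τ = 1.3 for LP vs ML; FDR < 0.05), and top-200 basal/luminal panels at
  τ = 3. Plus a generic hypergeometric over-representation test.
* **Lineage scoring** (`mamlin.lineage`) — per-cell ternary composition:
  for each signature set S, the raw score is the mean positive excess of
  quantile-normalized log2-CPM above a floor, normalized across the three
  sets to proportions summing to 1; argmax classification with a
  deterministic tie rule; mixed-lineage detection (≥3 foreign-signature
  genes above 5 RPKM in a host-dominant cell); marker flags (e.g.
  RPKM > 40).
* **Structure** (`mamlin.structure`) — leading log-fold-change distances
  (RMS of the largest 500 per-gene log2 differences, recomputed per cell
  pair), classical MDS, Euclidean hierarchical clustering of standardized
  expression.
* **Trend** (`mamlin.trend`) — the monotone-trend statistic: among genes DE
  across LP/Lum Int/ML (FDR < 0.01), the fraction whose Lum Int mean lies
  between the LP and ML means; genes ≥20% higher in Lum Int than both
  parents; cell-cycle cluster flagging.
* **Networks** (`mamlin.netview`) — DE genes (FDR < 0.001) mapped to human
  orthologs, induced subgraph of a curated interaction list (direct
  interactions only), signal-transduction / transcription-factor node
  classes, TSV + SIF export.

## Worked example

The numbered scripts under `analysis/` run the three study workflows on
the default synthetic designs (the `mamlin run --workflow ...` CLI does the
same). For example:

```bash
python analysis/03_luminal_ternary.py --seed 1 --out results/luminal
```

prints

```
derived signature sizes: {'basal': 100, 'LP': 100, 'ML': 100}
ternary classification accuracy on basal/LP/ML cells: 1.000
200 of 201 DE genes (99.5%) change monotonically from LP through Lum Int to ML
0 DE genes are >=20% higher in Lum Int than both LP and ML
tables written to results/luminal/
```

The generator planted 100 marker genes per cell type in the bulk data
(8-fold up in their own lineage), and the threshold tests recover exactly
those 300 genes. The Lum Int cells were simulated with gene means halfway
between LP and ML, so nearly all genes DE across the three luminal states
change monotonically through the intermediate — the signature of a transit
population rather than a distinct cell type (no gene sits ≥20% above both
parents here because no such gene was planted). Similarly,

```bash
python analysis/04_basal_mixed_lineage.py --seed 1 --out results/basal
```

prints

```
10 of 200 basal cells flagged mixed-lineage (10/10 planted mixed cells recovered)
```

recovering the planted 5% mixed-lineage subset with no false positives.

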