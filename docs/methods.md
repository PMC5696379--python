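# Methods

This note documents the statistical models, the synthetic study designs,
the numerical choices, and the limits of what the test suite demonstrates.

## Count model and differential expression

Counts for gene *g* in sample *i* are modeled as negative binomial with
mean μ_gi and variance μ_gi + φ_g μ_gi², log link, and offset log L_i
(library size = column sum of the filtered count matrix). All designs in
this pipeline are one-way group layouts, so the GLM coefficients separate
by group: each group coefficient is fit by one-dimensional Fisher scoring
(score Σ(y−μ)/(1+φμ), information Σ μ/(1+φμ)), which is the IRLS fit of
the group-indicator design expressed per group. Convergence is |step| <
1e-10 with at most 50 iterations; a fitted rate floor of 1e-12 per read
handles all-zero groups. The two-group fit was checked against an
independent reference GLM implementation on a frozen fixture (agreement to
~1e-8 in the LR statistic; `tests/test_de_nb.py`).

**Dispersions.** The common dispersion maximizes the summed Cox–Reid
adjusted profile likelihood APL_g(φ) = ll_g(φ; μ̂) − ½ Σ_groups log Σ
μ/(1+φμ), evaluated on a 21-point log grid over [0.001, 10] and refined by
golden-section search. Tagwise dispersions maximize APL_g + w·mean(APL)
over the grid plus the refined common point, with w = 10 prior genes by
default; w → ∞ reproduces the common value exactly. Tagwise resolution is
therefore the grid resolution (~1.55× steps), which is sufficient for the
shrinkage role it plays here.

**LRT.** 2·(ll_full − ll_null) against χ² with (n_groups − 1) df. On null
data with known φ = 0.1, n = 10 per group, the empirical type-I error at
α = 0.05 is ≈ 0.05 (acceptance suite).

**Threshold (TREAT-style) test.** H₀: |β| ≤ t with t = ln τ. Constrained
fits fix the group effect at ±t by folding exp(±t) into the exposure of
the second group. With z_near = sign(|β̂|−t)·√LR_near and z_far = √LR_far,
p = min(1, Φ̄(z_near) + Φ̄(z_far)). At τ = 1 this is algebraically the
two-sided LRT p-value; at |β| = t it is conservative (boundary rejection
≈ 0.05 at α = 0.05 in the acceptance suite, bounded at ≤ 0.07). The
construction is validated by these calibration properties rather than by
bit-equivalence to any particular package.

**Caveat.** Library-size offsets are raw column sums; no TMM-style
composition correction is applied. When a large fraction of counts moves
in one direction between groups, estimated fold changes absorb the
composition shift (visible in the calibration fixtures, which equalize
expected library sizes for exactly this reason).

## Signature derivation and ranking

A gene is cell-type specific when it passes the threshold test with
positive fold change toward that type against *both* other types, each
contrast at its own τ (defaults: 2 for basal vs LP and basal vs ML, 1.3
for LP vs ML) and FDR < 0.05 per contrast. The reported log2FC is the
smaller of the two contrasts and the FDR the larger (the binding
constraint). Top-N panels rank significant genes by ascending FDR, ties
by descending |log2FC|, then lexical gene id — "top DE" needs a total
order and this one is deterministic.

## Ternary lineage scoring

The per-cell raw score of signature set S is mean_{g∈S} max(0, x_gc −
floor) on quantile-normalized log2-CPM, with the floor defaulting to the
matrix-wide median of the values supplied; proportions are raw scores
normalized across the three sets. The per-set mean (not sum) removes
set-size bias; a count-of-detected-genes mode is provided as the obvious
alternative scoring. Cells with all signature values at or below the
floor are degenerate: proportions (⅓,⅓,⅓), label "unclassified". The
workflows score on the expression submatrix of the signature genes
(quantile-normalized over exactly the cell set being analyzed), so the
floor is the median over signature genes — the natural reference when the
question is which of three signatures dominates. Ties in argmax resolve
to the first class in declared order (basal < LP < ML). The optional
luminal-intermediate band labels a cell "Lum Int" when its LP and ML
proportions differ by less than b and both exceed the basal proportion;
it is off by default.

## Mixed-lineage detection

Among sorted host-lineage (basal) cells, a cell is flagged mixed when (i)
at least `min_foreign_genes` = 3 foreign-signature genes exceed the
detection level (5 RPKM, compared on the log2 scale) and (ii) the host raw
signature score exceeds the foreign score times a host-dominance factor
(default 1.0) — the cell co-expresses luminal genes while remaining
basal-like. The gene lists per cell are emitted for audit. Because the
detection level is absolute, its separation from baseline noise depends on
sequencing depth; see the design note below.

## Distances, MDS, clustering

The leading log-fold-change distance between two cells is the RMS of the
k = 500 largest |Δ log2-CPM| values, with the top-k set recomputed for
every pair (O(n²·g), computed in row blocks). Classical MDS
double-centers −½D², takes the top eigenvectors scaled by √λ (negative
eigenvalues clamped), and fixes each axis's sign so its largest-magnitude
loading is positive. Hierarchical clustering is Euclidean on per-gene
standardized values (SD with n−1; constant genes flagged and zeroed),
complete linkage by default, delegated to scipy's agglomerative
implementation with its deterministic tie behavior.

## Trend statistics

Genes DE across LP / Lum Int / ML (one-way LRT, FDR < 0.01) are called
monotone when the Lum Int mean lies within [min(LP,ML) − ε, max(LP,ML) + ε]
with ε = 0 by default; means are linear-scale CPM group means (a log-scale
mode exists) because the companion ≥20%-higher rule is multiplicative.
The elevated-intermediate rule lists genes with mean_Int ≥ 1.2·mean_LP and
≥ 1.2·mean_ML, restricted by default to the same DE universe. Under a
global null, BH at FDR < 0.01 returns essentially no discoveries, so the
exchangeability calibration (expected monotone fraction ⅓) is run with
the conditioning set widened to all genes, where the ⅓ argument holds
with usable precision.

## Synthetic study designs

The generator emulates the statistical structure the analysis assumes:

* **Background genes** (2,000 by default): mean CPM log-uniform on
  [1, 500], shared across populations.
* **Marker (cell-type-specific) genes** (100 per type): off-lineage
  baseline log-uniform on [0.25, 1] CPM, on-lineage ×2^3 (8-fold). Real
  lineage markers are essentially silent off-lineage; the low baseline is
  also what makes an absolute detection threshold meaningful.
* **Filler genes** (10): constant high-abundance "housekeeping" block
  absorbing the remaining library mass so drawn CPM values are true CPM.
* **Noise**: gene-wise NB dispersion lognormal (median 0.1 for cells, 0.05
  for bulk; σ = 0.3); library sizes lognormal (σ = 0.3) around 2×10⁶ read
  pairs for cells (deep C1-like), 2×10⁷ for bulk. Dropout (logistic in
  log2-CPM of the mean) is available but off by default; the default
  designs emulate deep full-length single-cell libraries, not shallow
  UMI data.
* **Lum Int**: gene means α·LP + (1−α)·ML on the linear scale, α = 0.5 by
  default (or per-cell uniform).
* **Mixed-lineage cells**: round(5%) of basal cells have 12 randomly
  chosen luminal-marker genes take luminal means. The sorted-basal design
  uses deeper libraries (median 3×10⁶): a power analysis of the detection
  rule shows that at 2×10⁶ the Poisson spread of off-lineage counts
  crosses the 5-RPKM level in ~1% of gene-cells — enough to flag ~15% of
  pure cells at min 3 foreign genes — while at 3×10⁶ leakage is ~10⁻⁴ per
  gene and per-cell sensitivity ≈ 0.99.

All randomness flows from one integer seed through per-stage child
streams, so adding a stage never perturbs earlier draws and outputs are
bit-reproducible.

What passing tests do **not** show about real data: no ambient RNA,
doublets, batch effects, UMI structure, or composition shifts are
simulated; markers here are cleanly bimodal, whereas real signature genes
grade continuously; and the planted effect sizes are favorable. The suite
demonstrates correctness and calibration of the machinery, not
performance guarantees on arbitrary datasets.

## Other numerical choices

* log2-CPM prior 0.5; log2-RPKM prior 5, scaled per column by
  libsize/mean(libsize) with the library inflated by twice the scaled
  prior (a plain unscaled mode is a config flag).
* Quantile normalization maps each column's sorted values to the
  across-column mean of sorted values; ties receive the mean of the
  reference values over their rank span.
* QC boundaries are literal: "fewer than X" drops strictly below X;
  "detected" means count ≥ 1; CPM rule is ≥ 1 CPM in ≥ 3 cells computed
  on post-cell-filter library sizes; filter order is gene-class strip →
  cell filter → gene filter. Mito/ribo recognition is by mouse symbol
  prefix (mt-; Rps/Rpl/Mrps/Mrpl), case-sensitive and configurable.
* Marker-positivity (e.g. RPKM > 40) compares on the log scale for
  log-stored values so a stored value exactly at the threshold is not
  flagged through de-log round-off.
* Hypergeometric enrichment is upper-tail with BH across sets; sets are
  intersected with the universe and skipped (with a warning) when
  disjoint from it.
* Network direction comes from the log2FC sign; human ids fed by mouse
  genes with conflicting signs are kept but marked "ambiguous". Induced
  subgraphs retain isolated mapped nodes.
* Output tables print floats at 6 significant digits for diffability;
  fixed seed ⇒ byte-identical reruns.

## Problem sizes

The default workflow designs (450–550 cells, ~2,300 genes; bulk 15
samples) were chosen so a full workflow completes in well under a minute
on one CPU while keeping every statistical property measurable; the
acceptance script runs all workflows plus calibration (2,000-gene null
and boundary panels) in under a minute.

## Known limitations

* No TMM/size-factor normalization or batch correction (out of scope).
* Tagwise dispersion is grid-resolution; fine for shrinkage, not for
  reporting per-gene φ.
* The mixed-lineage rule's absolute detection level ties its operating
  point to sequencing depth; on other depths the `detect_rpkm`,
  `min_foreign_genes` and dominance parameters should be re-examined.
* `estimate_dispersions` and the GLM fits assume a one-way layout;
  arbitrary design matrices are not supported.
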