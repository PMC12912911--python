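# uroquant

Quantitative analysis tools for a recurring problem in urothelial
biology: relating connexin 32 (Cx32/*GJB1*) expression, its subcellular
localisation, and its downstream transcriptional programme to the
behaviour of differentiated urothelium and luminal muscle-invasive
bladder cancer (MIBC). The package re-implements, as a tested and
reusable library, the bespoke computational procedures such a study
needs:

* **IHC localisation scoring** (`uroquant.ihc`) — per-cell
  quantification of DAB/haematoxylin immunohistochemistry: nucleus
  segmentation from the counterstain, exclusion of infiltrating
  lymphocytes by a minimum nuclear area (30 µm²), chromogen intensity in
  an annular "ring mask" (5.71 µm external radius) as a cytoplasmic
  surrogate, and membrane staining measured as the angular extent θ (in
  degrees about the nuclear centroid) of thin, skeleton-filtered
  suprathreshold structures. Calls are three-way per core —
  *membrane* (θ ≥ 7.5°), else *cytoplasmic* (ring ≥ 10 AU), else
  *absent* — and aggregate to patients by membrane > cytoplasmic >
  absent precedence.
* **Regulon refinement and survival stratification**
  (`uroquant.regulon`) — takes a gene set induced in vitro into a tumour
  cohort: TPM conversion (TPMg = 10⁶·(cg/ℓg)/Σ(c/ℓ)), log₂(TPM+1),
  nearest-centroid reassignment of stroma-rich consensus-class samples,
  restriction to luminal classes (LumP/LumNS/LumU), a pairwise Spearman
  ρ matrix, and iterative pruning of genes whose summary (median)
  co-regulation fails ρ > 0.5 until a mutually co-regulated "regulon"
  remains. Samples are then split by k-means (k = 2, Euclidean) into
  regulon-high/low groups and compared by Kaplan–Meier curves, log-rank
  (Mantel–Cox) and Gehan–Breslow–Wilcoxon tests, and the
  Mantel–Haenszel hazard ratio HR = (O₁/E₁)/(O₂/E₂).
* **Differential-expression ranking** (`uroquant.deg`) — donor-matched
  mean log₂((TPM+1)ratio) fold changes, selection of regulated genes at
  q ≤ 0.05 and |log₂FC| ≥ 1 (printed-precision boundary semantics, with
  a strict mode), and π-value pre-ranked `.rnk` export where
  π = log₂FC × (−log₁₀ q) and π = 0 genes are dropped as unranked.
* **Functional assays** (`uroquant.assays`) — wound-closure kinetics and
  WC₅₀ (first 50%-closure crossing by linear interpolation, per
  replicate then averaged), scrape-load dye-transfer index
  (mean LY⁺/RhoD⁺ over fields), TEER barrier metrics (tight iff
  > 500 Ω·cm²) and qPCR relative expression by 2^−ΔΔCt.
* **Synthetic data** (`uroquant.simulate`) — seeded, ground-truthed
  generators for every stage: two-channel IHC rasters with elliptical
  nuclei, membrane arcs and sub-30 µm² lymphocyte contaminants;
  expression cohorts with a Gaussian-copula co-regulation block, subtype
  mixtures and exponential survival at a configurable hazard ratio;
  donor-matched DE tables; logistic wound-closure, TEER and Poisson
  dye-count series.

A 54-gene reference table (the differential-expression result for
channel-dead Cx32^T134A^ versus wild-type overexpression in
differentiated urothelial cultures) ships with the package
(`uroquant.datasets.load_induced_gene_table`).

## Worked example

```python
import numpy as np
from uroquant import assays, deg, regulon as reg, simulate as sim

# 1. Select regulated genes from the bundled induced-gene table
up, down = deg.select_deg(deg.load_induced_gene_table())
print(f"{len(up)} genes up-regulated, {len(down)} down-regulated")

# 2. Refine the 50 induced genes to their co-regulated core in a
#    synthetic luminal cohort, then stratify survival
spec = sim.CohortSpec(n_samples=400, true_hr=1.77, seed=1)
cohort, truth = sim.gen_cohort(spec)
log_expr = reg.log2_tpm1(cohort.abundance)
classes = reg.reclassify_stroma_rich(log_expr, cohort.clinical["subtype"],
                                     truth["centroids"])
lum = reg.filter_luminal(cohort, classes)
mat = reg.spearman_matrix(reg.log2_tpm1(lum.abundance),
                          spec.regulon_genes + spec.decoy_genes)
res = reg.refine_regulon(mat, reg.RegulonConfig(), n_samples=len(lum.samples))
print(f"regulon: {len(res.retained_genes)} of {len(res.input_genes)} genes retained")
strat = reg.stratify_cohort(cohort, res.retained_genes, reg.RegulonConfig())
s = strat.stats_dict()
print(f"log-rank chi2 = {s['logrank_chi2']:.2f}, p = {s['logrank_p']:.2e}")
print(f"Mantel-Haenszel HR = {s['hazard_ratio']:.2f} "
      f"(95% CI {s['hr_ci_low']:.2f}-{s['hr_ci_high']:.2f})")

# 3. Wound-closure half time on a noiseless logistic series
tables = sim.gen_assay_series(sim.AssaySpec(wc50_true=7.7))
print(f"WC50 = {assays.wc50(tables['wound']).mean_h:.2f} h")
```

prints

```
50 genes up-regulated, 4 down-regulated
regulon: 25 of 50 genes retained
log-rank chi2 = 6.59, p = 1.02e-02
Mantel-Haenszel HR = 1.36 (95% CI 1.07-1.72)
WC50 = 7.69 h
```

The selection splits the 54-row table into its 50 induced and 4
repressed genes; the refinement recovers exactly the 25-gene planted
co-regulation block and rejects the 25 decoys; the two k-means groups
differ significantly in survival. A single cohort draw gives a noisy
hazard-ratio estimate (here 1.36 for a generating ratio of 1.77; the
k-means split only approximates the latent high/low groups), which is
why summary analyses below median over several cohorts. The WC₅₀ of
7.69 h reflects the 2-hourly sampling of a curve whose true half-closure
time is 7.7 h.

A command-line interface mirrors the library:
`uroquant simulate|ihc|regulon|deg|assay --help`.

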