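# Methods

This note records the measurement models, defaults, and numerical
choices behind `uroquant`, and what the synthetic-data generators do and
do not emulate.

## IHC localisation scoring

**Model.** A tumour core is a two-channel raster: a haematoxylin
counterstain in which nuclei are dark, and a DAB chromogen channel in
which higher pixel value means more signal (intensity convention, not
optical density). The pipeline is nucleus-anchored, mirroring
instruments that never segment whole cells: everything about a cell's
cytoplasm and membrane is inferred from the neighbourhood of its
nucleus.

1. *Segmentation.* Nuclei are thresholded from the counterstain (Otsu),
   holes filled, and touching nuclei split by a distance-transform
   watershed seeded at smoothed distance maxima
   (`watershed_min_distance_px`, default 5 px). Specks below
   `min_detect_area_um2` (4 µm²) are discarded; a blank image yields an
   empty result rather than an error. Optional region-of-interest
   polygons restrict detection to tumour areas.
2. *Lymphocyte exclusion.* Cells with nuclear area < 30 µm² are removed
   (`min_nuclear_area_um2`), the standard size criterion for
   infiltrating T-lymphocytes. The threshold is inclusive on the
   retained side (≥ 30 µm² kept), as are all positivity thresholds
   below; only the negative side is strict.
3. *Ring mask.* Cytoplasmic signal is the mean chromogen value over the
   annulus of pixels outside the nucleus but within `ring_radius_um`
   (5.71 µm) of its boundary, excluding pixels of any other nucleus. An
   empty annulus returns NaN as an undefined-measurement flag.
4. *Membrane angle.* Membrane labelling is detected as thin structures:
   a white top-hat with a radius-1 disk suppresses diffuse (cytoplasmic)
   staining and keeps bands at most a few pixels wide; the result is
   thresholded (`dab_positive_threshold_au`, default Otsu on the
   chromogen channel, always overridable) and despeckled (< 5 px,
   8-connected). Each surviving pixel at radius r from the nuclear
   centroid covers an angular window of half-width atan(0.5/r); the
   union of windows over the cell's nucleus-anchored zone (Voronoi
   partition by nearest nucleus, clipped at the ring radius), with
   sub-pixel gaps ≤ 0.5° bridged, is the staining angle in [0°, 360°].
   Disjoint arcs sum by default; `angle_mode="largest"` reports the
   longest single arc instead. On painted test arcs the measurement is
   accurate to a few degrees (slight overcount from the pixel windows at
   arc endpoints).
5. *Classification.* A core is *membrane* when its mean angle
   ≥ 7.5°, else *cytoplasmic* when its mean ring intensity ≥ 10 AU,
   else *absent*; membrane may co-occur with cytoplasmic staining.
   Patients take the strongest call over their cores
   (membrane > cytoplasmic > absent) — an "any positive core" rule.
   Percentages are reported exact and at integer rounding.

Intensities are handled in arbitrary 0–255 units; no claim of
equivalence to any particular instrument's AU scale is made.

## Regulon refinement and survival

**Pre-processing.** Counts convert to TPM per sample
(rate g = counts g / length g; TPM g = 10⁶·rate g/Σrate, columns sum to
10⁶ exactly), and all correlation/clustering operates on log₂(TPM+1).
Stroma-rich consensus-class samples — a purity label, not a
differentiation state — are reassigned to the best-fit urothelial class
by Pearson correlation against published class centroids on the shared
gene universe (Spearman optional; ties broken by the fixed order
Ba/Sq < LumP < LumNS < LumU < NE-like; a warning fires below 80% gene
overlap). The cohort is then restricted to LumP/LumNS/LumU; samples
reclassified to Ba/Sq or NE-like are excluded with the rest.

**Refinement.** The pairwise Spearman matrix (average-rank ties,
zero-variance genes flagged NaN and dropped with a recorded
disposition) summarises each gene by the median (configurable: mean) of
its off-diagonal correlations with the rest of the set. The default
procedure *iteratively prunes* the weakest gene and re-evaluates until
every survivor's summary exceeds `rho_min` (0.5). Iteration matters:
with a single pass over a half-contaminated input set, a genuinely
co-regulated gene's median correlation is dragged into the null range
by the decoys, and nothing survives a 0.5 cut; pruning lets the
co-regulated core emerge, and guarantees the stated property holds
*within the retained set*. `iterative=False` gives the literal single
pass. A second mode (`mode="significance"`) instead requires a
significant (two-sided P < 0.05, t-approximation; positive) correlation
with more than half of the other genes, again iteratively by default.
The two published descriptions of this step (mean-ρ threshold versus
median-significance) differ; both are implemented and the choice is
part of the configuration.

**Stratification.** K-means (k = 2, Euclidean, 10 restarts, fixed seed)
on the retained genes' log₂(TPM+1) profiles splits samples into groups,
labelled high/low by mean regulon expression. The description
"hierarchical clustering (Euclidean distance and K-means)" is
internally contradictory; k-means is implemented as primary since the
two-group split is its stated purpose. Survival comparison uses the
Kaplan–Meier product-limit estimator, the Mantel–Cox log-rank and
Gehan–Breslow–Wilcoxon (at-risk-weighted) tests — all via lifelines —
and a Mantel–Haenszel hazard ratio computed from our own
observed/expected decomposition, HR = (O₁/E₁)/(O₂/E₂), with a
log-scale CI using se(ln HR) = √(1/E₁ + 1/E₂). Survival times keep the
clinical table's units (months by convention); no conversion is
attempted.

## Differential-expression ranking

Fold changes are donor-matched means of log₂((TPM+1)treated/(TPM+1)control);
the +1 damps low-abundance noise (and introduces a small attenuation
for genes below ~50 TPM — intrinsic to the transform, not corrected).
π = log₂FC × (−log₁₀ q) ranks genes for pre-ranked enrichment; q = 0
must be floored explicitly (`floor_q`, default 10⁻³⁰⁰) since π would be
infinite. π = 0 genes are removed as unranked; ties in the `.rnk`
export break lexicographically so output is reproducible under input
shuffling. Selection semantics follow printed-table conventions:
q and log₂FC are rounded half-even to `boundary_tolerance` (2) decimals
and compared inclusively, so a row printed as q = 0.050, log₂FC = 1.00
counts as "q < 0.05, >twofold"; a strict mode applies literal
inequalities to unrounded values.

## Functional assays

WC₅₀ is the first crossing of 50% closure, linearly interpolated
between bracketing timepoints, computed per replicate and averaged
(curve-level analysis of a mean curve is a caller-side option).
A series already ≥ 50% closed at its first sample reports 0.0 h with a
quality flag rather than extrapolating backwards; series that never
reach 50% are excluded from the mean with a warning. The dye-transfer
index is the mean over fields of LY⁺/RhoD⁺ counts; zero-RhoD fields
are excluded. TEER is *tight* strictly above 500 Ω·cm², and barrier
recovery is the interpolated first return above threshold after the
wound event. qPCR uses the 2^−ΔΔCt model with technical-replicate means
taken first; efficiency-corrected models are out of scope.

## Synthetic data: what it emulates, and what it does not

* *IHC images* place non-overlapping elliptical nuclei (axis ratio
  1–2; tumour areas 45–90 µm², lymphocytes 12–25 µm², so the 30 µm²
  rule separates them exactly) on a bright background. Rasterised
  nuclear masks are trimmed/grown to the requested pixel area exactly.
  Cytoplasmic staining fills an annulus around the nucleus; membrane
  staining is a one-pixel arc of stated angular extent on a slightly
  larger ellipse at 180 AU; positive cells draw cytoplasmic intensities
  from 60–120 AU and negative cells < 10 AU, chosen so that ring-mask
  dilution (the fixed 5.71 µm annulus is larger than the stained band)
  keeps positive cells above the 10 AU call threshold. Gaussian pixel
  noise is optional. The generator does not attempt photorealistic
  histology, RGB stain mixing, or out-of-focus/section artefacts, so
  passing recovery tests demonstrates the measurement geometry and
  thresholds, not robustness to real staining variability.
* *Cohorts* induce a target within-block Spearman ρ through a Gaussian
  copula (Pearson 2·sin(πρs/6) on latent normals, log-normal marginals
  with per-gene location/scale; dependence and marginals therefore
  decouple exactly). Decoy genes are independent; consensus-subtype
  signal lives on a separate marker-gene set with per-class mean
  shifts (stroma-rich samples carry a latent urothelial class driving
  their markers), so subtype structure cannot leak into the
  co-regulation block. Survival is exponential (proportional hazards
  exact) with rate scaled by the hazard ratio for samples whose
  standardized mean regulon expression exceeds the median;
  censoring is administrative at the quantile matching the requested
  fraction, which makes the true HR well-defined for recovery tests.
  Real cohorts add batch structure, purity gradients and non-PH
  hazards, none of which are modelled.
* *Assays* use a logistic closure curve crossing 50% exactly at the
  requested time (rate 0.35 h⁻¹, 2-h sampling over 36 h, six
  replicates), a TEER course starting at the 2,500 Ω·cm² differentiated
  baseline, dropping to 300 Ω·cm² post-wound and recovering
  exponentially (τ = 10 h), and dye counts with RhoD ~ Poisson(25)
  (floored at 1 loaded cell per field) and LY conditionally Poisson
  with mean index × RhoD — conditioning makes the expected per-field
  ratio equal the index exactly.

## Problem sizes and determinism

Every generator and every stochastic operation (k-means restarts,
simulations) is driven by an explicit integer seed and reproduces
bit-identically. The bundled analyses use desk-scale sizes chosen for
tight statistical margins: 200-cell image suites for end-to-end IHC
recovery, cohorts of n = 300–400 with a 25-gene block among 25 decoys
for refinement (the pruning margin between block and decoy summaries is
> 5 null standard errors at n = 300), n = 1,000 for hazard-ratio
recovery, and 500–1,000 replicates for test calibration. The
acceptance script medians its hazard-ratio estimate over ten cohorts
because a single k-means split only approximates the latent groups and
single-cohort estimates scatter (typically ±20%) around the generating
value.

## Known limitations

* The membrane-angle measurement assumes membrane staining is thin
  (≤ ~3 px) relative to cytoplasmic staining; heavily saturated or
  thick membranous bands would be partially suppressed by the top-hat.
* The Voronoi cell-boundary surrogate misattributes signal when nuclei
  are far off-centre in their cells.
* The O/E hazard-ratio estimator is mildly conservative for large
  effects (a known property), visible as ~5–10% attenuation at HR ≈ 2.
* Printed-precision selection depends on the table's display rounding;
  use strict mode when unrounded statistics are available.
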