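# striatlas

Analysis toolkit for multimodal cell-type atlases of the primate striatum.
It implements, as a tested Python library, the bespoke computations that sit
between standard single-cell preprocessing and biological interpretation in
such an atlas:

- **Reference decomposition and labeling** — each spatial cell's targeted-panel
  counts are modeled as a Poisson mixture over snRNA-seq reference profiles;
  cells are classed as singlet / doublet-certain / doublet-uncertain /
  rejected and labeled by the strict *weight > 0.5* rule, in two rounds
  (major classes, then MSN subtypes).
- **Spatial niche assay** — k-means over each cell's 30-nearest-neighbor label
  composition; the niche richest in medium spiny neurons (MSNs) demarcates
  the striatum.
- **Spatial regression discontinuity (RDD)** — is a marker gene's transition
  across a tissue axis discrete or continuous?  A boundary is found by Otsu
  thresholding of the 1-D cell occupancy (raw axis or isomap embedding) and
  `expr ~ β₀ + β₁·1[x > b] + β₂·(x − b)` is fitted; the Wald test on β₁ is
  the discontinuity test.
- **Rostro-caudal gradients** — per-section abundance percentages with SEM,
  fold changes, LOESS curves, and a random-intercept linear mixed model
  (profile-REML) for the slope of abundance on section level.
- **Pseudobulk differential expression** — cell-type × animal aggregates
  (≥ 15 cells), TMM-style factors, log2-CPM, mean-variance precision weights
  and sample quality weights, residual-PCA surrogate variables, one-vs-all
  contrasts with empirical-Bayes moderation
  s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), and a covariate-adaptive FDR in
  which π₀ depends on mean expression.
- **QC** — the strict RNA rule filter (2500 < nFeature < 10000, mito < 5%) and
  two-round ATAC QC: fragment floor 10^3.5 then negative-binomial outlier
  scoring of `nFrags ~ TSSEnrichment + PromoterRatio + DoubletEnrichment`
  with a |Pearson residual| ≤ 2 cutoff.
- **Enrichment post-processing** — BH across the full cell-type × GWAS grid,
  signed −log10 adjusted p scores, "+" calls by double z-scoring (z > 1 both
  within study and within cell-type × trait-category bin), and a per-cell
  disease gene-set score against expression-bin-matched control sets.
- **Synthetic data with complete ground truth** (`striatlas.synth`) — a
  generator emulating a ~366-gene spatial panel over coronal sections:
  marker-block reference profiles, spatial territories from simple geometry,
  NB count noise with per-gene platform factors, logit-scale rostro-caudal
  gradients with animal/species random intercepts, and injected expression
  discontinuities.  Every cell carries its true type, so all downstream
  recovery tests are closed.

## Worked example

`examples/03_boundary_rdd.py` builds the bundled discontinuity demo — a
medial D1-VS-RGS6 band and a lateral D1-VS band with a TAC3-like jump
injected at x = 350 µm — and runs the RDD pipeline:

```
injected: gene gene0010, boundary 350.0 um, jump 3.0 counts
detected boundary: 350.0 um
jump = 0.713 log-units (se 0.079), p = 7.05e-19  [discrete transition]
control gene: jump = -0.055, p = 0.5  [smooth gradient, no jump expected]
```

The boundary is recovered at the injected divide; the jump gene shows a
highly significant discontinuity while a no-jump gradient control does not.
`examples/04_rc_gradients_lmm.py` does the same for abundance gradients:

```
D1-Matrix : beta = -0.22 %/level (se 0.41), p = 0.587; LOESS range 36.1-37.2%
D2-Matrix : beta = +1.93 %/level (se 0.34), p = 9.49e-09; LOESS range 27.8-35.6%
```

The caudally enriched type shows a strongly significant positive slope of
its MSN-group percentage per caudal section step; the flat type does not.

The other examples cover labeling, niche demarcation, pseudobulk DE,
enrichment calls, and QC; each prints the quantities it computes and what
they mean.

The same stages can be driven from the shell:

```bash
striatlas run --seed 7 --outdir demo_out     # full demo pipeline + manifest
striatlas rdd gene0010 "D1-VS,D1-VS-RGS6" --outdir demo_out
```

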