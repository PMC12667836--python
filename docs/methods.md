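# Methods

This note records the models, default parameters, numerical choices and
known limitations of each component, and what the synthetic generator does
and does not emulate.

## Synthetic data (`striatlas.synth`)

**Reference profiles.** A panel of G genes over T cell types; each type owns
a disjoint block of `n_marker_genes` markers (default 3) elevated
`marker_fold`-fold (default 10) over a baseline with mild log-normal
heterogeneity (sd 0.1 on the log scale) so no two types are exactly
proportional.  Rows are normalized to probability vectors.  Defaults
(T = 11, G = 366) match the scale of a targeted spatial brain panel over the
canonical MSN subtypes; the bundled demo uses 6 types × 120 genes.

**Counts.** Per-cell library sizes are log-normal (mean 300 transcripts,
log-sd 0.3).  Counts are gamma–Poisson: variance μ + αμ² with dispersion
α = 0.1 by default (α = 0 is the Poisson limit).  Spatial sections apply
per-gene log-normal platform factors (sd 0.3) to the profiles before
renormalization, emulating reference-vs-spatial platform differences.

**Territories.** Sections place cells by a homogeneous spatial Poisson
process within axis-aligned rectangles, discs, or half-planes (density in
cells/µm²); each territory carries baseline type weights.  Real anatomical
territories are curved and nested; simple geometry suffices to create the
statistical structure the analyses consume (compartment boundaries, gaps,
two-region sections).

**Abundance gradients.** Type abundance follows a logit-linear model in the
rostro-caudal coordinate (mm relative to the anterior commissure, rostral
positive): logit weight = intercept + slope·rc + animal + species random
intercepts (drawn once per animal/species and reused across levels) + a
per-section jitter (tissue heterogeneity beyond counting noise).  Gradients
act on the logit scale so proportions stay in (0, 1); the mixed-model stage
measures them on the percentage scale.

**The demo scenario** (`demo_config`) has a medial band (D1-Matrix,
D2-Matrix, D1-VS-RGS6), a lateral band (D1-Matrix, D2-Matrix, D1-VS), a
40 µm cell-free strip between them, and a separate cortical block of glia.
D2-Matrix rises caudally at −0.03 logit/mm (≈ +1.7 percentage points of the
MSN group per section step at the five standard levels AC+2 … AC−8 — the
scale of the strongest reported caudal gradient), offset by +0.03/mm
rostral-enriched VS types.  D1-Matrix's slope (−0.0025/mm) was solved by
root-finding so that its *expected percentage* of the MSN group is exactly
flat across levels: with a compositional response, a zero logit slope would
still drift because the denominator varies.  Random-intercept sds: animal
0.15, per-section 0.05.  `demo_discontinuity_config` is the two-band
geometry at higher density with a TAC3-like jump (3 counts on an intercept
of 2) injected in the first D1-VS-RGS6 marker at the strip center.

**Injected discontinuities** specify expected *depth-normalized* expression
intercept + slope·(x − b) + jump·1[x > b], clipped at 0, with optional
Gaussian jitter (noise_sd) on the expected value; each cell's count mean is
the field times its relative library size, so the pattern survives per-cell
depth normalization.  Without that scaling, replacing a marker gene's counts
shifts library sizes systematically by side and normalization leaks a
spurious step into *other* genes.

**Determinism.** All draws derive from `SimulationConfig.seed` through
name-hashed substreams (per section, per stage), so adding a section or a
stage does not perturb the other draws; identical configs give bit-identical
tables, and the seed is echoed into every output header.

## Decomposition and labeling (`striatlas.label`)

Counts of cell c are modeled as y_g ~ Poisson(N Σ_t w_t γ_g μ_{t,g}) with N
the cell's total counts, μ the reference profiles, γ the platform factors
and w on the probability simplex.  This is a deliberate simplification of
the full NB platform-effect model used by reference-based deconvolution
tools: at panel-scale counts the Poisson likelihood is adequate and the
machinery stays transparent.

The weights are fitted by a majorize-minimize iteration: the log term is
minorized by the EM surrogate and the surrogate maximized in closed form up
to a one-dimensional dual variable enforcing Σw = 1 against the unequal
platform-scaled profile masses (vectorized bisection; a closed form when
masses are equal).  Ascent of the exact objective holds at every iteration
and is asserted in tests.  Uniform start, tolerance 1e-8 on the largest
weight change, at most 1000 iterations.

**Platform factors** are the ratio of depth-normalized pseudobulk means with
a 0.5-count pseudocount, genes absent in either pseudobulk fixed at 1,
clamped to [0.05, 20]; an optional LOESS smoothing of log-γ against log
reference abundance is off by default (it would shrink genuine single-gene
effects).

**Doublet-mode classification** compares the best single-type log-likelihood
with the best two-type fit (pairs searched among the top-4 singlet types,
batched across cells): singlet if the improvement is < 10 nats
(`ll_margin`), doublet-certain if it is ≥ 20 nats with both weights ≥ 0.25,
doublet-uncertain otherwise.  A cell is **rejected** when its fitted
log-likelihood falls more than `reject_floor` = 3 standard deviations below
the closed-form expectation for data genuinely drawn from the best-fitting
model's own profile (mean Σ μ̂ log μ̂ − Σ μ̂, variance Σ μ̂ (log μ̂)² under
Poisson).  An absolute per-count floor cannot work here: even completely
unrelated uniform counts sit only ~0.7 nats/count below the best profile, so
the margin must be standardized.  The 3-sd default rejects depth-500 uniform
junk (z ≈ −3 to −3.8 measured) while genuine NB cells are never rejected in
simulation up to depth 3000.  Per-cell goodness-of-fit power is intrinsically
limited at low depth; deeply mismatched cells at very high depth drift into
doublet-uncertain rather than rejected, which is the intended conservative
behavior.

**Assignment** is the strict rule: the label with weight > 0.5, else
UNCLASSIFIED; ties at exactly 0.5 are UNCLASSIFIED.  Rejected cells are
excluded from labeled outputs.  Two-round labeling assigns major classes
first and re-decomposes cells labeled MSN against the subtype reference;
non-MSN cells keep their round-1 label.

## Niche assay (`striatlas.niche`)

Composition rows count the labels of each cell's k = 30 nearest labeled
cells (Euclidean, self excluded; kd-tree order gives a deterministic
tie-break).  Unlabeled/UNCLASSIFIED cells contribute to nobody's composition
but still receive one.  k-means (k = 30 niches, 10 restarts, fixed seed)
clusters the rows; the niche with the highest mean MSN fraction is the
striatum mask.  The composition is taken over *major classes* (MSN subtypes
collapsed): interior striatal cells then share near-identical rows and fall
into one niche, which is what makes a single argmax niche a usable mask.
Degenerate inputs (fewer distinct rows than clusters) reduce the effective
cluster count with a warning.

## Spatial statistics (`striatlas.spatialstats`)

**Axes.** Raw x/y coordinates, or a 1-D isomap embedding (symmetric kNN
graph, default 15 neighbors, geodesic distances, first classical-MDS
coordinate, sign fixed to correlate positively with x, then y).  Sections
above 2000 cells are embedded through a 2000-cell landmark subsample.
Disconnected graphs raise with instructions to increase the neighbor count.

**Otsu boundary.** Exhaustive scan over the interior edges of a 128-bin
histogram for the split maximizing between-class variance.  Exactly tied
maxima arise when the optimal split falls in an empty stretch (a physical
gap between two populations); the tie is broken by the edge closest to the
midpoint of that empty stretch — the natural threshold location — then
toward the data median, then the lower edge.  (Breaking ties by the data
median alone mislocates gap boundaries whenever the two sides have unequal
counts.)  Input is the pooled 1-D occupancy of the two compared cell types;
expression-weighted variants were considered and rejected as they do not
sharpen the boundary.

**RDD.** On log1p depth-normalized expression (normalization target: median
cell depth), the model expr = β₀ + β₁·posmark + β₂·centered_axis is fitted
by ordinary least squares (a Gaussian GLM with identity link); the two-sided
Wald p on β₁ is the test, with the linear-only model as the null.  No
interaction term by default; a separate-slopes mode is config-gated.  Both
sides must hold ≥ 20 cells.  Degenerate conventions: zero residual variance
gives p = 1 when β₁ = 0 and p = 0 otherwise.  The pipeline runs per section
and never pools across sections or animals.  Known limitation: a steep
gradient on the *count* scale is curved after log1p, and curvature leaks
into the jump term; the null is calibrated for gradients that are
approximately linear on the analysis scale (the bundled control uses
0.001 counts/µm, measured false-positive rate ≈ nominal).

**Gradients.** Percent = 100·count/group-total per section; SEM across
sections within an rc level (sample sd/√n); fold change percent(B)/percent(A)
flagged when A is absent.  LOESS is classic local-linear with tricube
weights over the span-fraction nearest neighbors (default span 0.75),
falling back to the local weighted mean on degenerate windows; it reproduces
any globally linear signal exactly.

**Mixed model.** y ~ intercept + β·x + (1 | group), fitted by profile REML:
for a given variance ratio φ = σ²_group/σ²_resid the GLS fixed effects and
residual variance have closed forms through per-group Woodbury identities;
the one-dimensional REML criterion is minimized over log φ (bounded search,
φ = 0 boundary checked explicitly).  Wald p on the slope uses the normal
reference.  With one group, or σ_group = 0, the slope equals the OLS slope
identically.  The fixed effect for rostro-caudal gradients is the ordinal
section index in rostral→caudal order (level spacing in mm is uneven and
the coding of published gradients is by section step).

## Pseudobulk DE (`striatlas.diffexp`)

Aggregates are cell-type × animal sums; aggregates with < 15 cells are
excluded and listed; the detection rate (fraction of genes with count > 0)
is a per-aggregate covariate.  Genes are filtered to CPM > 1 in ≥ 2
aggregates; ribosomal/mitochondrial symbols are dropped by prefix
(RPS/RPL/MRPS/MRPL/MT-).  Scale factors are trimmed means of M-values (30%
log-ratio trim, 5% abundance trim, inverse-variance weights, geometric mean
1), log2-CPM uses a 0.5 prior count.  Precision weights invert the LOESS
trend of √(residual sd) on mean log2-CPM to the fourth power, evaluated at
each observation's fitted abundance; sample quality weights come from two
rounds of per-sample residual-variance rescaling, clamped to [0.1, 10].
Intra-animal correlation is approximated by the animal-blocking structure of
the pseudobulk itself rather than a consensus-correlation estimate; this is
a documented simplification.

The design is ~0 + celltype + scaled numCells + scaled detection rate
(constant covariates dropped) plus surrogate variables: the top principal
components of the full-design residual matrix, dimension chosen by
permutation parallel analysis (10 permutations, 95th percentile, capped at
5).  Per gene, weighted least squares with one-vs-all contrasts
(c_t = e_t − mean of other type columns).  Moderation: (d₀, s₀²) by method
of moments on log s²_g (digamma/trigamma identities, Newton inversion of
trigamma); s̃² = (d₀s₀² + d s²)/(d₀ + d); t on d + d₀ df (normal when
d₀ = ∞, which is also the fallback when the moment estimate is non-finite).
d₀ = 0 reproduces the ordinary weighted t exactly.

**Covariate-adaptive FDR.** For λ on a grid (0.05 … 0.90 step 0.05) the
indicator 1[p > λ]/(1 − λ) is regressed on [1, standardized covariate];
predictions are averaged over the grid and clamped to [0.01, 1];
q = π₀(x) · BH(p).  "Within" adjusts per cell type, "between" pools all
cell types first (more conservative; the headline scheme).  A constant
covariate reduces exactly to scalar-π₀ q-values.

**Relatedness.** For each ordered type pair, the number of features
significantly up-regulated in the first type: pseudobulk moderated contrasts
(adj p ≤ 0.05) for expression, or single-cell Wilcoxon rank-sum tests
(normal approximation, tie-corrected) with FDR ≤ 0.05 and log2FC ≥ 0.25 for
accessibility-style matrices.  Pairs with fewer than two aggregates per side
are skipped and flagged.  **Cosine similarity** down-samples 500 nuclei per
region, projects log-normalized counts onto 20 PCs, averages all pairwise
cosine similarities within region pairs, and orders the display by
average-linkage clustering on 1 − similarity.

## QC (`striatlas.qc`)

RNA: strict inequalities exactly as stated (2500 < nFeature < 10000,
percent_mito < 5).  ATAC round 1: nFrags ≥ 10^3.5 plus an optional
precomputed doublet-filter flag (the upstream doublet simulation itself is
out of scope).  Round 2 fits the NB GLM (log link) by alternating IRLS for
the coefficients with bounded ML updates of θ (outer tolerance 1e-8, max 100
rounds; θ capped at 1e6, where the model is effectively Poisson and
flagged).  The standardized residual is Pearson, (y − μ̂)/√(μ̂ + μ̂²/θ̂),
two-sided cutoff 2 by default; the deviance scale and a one-sided cutoff are
available since the published wording does not fix either choice.

## Enrichment (`striatlas.enrich`)

BH runs once over the flattened cell-type × study grid (NaN entries are
excluded from the family and flagged); signed score = sign × (−log10 adj p),
exactly 0 when adj p = 1.  Double z-scoring restricts, by default, to pairs
significant at α = 0.05 — z₁ per study across cell types, z₂ within each
(cell type, trait category) bin — because z-scoring the full matrix lets a
sea of nulls manufacture calls; the full-matrix and |score| variants are
flags.  Bins with a single usable entry or zero variance give z = 0,
flagged.  A "+" requires z₁ > 1, z₂ > 1 and significance.

The per-cell gene-set score residualizes every gene on [1, log total
counts, log features] by one shared least-squares projection, averages
residuals over the set, and compares against 200 control sets drawn to match
the set's mean-expression bin histogram exactly (25 bins; sampling with
replacement, flagged, when a bin is too small): z = (observed − control
mean)/control sd.  This is a transparent stand-in for per-cell polygenic
scoring tools; it shares their matching logic but none of their
GWAS-side machinery.

## Pipeline (`striatlas.pipeline`, CLI `striatlas`)

Stages run in dependency order from a single config with one global seed,
split per stage by hashing the stage name (stage insertion does not perturb
other stages' draws).  Every stage writes a manifest entry with parameters,
derived seed and sha256 checksums; deterministic stages are byte-identical
across reruns.  Formats: MatrixMarket counts with the seed echoed in the
header comment, tab-delimited metadata/labels/results with header rows,
JSON summaries.

## Test and acceptance problem sizes

The test suite and acceptance script run fully synthetic problems sized for
a single CPU: RDD calibration on 500–1000 null sections of 1000 cells,
power on 300–500 replicates of 500 cells/side, Otsu recovery on 100–200
demo sections (~4500 cells), labeling accuracy on ~1800 reference cells,
niche demarcation on a ~2000-cell two-region section, LMM coverage on 200
replicates of 2 × 10 observations, FDR control on 100–200 replicates of
1500 tests, NB QC on 5000 cells, and 60–100 seeds of end-to-end jump
detection on ~2000-cell sections.  These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the methods assume —
NB counts, marker-block profiles, compositional gradients with nested random
effects, discrete expression boundaries versus smooth gradients — but not
segmentation errors, ambient contamination, spatially varying capture
efficiency, curved anatomy, or cross-modality barcode mismatches.  Passing
recovery tests therefore certifies the computations, their calibration and
their determinism, not robustness to those real-data pathologies; the QC
and doublet-mode machinery addresses them only to the extent the upstream
metrics capture them.
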