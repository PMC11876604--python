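# Methods

This note records the models, the defaults that matter, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## The communication model

The tumor-wide communication score is derived from a well-mixed ligand
balance in the tumor microenvironment,

    dS/dt = Σᵢ σ xᵢ Pᵢ − Σⱼ qⱼ yⱼ γ Pⱼ S − μS,

whose steady state is S* = σ Σᵢ xᵢPᵢ / (Σⱼ qⱼ yⱼ γ Pⱼ + μ). Assumptions:
ligands are well mixed (no spatial gradients), production is linear in
mean subpopulation ligand CPM, and internalization after receptor binding
is negligible (qⱼ small), under which the signal received by a cell of
subpopulation *j* through pathway *k* is proportional to y_jk Σᵢ x_ik P̂ᵢ.
Reported scores drop the constant γσ/μ: cross-sample standardization
removes any fixed proportionality anyway. `steady_state_signal` keeps the
full constants for model work and exactness tests.

Sender and receiver profiles are within-sample subpopulation means of CPM
expression; pairs are single ligand / single receptor (no multimeric
complexes). Cell-type scores sum over sender bins and
abundance-weight-average over receiver bins. Standardization is across all
cohort samples jointly (both treatment arms, all timepoints) with the n−1
standard deviation; zero-variance pathways are set to 0 rather than left
undefined. The per-pair summary C̄ is the median of standardized scores
over pathways with non-absent values (absence — a cell type missing from a
sample — is NaN, never 0). A consequence worth knowing: because the score
factorizes into sender term × receiver term, a ligand-side change
propagates to every receiver type whose receptor expression is nonzero;
receiver specificity comes from receptor expression patterns, not from the
score itself.

## Subpopulations

Each broad cell type is embedded separately. When per-cell pathway scores
(ssGSEA-like) are supplied they are embedded as given; otherwise log1p
expression is used as the phenotype matrix, and the fallback is logged.
Embedding method is UMAP (seeded) or PCA with a deterministic sign
convention; the fast benchmark sweeps use PCA so that hundreds of replicate
cohorts stay inexpensive. Embedding dimensionality can be chosen with the
greedy packing-number capacity-dimension estimate
d̂ = −(log M(r₂) − log M(r₁))/(log r₂ − log r₁), rounded and clipped to
[1, 5]. The estimator is only meaningful when the packing counts stay well
below the number of points at both radii; with ~10³ points that means radii
around 5–20 % of the data diameter.

Binning uses a per-axis product grid of equal-width intervals (default 4
per axis) over each axis range, computed cohort-wide per cell type so that
subtype identities are shared across samples; proportions P̂ are per
sample. Bins below `min_cells` (default 30) are merged, sparsest first,
into the nearest occupied bin by centroid distance; a cell type with fewer
than `min_cells` cells cohort-wide becomes a single subtype with a
warning. Subtype names are ordered along the first embedding axis, so on a
one-dimensional phenotype gradient the subtype index tracks the latent
order.

## Network contrasts

The randomization test shuffles tumor response labels; all biopsies of one
patient move together. The same shuffle is applied to every directed pair,
so the null preserves each randomized network's internal structure. With
sampling, the two-sided p uses the add-one convention
p = (1 + #{|null| ≥ |obs|})/(B + 1), and B defaults to 1000; when the
number of distinct label assignments does not exceed B, the test
enumerates them all and reports the exact rank p (this engages
automatically for small cohorts, e.g. all 20 assignments of 3 vs 3
tumors). z = (obs − null mean)/null sd carries the direction. Holm's
step-down correction is applied across the directed pairs of one
(treatment, timepoint) contrast. Whether shuffling is with or without
replacement was an open choice; permutation without replacement is the
default because it makes small-cohort tests exact.

Per-pathway contrasts use a two-sample t test on per-tumor log(1 + C)
(the linear-model t on a group indicator) with BH-FDR across the pathways
of one directed pair. Pathways absent in every tumor are excluded and
logged; log1p keeps all-zero groups finite.

## Compositions and archetypes

Proportions are clamped to [eps, 1−eps] (default eps = 1e−3, logged)
before the logit transform; logit-Euclidean distance is then the Euclidean
distance in logit space. The archetype embedding is therefore fitted with
UMAP on the logit coordinates with the Euclidean metric — identical
distance structure to feeding the precomputed distance matrix, but it
supports `transform()`, which the projection of validation cohorts needs.
The mixture is a full-covariance GMM over K in 1..6 selected by minimum
BIC (5 restarts, seeded). `assign` projects new samples through the frozen
UMAP and classifies with the frozen GMM; rows numerically identical to a
training composition keep their training label, because UMAP's transform
of its own training points is only approximate. A Ward-linkage view of the
same distances and an archetype × response chi-square table are provided
as conveniences for heatmap-style summaries; the chi-square is a
descriptive check, not a compositional regression.

## Myeloid polarization

Clustering is a full-covariance GMM over K in 2..25 (BIC-selected).
The differentiation skeleton is the minimum spanning tree over cluster
centroids with Euclidean weights, rooted at the cluster with the highest
fraction of monocyte-flagged cells. Principal curves are deliberately
simplified to the MST polyline: cells are orthogonally projected onto
their nearest edge segment and pseudotime is root-to-projection arc
length. Every root-to-leaf lineage through the projected edge assigns the
same arc length, so the "average pseudotime" equals it; the lineage count
is reported for transparency.

The two-state pseudotime mixture uses unequal variances; if BIC prefers
one state, all cells are undifferentiated (with a warning). The M1/M2
division boundary is a cubic smoothing spline with GCV-chosen penalty
through the undifferentiated cells, clamped to its endpoint values outside
the fitted range; duplicate abscissae are averaged. Polarization is
sign(axis2 − b(axis1)) × pseudotime with the positive side M2-like by
convention; if a per-cell M2 marker score is supplied and the negative
side has the higher mean marker, the orientation flips. M1-like cells are
those with polarization below the cohort mean. Gene trends regress
expression on a 6-df cubic B-spline basis of polarization and rank genes
by the F statistic against the constant model; direction is the sign of
the linear correlation.

## Growth assay

rgr uses natural logarithms over a 75-hour window by default; the window
is a parameter because imaging designs vary. Requested endpoints match the
nearest observation within ±6 h (imaging every 24–72 h), otherwise an
error. Dose trends are Spearman rank correlations of rgr against IL-15
dose within each (line, culture, ribociclib) stratum; single-dose strata
report NaN. Fluorescence-to-abundance conversion is upstream and out of
scope; abundances are inputs.

## The synthetic generator

The generator emulates: per-sample compositions drawn from planted
archetypes (Dirichlet around archetype proportions; concentration 150 for
the tightly controlled benchmark cohorts, 40 for archetype-recovery
cohorts, where the three planted classes — immune-hot, cancer-dominated,
stromal-enriched — remain visibly separated, as archetypes are in real
cohorts); a uniform 1-D latent phenotype per cell with linear expression
gradients on selected genes (so binning has real structure); log-normal
multiplicative cell noise on CPM means (σ = 0.6, mean-preserving);
per-tumor, per-gene log-normal random effects (σ = 0.05, shared across a
patient's timepoints); and additive planted shifts of mean ligand CPM in
one response group. Expression is simulated directly on the CPM scale for
a compact panel; the rest of the transcriptome is implicit, so rows are
not forced to sum to 10⁶. Not modeled: UMI counting noise, doublets,
ambient RNA, batch effects, copy-number subclones. Benchmarks on this
generator therefore demonstrate the statistical machinery — calibration,
power, recovery — under clean compositional and expression structure, not
robustness to the technical artifacts of real droplet data.

The benchmark cohort uses 3 cell types (Cancer 0.5, Myeloid 0.3, T cell
0.2), 300 cells per sample, one timepoint, and a 6-pathway
cytokine/growth-factor panel in which each receptor is expressed only in
its designated receiver type. That restriction is a consistency
requirement of planted truth, not a simplification of convenience: the
score factorizes, so a receptor expressed in several receiver types would
propagate a planted ligand shift to all of them and the planted truth
would no longer name a unique differential pair. The planted
cancer→myeloid effect is an IL-15 ligand shift touching the panel's two
IL-15 receptor pathways (IL15RA and IL2RB), as a cytokine program would; a
pre-registered design calculation showed that a shift confined to a single
pathway is structurally diluted by the median-over-pathways network
summary and cannot dominate the pair-level z, whereas a two-pathway ligand
effect can. The planted effect size "one cohort-sd" means one standard
deviation of the ligand's CPM across sender-type cells of a null cohort,
measured at run time from a seeded pilot cohort.

Benchmark problem sizes — 5v5 tumors × 150 cells for the 200-cohort null
calibration, 10v10 × 300 for the 100-replicate power study, 1500 manifold
cells, 60 composition samples — keep every experiment in the
seconds-to-minutes range on a single CPU while leaving the measured rates
far from their thresholds.

## Determinism and numerics

All randomness flows through seeded `numpy` generators; UMAP and GMM take
explicit seeds; PCA axes get a deterministic sign convention. TSV writers
use a fixed float format and LF endings, so identically seeded pipeline
runs are byte-identical. Medians use the standard midpoint convention;
permutation tie comparisons use a 1e−12 tolerance on |null| ≥ |obs|;
standardization uses the n−1 denominator. Degenerate inputs have defined
behavior throughout: zero-variance pathways standardize to 0, empty
groups and zero-total cells raise errors naming the offenders, and
single-dose strata report absent trends.

## Known limitations

Spatial signaling gradients, multi-subunit receptor complexes, and
CellChat-style interaction probability models are out of scope. The
tumor-level two-group contrasts stand in for hierarchical random-effects
models; with repeated biopsies per tumor they discard within-tumor
correlation structure beyond averaging. The MST-polyline pseudotime is
coarser than principal curves near branch points. Archetype discovery
inherits UMAP's sensitivity to its neighborhood size on small sample
counts.
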