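# Methods

This note documents the models and procedures implemented in
`embryolin`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Data model

Expression is handled as gene × cell matrices tagged with a unit
(`FPKM`, `count` or `log2FPKM`). The log transform is log₂(FPKM + 1);
the pseudocount of 1 is a convention chosen because it is zero-preserving
and monotone, and its inverse (2^x − 1) recovers FPKM exactly. Gene
identifiers are opaque symbols: annotation-version resolution is
upstream of this package. When studies are merged, the gene set is the
*intersection* of the inputs (lexicographically ordered): cross-study
comparison is only meaningful on features quantified in every study.

## Library QC

Three filters, applied in the order depth → coverage bias → PCA screen
(the first two commute; the screen runs on survivors):

- **Depth**: libraries with fewer than 500,000 mapped reads are removed
  (a library at exactly the threshold is kept).
- **Coverage bias**: gene bodies are divided into 100 gene-length
  percentile bins; the bias ratio is the read mass in bins 50–100
  (1-based, 51 bins) over bins 1–49. The boundary assignment of bin 50
  to the 3' half follows the literal reading of the rule; a uniform
  profile therefore gives 51/49 ≈ 1.041. Ratios strictly above 2 remove
  the library; the ratio is scale-invariant and +∞ when the 5' half is
  empty.
- **Stage-wise outliers**: within each annotated stage (≥ 3 cells), the
  matrix is centred and cells whose PC1 or PC2 score deviates from the
  group median by more than k median absolute deviations (default
  k = 5) are flagged. The criterion is a package choice — robust,
  deterministic and conservative; no threshold is inherited from
  elsewhere.

## Variable-gene selection

CV² is computed on the raw FPKM scale (sample variance over squared
mean), plotted as log₁₀ CV² against mean log₂(FPKM + 1). The
mean–dispersion trend is a local polynomial regression (degree 2,
tricube weights, span 0.3 of genes) — an assumption-light smoother whose
exact form is a package choice. Selection applies strict thresholds on
both axes (defaults: mean log₂ FPKM > 2 and log₁₀ CV² > 0.5; the log
base is 10, making the default equivalent to CV² > 3.16, which is a
plausible dispersion floor for single-cell FPKM data); the positive
trend residual is an optional additional criterion (`use_residual`),
off by default because selection by axis thresholds alone is the
primary behaviour. For multi-study data, genes are selected per study
and intersected.

## Lineage classification

The default 12-gene marker panel carries four genes per blastocyst
lineage (EPI: NANOG, SOX2, KLF17, TDGF1; PrE: GATA6, SOX17, GATA4,
PDGFRA; TE: GATA2, GATA3, KRT8, CDX2) and is user-replaceable.

PCA is an exact SVD of the per-gene mean-centred matrix, without
unit-variance scaling (magnitude carries signal in marker panels;
scaling is available as an option); component signs are fixed by making
the largest-magnitude loading positive.

Clustering follows the package-wide convention: Euclidean distance,
average agglomeration, deterministic lexicographic processing order.
`scipy.cluster.hierarchy` provides the implementation; the test suite
verifies its merge sequence against an independent O(n³) brute-force
agglomerator on small instances.

**POU5F1 classes.** Late-ICM extraction clusters cells 1-D into
high/medium/low POU5F1 classes. The op's default coordinate is the
third principal component of the supplied embedding (matching the
narrative workflow in which the POU5F1-tracking axis was identified by
inspection); because which component tracks POU5F1 is dataset-dependent,
two data-driven alternatives are provided: `component="auto"` (the
component most correlated with POU5F1) and `component="supervised"`
(POU5F1 denoised by its least-squares fit on the top five components).
The end-to-end workflow uses the supervised coordinate: on synthetic
data no single axis reliably tracks POU5F1 across generator seeds, and
the denoised coordinate orders EPI > intermediates > PrE > TE so the
three-class cut lands in the large PrE–TE gap. Classes are labelled by
descending mean POU5F1; ties break by group size (larger → lower).

**EPI / PrE / intermediate.** POU5F1-high and -medium cells are
clustered (k = 3) on marker-panel PCA coordinates. The cluster with the
highest mean NANOG:PDGFRA log-ratio is EPI and the lowest PrE; the
middle cluster is intermediate unless its mean ratio itself clears the
per-cell threshold τ (default 1, i.e. 2-fold), in which case it takes
the corresponding mature label — this guards against a dropout-shifted
chunk of a mature lineage being forced into the intermediate slot.
τ is configurable; the ratio rule is antisymmetric under swapping the
two genes.

**Pseudotime.** A methodological stand-in, clearly labelled as such: a
Gaussian kernel on the kNN graph (local bandwidth = distance to the
k-th neighbour, k = 15), symmetrised, row-normalised; pseudotime is the
rank-normalised coordinate along the first non-trivial right
eigenvector, oriented so a designated root group (default: earliest
embryonic day present) sits early. Disconnected graph components are
processed separately with a warning. The early-ICM finder intersects
the lowest-pseudotime hierarchical cluster (k = 3 by default, so the
three E5 subpopulations can separate) with cells scoring above the E5
median on the early-ICM marker panel; within E5 the pseudotime root is
the top quartile of marker scorers.

## Co-expression modules

Unsigned adjacency a_ij = |pearson(g_i, g_j)|^β with β = 10 (the
signed variant is not implemented; unsigned is the conventional
default). TOM similarity uses the standard formula
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij). Module
detection cuts the average-linkage tree of 1 − TOM at a static height:
starting at 0.99 of the tallest merge and descending in steps of 0.01
(of that height), the cut stops as soon as the partition into groups of
at least `min_size` genes (default 50) is unchanged across one step;
smaller groups are unassigned (module 0). This is a deliberate,
deterministic simplification of Dynamic Tree Cut: on well-separated
structure the inter-module merges sit within 1% of the tallest merge,
so the first cut already isolates the modules and the stability check
terminates immediately, while homogeneous noise yields no stable group
of sufficient size. Eigengenes are unit-norm first principal components
of the standardised member submatrix, oriented to correlate positively
with their members on average; modules whose eigengene dissimilarity
(1 − r) falls below 0.35 are merged greedily (closest pair first,
eigengenes recomputed after each merge), which can only reduce the
module count and is idempotent. Hubs are the top 50 genes per module by
intramodular connectivity (sum of adjacency to same-module genes), ties
broken lexicographically.

The compendium-scale behaviour of this machinery (on the real pooled
data, 14 initial modules reducing to 7 after merging) requires the
deposited accessions; the tests substitute planted-block recovery with
known ground truth.

## Stage signatures and marker rules

Stage profiles are per-gene mean FPKM over the ordered stages zygote,
4-cell, 8-cell, morula, early ICM, EPI, PrE, summarised as per-gene
Z-scores across the stage axis (sample SD; genes without cross-stage
variance are excluded — a relative variance floor keeps float noise on
constant genes out).

The SOM is a 30×30 hexagonal grid, batch-trained for 100 epochs with
PCA-plane initialisation (deterministic: no random sampling anywhere),
a Gaussian neighbourhood on grid coordinates and a radius decaying
linearly from max(width, height)/2 to 1. Features are the Z-score
profiles by default; raw mean profiles are available by flag, covering
both readings of "ranked by expression level and Z-score".

"Transcriptional contribution" of a gene at a stage is implemented as
the share of the gene's summed cross-stage mean FPKM (contributions sum
to 1 per gene) — the simplest self-consistent reading. Late lineage
markers require contribution > 75% at the lineage stage and ≥ 10 FPKM
there. Early markers read the developmental path as the contiguous set
{8-cell, morula, early ICM, lineage}: summed path contribution > 75%,
fold change ≥ 4 between the two lineages with a pseudo-floor of
ε = 0.01 FPKM (negligible against the 10 FPKM expression floor), and
≥ 10 FPKM in at least one of the five relevant stages. As written, the
early rule also admits genes expressed only at the terminal lineage
stage (the path includes it); the implementation keeps that literal
semantics.

## Fractional identity

Stage signatures are per-stage arithmetic means on the linear FPKM
scale (log-scale deconvolution is exposed as an option but linear is
the default, matching the definition of the signature as average
expression). The decomposition solves

    minimise ‖S f − x‖²  subject to  f ≥ 0, Σ f = 1

with a primal active-set method: equality-constrained KKT solves on the
free set, feasible steps that clamp variables at zero, and release of
clamped variables with negative reduced gradient. The problem is convex,
so the returned KKT certificate (stationarity and dual feasibility
normalised by the gradient magnitude, primal feasibility absolute)
implies global optimality; the solver is exact to machine precision on
noiseless mixtures. When two signature columns coincide within 1e-9 the
optimum is not unique; a flag is raised and one optimum returned.
An independent two-stage simplex grid search (0.01 lattice, locally
refined to 0.001) serves as the test oracle.

Differential expression is a two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg adjustment — a deterministic substitute for
error-model-based single-cell DE methods, which are out of scope; the
significance thresholds (adjusted P < 0.001, |log₂ FC| > 1.5) are
parameters. The exact tie-free null is used for total group sizes up to
30 (matching the combinatorial oracle on complete separation) and the
normal approximation beyond. Fold changes use group means with a
pseudocount of 1. Stage correlations are Pearson on the log₂ scale,
restricted to a supplied DE gene set, with NaN for zero-variance stages.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for all tests. Per-cell
log₂ means follow per-stage programmes; a per-(gene, study) Gaussian
batch factor (SD 0.3 log₂), per-entry Gaussian noise (SD 0.5 log₂) and
optional per-gene extra dispersion are added; FPKM = max(2^x − 1, 0);
per-study Bernoulli dropout (rates 0.1 / 0.3 / 0.2 for the three
emulated studies) zeroes entries. Everything is deterministic given the
seed (default 0).

Fixed conditions (chosen once, from the mean/CV² arithmetic of the
log-normal-plus-dropout model, so that planted signals clear the
published selection thresholds and flat genes do not):

- Marker programmes: on 12 log₂ (≈ 4100 FPKM), off 0, mutually
  exclusive across mature lineages; NANOG and GATA6 co-expressed at mid
  level (5) in the early ICM.
- POU5F1: 6–7 log₂ from zygote through early ICM, 8 in EPI, 5 in PrE,
  1 in TE — broad early expression restricting to the ICM late.
- Intermediates: convex combinations w·EPI + (1−w)·PrE with
  w ~ U(0.3, 0.7) per cell, giving mid-range GATA6 automatically.
- Shared variable genes (100): lineage- or stage-run-linked (on 8 log₂,
  off 2) with extra dispersion SD 1.2; the dedicated selection fixture
  instead uses stage-free dispersed genes (mean 5.5, dispersion SD 3.0),
  whose population log₁₀ CV² ≈ 1 sits well above the 0.5 threshold in
  every study even after dropout.
- Study-specific "protocol" genes (60 per study, detected at 9 ± 2.5
  log₂ only in their own study) emulate library-construction bias; they
  enter per-study variable sets but never the intersection.
- Planted early/late lineage markers at exactly 15 / 20 FPKM, a 30-gene
  TE programme at 10 log₂, and per-stage marker genes at 20 FPKM feed
  the deterministic marker-rule tests.
- Module blocks share a latent factor with loading σ·√(w/(1−w)) so the
  within-block correlation is ≈ w; block genes are raised to a
  well-detected baseline (≥ 8 log₂) so the zero clip does not truncate
  the factor signal; w = 1 produces exact affine copies.
- Library statistics plant exact coverage ratios by allocating mass
  r/(1+r) vs 1/(1+r) between the two gene-body halves; passing
  libraries keep ≥ 10% margin on both filters.

Not emulated: count noise (the unit is FPKM-like, so negative-binomial
sampling is deliberately omitted), expression-dependent dropout, gene
length or GC effects, doublets, cell-cycle structure, or the absolute
FPKM distributions of the real accessions. Passing tests therefore
demonstrate the pipeline's correctness and its robustness to
multiplicative batch structure and uniform dropout — not performance on
the real compendium, whose headline numbers (188 intersected variable
genes, 43/336 early-ICM cells, 14 → 7 modules, n = 2860 DE genes,
naive-PSC EPI identity > 0.75 vs < 0.54) depend on the deposited
accessions and are out of desk-scale reach. The acceptance script
reports the synthetic analogues it computes.

Problem sizes used throughout (300 cells, 2000 genes, 200-cell module
fixtures, 12×12–30×30 SOM grids) were chosen as the smallest at which
each statistical effect is comfortably detectable.

## Numerical choices and degenerate inputs

- Strictness at boundaries follows the stated rules everywhere:
  500,000 reads kept, bias ratio exactly 2 kept, thresholds on
  variable-gene axes strict.
- Constant matrices give zero-variance PCAs (all coordinates zero);
  all-identical POU5F1 warns and labels arbitrarily; all-constant
  eigengene members and single-cell variance computations raise.
- Pseudotime quantises the eigenvector coordinate (10⁻⁶ of its range)
  before ranking so duplicated cells receive tied ranks; kNN lists
  exclude the cell itself even under zero-distance ties.
- The active-set solver renormalises Σf = 1 after clamping; its
  iteration cap (500) is never reached on problems with ≤ 10 stages.
- Ties: cluster labels renumber by order of first appearance after
  lexicographic cell ordering; hub ranking breaks ties by gene id;
  POU5F1 class means tie-break by group size.

## Known limitations

- The static-height tree cut is coarser than Dynamic Tree Cut and can
  under-split nested module structure; it trades resolution for
  determinism.
- The rank-sum DE substitute does not model the single-cell error
  structure (dropout inflation, overdispersion) that dedicated methods
  capture; with FPKM input it treats values as exchangeable within
  groups.
- Pseudotime assumes a dominant one-dimensional trajectory; branching
  topologies are outside its contract.
- Fractional identity is only as identifiable as the signature matrix:
  strongly collinear stages (adjacent cleavage stages, EPI vs PrE at
  early time points) spread weight along near-degenerate directions;
  the non-uniqueness flag covers exact duplication only.
- With uniform dropout at the simulated rates, single-gene quantities
  (the per-cell NANOG:PDGFRA ratio, per-cell POU5F1) are unreliable in
  up to ~30% of cells of the worst study; the pipeline's cluster-level
  pooling is what restores accuracy, and per-cell calls should be read
  accordingly.
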