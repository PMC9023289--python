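# Methods

## Model and assumptions

The deconvolution rests on one assumption: single-cell and spatial
measurements of the same tissue share latent expression programs, so a
gene-by-topic distribution φ learned on the annotated reference is valid for
the spatial data. Cells are bags of gene tokens; latent Dirichlet allocation
with K topics, a symmetric document prior α and a symmetric topic prior β is
fitted by online variational Bayes (scikit-learn's implementation of the
Hoffman et al. algorithm). The topic-by-cell matrix Z is obtained by a
variational fold-in E-step with φ frozen — the same routine later applied to
spots — so a spot whose counts equal a reference cell's receives that cell's
topic profile by construction.

Labels enter only after training: T averages Z within each cell type, and the
Bayes inversion C_nk = T_kn·Q_n / P_k converts "which topics does this type
use" into "which type does this topic indicate". The spot proportions
ST = C·Y are renormalized per spot to sum exactly to one. This treats the
reference label frequencies Q as the prior over cell types; when the spatial
tissue has a very different composition, a user-supplied prior should replace
it (supported by `make_tables(Q=...)`).

Because the deconvolution is a linear map from topic space, it inherits the
resolution of the topics: transcriptionally similar types (e.g. T-cell
subtypes) that share topics cannot be fully separated, which is a known limit
of the approach.

## Normalization

Raw counts are depth-scaled per column to 10,000 (configurable) and each gene
row is then divided by its population standard deviation (ddof = 0, no
centering, so the matrix stays non-negative and can serve as fractional token
weights for the variational updates). Rows with zero variance are set to
zero — they carry no between-cell information. Whether the per-gene SDs for
spatial data are recomputed on the spatial matrix (default) or reused from
the reference (`gene_sd=`) is configurable: recomputation matches applying
the scheme "per matrix", but on spatially organized tissue a cell type
confined to one region has artificially low spatial variance and its markers
get over-weighted, so reusing reference SDs is the safer choice there
(demonstrated in `examples/03_spatial_domains.py`). A single spot has no
per-column variance at all and must use reference SDs.

## Feature genes

The default feature space is the union of per-cell-type marker genes: a
one-vs-rest Wilcoxon rank-sum test (one-sided, asymptotic) on normalized
expression, ranked by p-value with ties broken by descending log2 fold change
and then gene id. Restricted contrasts (`contrasts={type: [backgrounds]}`)
compare transcriptionally similar types only against each other. Highly
variable genes are ranked by the variance-to-mean dispersion of depth-scaled
counts; `all`, `hvg` and `markers_plus_hvg` modes exist, but markers are the
default — training on all genes of the block fixture showed that a large
uninformative background can absorb a topic and merge two cell types, while
the marker space separates them reliably. Feature genes are always restricted
to the genes shared between the reference and the spatial matrix.

## Topic model settings

Defaults: α = 1/K, β = 0.01, online variational Bayes with mini-batches of
256 cells and 20 passes; training is deterministic given the seed. The
candidate grid for K defaults to {N, ⌈1.5N⌉, 2N, 3N} for N cell types; each
candidate is scored by the re-annotation accuracy of the reference cells and
exact ties resolve to the smallest K (the simplest model). Accuracy is
computed on the full training set, matching the re-annotation reading of the
selection rule. Fold-in iterates the per-document E-step to a mean absolute
change below 1e-6 with a cap of 100 iterations; spots with zero total feature
expression get the uniform topic distribution and a warning. Argmax ties in
cell annotation and dominant-type assignment resolve to the lexicographically
smallest type name.

## Spot simulators

All simulators aggregate raw integer counts of real (here: synthetic
reference) cells, so each spot has an exact, integer-derived ground truth and
the spot column equals the (possibly down-sampled) sum of its provenance
cells.

* **Random spots** — per spot, a uniform 2–10 cells sampled without
  replacement; aggregates above 25,000 UMIs are down-sampled to 20,000 by
  multivariate hypergeometric sampling (without replacement from the UMI
  multiset, so totals are exact and counts never exceed the input).
* **Depth ladder** — 1,000 spots of 10 cells down-sampled to
  20,000/15,000/10,000/5,000/2,500/1,000 counts. Levels are nested by default
  (each shallower level is a subsample of the previous), making depth the only
  varying factor; independent subsampling is available via `nested=False`.
* **Tumor microenvironment** — four compartments of 250 spots (tumor core,
  invasive margin, tumor stroma as 125+125 spots with two alternative
  pairings, tertiary lymphoid structure). Each compartment fixes the mean
  fractions of one co-localized pair (e.g. malignant 50% / CD8 T 30% in the
  core), allows a stated set of free types, and excludes everything else
  exactly. Pair fractions are bivariate logit-normal (σ = 0.35 on the logit
  scale) around the fixed means. The generative law behind the target
  correlation of 0.7 is this module's open design choice: the truth is
  quantized to multiples of 1/10 (10 cells per spot, largest-remainder
  apportionment), which attenuates correlation, so the latent correlation is
  calibrated by a short fixed-point loop at generation time until the
  realized integer proportions hit the target within 0.005 (typically 2–3
  iterations). Free types share the per-spot residual mass via a symmetric
  Dirichlet.

The block fixture emulates a clean reference: each type owns a private block
of high-rate markers over a shared background, with multinomial counts of a
Poisson total per cell. It does **not** emulate ambient RNA, doublets, batch
effects, continuous lineages, or transcriptionally overlapping subtypes —
passing recovery tests on it shows the estimator is correct under its own
model, not that real-tissue accuracy will match.

## Evaluation metrics

Per-spot Pearson correlation (across cell types) measures each spot's
deconvolution accuracy; per-cell-type correlation (across spots) measures the
ability to distinguish types. The presence/absence split RMSE divides each
spot's cell types by truth strictly greater than zero — exact zeros are
guaranteed by the simulators, so no epsilon is needed — and reports the RMSE
within each group: the present group reads as sensitivity, the absent group
as specificity. Zero-variance groups yield NaN with a warning. Marker
signature scores are either plain sums of (externally normalized) marker
rows, or bin-controlled module scores (24 mean-expression bins, 100 control
genes per marker gene, the scored set excluded from its own control pools —
necessary at small vocabulary sizes, harmless at genome scale).

## Spatial domains and cell mapping

Neighborhoods default to the 6 nearest spots (the hex-grid degree of
ST/Visium arrays); a fixed-radius rule is available. K-means (seeded
k-means++, n_init = 10) runs on the concatenation
[w·own composition, (1−w)·neighborhood composition] with w = 0.5, i.e. equal
weights. Given a user-named core cluster, every other spot is labeled by its
Euclidean distance (array units) to the nearest core spot: edge within 2
units, border within 4, stroma beyond; a distance exactly at the threshold
counts as border. The 4-unit threshold is in array units — the platform's
physical pitch converts it to µm.

Cells map into spots by cosine similarity of topic profiles: each type's
quota is the largest-remainder apportionment of n_cells = 10 by the
deconvolved proportions, and the top-quota most similar cells of that type
are selected (ties by cell id; quotas beyond the pool recycle the ranked
list, with a warning). Pooled per-type counts of the selected cells give a
rough cell-type-resolved expression per spot.

## Serial-section alignment

Adjacent slides are coupled by fused Gromov–Wasserstein optimal transport
over topic profiles X and intra-slide Euclidean distance matrices D:

    F(Π) = (1−λ) Σ_ij c(X·i, X′·j) Π_ij + λ Σ_ijkl (D_ik − D′_jl)² Π_ij Π_kl

with uniform marginals (each spot carries equal mass — the formulation
implies no other weighting). The topic cost c defaults to squared Euclidean
distance between topic columns (bounded and symmetric); cosine and smoothed
KL are options. λ defaults to 0.1, i.e. weakly structural: the feature term
drives the matching and the Gromov term regularizes it; results on the test
geometries are insensitive to λ in [0.05, 0.5], but users should treat λ as a
sensitivity parameter. The solver is conditional gradient (Frank–Wolfe) with
the exact quadratic line search and an exact linear-programming optimal
transport solve (HiGHS) for the linearized subproblem; iteration stops on a
relative cost change below 1e-9 or after 100 iterations (the best iterate is
returned with a warning if the cap is hit). This exact small-scale solver is
appropriate for slide sizes up to a few thousand spots.

A coupling then yields the rigid transform minimizing the coupling-weighted
squared distances between matched spots: center both coordinate sets by the
coupling-marginal means, SVD the 2×2 weighted cross-covariance, and set
R = U·diag(1, det(UVᵀ))·Vᵀ — the determinant correction guarantees a proper
rotation even when the unconstrained optimum is a reflection. A coupling
whose mass is concentrated on too few spots makes the cross-covariance
singular and raises an error. Slide series are aligned sequentially (chained
pairwise, never one joint optimization), and the z coordinate is the section
index times a configurable spacing (default 1 array unit; real section
thickness is data the package cannot know).

## Problem sizes and numerical choices

The test and acceptance workloads use a 5-type, 500-cell, 200-gene reference
with 200 simulated spots for parameter recovery (median per-spot r ≈ 0.998,
absent-group RMSE ≈ 0.003), an 11-type reference of 660 cells for the
tumor-microenvironment simulator, and slides of 4–30 spots for the alignment
oracles — sizes at which every check runs in seconds while exercising the
full code paths. Probability tables are validated to 1e-8 (columns of φ, Z,
Y, T, C, SC) and 1e-6 (renormalized ST). All randomness flows through
`numpy.random.default_rng` seeds or scikit-learn `random_state`; reruns with
the same seed are bitwise identical.

## Known limitations

Proportions are relative: the package does not estimate absolute cell counts
per spot. Deconvolution quality degrades for cell types missing from the
reference (their mass is redistributed over the types the model knows) and
for transcriptionally similar subtypes. The spatial-domain thresholds (edge
radius 2, border threshold 4) operationalize a dataset-specific definition
and should be revisited per platform. The alignment assumes mostly-rigid
serial sections; non-rigid warping is out of scope.
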