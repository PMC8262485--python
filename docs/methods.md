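# Methods

`stcoloc` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the analysis chain used to localize immune cells
within spatial transcriptomic sections of injured kidney: reference
signature building, spot deconvolution, suppressed-rank secondary
immune labeling, colocalization odds-ratio inference, colocalization-
conditioned marker discovery, and regional expression analysis. This
note records the models, the default study conditions, the numerical
choices, and what the synthetic study does and does not demonstrate.

## The spot mixture model

A Visium-style spot is 55 μm across and overlies several cells, so its
expression profile is a mixture of cell-type profiles. We model the
expected counts of spot *s* as

    E[y_s] = L_s · Σ_k w_sk · μ_k ,   Σ_k w_sk = 1,  w_sk ≥ 0,

where `μ_k` is the expression profile of reference cluster *k*
(normalized to sum to 1), `w_sk` its compositional weight, and `L_s`
the spot's library size. Counts are negative binomial (gamma–Poisson)
around that mean. Mixing happens at the mean level — mix profiles, then
sample once — rather than by summing sampled cells; this keeps every
spot's expected profile analytically known, which is what makes the
deconvolution oracle tests exact. A deterministic mode rounds the means
instead of sampling for unit tests that need exact arithmetic.

## Reference processing

Cells are filtered by three rules applied in order, each cell charged
to its first failure: mitochondrial count fraction strictly above 0.50;
fewer than 200 detected genes (strictly); detected-gene count outside
the [10th, 95th] percentile band of the per-sample distribution, the
band computed on cells surviving the first two rules (the ordering is
a package choice; the rules themselves are standard). The mitochondrial
gene set is an explicit argument (`mt-` prefixed genes in the synthetic
data); no convention is hard-coded.

Normalization is log1p of counts-per-10k (CP10K). A regularized
variance-stabilizing transform would serve the same role; the pipeline
contract is agnostic to the normalizer and the step is pluggable.

Clustering is PCA → kNN graph → Leiden community detection (resolution
0.65 by default, 1.4 for subclustering; seeded, hence deterministic —
Leiden is used in place of Louvain for exactly that reproducibility).
Before PCA the matrix is reduced to the 500 highest-variance genes of
the log-normalized data and scaled to unit variance. Plain variance is
used deliberately instead of the mean-binned dispersion statistic:
with a few hundred cells and thousands of genes, sample covariance
eigenvalues of pure noise exceed the variance carried by a small
bimodal program, and the dispersion statistic empirically ranks such
programs (which are exactly what subcluster discovery must find) below
high-mean noise genes.

Marker discovery is a per-gene two-sided Wilcoxon rank-sum test with
midrank ties: exact enumeration of rank allocations when both groups
have ≤ 10 observations, the tie-corrected normal approximation
otherwise. Log fold changes are natural logs of pseudo-counted
(1e-9) CP10K means. Bonferroni-adjusted p-values drive marker
selection (mirroring the common single-cell convention);
Benjamini–Hochberg values are reported alongside. The signature matrix
holds, for the union of each cluster's top positive markers,
log1p of the cluster's arithmetic-mean CP10K — log of the mean rather
than mean of logs, so that `expm1(signature)` is an unbiased
linear-scale cluster profile.

## Deconvolution and labeling

Per spot, weights solve the non-negative least squares problem
`min ‖Sᵀw − y‖₂, w ≥ 0` over the genes shared between the spot matrix
and the signature, then are renormalized to sum to 1. The regression
runs on the **linear** CP10K scale (inputs are the log-normalized
matrices, converted internally): mixtures are additive in linear
expression and not after a log transform, and only on the linear scale
does noise-free mixture recovery hold exactly. NNLS is deterministic
and oracle-testable, which is why it stands in for heavier seeded
deconvolution machinery; the module interface admits other back-ends.
Spots with zero counts on the shared genes or with relative residual
above 0.99 are flagged unassigned.

The dominant label is the argmax score (alphabetical tie-break,
documented). The secondary label suppresses the dominant non-immune
clusters (all epithelial + endothelial by default, overridable) and
assigns the top-ranked immune identity only where it **strictly**
exceeds the fibroblast control score; ties fail the gate
(conservative reading of "at least exceed"). The control is
configurable because it is a modeling choice which non-immune score
the immune signal must beat.

## Colocalization inference

For an (epithelial E, immune I) pair, spots are cross-classified as
(dominant = E vs not) × (secondary = I vs not) into counts a, b, c, d;
spots labeled `none` count in the not-I margin. The association is the
odds ratio ad/bc with a one-sided exact Fisher p-value — P(A ≥ a)
under the central hypergeometric null, enumerated in log space — and a
95% Woolf CI with Haldane–Anscombe +0.5 on all cells whenever a cell
is zero. Pairs require a+b ≥ 5 dominant-E spots and a+c ≥ 1 labeled
spot (a guard against vacuous tables; no threshold is canonical).
Decisions mirror unadjusted p < 0.05; BH q-values are attached.
Condition-vs-reference comparison is done by computing each sample's
within-sample table and pairing records, flagging pairs significant in
the condition but not the reference; samples are never pooled into one
table. Only same-spot co-occurrence is tested, not spatial adjacency.

## Marker discovery conditioned on colocalization

Candidate chemotactic factors are genes separating E-dominant spots
colocalized with I from E-dominant spots colocalized with any other
immune cluster **or with the fibroblast control** (the union
convention; configurable). The test is exactly `find_markers` on the
two spot groups (asserted bitwise in the suite). The expression-
distribution gate test binarizes a gene as detected (count > 0) versus
not and applies the one-sided Fisher test to the detection table; a
Wilcoxon on the continuous values is reported alongside because the
binarization rule is a choice, not a given.

Subcluster profiling restricts the reference to the target clusters,
reclusters at resolution 1.4, and reports per subcluster the cell
count, origin-cluster composition, expressing fraction and mean of a
probe gene — the evidence pattern for a signaling subpopulation.

## Regional analysis

Total counts per spot are mapped with coordinates. Region membership
is purely geometric: in-tissue spot centers inside a closed circle or
simple polygon (boundary included — deterministic and easy to test).
"Size-matched" regions are enforced by a ±10% area tolerance with a
warning. Region DE pools all spots regardless of identity (Wilcoxon);
per-cluster spot-distribution shifts use the exact Fisher machinery
(one-sided in the direction of observed enrichment plus two-sided).
Pathway enrichment is a generic hypergeometric over-representation
test over user-supplied GMT gene sets with BH adjustment — the
inferential step without a bundled pathway database. Nuclei counts are
accepted only as an externally supplied table; no image analysis.

## The synthetic study conditions

The generator emulates a murine AKI experiment and its defaults are
the study conditions for every statistical claim in the test suite:

* 9 clusters — PT-S1S2 (300 cells), PT-S3 (420), TAL, DCT-CD,
  Endothelial, Fibroblast, Neutrophil, Macrophage, NK (150 each);
  proximal tubule dominates, as in real kidney references.
* 2000 genes. Generic baselines are lognormal(0, 1). Each cluster gets
  60 markers at fold 8 over a fixed low shared baseline (0.4):
  specificity comes from near-silence outside the cluster, not from
  extreme folds. Spreading the identity signal over many individually
  weak markers is deliberate: the aggregate keeps NNLS scores precise
  (few spurious immune labels) while no single marker separates spot
  groups strongly enough to crowd out the planted chemotactic gene in
  the DE ranking — mirroring real data, where identity programs are
  broad and chemotactic induction is a large fold on one gene.
* Named genes have fixed baselines (so planted signal strength does
  not swing with the seed): Mdk 25 (diffuse, high), Atf3 0.04
  (near-silent outside the stress state), injury genes Havcr1/Lcn2 3,
  eight immediate-early co-genes 6, seven `mt-` genes 14 (≈3%
  mitochondrial fraction in healthy cells).
* Negative binomial size 10 for cells, 50 for spots (spots average
  over many cells, so their relative overdispersion is lower); cell
  library ~5e3 (lognormal σ 0.35), spot library ~2e4 (σ 0.25).
* 34×34 row-offset hex grid at 100 μm spacing (1156 spots, 55 μm spot
  diameter). Compositions are Dirichlet draws with region-specific
  concentrations: an "outer stripe" circle (r = 800 μm) concentrated
  on PT-S3, a "cortex low" circle with the background composition, and
  the remaining tissue; fibroblast weight is substantial everywhere
  (the gate needs a real control signal), background immune weight is
  trace (0.002) — an uninjured background, so infiltration is the
  planted event and not a property of every spot.
* Planted truths: 20% of the PT-S3-dominant spots in the outer stripe
  receive Neutrophil weight 0.2 (renormalized); those same spots have
  Mdk multiplied by 4; the low region's library is scaled by 0.5 and
  its injury genes by 4; 20% of PT-S3 reference cells form a stress
  subpopulation with Atf3 ×6 plus the co-gene program ×10 (a
  single-gene subpopulation would not be clusterable even in
  principle).
* QC contaminants: 6% of cells with a 20–80× mitochondrial boost, 4%
  debris-like cells at ~4% of the normal library.
* `SimulationConfig.null()` is the matched null: no planted
  colocalization, unit chemotactic fold, immune background removed.
  Because secondary labels are functions of the expression being
  tested, label-conditioned groups are never literally identically
  distributed even under this null (selecting spots by a noisy immune
  score selects on its marker counts); null DE checks therefore also
  permute the secondary labels across spots — the same permutation
  construction the colocalization null uses — which breaks that
  coupling exactly.

What passing tests show — and do not. The generator plants mixtures,
markers, region structure and an infiltration pattern with known truth;
it does not simulate spatial autocorrelation beyond region membership,
doublets, ambient RNA, batch effects, platform-specific capture
biases, or segmentation noise. Recovery under these conditions
demonstrates the correctness and calibration of the pipeline's
statistics and estimators, not field performance on tissue data.

## Problem sizes and determinism

The default study (1156 spots, 1770 reference cells, 2000 genes)
deconvolves in a few seconds per replicate; replicate-based checks use
20 seeded replicates and the permutation null uses 1000 label
permutations. The deconvolution accuracy check uses a 506-spot grid.
All randomness flows from a single integer seed through separate
`numpy` Generator streams for gene structure, cells and spots, so
every artifact — including the full pipeline's CSV outputs and
manifest hashes — is byte-identical across reruns with the same
configuration.

## Known limitations

* NNLS proportions estimate expression shares, which equal cell-count
  shares only when clusters have comparable per-cell RNA content (true
  in the generator by construction, only approximately true in
  tissue).
* The fibroblast gate inherits the noise of small NNLS scores: a small
  number of background immune labels survive it (~1% of spots under
  the default conditions), which is visible as scatter in the
  secondary-label maps.
* The exact Wilcoxon path enumerates rank allocations and is only used
  for groups of ≤ 10 observations; larger groups use the tie-corrected
  normal approximation, standard but approximate.
* Colocalization is same-spot co-occurrence; neighboring-spot effects
  are out of scope.
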