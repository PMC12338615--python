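# Methods

`laminax` reimplements, as a tested pipeline, the analysis strategy used in
paired spatially-resolved transcriptomics (SRT) + single-nucleus RNA-seq
studies of cortical lamination: quality control and feature selection,
pseudobulk enrichment statistics, spatial registration of annotation
systems by marker t-statistic correlation, cross-validated NMF with
transfer of expression programs across modalities and regions,
within-donor cross-region differential expression, smFISH expressor
calling, and gene-set enrichment. Every stage is verifiable against a
synthetic-data generator with known ground truth; no stage requires a
download.

## Data model

Count matrices are held genes x observations (`CountAssay`), with gene and
observation metadata tables keyed by identifier. All joins across
datasets are by identifier with set semantics — file order never carries
meaning. `SpatialSample` couples an assay with spot coordinates and
tissue flags; spatial-domain labels (the output of an external clustering
such as PRECAST, or the generator's ground-truth bands) live in the
observation metadata and are consumed, not computed. Log normalization is
`log2(count / column_total * S + 1)` with `S = 1e4` (cp10k) or `1e6`
(CPM); all-zero columns map to all-zero columns.

## Quality control

SRT spots use the hard filter: out-of-tissue, all-zero, fewer than 20
detected genes, fewer than 20 total UMIs (both strict `<`), or a 100%
mitochondrial rate. Median-absolute-deviation outlier flags (3 MADs,
consistency constant 1.4826) are computed for reporting but deliberately
not applied to spots, because MAD flags preferentially remove white-matter
spots whose low complexity is biological; nuclei, in contrast, are
filtered by the MAD rules (low sum and detected on log1p scale, high mito
raw — the transform choice is exposed in configuration). Droplet
filtering uses the barcode-rank knee: ties are collapsed to their average
rank, a cubic smoothing spline of log10(total) on log10(rank) supplies
derivatives, the cliff is the steepest point and the knee the minimum
signed curvature at or above the cliff's rank; a flat or straight log-log
curve has no knee and is an error. The spline smoothing factor defaults
to `n/1000` which we found stable for curves of 1e3–1e5 barcodes; it is a
parameter. The knee filter is this package's droplet filter — the
Monte-Carlo ambient-profile test used by droplet tools is out of scope.

Feature selection ranks genes by Poisson deviance against the
constant-proportion null (mu_gj = column_total_j * gene_share_g, with
0·log 0 = 0), and the same null yields Pearson residuals
`(y - mu)/sqrt(mu)` as the PCA input of the GLM-PCA approximation.

## Spatially variable genes

The per-sample scorer is Moran's I of log-normalized expression on the
symmetrized, row-normalized k-nearest-neighbour spot graph (k = 6, the
hexagonal neighbourhood of the capture platform). It is a stand-in with
the same interface as a Gaussian-process scorer: any per-sample rank table
can be fed to the aggregation. The aggregation is the pipeline's real
contribution: per-sample dense ranks (ties by mean expression then gene
id), a gene's mean rank across samples (genes filtered out of a sample
contribute rank G_s + 1 — absence is penalized, not rewarded; a
present-only mode exists), and a replication rule: a gene is "replicated"
when it ranks in the per-sample top 1000 in at least 2 samples.
Replicated genes ordered by mean rank form the final list.

## Pseudobulk differential expression

Counts are summed over observations sharing a (group, sample) pair;
columns with fewer than 10 members are dropped and reported, and genes
failing a deterministic expression rule (CPM >= 1 in at least as many
columns as the smallest group) are removed before modeling. Models act on
plain `log2(CPM + 1)` (no prior-count dialect). The enrichment model
fits, per group, least squares of expression on a one-vs-rest indicator
plus covariate fixed effects (donor by default, since pseudobulk columns
are nested in donors); per-gene residual variances are shrunk by the
standard empirical-Bayes moderated-t construction — prior df and prior
variance estimated by moment matching on log s^2 via digamma/trigamma
equations, with the trigamma inversion by Newton iteration and the prior
df capped at 500 where shrinkage is numerically complete. The moderated
t has d0 + d_res degrees of freedom; BH adjustment is applied per group.
`prior_df=0` disables moderation and reproduces per-gene OLS exactly
(tested to 1e-10). The pairwise model is the same machinery restricted
to two groups, logFC = mean(a) − mean(b). Significance combines
`fdr < 0.05` and `|logFC| > 1.5`, both strict.

## Spatial registration

Two annotation systems are compared through their enrichment t-vectors:
the marker set is the union, over reference groups, of each group's top
100 genes by t on the common-gene intersection, and each (reference,
query) pair gets the Pearson correlation of the two t-vectors over that
set. Correlations over a zero-variance vector are reported missing, never
as 0. A confidence mask marks correlations at or above a threshold
(default 0.25 — the underlying studies do not print their cutoff, so it
is exposed in configuration).

## NMF and pattern transfer

The snRNA-seq log-normalized matrix is factorized by HALS (alternating
nonnegative least-squares column updates) minimizing the Frobenius loss,
with seeded uniform initialization scaled to the data mean, stopping at a
relative loss change below 1e-6; loadings are L2-normalized at the end
with scales absorbed into the weights, and the loss trace is
non-increasing (asserted in tests). An optional scale-invariant L1
soft-threshold on the loadings (`l1_w`) produces gene-sparse,
marker-concentrated patterns at the cost of strict loss monotonicity; the
default fit is plain.

The rank is selected by speckled cross-validation: a seeded random 5% of
entries is held out (masks that would blank a row or column are redrawn),
the model is fitted with EM-style imputation (masked entries replaced by
the current reconstruction each sweep), and the rank minimizing held-out
MSE (ties to the smaller rank) wins.

Patterns whose weights correlate (|Pearson r| >= 0.5; the threshold is
not printed by the underlying studies and is exposed) with technical
covariates — library size, detected genes, mito rate, and 0/1 dummies for
donor and sex — are flagged technical and excluded from annotation. Each
cell type is assigned the non-technical pattern with the highest mean
weight in that type (ties by specificity ratio, then lower index), and
each pattern records its top-10 loading genes.

Transfer into a new dataset restricts the loadings and the target to the
shared gene set in a common order and solves, per observation,
nonnegative least squares `min_{h>=0} ||x − W h||^2` (active-set solver;
deterministic). Pattern-positive differential expression classifies
spots by the literal nonzero rule (`h > 0`, with a configurable epsilon),
excludes and counts doubly-positive spots, and runs the pairwise
moderated-t model on the two classes pseudobulked by sample.

### Known limitation: the binary nonzero rule at desk scale

At the scale of the synthetic study (about 15 patterns, 2000 genes, 3000
nuclei), the fraction of spots with a strictly positive projected weight
for a pattern that is truly absent is not small: when a spot's counts on
the pattern's marker genes are all zero, the NNLS gradient for that
pattern is approximately zero, and the sign is decided by the alignment
of sampling noise with the pattern's small non-marker loading floor — a
residue of the additive shift degeneracy of NMF. The result is roughly
coin-flip positivity in the region that lacks the rare type, even though
the weight magnitudes separate by more than an order of magnitude (the
deep-band median weight is ~20 versus ~0.4 elsewhere). Factorizations
with many more patterns, genes and cells (as in the motivating studies)
empirically escape this regime. Magnitude-based summaries
(`mean_weight_by_group`) and the pattern-positive DE marker ranking are
robust; the binary nonzero-fraction contrast between regions is reported
but understates the localization at desk scale.

## Cross-region comparison

The two regions' pseudobulks are merged on shared genes with Tissue,
Donor, Layer and a combined Layer_Tissue factor; library normalization is
recomputed on the merged matrix, and shared donors are required. Per
gene, a linear mixed model with Layer_Tissue cell means and a donor
random intercept is fitted by REML, profiling the variance ratio
lambda = var(donor)/var(residual) by golden-section search on
log10(lambda) in [−8, 8] (tolerance 1e-8), in the shared eigenbasis of
Z Z^T so the covariance is diagonal for every lambda; the boundary
lambda = 0 is always compared and taken when at least as good. The
contrast between two Layer_Tissue levels uses Wald inference on the
normal reference; z is the signed probit transform of the p-value, which
coincides with the Wald statistic. Precision weights (the mean–variance
weighting of the cited voom-style workflow) are omitted: expression is
modeled homoskedastically per gene, and the DEG decision rule — |z| >
1.645 and |log2 FC| > 1.5, both strict — is preserved exactly. DEG
counts over all (region-A domain, region-B domain) pairs form a matrix
whose rows are scaled by the A-domain's total. LogFC–logFC concordance
classifies genes at a threshold of 1.25 into A-enriched, B-enriched,
both, or neither, with the Pearson correlation over all shared genes.

## smFISH quantification

Anchor gating runs k-means (k = 3, 20 seeded restarts, features
standardized — the underlying protocol does not state standardization, so
it is exposed) on the anchor gene's copy count and intensity; the top 2
clusters by centroid copy count are positive, and the implied minimum
copy count and intensity over positives are reported. Analysis is
restricted to a polygon (manual closed vertex list, boundary inclusive,
self-intersections rejected; or the convex hull of anchor-positive cells
in automatic mode). Copy counts are divided by area/median(area) — the
normalization-by-size reading; the multiplicative reading is available by
configuration. Expressors are called per gene and sample by a
two-component Gaussian mixture (EM, k-means initialization, 10 restarts,
tolerance 1e-8, variance floor 1e-6), "expressing" being posterior >= 0.5
for the higher-mean component; an all-identical input is degenerate and
all-negative. Coexpression reports the proportions expressing exactly
two and all genes, the conditional matrix P(j | i) with undefined rows
missing (never 0), and pairwise Spearman correlations with average-rank
ties.

## Gene-set enrichment and genome annotation

External DEG signatures are restricted to the local gene universe and
split at adjusted p < 0.1 into up (logFC > 0) and down (logFC < 0);
domain sets use fdr < 0.05 and logFC > 1 (strict). The two-sided
Fisher exact p sums hypergeometric probabilities at most the observed
table's (relative tolerance 1e-7), matching full enumeration to 1e-12;
BH runs across the test family. Mouse genes pass through a
user-supplied ortholog table (one-to-many resolved by a priority column
or dropped). Heritability annotations take the pseudobulk (columns with
>= 50 observations), apply the expression rule, drop duplicate symbols
and non-protein-coding genes, rank genes per group by normalized CPM
(default) or by the specificity ratio group-CPM/total-CPM (the source
phrase "specificity score" does not print a formula, so both are
implemented), keep the top decile, widen intervals by 100 kb each side
clipped at zero, and write 0-based half-open BED per group.

## The synthetic generator

`simulate_paired_regions` emulates the study design: region A (agranular,
bands L1/L2/L3/L5/L6a/L6b/WM) lacks the granular L4 band of region B
(L1–L6/WM); the same donors contribute one strip per region plus matched
nuclei. Counts are gamma-Poisson: per-gene lognormal base rates (13
abundant mito genes), band/type marker multipliers, per-(gene, donor)
lognormal effects (sd 0.1), and lognormal library sizes (mu 7.6, sigma
0.35 — about 2000 UMIs per observation at 2000 genes, matching typical
per-gene depth of spot data). Band programs span 40 genes at a 4-fold
(log2 = 2) in-band effect: laminar signatures are broad, and the
top-100-marker registration instrument presupposes that breadth. Two
small programs are "highly specific": a deep-L5 program (present in the
deep half of L5 in both regions and in a deep-L5 cell type) and a
rare-type program (the von-Economo-neuron analog: a 5%-prevalence cell
type and the deep half of region A's L5 only), each 10 genes with
baseline at 1% of a typical gene and in-target level 16x typical — the
on/off ratio of genes like PCP4 or GABRQ. Fifty "technical" genes scale
with library size only, planting a technical factor for the NMF filter.
The rare type also expresses the deep program at half strength, the
overlap that lets the factorization separate a rare-type pattern from the
deep-band pattern. A single seeded generator stream makes output
byte-identical per seed.

What the generator does not emulate: spatial autocorrelation beyond band
structure, cell-type mixtures within spots beyond the band programs,
ambient RNA, doublets, batch chemistry effects, and spot-level segment
geometry. Recovery results on this generator therefore show that the
implementations are correct and that the statistical instruments behave
as designed under the stated noise model — not that they would perform
identically on tissue data.

`simulate_smfish` scatters cells on a 500 x 500 um field with lognormal
areas, an anchor gene elevated (two positive levels, so k = 3 gating is
meaningful) only inside a horizontal band, and target genes as
two-component mixtures (N(20, 3^2) vs N(0.5, 0.5^2), clipped at zero)
with observed copies scaled by relative area and intensity linear in
copies. `simulate_low_rank` plants a block non-negative rank-r signal
(in-block loadings U(1,2), off-block U(0,0.1)) plus Gaussian noise
(sd 0.5 by default) for rank-selection studies.

## Problem sizes used in the shipped checks

The acceptance computations run the generator defaults (10 donors, 2000
genes, 140 spots per region-A sample, 160 per region-B sample, 3000
nuclei), a k = 15 factorization, rank cross-validation on 500 x 600
matrices over ranks 1–6 with 10 seeds, and a 2000-cell smFISH table.
These sizes keep the full suite and the acceptance script each under a
few minutes on one CPU while leaving every recovery margin wide.

## Command-line interface

One executable (`laminax`) exposes per-stage subcommands (simulate, qc,
svg, pseudobulk-de, register, nmf, project, cross-region, smfish,
enrich), each a thin file-in/file-out wrapper over the library functions,
driven by a YAML config with flag overrides and writing a JSON
run-manifest (inputs, parameters, seed, package version) next to its
outputs.
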