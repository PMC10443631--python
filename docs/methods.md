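# Methods

`ossa` reimplements, as a reusable and tested library, a family of
permutation-based statistics for asking whether one bone-marrow compartment
(in the motivating application: the skull calvaria, compared with scapula,
humerus, vertebra, pelvis and femur, alongside dura/meninges and brain)
transcriptionally diverges from the others in single-cell RNA-seq data.
This note records the models, the parameter choices that matter, what the
synthetic cohorts do and do not emulate, and the numerical conventions.

## Data model and preprocessing

A cohort is a sparse cells × genes UMI count matrix with per-cell
annotations (region, condition ∈ {naive, sham, mcao}, cell type, sample,
tissue class) and per-gene annotations (id, mitochondrial flag).  Derived
per-cell columns (`total_umi`, `mito_fraction`) are always recomputed from
the matrix, never trusted from sidecars.  On disk: Matrix Market
coordinate integers stored genes × cells, TSV sidecars, and a checksummed
manifest.  Floats in result tables are written at 17 significant digits so
write → read round trips are lossless.

**Quality control** is tissue-class aware: mitochondrial-fraction caps of
0.2 (bone), 0.3 (meninges) and 0.6 (brain); minimum UMI of 1000 (bone) and
500 (meninges, brain); a global 50,000-UMI cap; removal of cells with
doublet score > 0.1 (scores are consumed as input — computing them is out
of scope); and finally removal of genes expressed in fewer than 10
surviving cells.  Filters are applied in the fixed order mito → umi_min →
umi_max → doublet → gene filter so the per-filter attribution in the QC
report is deterministic; the surviving cell set itself is order-independent.

**Size factors** follow a cluster-aware median-of-ratios scheme standing in
for pooling deconvolution: cells are clustered (Leiden at resolution 1 on a
30-nearest-neighbour graph in PCA space of total-count/log1p data; clusters
under 100 cells merged into the neighbour they share the most edges with),
then θ_c = median over co-expressed genes of (cluster mean profile /
overall mean profile) and s_i = θ_c(i) · total_i / mean(total over the
cluster), rescaled to mean 1.  The interface accepts externally supplied
factors, so a pooling-deconvolution implementation can be swapped in.
Normalized expression is ln(count / s_i + 1), zeros preserved.

**Highly variable genes** are selected per sample on de-logged (expm1)
normalized values: dispersion = variance/mean, 20 quantile bins by mean,
within-bin centering/scaling by median and MAD, top 4,000 per sample.  The
merge rule across samples is this package's choice (the combination rule is
not pinned down by the upstream procedure): rank genes by the number of
supporting samples, tie-break by median normalized dispersion then gene id,
truncate to the per-sample budget.  Ties in the per-sample ranking are also
broken by gene id so the selection is invariant to gene column order.

**PCA** is an exact thin SVD of the centered matrix (no randomized solver),
eigenvalue_j = s_j²/(n−1), K = min(50, cells−1, genes), with component signs
fixed so each component's largest-magnitude loading is positive.  Whether
the divergence PCA should run on HVGs or all genes is not pinned down
upstream; the default here is the HVG subset, configurable per call.

## The divergence score

For one cell-type population, regions are compared one-vs-rest.  With
per-cell component scores and eigenvalues λ_j from a PCA of that
population, each component is regressed on the binary group indicator;
R²_j is the squared Pearson correlation (identical to the one-covariate
OLS R²), and

    V = Σ_j R²_j λ_j / Σ_j λ_j ∈ [0, 1].

Zero-eigenvalue components contribute zero to both sums.  Scores are only
computed when both groups hold ≥ 20 cells.  Significance: the region
labels are permuted (1000 by default); k counts permuted scores ≥ the
observed one; p = k/n_perm; a score is *significant* only at k = 0 — with
1000 permutations that is the only outcome compatible with "p < 0.0001",
and it is why the estimator is k/n rather than (k+1)/(n+1).  The PCA is
never recomputed per permutation: the decomposition does not depend on the
labels, so this is exact, not an approximation.  One shuffled label vector
per permutation is shared by all eligible regions of a cell type (an
independent-streams mode exists); permuted scores are compared per region
against that region's observed score.

Calibration: on cohorts with no planted structure the permutation p-values
are uniform (the test suite checks the fraction ≤ 0.05 across 400+
region-replicates).  Note the one-vs-rest construction means a single
strongly divergent region also raises the observed score of the *other*
regions (their "rest" contains the divergent one); this is a property of
the statistic, not a defect, and on null cohorts it vanishes.

**Region dendrograms**: per-region means of the 50 component scores →
Pearson correlation matrix between regions → complete-linkage agglomeration
on the Euclidean distance between correlation-matrix rows (mirroring the
observed behaviour of the common dendrogram implementation; a "1 − r,
average linkage" alternative is behind a flag), ties broken by
lexicographic region order, exported as Newick with merge heights converted
to branch lengths.

## Gap-split combinatorial differential expression

Per gene and cell-type stratum: order regions by descending mean
log-normalized expression (ties → lexicographic region order); compute the
gaps between consecutive means; split after the largest gap (ties → the
split closest to the top; all-equal means degenerate to k* = 1 with a
warning).  Two Welch t-tests: all cells of the high group vs all cells of
the low group (pooled cells, not per-region means), and the two regions
flanking the gap.  The final p is the max of the two and the final log2
fold change the min; a DEG requires p_final < 0.05 and lfc_final > 1
(> 0.5 for the neutrophil cross-compartment setting).  Fold changes are
log2 of the ratio of de-logged (expm1 of the mean log-normalized value)
group means with a 1e-9 pseudocount in numerator and denominator — the
ecosystem convention; the exact formula and base are not stated upstream.
Welch rather than Student everywhere because group sizes and variances are
systematically unequal; no multiple-testing correction inside this test
(the raw p < 0.05 rule is part of the procedure; BH is applied only in the
grouped t-tests below).  Degenerate zero-variance comparisons return p = 1
when means agree and p = 0 otherwise.

The whole scan is vectorized from per-region summary statistics (n, Σx,
Σx², Σexpm1) and is checked exactly, per gene, against a brute-force oracle
that evaluates every consecutive split with independent t-tests.

**Grouped t-tests** (DAMP / inflammation genes): Welch per listed gene
between two condition groups within a cell mask, Benjamini-Hochberg over
the listed genes only; absent genes yield NA rows, never imputation.
**Gene-set scores**: per-cell mean log-normalized expression over the
present set genes, summarized mean ± SD per group.  The default
pro-inflammatory set {Il6, Il1a, Il1b, Ifng, Il11, Il7d, Il7f, Il18, Tnf}
and anti-inflammatory set {Il1rn, Tgfb1, Il4, Il10, Il12a, Il13} are loaded
verbatim as printed in the source figure caption; "Il7d"/"Il7f" have no
standard mouse gene symbol (likely Il17d/Il17f) but are deliberately not
silently corrected.  **Proportion correlation**: scRNA-seq cell-type
proportions are re-expressed relative to a parent gate (as flow cytometry
reports them) before per-sample Pearson correlation; a zero parent gate
gives NA, excluded pairwise.

## Ligand-receptor permutation analysis

An interaction is (ligand, receptor, sender type, receiver type) within one
region.  Only cell types with ≥ 10 cells in *every* analysed region enter.
Within a region every eligible type is resampled to exactly 400 cells —
down-sampling uniformly without replacement (a uniform stand-in serving the
same balanced-background purpose as sketching; the sampler is pluggable),
up-sampling with replacement below the target.  The score is
μ = (mean ligand over senders + mean receptor over receivers)/2 on
log-normalized values; complexes written `A+B` are represented by the
member with the minimum per-type mean.  Pairs with an expressing fraction
below 0.1 in either partner are *inexpressible* and skipped (the referenced
framework's default floor, not restated upstream).  The null shuffles the
type labels of the balanced sample jointly, one shuffle per permutation
shared by every interaction of the region, which keeps cross-interaction
p-value differences coherent; p = k/n_perm with k = #(permuted μ ≥ observed
μ), and significance again means k = 0 at 1000 permutations.

Cross-region calls: *common* = significant in every region; *unique to r* =
significant in r with p > 0.95 in each other region (strict inequality;
with more than two regions the difference is evaluated against every other
region separately — the upstream aggregation is not stated).  Untested
interactions count as p = 1, which is what makes region-unique biology
detectable at all: a ligand truly private to one bone sits below the
expression floor elsewhere.

Two calibration caveats, verified by simulation and inherited from the
balanced-resampling design rather than introduced by this implementation:
(1) when a type is *upsampled*, duplicated cells sit together in the
observed groups but are split by permutations, inflating both p-value
tails; the permutation null is exactly calibrated only in the
downsampling-only regime, and the null-calibration tests are run there.
(2) when cell types genuinely differ (marker genes), per-type library
composition differs, so even genes with no type-specific biology acquire
small type-associated shifts after per-cell normalization; the test
correctly reports these as structure.  Null-calibration checks therefore
use exchangeable types (marker fold 1); uniqueness specificity checks use
the full marker structure.

## Synthetic cohorts

The generator emulates the study design: regions × conditions as samples,
coarse cell types with disjoint marker-gene blocks, lognormal baseline gene
abundances (normalized to relative abundances), lognormal library sizes
(median 2,500 UMI, σ_log = 0.35 — chosen so the bone 1000-UMI floor removes
only ~0.1 % of singlets), negative-binomial counts with size 10 (optionally
gene-varying), mitochondrial genes pinned to a 5 % expected share of
baseline expression, and doublets as sums of two same-sample singlet
profiles with doublet scores drawn above 0.1 (singlets below).  Planted
effects multiply the NB mean by 2^log2_fold for matching (region, type,
condition); planted ligand-receptor pairs reduce to two such effects.  The
`pinned_rel_abundance` option fixes chosen genes' baseline at a multiple of
the mean gene abundance — region-unique LR fixtures pin the pair at 0.005×
so its expressing fraction sits well below the 0.1 floor except where
planted up.  The full-design preset is 8 regions (calvaria, scapula,
humerus, vertebra, pelvis, femur, meninges, brain) × 3 conditions × 5 cell
types × 210 cells/sample ≈ 5,000 singlets and 1,200 genes, with real mouse
gene symbols embedded so the bundled ligand-receptor database and the
inflammation sets resolve.

Not emulated: batch effects and ambient RNA (the motivating analysis found
no batch correction necessary), spliced/unspliced layers, fine cell-type
hierarchies, and condition-dependent composition shifts.  Passing recovery
tests on these cohorts demonstrates the statistics do what they claim under
the stated generative assumptions; it does not certify behaviour under
violations of them (e.g. strong ambient contamination).

All randomness flows through a single seeded PCG64 generator per
simulation; identical configuration gives bit-identical cohorts.

## Pipeline and determinism

`run_pipeline` executes simulate → qc/normalize → divergence/dendrogram →
DE/gene sets → LR with a resolved-config JSON manifest (file checksums per
stage) and structured logs.  One global seed is expanded into per-stage
streams by hashing the stage name into a SeedSequence spawn key, so
toggling a stage never perturbs another stage's randomness; two runs with
the same config produce byte-identical result tables.  The bone-level
statistics (divergence, DE, LR) run on the `bone` tissue class by default;
the dendrogram spans all regions.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen once as the smallest sizes at
which the distributional claims are meaningful: oracle equivalences on
≤ 200-cell instances; calibration on 67 null cohorts of 6 × 300 cells
(402 region-tests); power and uniqueness over 20 seeds at 1000
permutations; gap-split recovery at 6 × 500 cells and 1,000 genes; the
end-to-end determinism check at the full ≈ 5,000-cell preset.
`scripts/acceptance.py` recomputes the same quantities with
seed-controlled replicates.

## Known limitations

- The cluster-median-of-ratios size factors approximate pooling
  deconvolution; per-cluster scaling couples cells within a cluster, and
  with few cells per cluster this coupling is visible to the permutation
  tests (see the calibration caveats above).
- The gap-split test assumes the informative partition of regions is a
  contiguous split of the mean ordering; multimodal patterns across bones
  are reported as their best contiguous approximation.
- p = k/n permutation p-values are granular at 1/n_perm; "significant"
  (k = 0) events have an irreducible false-positive rate of about
  1/(n_perm+1) per test.
- The bundled ligand-receptor database is a ~50-pair toy catalog for
  fixtures and demonstrations, not a curated resource.
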