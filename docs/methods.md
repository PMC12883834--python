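# Methods

`evoselect` reconstructs, at desk scale, an integrated workflow for
mapping multigenic evolutionary selection onto functional brain
networks. This note documents the model and procedure each module
implements, the parameters that matter, the numerical choices made
where the design was open, and what the synthetic benchmark does and
does not demonstrate.

## Data layers and notation

* **F(n, s)** — per-network z-scores at biopsy sites, derived from
  volumetric meta-analytic "uniformity" z-maps in MNI152 space
  (one NIfTI per network *n*, sampled at sites *s*).
* **G(g, s)** — gene × biopsy-site expression, with MNI mm coordinates
  per site.
* **ω(g, b)** — per-gene maximum-likelihood dN/dS along phylogenetic
  branch *b* (e.g. AMH, Neanderthal, Denisovan, Chimp, ancestral
  branches), with a per-cell status code describing the estimator
  outcome. ω > 1 indicates adaptive selection, ω ≈ 0 purifying
  selection.
* **C(g, c)** — cluster-level single-cell mean expression with
  supercluster / class / neurotransmitter / neuronal annotations.

## Volume-to-site projection

The sampling radius adapts to local biopsy-site density. For each
site, the squared Euclidean distance to its nearest other site is
computed (exactly, from coordinate differences, so a representable
squared distance such as 1² + 2² = 5 sits exactly on the boundary).
If that distance is at or below `density_threshold` (default 5 mm²)
the site takes the z-value of the voxel whose center is nearest
(ties broken toward the lexicographically smallest voxel index);
otherwise it takes a Gaussian-weighted average of voxel z-values,
w(d) = exp(−(d − μ)²/2σ²) with μ = 0 mm and σ = 20 mm on the
site-to-voxel-center distance. The Gaussian neighborhood is all
finite voxels within 3σ (weights beyond that are negligible) and the
average is normalized by the weight sum, making a constant volume a
fixed point of both rules. Non-finite voxels are excluded; if the
nearest voxel of a dense-regime site is non-finite the site falls
through to the Gaussian rule (logged). Geometry (neighbor lists and
weights) is computed once per grid and shared across networks.

Open choices resolved here: σ applies to distance in mm (not squared
distance), and the density rule compares against other biopsy sites,
not voxels — the rule is about site density.

## Correlation and network domains

r(g, n) is the Spearman rank correlation between each gene's site
profile and each network's site profile, computed over pairwise
complete observations (the subset of sites finite in both profiles is
re-ranked per pair); pairs with fewer than 3 complete sites are
missing. Networks are grouped into domains by Ward minimum-variance
hierarchical clustering of their correlation profiles (rows of r),
with squared Euclidean distance; the tree is cut at every k in a
search range (default [2, 12], clamped to n_networks − 1) and the k
maximizing the average silhouette width — computed on the same
squared-Euclidean distances — is selected, ties going to the smaller
k. Missing correlations are zero-imputed before clustering with a
logged count. Map overlap diagnostics use the Dice coefficient
2|A∩B|/(|A|+|B|) on thresholded masks (threshold configurable,
default z > 0) and the voxelwise Pearson correlation.

## Preparing the selection × correlation matrix

**Constraint handling.** Unstable estimates (including short-edge
instability) are always dropped. The relaxed mode additionally
recodes the degenerate estimator outcomes: dN = 0 → ω = 0
(purifying), identical sequences → ω = 0 (neutral), dS = 0 → the
maximum retained ω of that branch (adaptive). The conservative mode
drops all three.

**Omega rank normalization** (per branch, competition/minimum ties):

    ω̃_ij = (1 + #{k ≠ i : ω_kj < ω_ij}) / #{k : ω_kj present and > 0}

The denominator counts only strictly positive entries, so when a
branch holds zeros the largest values exceed 1; the formula is
followed literally and not capped (range [0, 1 + ε]). A branch with
no positive entries becomes all-missing.

**Correlation rank normalization** (per gene, maximum ties):

    r̃_ij = (1 + #{k ≠ j : r_ik < r_ij}) / n_networks

Each gene's best network maps to 1. Afterwards the per-gene minimum
entries are set to 0, and rows of genes whose |r| stays below 0.1 for
every network are zeroed entirely (the spatial-informativeness
filter; the absolute value is used because a strong negative spatial
correlation is equally informative — configurable). A second
retained-gene criterion at 0.75 is implemented on either raw or
rank-normalized rows; on normalized rows it is nearly vacuous (any
non-zeroed row peaks at 1), so the pipeline leaves it switchable and
off by default.

**Gene pools.** Per branch, the high pool is ω > 1 and the low pool
ω ≤ 10⁻⁹ (exact zeros after constraint handling). Pool sizes are
harmonized across branches by deterministic truncation to the
cross-branch minimum, keeping the most extreme raw ω (largest for
high, smallest for low; gene label breaks exact ties). A seeded
random-subsample alternative exists for sensitivity checks.

**Concatenation.** For each branch the analysis matrix is
[ω̃(·, b) ‖ r̃], restricted to spatially informative genes with a
defined ω̃ on that branch; column classes (omega/network) travel with
the matrix.

## Genetic-algorithm biclustering

A bicluster B = (g_sub, [b_sub n_sub]) is defined by a column subset
of the thresholded incidence matrix; its gene set is the rows
qualifying in every selected column (exact membership by default; a
relaxed row-consistency fraction is exposed). Incidence thresholds
are branch-specific: the omega-rank cutoff is placed at the extreme
normalized rank of the branch's harmonized pool (minimum over the
pool for high-ω runs, maximum for low-ω), so the omega-qualifying
genes are exactly the pool up to rank ties; network columns qualify
at r̃ ≥ 0.75. All comparisons are inclusive; missing never qualifies.

The search encodes candidates as binary masks over network columns
(the branch's omega column is forced into every candidate) and
evolves `popsize` candidates (default 250 for high-ω, 1,200 for
low-ω runs) split evenly over `nsubpops` = 4 isolated subpopulations
for `generations` = 100 generations, with tournament selection
(size 2), uniform crossover (rate 0.7), per-bit mutation (rate
1/#columns), one elite per subpopulation and no migration. Candidates
start sparse (≈2 network columns) so early candidates retain enough
supporting genes to create a fitness gradient. Fitness is the
bicluster size |genes| × #columns, optionally class-weighted
(`do_weighting`: omega ×2, network ×1); candidates below `min_genes`
= 5 genes or without a network column score zero. Ties are broken
toward the lexicographically smallest column mask.

`amountOfBiclusterSearches` = 20 independent searches run per branch
and direction; each emits its best valid candidate, whose qualifying
cells are then masked to zero (tabu) for the column classes whose
`variableClassNotOnTabuList` flag is False — the flag name is read
literally: True exempts a class from masking. The omega column is
never masked in the standard combos, since masking it would remove
genes from all later searches. The `global_optim` wrapper cycles, in
fixed order, through the four combinations
(do_weighting ∈ {T, F}) × (tabu flags ∈ {(T,T), (T,F)}), deriving a
child seed per iteration from the master seed; a count that is not a
multiple of 4 triggers a validation warning.

Similar biclusters — gene overlap strictly above 50% of the smaller
set, or identical network sets — are merged by connected components,
with scores recomputed on the union; the pass iterates to a fixed
point so merging is idempotent. At moderate network counts the
identical-network-set rule occasionally absorbs a small unrelated
bicluster into a planted one, diluting gene precision; this is
inherent to the rule, not a search failure, and is visible in one of
ten benchmark seeds.

Everything descends from one integer seed (per-branch/direction child
seeds are derived by hashing the master seed with the branch label
and direction), and repeated runs are byte-identical.

## Post-processing and cell-type enrichment

The top biclusters are selected by score, either overall (default 40)
or per branch (default 20), ties resolved toward the larger gene set
then stable input order. Each bicluster is assigned to every domain
its networks span. The branch × domain summary accumulates scores
per cell (normalized by the global matrix maximum; per-branch
normalization is available) and counts the union of contributing
genes per cell.

For enrichment, the cell matrix is restricted to the genes shared
with the ω table, and per cluster column every value strictly below
the column's 90th percentile (linear-interpolation quantile; values
at the cutoff kept) is zeroed. Each branch × domain gene set is
correlated with every cluster column as a point-biserial correlation
of the binary membership indicator over the shared universe
(mean-expression-of-set is available as an alternative statistic,
since the construction is not uniquely determined by the source
description). Correlations are z-scored across clusters within each
branch × domain cell (sample SD; at least 3 defined correlations
required; zero variance → no enrichment) and clusters with z
strictly above 1.96 are flagged. Flags are collapsed by
supercluster, class and neurotransmitter — counting, per metadata
group, the number of branch × domain cells with at least one
enriched cluster (presence, not multiplicity) — separately for
neuronal and non-neuronal clusters. Plain-text gene lists per
branch × domain are exported for external GO tooling.

## Synthetic benchmark

The generator plants known structure in all four layers: smooth
Gaussian-blob network volumes grouped into a domain partition
(same-domain networks share a base pattern), sites mixing 1 mm twin
pairs (dense projection regime) with jittered-lattice spacing
(Gaussian regime), module genes whose expression is
effect × z-scored network site-profile + N(0, noise_sd²) and whose ω
is planted extreme on one branch, background ω drawn
exponential-like in (0, 1) with per-branch scatterings of high
(6%), zero (6%) and degenerate-status (0.5% per code) cells, and one
cell cluster per module over-expressing the module's genes. Defaults:
800 genes, 300 sites, 12 networks in 4 domains, 6 branches, 50
clusters, 24³ grid of 2 mm voxels, two 40-gene modules (one high-ω,
one low-ω) with effect 2.0 and noise SD 0.5.

What passing shows: the full chain — projection, correlation,
normalization, pool construction, thresholding, GA search, merging,
domain assignment, enrichment — recovers structure that is actually
encoded in the data, at the planted effect size, and is fully
reproducible from a seed. What it does not show: performance on real
atlas data, whose expression covariance, spatial autocorrelation,
missing-data patterns and ω distributions are far richer than this
generator's; nor calibration of enrichment p-values (the z > 1.96
rule is a fixed cut, not a corrected test).

Two scale constraints matter when shrinking the generator: each
planted module must stay within the top-10% survivor budget of the
percentile filter, and with n networks the r̃ ≥ 0.75 rule admits only
each gene's top ⌈n/4⌉ networks, so planted network sets must be at
most that large (at the 12-network default, 3-network modules fit).

## Problem sizes and budgets in the shipped tests

Unit and acceptance tests run the GA at reduced budgets (popsize
60–120, 20–60 generations, 2–3 searches) — sufficient for the small
column spaces involved, as the exhaustive-enumeration comparisons
demonstrate — while the package defaults remain the full values
above. The end-to-end recovery benchmark runs biclustering on the
planted branches in both directions; recovery is scored as the best
gene-set Jaccard over all found biclusters against each planted
module.
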