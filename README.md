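# evoselect

Mapping multigenic evolutionary selection onto functional brain
networks.

`evoselect` is a research pipeline for neuroscientists and
evolutionary biologists who want to ask where in the brain's
functional architecture natural selection has acted. It links three
data layers of the adult human brain — task-associated functional
network z-maps (volumetric, MNI152 space), spatial gene expression at
biopsy sites *G(g, s)*, and per-gene, per-phylogenetic-branch dN/dS
selection estimates *ω(g, b)* (branches such as AMH, Neanderthal,
Denisovan, Chimp and ancestral splits) — and mines them jointly for
**biclusters**: gene sets under coherent selection on a branch that
also co-localize spatially with specific functional networks.
Downstream, biclusters are aggregated over network domains and tested
for cell-type enrichment against a cluster-level single-cell
taxonomy.

## The method in brief

1. **Projection.** Each network volume is sampled at the biopsy
   sites with a density-adaptive rule: sites whose squared distance
   to their nearest neighbor is ≤ 5 mm² take the nearest voxel's
   z-value directly; sparser sites take a Gaussian-weighted voxel
   average (μ = 0, σ = 20 mm), giving *F(n, s)*.
2. **Correlation.** Spearman rank correlation over sites (pairwise
   complete observations) gives *r(g, n)*; Ward clustering of network
   correlation profiles with silhouette-based model selection groups
   networks into domains.
3. **Normalization.** ω is rank-normalized per branch
   (ω̃ = (1 + #{ω_kj < ω_ij}) / #{ω_kj > 0}, minimum tie ranks) and
   r per gene (r̃ = (1 + #{r_ik < r_ij}) / |n|, maximum tie ranks),
   with per-gene minima and spatially uninformative genes
   (max |r| < 0.1) zeroed. Per branch, high-ω (> 1) and low-ω (≈ 0)
   gene pools are selected and size-harmonized across branches.
4. **Biclustering.** A seeded genetic algorithm searches the
   thresholded matrix [ω̃(g, b) ‖ r̃(g, n)] per branch and direction,
   with subpopulations, tabu masking of found biclusters, an optional
   parameter-cycling global-optimization loop, and merging of similar
   results (gene overlap > 50% of the smaller set, or identical
   network sets). A bicluster's score is its size.
5. **Summaries.** Top biclusters (per branch or overall) are assigned
   to the domains their networks span; branch × domain matrices
   accumulate normalized scores and unique gene counts; gene sets are
   correlated with percentile-filtered single-cell cluster profiles,
   z-scored within branch × domain, flagged enriched at z > 1.96, and
   collapsed by supercluster / class / neurotransmitter.

A synthetic-fixture generator plants known modules, domains and
enriched cell clusters across all four input layers, so the entire
pipeline is testable without any data download.

## Worked example

```python
from evoselect.fixtures import FixtureConfig, make_dataset, end_to_end_truth_check
from evoselect.gabi import GabiParams
from evoselect.pipeline import PipelineConfig, run_pipeline

dataset = make_dataset(FixtureConfig(seed=7))   # 800 genes, 300 sites, 12 networks
gp = GabiParams(amountOfBiclusterSearches=4, popsize=100, generations=50)
result = run_pipeline(PipelineConfig(gabi_high=gp, gabi_low=gp, seed=7, top_n=10),
                      dataset=dataset)

print(result.assignment.k)                       # 4
best = max(result.biclusters, key=lambda b: b.score)
print(best.score, len(best.genes), sorted(best.networks))
# 200.0 40 ['net00', 'net01', 'net02', 'net03']
print(end_to_end_truth_check(dataset.truth, biclusters=result.biclusters,
                             assignment=result.assignment,
                             enrichment=result.enrichment))
```

On this seed the domain clustering recovers the planted 4-domain
partition exactly (silhouette peaks at k = 4 with 0.958; adjusted
Rand index 1.0), the top bicluster holds all 40 genes of the planted
high-ω module on the AMH branch together with its domain's networks
(score 200 = 40 genes × 5 columns), the planted modules are recovered
with gene-set Jaccard 1.0 and 0.875, and both planted enriched cell
clusters are flagged (recall 1.0).

The same workflow runs from the shell:

```bash
evoselect fixtures --seed 7 --out data/
evoselect run --config pipeline.yaml     # paths + parameters in YAML
```

with intermediate stages also available as individual subcommands
(`project`, `correlate`, `domains`, `prep-omega`, `prep-corr`,
`gabi`, `postprocess`, `enrich`).

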