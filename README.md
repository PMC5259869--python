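# comodule

Joint **gene–miRNA co-module detection** in integrated coexpression networks.

MicroRNAs regulate genes post-transcriptionally, and groups of genes and
miRNAs that act together show up as densely connected subnetworks when paired
expression data are turned into networks. `comodule` finds such **co-modules**
— subnetworks containing genes *and* miRNAs together with gene–gene,
miRNA–miRNA *and* gene–miRNA connections — from a gene expression matrix and
a miRNA expression matrix measured on common samples, optionally anchored by
experimentally known gene–miRNA interactions (miRTarBase-style pair lists).
It is aimed at systems-biology analyses of tumor expression cohorts of the
TCGA kind, but any paired feature-by-sample matrices work.

## Method

1. **Networks.** Pearson correlations over the common samples are hard
   thresholded: an edge joins two features when |r| > τ. Within-type
   networks A_g (genes) and A_m (miRNAs) use a cutoff chosen so the degree
   distribution is approximately scale free (OLS of log₁₀ f(d) on log₁₀ d;
   study value τ = 0.60). The gene–miRNA matrix C is the union of the
   thresholded cross-correlations and the known interactions.
2. **Objective.** A hard assignment of nodes into K modules (indicators
   S_g, S_m) is scored by

       Ψ(S_g, S_m) = Σ_k  s_gkᵀ(2A_g − D_g)s_gk / s_gkᵀs_gk
                   + Σ_k  s_mkᵀ(2A_m − D_m)s_mk / s_mkᵀs_mk
                   + λ Σ_k s_gkᵀ C s_mk / (‖s_gk‖‖s_mk‖),

   where D is the degree matrix and λ (default 1) balances within-network
   modularity against cross-network connectivity.
3. **Spectral relaxation.** Normalizing the indicator columns and relaxing
   to an orthonormal frame turns maximization of Ψ into trace maximization
   of L = diag(2A_g−D_g, 2A_m−D_m) + λ[[0, C], [Cᵀ, 0]]; the top-K
   eigenvectors T are the optimum. Hard modules come from k-means on the
   row-normalized T, run per connected component.
4. **Scores and tuning.** T̃T̃ᵀ (rows of T scaled to unit norm) scores every
   node pair for co-membership. The gene–miRNA cutoff is chosen by the
   Mann–Whitney rank AUC of the known interactions among all gene–miRNA
   pair scores, averaged over a grid of K (study grids: τ ∈ 0.1…0.9,
   K ∈ 100…200).
5. **Filtering, merging, enrichment.** Clusters lacking either node type or
   any of the three edge types are discarded; modules from different K runs
   overlapping by more than 90% are merged; modules are tested against
   reference sets (miRNA genomic clusters, cancer-miRNA lists, GMT
   collections) with the hypergeometric upper tail and Bonferroni
   correction.

## Worked example

A planted dataset with three modules (10 genes + 4 miRNAs each sharing a
latent factor across 100 samples) plus background noise features:

```python
from comodule import (PlantedParams, generate_planted_dataset, correlation_matrix,
    threshold_adjacency, threshold_cross_adjacency, IntegratedNetwork,
    detect_modules, mean_auc_over_K)

ds = generate_planted_dataset(PlantedParams(
    n_modules=3, genes_per_module=10, mirnas_per_module=4,
    n_background_genes=8, n_background_mirnas=5,
    n_samples=100, loading=0.9, noise_sd=0.3, seed=7))

genes, mirnas = ds.gene_ids, ds.mirna_ids
a_g = threshold_adjacency(correlation_matrix(ds.expr_g), 0.6, genes)
a_m = threshold_adjacency(correlation_matrix(ds.expr_m), 0.6, mirnas)
c = threshold_cross_adjacency(
    correlation_matrix(ds.expr_g, ds.expr_m), 0.6, genes, mirnas)
net = IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=1.0)

assign, modules = detect_modules(net, k=3, seed=0)
valid = [m for m in modules if m.valid]
print(f"valid co-modules: {len(valid)}")
for i, m in enumerate(valid, 1):
    print(f"  module {i}: {len(m.genes)} genes, {len(m.mirnas)} miRNAs, "
          f"edges {m.edge_counts}")
auc = mean_auc_over_K(net, ds.known_pairs, k_grid=[3], seed=0)
print(f"rank AUC of known interactions: {auc.auc:.3f} "
      f"(q={auc.q} known, p={auc.p} other pairs)")
```

prints

```
valid co-modules: 3
  module 1: 10 genes, 4 miRNAs, edges {'gene_gene': 45, 'mirna_mirna': 6, 'gene_mirna': 40}
  module 2: 10 genes, 4 miRNAs, edges {'gene_gene': 45, 'mirna_mirna': 6, 'gene_mirna': 40}
  module 3: 10 genes, 4 miRNAs, edges {'gene_gene': 45, 'mirna_mirna': 6, 'gene_mirna': 40}
rank AUC of known interactions: 0.855 (q=36 known, p=324 other pairs)
```

Each planted module is recovered intact — 45 gene–gene edges is the complete
graph on its 10 genes — and the known interactions (planted mostly within
modules) rank far above chance (0.5); they tie with the other within-module
pairs, which is what caps the AUC below 1.

The same workflow is available from the shell:

```sh
comodule simulate --preset small --seed 7 --out data/
comodule run --gene-expr data/gene_expression.tsv \
             --mirna-expr data/mirna_expression.tsv \
             --known-pairs data/known_pairs.tsv \
             --clusters data/mirna_clusters.tsv \
             --out run/
```

which writes cleaned matrices, edge lists, the AUC tuning table, merged
modules (`modules.json`, `modules.tsv`), enrichment tables and a
`manifest.json` from which the run can be replayed exactly.

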