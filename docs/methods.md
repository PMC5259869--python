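# Methods

## Model

The package treats paired expression data as a two-layer network. Nodes are
genes and miRNAs; within-layer edges join features whose expression profiles
correlate strongly across samples, and between-layer edges join gene–miRNA
pairs that either co-express strongly or are known to interact. A co-module
is a subnetwork that is dense in all three edge types at once — the working
assumption being that a miRNA and its functionally coupled genes co-vary
across tumors, so regulatory units appear as correlation blocks spanning
both layers.

Module quality of a hard K-way assignment (indicator matrices S_g, S_m, one
module per node) is

    Ψ = Σ_k s_gkᵀ(2A_g − D_g)s_gk / s_gkᵀs_gk
      + Σ_k s_mkᵀ(2A_m − D_m)s_mk / s_mkᵀs_mk
      + λ Σ_k s_gkᵀ C s_mk / (‖s_gk‖₂‖s_mk‖₂).

The within-layer terms are Rayleigh quotients of 2A − D: a module scores
positively when its nodes have more than half of their degree inside the
module. The cross term counts gene–miRNA connections inside the module,
normalized by the two side sizes so that modules with very unbalanced gene
and miRNA counts are not favored. λ ≥ 0 weighs the cross-layer term
(default 1: within- and between-layer connectivity count equally). A module
empty on one side contributes 0 to its cross term (the limit of the
normalized expression).

## Spectral relaxation

Scaling each indicator column to unit norm and relaxing the binary
constraint to orthonormality reduces the problem to

    max Tr(TᵀLT)  s.t. TᵀT = I_K,
    L = diag(2A_g − D_g, 2A_m − D_m) + λ [[0, C], [Cᵀ, 0]],

solved exactly by the eigenvectors of the K algebraically largest
eigenvalues of L. Note L is indefinite (2A − D is not a graph Laplacian up
to sign), so "largest algebraic", not "smallest", is the right end of the
spectrum. Hard modules are then k-means clusters of the rows of T.

A hard assignment maps into the relaxed feasible set as the orthonormal
columns u_k = [s_gk/‖s_gk‖; s_mk/‖s_mk‖]/√2 (a module with one empty side
uses its non-empty normalized side alone, which already has unit norm).
Then u_kᵀLu_k = (ψ_gk + ψ_mk)/2 + λ·cross_k, and since the u_k form an
orthonormal K-frame whenever all K modules are non-empty, the spectral
optimum bounds this normalized discrete objective from above. Assignments
with empty modules have no normalized counterpart and are excluded from the
bound (with negative eigenvalues the top-K eigenvalue sum can genuinely lie
below the value of a smaller frame). `bruteforce_max_normalized_objective`
enumerates all surjective assignments on small networks and is used to
verify the bound instance by instance.

## Numerical choices

- **Eigensolver**: dense symmetric `scipy.linalg.eigh` on the requested
  index range; eigenvalues returned non-increasing. Eigenvector signs are
  arbitrary, so each column is flipped to make its largest-magnitude entry
  positive — required for bit-reproducible output.
- **k-means**: scikit-learn, k-means++ seeding, 50 restarts, tolerance 1e-6,
  fixed seed. By default it runs on the row-normalized embedding T̃ (the
  same normalization the pair scores use); a switch allows raw T.
- **Connectivity**: the relaxation is stated for a connected integrated
  network. `build_integrated_matrix` refuses disconnected input;
  `detect_modules`/`embed_network` implement the per-component strategy
  instead: every connected component with at least two nodes receives at
  least one of the K embedding columns (allocation proportional to
  component size, largest-remainder rounding, capped at the component
  size — so the effective number of clusters can exceed a too-small K),
  and each component is embedded and clustered on its own block of L.
  Isolated nodes are pooled into a single unassigned cluster, which can
  never pass module filtering.
- **Thresholding** is strict (|r| > τ), which matters at grid boundaries;
  correlations of constant features are set to 0 and logged rather than
  propagating NaN.
- **Scale-free fit**: f(d) is the raw count of nodes with degree exactly d;
  zero-degree nodes are excluded (log undefined) and no log-binning is
  applied. The acceptance level min R² = 0.8 is a configuration knob, not a
  derived quantity. Raw per-degree counts make the tail noisy: even genuine
  preferential-attachment graphs of 1000 nodes show R² anywhere from ~0.75
  to ~0.95 across random seeds, so the fit discriminates degree laws but is
  not a sharp test statistic.
- **Rank AUC**: average ranks for ties, making the statistic exactly the
  normalized Mann–Whitney U. The pair universe is restricted to gene–miRNA
  pairs whose endpoints both lie in a non-trivial connected component:
  isolated nodes have no embedding signal and their scores are an arbitrary
  0 (the count of excluded pairs is logged). During threshold tuning, C is
  built from coexpression alone — known interactions are held out of the
  network so the AUC they define is not circular — and only after the
  cutoff is fixed are they folded into C. Grid ties go to the smaller
  threshold (the sparser cross network).
- **Merging**: overlap percentage is |A∩B| / min(|A|,|B|) over the combined
  gene+miRNA node sets, merged strictly above the cutoff (default 0.90) and
  iterated to a fixed point, so the operation is idempotent; min makes
  nesting count as full overlap, which is the behavior wanted when
  de-duplicating across K runs (Jaccard is available as an alternative).
- **Enrichment**: upper hypergeometric tail P(X ≥ observed) via the
  survival function; Bonferroni multiplier equals the number of pairs
  actually tested (those meeting the minimum overlap, default 3), not all
  possible pairs. The default background universe is the miRNAs present in
  the analyzed network, the conservative in-analysis choice; it is a
  parameter so wider universes can be tried. miRNA identifiers are
  harmonized by lower-casing and stripping the species prefix, collapsing
  -5p/-3p arm suffixes only when the exact id is absent from the universe.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `gene_top_n` | 3200 | most-variable genes kept before network building |
| `coexpr_tau` | 0.60 | within-type \|r\| cutoff (scale-free regime) |
| `gm_tau_grid` | 0.1…0.9 step 0.1 | candidate gene–miRNA cutoffs |
| `k_grid` | 100…200 step 10 | module counts scanned (full-cohort scale) |
| `lam` | 1.0 | cross-layer coupling weight λ |
| `merge_overlap` | 0.9 | strict overlap fraction for cross-K merging |
| `min_overlap` | 3 | minimum overlap for an enrichment test |
| `alpha` | 0.05 | Bonferroni-adjusted significance level |
| `min_r2` | 0.8 | scale-free acceptance level |

Variance is the unbiased (n−1) sample variance; probe-level rows are
averaged per sample (missing-aware) before gene-level mean imputation, with
a configuration switch for the opposite order since either is defensible.

## Synthetic data

`generate_planted_dataset` draws, per module, one standard normal latent
factor per sample; member genes and miRNAs are loading × factor +
N(0, noise_sd), giving expected within-module correlation
loading²/(loading² + noise_sd²) ≈ 0.74 at the defaults (loading 0.85, noise
0.5) — comfortably above the 0.60 cutoff, while between-module and
background correlations are near 0. Background features are unit-variance
noise so their scale resembles module features (variance ≈ 0.97) and
variance filtering is not a trivial separator. Known pairs are Bernoulli:
rate 0.3 for within-module gene–miRNA pairs, 0.005 for every other pair.
The standard preset has 6 modules of 30 genes + 5 miRNAs, 50 background
genes, 20 background miRNAs and 200 samples; tests run detection at this
scale and tuning over K ∈ {4, 6, 8} and τ ∈ {0.4, 0.6, 0.8}, which keeps
the whole suite in seconds while leaving the module-recovery problem
non-trivial in node count.

What the generator does not emulate: heavy-tailed expression noise, batch
and copy-number structure, correlated noise across features, the asymmetric
(repressive) sign structure of real miRNA regulation, and realistically
scale-free network topology — the planted blocks give near-complete module
subgraphs. Passing tests therefore demonstrate correctness of the machinery
and recoverability under the assumed block-correlation model, not
performance on real tumor cohorts.

A consequence of the clean block structure worth knowing: with one
embedding column per planted component, row normalization collapses all
within-module pair scores to exactly 1 and all cross-component scores to
exactly 0. Known pairs then tie with the other within-module pairs, and any
known pair planted across modules can at best tie the zero mass, which caps
the attainable rank AUC (≈0.86–0.90 at the default rates) well below 1
even under perfect module recovery; giving a component a second eigenvector
spreads its scores over [−1, 1] and lowers the AUC further. Real data, with
its graded correlation structure, does not produce these exact ties.

## Limitations

- K must be supplied; the cross-K merge mitigates but does not remove the
  choice.
- One module per node per run; overlapping membership only arises across
  runs before merging.
- In-sample AUC tuning (as in the study design) — no held-out validation.
- Hard thresholding discards correlation magnitude; soft/weighted networks
  are out of scope.
- Dense eigendecomposition is O(N³); fine for a few thousand nodes
  (seconds at the 3200 + ~600 study scale), not for genome-wide
  unfiltered inputs.
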