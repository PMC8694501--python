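# moclust

Multi-omics consensus-ensemble subtyping for cancer cohorts.

Molecular subtypes of a tumour cohort are rarely stable under a single
clustering algorithm: kernel-fusion, matrix-factorization and resampling
methods each impose different structure on the same data. `moclust`
implements the consensus-ensemble strategy used in multi-omics cancer
subtyping studies (the motivating application is prostate cancer profiled
on mRNA, lncRNA, miRNA, DNA methylation and somatic mutation layers):
cluster the cohort with several integrative algorithms, fuse all partitions
into a co-clustering consensus matrix, cut that matrix into the final
subtypes, and carry the subtypes through marker derivation, external-cohort
reproduction and survival statistics. Because the real cohorts cannot be
redistributed, the package ships a first-class synthetic-data generator
that plants known subtype structure, so every stage is testable end to end.

## The method

**Integrative clustering.** Five algorithms spanning the main families,
all behind one interface (`moclust.cluster.run_algorithm`):

* `snf` — similarity network fusion: per-layer scaled exponential kernels
  `W(i,j) = exp(−d²(i,j)/(μ ε_ij))` with the local scale
  `ε_ij = (mean d to i's K nearest + mean d to j's K nearest + d(i,j))/3`,
  cross-layer diffusion `P_v ← S_v · mean(P_w, w≠v) · S_vᵀ`, spectral
  clustering of the fused graph;
* `cc` — Monti-style consensus clustering (repeated k-means on 80%
  subsamples, hierarchical cut of the co-clustering frequency matrix);
* `intnmf` — joint NMF, `min Σ_v θ_v ‖X_v − W H_v‖²_F` with a shared
  sample-factor matrix `W` and layer weights `θ_v = 1/‖X_v‖²_F`;
* `coca` — cluster-of-clusters on stacked one-hot layer memberships;
* `spectral` — spectral clustering of one kernel on the concatenated
  z-scored continuous layers.

**Consensus ensemble.** The M partitions are fused into the consensus
matrix `M(i,j) = (1/M) Σ_m 1[labels_m(i) = labels_m(j)]`; Ward-linkage
clustering of `1 − M` gives the final subtypes, with the proportion of
ambiguous clustering (PAC) and consensus silhouette as stability measures.

**Cluster number.** The gap statistic (uniform-box reference, Tibshirani's
one-standard-error rule) and a clustering prediction index (subsample /
predict held-out samples / measure ARI agreement) are combined by averaging
their min-max-normalized curves over the candidate range.

**Markers and nearest-template prediction.** Top-N (default 100)
upregulated subtype markers by one-vs-rest Welch t with Benjamini–Hochberg
control; external cohorts are classified by cosine distance to binary
subtype templates over the marker genes, with a matched random-gene-set
permutation null and BH FDR across samples.

**Downstream statistics.** Single-sample GSEA (rank-weighted running-sum
enrichment) and mean-z signature scores with Kruskal–Wallis subtype
comparisons; Kaplan–Meier/log-rank recurrence-free-survival separation;
multivariable Cox proportional-hazards adjustment (Efron ties) for age,
PSA, T stage and Gleason; tumour mutation burden and per-gene mutation
enrichment with exact small-table tests.

## Worked example

```python
import moclust
from moclust.cluster import ALGORITHMS, AlgorithmParams, run_algorithm
from moclust.ensemble import build_consensus_matrix, ensemble_labels, adjusted_rand_index
from moclust.markers import derive_markers
from moclust.survival import km_logrank

cfg = moclust.SimulationConfig(seed=7)          # n=300, 3 subtypes, 5 layers
dataset, truth = moclust.simulate_multiomics(cfg)

results = [run_algorithm(a, dataset, 3, AlgorithmParams(seed=0)) for a in ALGORITHMS]
for r in results:
    print(f"{r.algorithm:>8}: ARI vs truth = {adjusted_rand_index(truth.true_labels, r.labels):.3f}")

consensus = build_consensus_matrix(results)
ens = ensemble_labels(consensus, 3)
print(f"ensemble: ARI = {adjusted_rand_index(truth.true_labels, ens.labels):.3f}, "
      f"PAC = {ens.pac:.3f}, silhouette = {ens.mean_silhouette:.3f}")

markers = derive_markers(dataset.layer("mRNA"), ens.labels, n_top=100)
print("markers per subtype:", {s: len(g) for s, g in markers.markers.items()})

km = km_logrank(dataset.clinical["rfs_months"], dataset.clinical["rfs_event"], ens.labels)
print(f"log-rank: chi2 = {km.chi_square:.1f}, p = {km.p_value:.2e}")
```

prints

```
     snf: ARI vs truth = 1.000
      cc: ARI vs truth = 1.000
  intnmf: ARI vs truth = 0.694
    coca: ARI vs truth = 1.000
spectral: ARI vs truth = 1.000
ensemble: ARI = 1.000, PAC = 0.136, silhouette = 0.955
markers per subtype: {1: 100, 2: 100, 3: 100}
log-rank: chi2 = 165.5, p = 1.15e-36
```

The per-algorithm adjusted Rand indices measure how well each method alone
recovers the planted subtypes (joint NMF is the weakest on this draw); the
ensemble matches the truth exactly with low clustering ambiguity (PAC),
each subtype contributes a full top-100 marker list, and the subtypes
separate recurrence-free survival decisively.

The same analysis runs from the shell: `moclust run --seed 7 --out run/`
executes every stage (simulate → select-k → cluster ×5 → ensemble →
markers → NTP on a batch-shifted external cohort → scoring →
survival/mutation tables) and writes plain TSV/GMT/JSON artifacts plus a
manifest; rerunning resumes from the manifest. Individual stages are
exposed as `moclust simulate|cluster|ensemble|select-k|markers|ntp|score|
survival|mutstats`.

## Layout

| module | contents |
| --- | --- |
| `moclust.simulate` | synthetic multi-omics cohorts with planted subtypes, survival, external cohorts |
| `moclust.io` | `OmicsLayer` / `MultiOmicsDataset` / `GeneSetCollection`, TSV + GMT I/O |
| `moclust.cluster` | the five integrative clustering algorithms |
| `moclust.ensemble` | consensus matrix, ensemble cut, PAC, ARI |
| `moclust.model_selection` | gap statistic, clustering prediction index, combined choice |
| `moclust.markers` | marker derivation, templates, nearest-template prediction |
| `moclust.scoring` | ssGSEA and mean-z signature scores, Kruskal–Wallis comparisons |
| `moclust.survival` | KM/log-rank, multivariable Cox, TMB, mutation enrichment |
| `moclust.pipeline` / `moclust.cli` | end-to-end orchestration and the `moclust` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
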