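# Methods

This note records the modelling assumptions, defaults and open design
choices behind `moclust`. It documents what the code computes; every
empirical number quoted in the README is printed by the code itself.

## Synthetic cohort model

The generator emulates a prostate-cancer-style multi-omics cohort. Each
sample carries a latent subtype drawn from a multinomial with configurable
proportions (default: n = 300, k = 3, balanced). Layers:

| layer | kind | features | informative / subtype | effect |
| --- | --- | --- | --- | --- |
| mRNA | gaussian | 1000 | 100 | mean shift δ = 1.0 |
| lncRNA | gaussian | 200 | 20 | δ = 1.0 |
| miRNA | gaussian | 100 | 10 | δ = 1.0 |
| methylation | beta | 500 | 50 | δ = 1.0 on the logit scale |
| mutation | binary | 50 | 5 | rate 0.35 vs baseline 0.05 |

Gaussian features are N(0, σ²) noise (σ = 1) with +δ added on a subtype's
informative block; blocks are disjoint within a layer. Methylation values
are the inverse-logit of such Gaussians, so they lie strictly in (0, 1)
and the planted shift acts on the logit scale. Mutation features are
Bernoulli indicators with an enriched rate in the informative subtype.
This scale is roughly one fifth of the cohort the package is modelled on
(1526 mRNAs / 242 lncRNAs / 30 miRNAs / 1073 CpGs / 23 mutant genes) and
keeps a full pipeline run to seconds while preserving the
features-per-informative-feature ratio.

Survival is exponential per subtype — the simplest model consistent with
the proportional-hazards analyses downstream — with monthly event hazards
(0.08, 0.02, 0.01), so subtype 1 is the aggressive subtype, and uniform
censoring on (24, 120) months (a realistic recurrence-free-survival
follow-up window; the observed event fraction is ~60–70% for the
aggressive subtype). Clinical covariates: age ~ N(66, 7²) clipped to
[45, 85], PSA log-normal(2.2, 0.6), ordinal T stage with population-like
frequencies; these are independent of subtype by default so the Cox
adjustment has a known null, with a `subtype_linked_clinical` switch for
confounded scenarios. The per-subtype probability of a high (≥8) Gleason
score is (0.23, 0.618, 0.097), echoing the skew reported in the
motivating cohort.

External validation cohorts reuse the first gaussian layer's
informative-feature means and add a per-feature offset ~ N(0,
batch_shift_sd²), emulating a location (platform/batch) shift — the
failure mode nearest-template prediction must tolerate. The generator does
**not** model feature–feature correlation (co-expression, co-methylation),
scale differences between batches, copy-number structure or missingness;
passing tests therefore demonstrate correctness of the machinery under
clean location-shifted signal, not robustness to every artefact of real
arrays.

## Clustering algorithms

Ten published integrative algorithms were behind the subtyping this
package re-implements; re-creating all ten verbatim is out of scope.
Five natively implemented algorithms span the kernel-fusion (SNF),
resampling-consensus (Monti), joint matrix-factorization (intNMF-style),
cluster-of-clusters (COCA) and baseline spectral families, and the
ensemble accepts any M ≥ 2 partitions, so further algorithms can be
plugged in. Defaults follow each family's original conventions:
K neighbours = min(20, n/10), kernel bandwidth scale μ = 0.5, 20 diffusion
iterations, 100 resampling rounds at 80% subsampling, 10 k-means/NMF
restarts, NMF tolerance 1e-5 of the objective.

Numerical choices worth noting:

* the SNF fused matrix is symmetrized and Sinkhorn-scaled after diffusion
  so it is simultaneously symmetric and row-stochastic (within 1e-6),
  which the spectral step and its tests rely on;
* k-means uses k-means++ with fixed seeds; consensus resampling uses 2
  inits per round (stability comes from aggregation, not per-round
  optimality);
* binary layers enter kernels via Hamming fraction distance, enter COCA
  via a k-modes partition (majority-vote updates), and enter joint NMF
  directly (values already non-negative); continuous layers are
  min-subtracted per feature before NMF;
* labels are 1-based and renumbered consecutively; a hierarchical cut that
  yields fewer than k groups warns and reports the achieved k.

## Consensus ensemble

Consensus entry (i,j) = fraction of algorithms co-clustering i and j.
Ward linkage on 1 − consensus gives compact blocks; final subtypes are
renumbered by decreasing size so outputs are reproducible across runs.
PAC uses the conventional (0.1, 0.9) ambiguity band (configurable). All
algorithms are weighted equally; no soft consensus.

## Cluster-number selection

The gap statistic follows the classic construction: pooled within-cluster
dispersion W_k from k-means, B uniform reference draws over each feature's
observed range (the simpler box, not the PCA-rotated variant), Gap(k) =
mean log W*_k − log W_k, s_k = sd·√(1+1/B), choose the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}.

The clustering prediction index is operationalized as a
subsample/predict/agree score: cluster an 80% subsample, assign held-out
samples to the nearest subsample centroid, and average the ARI between
stitched and full-data labels over B rounds. The original index the name
comes from is described only informally in the literature this package
follows; this construction (in the spirit of intNMF's cluster-prediction
index) is the package's explicit definition. A caveat that follows from
it: in very low dimensions an arbitrary k = 2 split of structureless data
retains some reproducibility, so the "noise ⇒ CPI ≈ 0" intuition holds in
the high-dimensional regime the package targets (hundreds of features),
which is how the tests exercise it.

The combined rule averages min-max-normalized CPI and gap curves and takes
the argmax; an externally supplied prior k (e.g. an established
classification's class count) only breaks exact ties.

## Markers and nearest-template prediction

Marker scoring uses one-vs-rest Welch t with BH control at 0.05 —
deliberately the simplest defensible differential statistic, isolated
behind `derive_markers` so a moderated-t variant can be swapped in. Only
upregulated genes qualify; a gene significant for several subtypes is
assigned to the subtype with the larger statistic, making the lists
disjoint by construction. Marker lists come from the mRNA layer, since
external validation cohorts are expression-only.

NTP distance: cosine between the sample's per-gene z-scores restricted to
a template's support and the all-ones template of that size. The
permutation null draws, per replicate, one random gene set per template
(matched sizes, from all genes) and takes the minimum distance — mirroring
the argmin selection of the observed statistic. Computing the null
without this matching (single random sets against a min-over-templates
observed distance) is anti-conservative; the matched construction makes
observed and null statistics exchangeable under a structureless cohort, so
p-values are super-uniform, which the tests verify by KS. Samples failing
the FDR cutoff keep their argmin label but are flagged unclassifiable, so
survival analyses can run with or without them.

## Signature scoring

ssGSEA uses integer rank values 1..N (highest expression = N), weight
exponent α = 0.25, and the running-sum difference between the weighted
in-set CDF and the unweighted out-of-set CDF, summed over all positions.
Scores are invariant to any strictly monotone per-sample transform, since
only ranks enter. Immune-infiltration style analyses are operationalized
as ssGSEA over marker gene sets — a deliberate simplification, not a
deconvolution model. The mean-z scorer is provided for single-signature
comparisons.

## Survival and mutation statistics

Kaplan–Meier, the G-group log-rank test and Cox regression are delegated
to lifelines; Cox uses Efron tie handling (ties are common at month
resolution) and expands categorical covariates against explicit reference
levels (subtype reference = best-prognosis group; lowest T stage and
Gleason as references), so output tables are directly comparable across
runs. Non-convergence, separation warnings or extreme coefficients yield a
flagged fit rather than an exception. Tumour mutation burden is a count
over the gene panel (the panel is synthetic; no per-megabase scaling).
Per-gene enrichment uses the chi-square test, switching to an exact
conditional test when any expected cell is below 5: scipy's Fisher test
for two groups, and for k > 2 groups a multivariate hypergeometric
enumeration over all allocations of the mutated count (feasible because
mutated counts in a 50-gene panel are small; a chi-square fallback guards
the rare large case).

## Problem sizes and determinism

Default analyses run at the generator's native scale (n = 300, ~1900
features). Monte-Carlo summaries use 20 cohorts for cluster-number
selection accuracy, 50 replicates for Cox recovery, 100 for log-rank
power, and 200 null samples for NTP calibration — sizes at which the
binomial error of the reported rates is a few percent. Every stochastic
step takes an explicit seed; fixed seeds give bit-identical outputs,
including across pipeline resumes.

## Known limitations

* No modelling of inter-feature correlation; clustering difficulty at a
  given effect size is optimistic relative to correlated real data.
* The ensemble assumes all contributed partitions are over identical
  sample sets; no handling of partially overlapping cohorts.
* The exact enumeration test grows combinatorially with the mutated count
  and the number of groups; it is intended for small panels.
* No Bayesian integrative clustering, multiple-kernel learning or
  perturbation clustering; no copy-number, fusion or drug-response
  modelling.
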