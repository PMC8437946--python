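# Methods

## Model

An observed bulk methylation fraction at locus *l* in sample *s* is
treated as a mixture over cellular compartments with additive global
tumor-intrinsic processes:

```
m(l,s) = (1 − f_imm(s) − f_caf(s)) · m_tumor(l,s)
         + f_imm(s) · m_immune(l) + f_caf(s) · m_caf(l) + ε(l,s)

m_tumor(l,s) = b(l) − c(s)·λ_clock(l) + g(s)·λ_mg(l) − u(s)·λ_ml(l) + cis/local terms
```

with per-sample latents: immune and CAF fractions `f`, a replication
clock latent `c`, instability latents `g` (MG) and `u` (ML), and
per-locus loadings `λ` (the clock loading grows with late replication
timing). The pipeline never fits this model directly; it removes the
compartment term empirically (K-nn normalization) and then reads the
latents off correlation structure.

Key assumptions, in decreasing order of importance:

- TME composition is observable through expression: the immune/CAF gene
  modules' mean expression is a faithful monotone proxy for `f`.
- Tumors with similar (immune, CAF) signatures have exchangeable TME
  methylation content, so a K-neighborhood mean estimates the
  compartment term. This is a *shrinkage* estimator: at n = 500 and
  K = 30 the neighborhood mean has slope ≈ 0.9–0.95 on the true
  fraction, so a residual sliver of TME signal always survives; it
  shrinks as the cohort grows or the signature-space density flattens.
- The global layers are low-rank: many loci share one latent each, so
  locus–locus correlation clustering separates them.
- Cis effects are locus-private: a truly cis-regulated promoter
  correlates with its own gene beyond what any trans factor induces
  across thousands of promoters, which is exactly what the rank
  statistic measures.

## Parameters

All defaults live in `epilayers.core.Parameters` and are overridable per
run. The consequential ones:

| parameter | default | meaning |
|---|---|---|
| promoter window | −500/+50 bp around TSS | strand-aware, 0-based half-open |
| meth_mean_bounds | [0.1, 0.9] | loci outside are uninformative for cross-correlation |
| corr_floor | 0.25 | retention floor for rows/columns and locus partners |
| knn_k | 30 (ER+), 15 (ER−/normal) | smaller K = noisier neighborhood mean; larger K = less homogeneous neighborhood (see the sweep in `knn_sensitivity_sweep`) |
| n_cross_clusters | 30 | cross-correlation tree cut |
| n_layer_clusters | 3 | clock / MG / ML |
| layer_sample_size | 50,000 | locus subsample bound for the layer correlation matrix |
| tme_corr_threshold | −0.3 | promoter qualifies for the raw-methylation TME score |
| clock/mg–ml locus thresholds | 0.6 / 0.5 | score-correlation cutoffs for reported locus sets |
| min_corr_samples | 50 | pairwise-complete support floor for any correlation |
| distal_window | 500 kb | pairing window, locus midpoint to TSS, strand ignored |
| epipoly depth / CpGs | 30 / 5 | fixed read depth and epiallele length |
| enhancer calling | top 3%, ≥2 kb from promoters, 200 bp | H3K4me1-based |
| tor bins | ≤20% late, 20–60% intermediate, >60% early | plus a median 2-bin split (ties → late) |

## Numerical choices

- **Correlation.** All cross-correlations are pairwise-complete Pearson
  computed by masked matrix products; cells under `min_corr_samples`
  support or with zero variance are missing. A dense fast path is used
  when no values are missing. Equality with an explicit-loop oracle is
  asserted to 1e−10 in the tests.
- **Ward clustering.** `scipy` Ward on raw observation vectors, which
  reproduces the `ward.D2` convention (squared Euclidean distances
  inside the merge criterion). Cluster ids are relabeled in dendrogram
  leaf order, making labels deterministic; missing correlations are
  imputed as 0 before clustering (neutral under Euclidean distance).
- **K-nn.** Signature axes are z-scored before the Euclidean distance
  (raw-axis mode behind a flag); self is excluded from its
  neighborhood; exact coordinate ties resolve by stable input order;
  a cell with fewer than K/2 observed neighbors becomes missing.
- **Layer labeling.** Clusters are ordered by mean raw methylation in
  normal samples — lowest = MG, middle = ML, highest = clock — with a
  replication-timing enrichment check on the clock (warning if absent).
  Without normals a weaker skew-based heuristic is used, with a
  warning. Loss layers (clock, ML) have their scores sign-flipped so
  that a higher score always means a larger departure from normal.
- **Rank screen ties.** Ascending correlation ranks break ties by
  promoter order; best-gene selection in the distal screen breaks |r|
  ties by gene id. The negative (repression) pass is primary; a
  mirrored descending pass covers methylation-associated induction.
- **Epi-polymorphism.** Coverage ties in the 5-CpG selection go to the
  leftmost position; downsampling is uniform without replacement
  (with-replacement behind a flag); average methylation is always
  recomputed from the downsampled multiset.
- **Degenerate inputs.** Zero-variance profiles, all-missing TOR,
  missing annotation sections, empty epi-polymorphism strata, and
  constant association features are skipped or propagated as missing
  rather than raised, except where silent recovery would hide a real
  mistake (unknown strand, K ≥ n, depth mismatch, missing upstream
  pipeline stage) — those raise.

## The synthetic cohort

The generator (`epilayers.simulate`) emulates the statistical structure
the pipeline assumes. Defaults describe the study conditions used
throughout the tests: 500 tumors + 60 normals; 1,200 promoters, 1,600
MspI fragments, 240 enhancers; 5% of loci per global layer; 50 planted
cis pairs at ρ = 0.6; immune/CAF fractions flat over [0.05, 0.35];
uniform latents; heteroscedastic noise with sd `0.03·2·sqrt(m(1−m))`
(read-sampling-like, keeping [0,1] clipping below 1%).

Choices worth explaining:

- **Contamination distribution.** A flat, bounded Beta(1,1) over
  [0.05, 0.35]. Because the K-nn neighborhood mean is a shrinkage
  estimator, a strongly skewed fraction distribution leaves a
  density-gradient bias in the residuals; a smooth bounded density
  matches the regime in which neighborhood averaging works, which is
  the regime the method is designed for.
- **TME differentials.** Immune/CAF cell methylation differs from the
  tumor profile by U(0.2, 0.4) at marker loci — moderate, locus-
  dependent differences as seen in sorted-cell methylomes, rather than
  an all-or-nothing 0-vs-1 contrast.
- **Marker coherence.** TME marker genes carry residual expression
  noise of 0.1 (log scale) around `7 + 3f`, i.e. pairwise correlations
  ≈ 0.9, as canonical marker panels show in real bulk cohorts. 150
  additional genes track the MG/ML latents in trans, mirroring the
  large co-expression programs real instability layers drive — and
  giving the 30-way cluster cut a realistically sized matrix.
- **What the simulator does not model.** Read-count-dependent missing
  data, CpG-level autocorrelation along fragments, subclonal structure,
  SNP effects, batch effects, and any coupling between the clock and
  instability latents (they are independent by construction). Passing
  recovery tests therefore demonstrates correctness of the machinery
  under the model's assumptions, not performance on violations of them.

## Design choices where the design was open

- The locus eligibility filter for layer inference acts on *normalized*
  mean methylation (|mean| < 0.1). A raw-methylation reading would
  exclude the raw-hypermethylated clock loci outright, contradicting
  the clock's own definition; both modes exist behind
  `layer_filter_on_normalized`.
- Promoter aggregation is coverage-weighted (pooled read ratio) by
  default, matching RRBS practice; `weighted=False` averages per-CpG
  fractions.
- On a *null* cohort (no planted latents) the partner filter
  (|r| > 0.25) leaves essentially no eligible loci at n = 500 and layer
  fitting refuses with an error. This refusal — rather than a
  numerically small correlation among forced noise clusters — is the
  package's specificity guarantee: scores of chance clusters are ratios
  of correlated small-sample noise and are not meaningfully bounded.
- MG-retention under normalization is asserted directionally
  (post ≥ pre − 0.05 per locus): with compartment mixing, normalization
  *raises* the latent correlation by removing dilution variance, so a
  two-sided band would reject improvements.
- Null tests of the distal screen use a gene-dense toy genome (10 Mb
  chromosomes) so that chance pairings are frequent enough (~15–20 per
  run) for the shuffled/real ratio to be a stable statistic; this is a
  problem-size choice, not a change to any threshold.

## Problem sizes

Tests and the acceptance script run on: one 500-tumor default cohort
(shared across tests), 20 × (500-gene, 200-sample) null screens plus one
(2,000-gene, 500-sample) power screen, 20 distal-null geometries
(1,000 loci × 600 genes × 150 samples), 1,000 random epiallele
compositions, a 200-gene dosage cohort, and two 150-tumor full pipeline
runs for byte-level determinism. The full suite completes in about
90 seconds on one CPU.

## Known limitations

- Layer labeling needs normal samples for full reliability; the
  normal-free heuristic is a fallback, not an equivalent.
- The K-nn residual retains a small TME component (shrinkage); analyses
  that are exquisitely sensitive to residual immune signal should
  additionally covary the signatures out downstream.
- The empirical k/m FDR is conservative when many true cis couples
  exist (m counts true and false alike).
- Distal pairing treats the best-correlated gene only; secondary
  targets within the window are not reported.
- The dosage-compensation screen tests marginal contrasts per gene; it
  does not model interaction between CN state and the global layers.
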