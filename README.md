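# epilayers

Layered deconvolution of bulk tumor DNA methylomes.

Bulk tumor methylation profiles (e.g. RRBS of breast cancer biopsies)
superimpose several independent processes: DNA from infiltrating immune
cells and cancer-associated fibroblasts (the tumor microenvironment,
TME), a replication-linked clock of genome-wide methylation *loss*
concentrated in late-replicating domains, two epigenomic-instability
processes at CpG-island loci (methylation gain, **MG**, at normally
unmethylated sites and methylation loss, **ML**, at partially methylated
sites), copy-number dosage effects, and locus-specific *in-cis*
regulation of individual genes. `epilayers` peels these layers apart in
order, for anyone analyzing tumor methylation matrices alongside
expression, copy-number and mutation data.

## The method

1. **TME module discovery.** Pearson cross-correlation of log expression
   (genes) against raw promoter methylation (loci), per sample group
   (ER+, ER−, normal); loci with mean methylation outside [0.1, 0.9] are
   excluded and rows/columns without any |r| > 0.25 are dropped. Ward
   (ward.D2) clustering into 30 clusters; the gene clusters holding the
   canonical immune (CD3D, ...) and fibroblast (CAV1, ...) markers are
   the TME modules.
2. **K-nn normalization.** Per-sample immune and CAF signatures are the
   mean log expression of the two modules. In the 2D signature plane,
   each tumor's K nearest neighbors (K = 30 for ER+, 15 for ER−/normal)
   define a neighborhood, and

   `m'(l, s) = m(l, s) − mean_{t ∈ N_K(s)} m(l, t)`

   removes all methylation variation explained by cell composition.
3. **Layer inference.** Up to 50,000 normalized locus profiles are
   correlated against each other, filtered (≥1 partner with |r| > 0.25),
   Ward-clustered into three groups, and labeled from raw methylation in
   normal samples: clock (hypermethylated in normals, losses graded by
   late replication timing), MG (≈0 in normals), ML (partially
   methylated in normals). Per-sample scores are oriented means of
   normalized methylation over each layer's loci.
4. **Cis screen.** For each gene, the correlation of its own promoter is
   ranked against all promoters (rank 1 = strongest negative); the
   empirical FDR at rank k is k/m, m = #genes with own-promoter rank ≤ k.
   Distal elements are paired with their best-correlated gene when its
   TSS lies within 500 kb; the pairing FDR is shuffled/real pairing
   counts.
5. **Epi-polymorphism.** Reads per MspI fragment are projected on the 5
   most-covered CpGs, downsampled to exactly 30 reads, and scored with
   the Gini–Simpson diversity `1 − Σ p_i²` of the 32 epiallele patterns.
6. **Genomic integration.** Wilcoxon/Spearman associations of the five
   scores (Immune, CAF, Clock, MG, ML) with mutations, CNAs, CIN and
   MATH; KS contrasts of promoter methylation and expression across
   copy-number strata flag methylation-mediated dosage compensation.

A bundled synthetic-cohort generator (`epilayers.simulate`) produces
matrices with exactly this structure plus ground truth, so every stage
has a recovery test without any external data.

## Worked example

```
$ python examples/03_layer_inference.py
loci per layer: {'ml': 154, 'mg': 152, 'clock': 152}
mean raw methylation in normals per layer: {'clock': 0.76, 'mg': 0.05, 'ml': 0.56}
clock score vs planted latent: r = 0.964
   mg score vs planted latent: r = 0.966
   ml score vs planted latent: r = 0.971
clock loci mean replication timing 32 vs genome 51 (lower = later S-phase)
```

On a simulated 500-tumor cohort the three inferred layers recover the
planted locus sets, each per-sample score tracks its hidden process at
r ≈ 0.96, the clock cluster sits in late-replicating domains, and the
normal-sample methylation levels (0.76 / 0.05 / 0.56) are what identify
which cluster is the clock, MG, and ML. The other scripts in
`examples/` walk through simulation, TME normalization, the cis screens,
epi-polymorphism and genomic integration the same way.

There is also a thin CLI (`epilayers simulate|crosscor|normalize|layers|
cis|epipoly|integrate|run-all --seed N --out DIR`) that runs the same
stages over TSV inputs and writes one deterministic TSV per stage.

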