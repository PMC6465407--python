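# eqtlink

Linking GWAS risk variants to the genes they regulate, from summary
statistics alone.

Genome-wide association studies localize disease risk to non-coding
variants whose target genes are usually unknown. `eqtlink` implements two
complementary summary-statistics workflows for closing that gap, built for
case-control GWAS (e.g. breast cancer meta-analyses) combined with large
collections of published cis-eQTL results across tissues:

1. **Target-gene prediction.** Independently associated *sentinel risk
   variants* are selected from GWAS summary statistics by approximate joint
   analysis (COJO-style stepwise selection using reference-panel LD). In
   parallel, each eQTL dataset is reduced per gene to *sentinel eQTL*
   (cis filter, Bonferroni significance filter, greedy LD clumping at
   r² < 0.05 within ±2 Mb). A gene is predicted as the target of a risk
   variant when one of its sentinel eQTL is in high LD (r² > 0.8) with it.
   For every prediction the package calls the **directional effect**:
   whether the disease-protective allele (the GWAS allele with log-OR < 0)
   is associated with higher or lower expression of the gene, after full
   allele harmonization across GWAS, eQTL catalog and panel; conflicting
   signed evidence is reported as *ambiguous*. Predictions can be annotated
   with functional support by intersecting sentinels and their proxies
   (r² > 0.8, MAF > 0.01) with enhancer/chromatin-interaction intervals.

2. **Gene-based discovery of unreported risk loci.** The genome is first
   *adjusted* for all sentinel risk variants (conditional analysis from
   summary statistics plus LD), so that no single variant remains
   genome-wide significant. Single-variant chi-squares are corrected by a
   genomic-control / LD-score intercept λ (chi² → chi²/λ). For each gene,
   the union of eQTL across all datasets and tissues is clumped
   (r² < 0.1, ±1 Mb) into a cross-dataset sentinel list, and the gene-level
   statistic is the sum of corrected chi-squares over those sentinels
   (substituting an r² > 0.8 proxy when a sentinel is absent):

       T = Σⱼ χ²ⱼ / λ,   E[T] = m,   Var[T] = V = 2 Σⱼₖ r²ⱼₖ

   Under the null, T is a quadratic form in correlated normals; its
   significance is computed with Satterthwaite's two-moment approximation,
   T/c ~ χ²ᵥ with scale c = V/(2m) and df ν = 2m²/V, which is exact at
   independence (c = 1, ν = m) and at rank-1 collapse. Experiment-wide
   significance uses the threshold 0.05/N over the N genes tested. An
   exact quadratic-form oracle (Ruben's mixture series; also Imhof
   integration and eigenvalue Monte Carlo) is included for validating the
   approximation.

Because the real consortium inputs are not distributable, the package
ships a first-class synthetic-data module: LD-blocked genotype panels
(latent-Gaussian AR-1 haplotypes), case-control GWAS with planted log-odds
effects estimated by per-variant score tests, and multi-tissue eQTL
catalogs with planted signed effects — all pure functions of (spec, seed),
with machine-readable ground truth for end-to-end recovery tests.

## Worked example

Simulate a world in which one variant drives both disease risk
(log-OR 0.12) and expression of `G_target` (+0.5 SD in two tissues), with
an independent decoy eGene, then run target prediction:

```sh
eqtlink simulate --name shared_causal_basic --seed 7 --out scen/ \
    --panel-n 800 --n-cases 20000 --n-controls 20000
eqtlink predict --gwas scen/gwas.ma --eqtl scen/eqtl.tsv \
    --panel scen/panel.vcf --out pred/ --min-n 10000
```

`pred/sentinel_risk_variants.tsv` contains the joint selection — the
planted causal variant with its joint effect estimate:

```
variant_id   b_joint          se_joint         p_joint
v1_1050000   0.104515574525   0.0143601478199  3.38382703189e-13
```

and `pred/predictions.tsv` the LD-intersection call:

```
risk_variant  gene_id   n_evidence  best_r2  direction
v1_1050000    G_target  2           1        decreased_expr_decreased_risk
```

The planted variant is recovered as the sole sentinel risk variant (joint
log-OR 0.105 ≈ planted 0.12 estimated from 40,000 individuals), `G_target`
is predicted from both tissue datasets at r² = 1, the decoy gene is not
predicted, and the direction call says the protective allele lowers
expression — matching the planted configuration (risk allele raises both
risk and expression). `eqtlink discover` runs the gene-based workflow the
same way and writes a per-gene table (m eQTL tested, number nominally
significant, T, p, experiment-wide flag). All outputs embed the config
hash, seed and input checksums; identical inputs give byte-identical
reports.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computations from scratch: it recomputes the
two analytic significance thresholds from their printed inputs
(0.05 / (55,764 × 1000) and 0.05 / 19,478), simulates the shared-causal
scenario and runs the full target-prediction pipeline on it, and simulates
the multi-eQTL scenario and runs the gene-based discovery pipeline,
printing a short summary and writing the acceptance JSON to `--out`. All
randomness derives from `--seed`.
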