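# epistate

Chromatin state and DNA methylation are mechanistic links between genotype
and gene expression. `epistate` implements a pipeline for quantifying that
link in a panel of inbred mouse strains and for carrying it into a
Diversity Outbred (DO) population:

* **Metagene coordinates.** Gene bodies are normalized so the TSS is 0 and
  the TES is 1 (strand-aware), with 1-kb flanks mapping below 0 and above
  1, and features are aggregated on a fixed grid of 42 bins spanning
  [−0.5, 1.5]. Genes closer than 2 kb to a neighbor are excluded to avoid
  contamination from adjacent regulatory regions.
* **Association model.** Everywhere the same single-predictor regression is
  fit on rank-normal (Blom) scores:

      y_e = β x_s + ε

  where *y_e* is transformed expression and *x_s* the transformed
  proportion of the gene body in chromatin state *s* (or the local state
  presence / percent methylation in one spatial bin). Each state is fit
  marginally, per strain across genes (effects and 95% CIs averaged across
  strains after a homogeneity check) and across strains on per-gene
  standardized values.
* **Methylome.** Replicate CpG calls are merged per strain, averaged and
  rounded to {0, 50, 100}% (unmethylated / hemi- / fully methylated).
  A CpG is *strain specific* if present in all replicates of some strain
  and absent from all replicates of another. Missing sites count as 0%
  methylated in association fits.
* **DO imputation.** For each transcript, founder features (state one-hot,
  SNP alleles, percent methylation) over TSS−1 kb..TES+1 kb are mixed by
  the individuals × 8 founder haplotype probabilities at the marker nearest
  the TSS: `imputed[i,l,p] = Σ_f hap[i,f]·founder[f,l,p]`. Expression
  (residualized for sex/diet/generation) is regressed on one imputed level
  at one position at a time — a single degree of freedom per test, so R² is
  comparable across feature classes. Significance beyond what the
  haplotypes themselves explain comes from a permutation null that shuffles
  founder labels on the feature array, re-imputes and re-scans; the
  empirical *p* is the fraction of permutation max-R² values that meet or
  exceed the observed one.
* **Synthetic data.** A first-class generator emulates the study design
  (9 strains × 3 replicates, 14 states from 4 binary histone marks,
  strain-specific CpGs, DO founder mosaics with Poisson crossovers) with
  known ground-truth effects, so every estimator is exercised against truth.

## Worked example

```python
import numpy as np
import epistate as ep

cfg = ep.SimConfig(n_genes=500, seed=3, noise_sd=0.5,
                   state_betas=np.r_[1.0, -1.0, np.zeros(12)])
panel = ep.simulate_founder_panel(cfg)
props = {s: ep.state_proportions(t, panel.genes, 14)
         for s, t in panel.tracks.items()}

per_strain, pooled, anova_p = ep.associate_across_genes(panel.expression, props, 1)
print(pooled.beta, (pooled.ci_lo, pooled.ci_hi), anova_p)
# 0.363  (0.258, 0.467)  0.99
```

State 1 was simulated with a true positive effect: the pooled across-gene
slope is 0.363 with a 95% CI excluding zero, and the per-strain effects are
statistically homogeneous (P = 0.99), justifying the averaging. The
across-strain fit gives beta 0.070, CI (0.032, 0.108) over 2700
standardized strain-gene observations — weaker, as cross-strain state
variation is sparser than cross-gene variation. The merged methylome holds
27,217 CpG sites of which 17.6% are strain specific (the generator's
target fraction is 17.8%).

Imputing into a simulated DO population and scanning one transcript:

```python
do = ep.simulate_do_population(panel.config, panel)
scan = ep.scan_gene(panel, do, "gene0001")
print({k: round(v.max_r2(), 3) for k, v in scan.items()})
# {'haplotype': 0.112, 'state': 0.355, 'snp': 0.138, 'methylation': 0.092}
```

The causal chromatin state explains 35.5% of expression variance at its
true position (4500 bp, where the scan's argmax lands), three times what
the best single founder haplotype explains — the signature of an epigenetic
feature that groups several founders. `build_gene_report` assembles the
aligned per-position view (R² by class, founder state tracks, SNPs,
methylation, haplotype effects) and flags positions where a non-haplotype
class beats the best single-haplotype R².

A command-line interface mirrors the library:

```sh
epistate simulate --n-genes 300 --seed 1 --outdir fx/
epistate assoc --states fx/tracks --genes fx/genes.bed --expr fx/expression.tsv \
               --grid 42:-0.5:1.5 --out out/
epistate permute --fixtures fx/ --feature state --n-perm 1000 --seed 1 --out out/
```

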