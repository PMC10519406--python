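# Methods

## Coordinate system and binning

Genomic coordinates are 0-based half-open (BED convention) in memory and in
every file. Gene-relative coordinates are the affine map
r = (pos − tss) / (tes − tss), with tss/tes taken as the interval
boundaries nearest the first/last transcribed base (on the − strand
tss = end, tes = start, so larger genomic coordinates give smaller r). The
first transcribed *base* of a − strand gene is end−1; using the boundary
instead shifts profiles by less than one bp over a gene length and keeps
the map exactly affine.

Flanks are normalized on the same gene-length scale as the body, so 1 kb of
flank spans 0.25 relative units for a 4-kb gene and 0.5 for a 2-kb gene;
positions beyond the grid are discarded at binning. An alternative
`fixed` mode (`relative_positions(..., mode="fixed")`) maps 1 kb of flank
to 0.5 units for every gene; the default was chosen because the body is
normalized by gene length and a single affine map keeps window midpoints,
CpG positions and SNPs on one common axis.

The default grid has 42 equal bins on [−0.5, 1.5]; bins are left-closed
right-open except the last, which also contains the right edge, so every
position in range belongs to exactly one bin. 200-bp state windows enter
positional analyses by their midpoint — a single unambiguous position per
window. Genes within 2 kb of another gene body are removed before profile
and association analyses (`filter_isolated_genes`, idempotent; the
inter-interval distance of [a,b) and [c,d) with b ≤ c is c − b).

## Association model

All association fits are the same marginal simple regression on
rank-normal scores: midranks for ties, mapped through Φ⁻¹ at
(r − 0.375)/(n + 0.25) (the Blom offset). A constant vector degenerates to
all-zero scores and raises a `DegenerateDataWarning`. Fits include an
intercept (rank-normal scores are mean-zero, so the slope is unaffected);
slopes, 95% CIs and R² come from OLS (statsmodels). Each chromatin state is
fit independently — the quantity of interest is the marginal effect, and no
multiple-regression mode is provided.

*Across genes*: per strain, transformed strain-mean expression (replicates
averaged before transformation) on transformed state proportion over genes.
The pooled effect is the arithmetic mean of per-strain slopes and of their
CI bounds — deliberately literal pooling; a variance-weighted pool is a
one-line change but is not the default. Strain homogeneity is tested with a
Cochran-Q-style one-way statistic over per-strain slopes weighted by
bootstrap standard errors (100 gene resamples per strain) against
χ²(k−1). A naive ANOVA over the bootstrap replicates themselves treats
resamples as independent observations and rejects almost surely under
homogeneity; the Q form is calibrated.

*Across strains*: expression and state proportion are z-scored per gene
across strains (zero-variance genes dropped), concatenated over genes,
rank-transformed and fit once. "Standardized" is read as per-gene z-score
across strain means; this is configurable in principle but is the only
reading implemented.

*Positional*: the per-bin predictor is the mean 0/1 presence of the state
among a gene's windows in that bin; empty bins yield no effect (missing,
never zero-filled). Methylation uses the same machinery with the per-bin
mean percent methylation, missing sites counted as 0%, and only positional
fits — methylation's effect on expression is strongly position dependent,
so a whole-gene summary is not computed.

Expression filtering follows the <1 CPM rule: a transcript is dropped when
two or more replicate columns (over the whole panel) fall below the
threshold.

## Methylome rules

Replicate percents are averaged over detecting replicates and rounded to
the nearest of {0, 50, 100}; exact ties (25, 75) round upward —
deterministic and documented, since hemi-methylation boundaries are
arbitrary. Rounding is idempotent. "Present" for merging means detected in
≥1 replicate; the strain-specific predicate requires presence in **all**
replicates of some strain and absence from **all** replicates of another.
Inter-CpG density uses the distance to the next site downstream on the same
chromosome (the last site contributes nothing); values are strictly
positive where defined. Conditioning on a chromatin state is per strain: a
CpG stays present for a strain only where that strain's track assigns the
state.

## Fold enrichment and state alignment

Fold enrichment is computed at base-pair resolution over merged intervals:
FE = (overlap/feature_bp)/(annotation_bp/genome_bp), which is symmetric in
the two roles and equals the per-base counting limit of window-based
implementations (segment-edge effects of binned tools are not replicated).
Ratios of enrichments are taken on raw FE values; logs are display-only.
State models are aligned by thresholding emission probabilities at 0.3 into
binary mark signatures (2^M possibilities for M marks); identical
signatures across models match states, collisions are reported and never
merged, and raising the threshold can only clear bits (monotone).

## DO imputation and scans

Founder feature arrays span TSS−1 kb..TES+1 kb: chromatin state as one-hot
indicators at every 200-bp window midpoint, SNP alleles as A/C/G/T one-hot
at SNP coordinates, methylation as a single continuous percent level per
window (mean of merged CpG values in the window, absent strains 0%, empty
windows 0%). Methylation is deliberately 1-df; a 3-level one-hot mode would
break the equal-df comparison and is not the default. SNP scans use
biallelic sites.

Imputation is the exact linear mixture `einsum("if,flp->ilp")`; it is
linear in the haplotype rows, and one-hot founder features keep level-sums
equal to the haplotype row-sums. Sex, diet and DO generation are
residualized (least squares with intercept; rank-deficient designs fall
back to the pseudo-inverse with a warning) out of expression *and* every
imputed predictor before scanning, so covariate variance never inflates R².
The residualization order is fixed: covariates first, then scans — also for
permuted features.

The single-df scan is the closed-form simple regression per (level,
position) cell, vectorized over all cells; it is verified cell-by-cell
against statsmodels OLS in the tests. A cell whose predictor spread is
negligible relative to its magnitude (tolerance 10⁻⁸ in predictor units) is
reported missing: covariate residualization leaves O(10⁻¹⁶) float noise on
an exactly constant column, and treating that noise as a predictor produces
arbitrary R² values that are identical under every founder permutation and
wreck the permutation null's calibration.

Permutations shuffle the founder axis of the feature array, re-impute and
re-scan, keeping haplotype probabilities and expression fixed: the
haplotype-expression association is preserved while the feature-founder
assignment is broken. One RNG stream per transcript is seeded from the
global seed plus an FNV-1a hash of the transcript id, so results are
independent of processing order. The empirical p-value is
#{perm ≥ obs}/n_perm exactly — no +1 correction; p = 0 is possible and is
flagged as "< 1/n_perm". Uniformity of p-values over transcripts is
assessed with a one-sample KS test against U(0,1) and a Kruskal–Wallis
comparison against a deterministic uniform grid; both are reported because
the appropriate grouping is a judgment call.

The per-gene report aligns all feature classes on the state-window midpoint
grid (SNP positions snap to the nearest grid point, keeping the maximum
when several collide) and flags positions where any non-haplotype class
exceeds the best single-haplotype R² anywhere in the gene — the criterion
for "this epigenetic feature explains more than any one founder lineage
does".

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical skeleton of the study design on
one synthetic chromosome: 9 strains × 3 replicates; genes of 2–6 kb laid
out sequentially, 90% isolated by ≥2.4 kb gaps and the rest in close pairs
(exercising the isolation filter); 14 chromatin states with distinct binary
signatures over 4 marks (emission 0.9/0.05); CpG sites at ~0.005/bp with a
4× density boost within 500 bp of the TSS, TSS-hypomethylated and
intragenically methylated levels, and a configurable strain-specific
fraction (default 17.8%) enforced exactly at the site level (present in all
replicates of a random proper subset of strains, absent from the rest).
Expression is generated directly on the normalized scale —
Σ_k β_k·proportion_k plus strain-level N(0, 0.5) and replicate-level
N(0, 0.2) noise — because the pipeline consumes already-normalized
expression and upstream normalization is out of scope.

Two structural choices matter for the pipeline's operating
characteristics:

* **Gene-body composition heterogeneity.** Each gene's body states are
  drawn from a gene-level Dirichlet(0.03) composition, so bodies are
  dominated by one or a few states — as real transcribed vs repressed genes
  are. This sets the across-gene variance of state proportions; at the
  default, a true β of 1 yields a proportion-expression correlation of
  ≈0.35–0.39 at noise 0.5 (500 genes).
* **Block-structured strain variation.** Across-strain differences come
  from variant blocks (mean 3 windows) carried by an arbitrary strain
  subset (each strain with probability 0.4), mimicking ancestry-shared
  variants, rather than independent per-strain window flips. Besides
  realism, this matters for the permutation null: with single-strain flips
  the founder subsets defining imputed predictors are mostly singletons,
  and the max-R² statistic is then invariant under many founder
  permutations — exact ties that the "met or exceeded" rule counts,
  pushing null p-values toward 1. Subset-structured variation makes ties
  rare and the null p-values uniform (KS non-rejection at α = 0.01).

Where a causal state effect is simulated, the causal state is planted
polymorphically at the gene's causal window with 2–6 of the 8 DO founders
as carriers. A single-carrier "state" is literally one haplotype — the
state scan and the haplotype scan are then the same test and the
state-beats-haplotype comparison is ill-posed; multi-founder grouping is
the phenomenon of interest.

DO individuals are two founder gametes with Poisson(1) crossovers placed
uniformly (no recombination map is needed at this scale); haplotype
probabilities at the TSS marker are exact dosages in {0, ½, 1} by default,
with an optional Dirichlet blur. Sex and diet are balanced binary
covariates; generation cycles 1–3; their effects default to 0 and are
configurable. DO expression is driven by the individual's true diplotype
state at the causal window — which may differ from the TSS-marker
haplotype due to intervening crossovers, exactly the decay the scan should
tolerate.

The generator does **not** simulate reads, peak calling, bisulfite
conversion, segmentation-model training, linkage disequilibrium beyond the
single chromosome's mosaic structure, or expression count distributions.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the inference under the model's assumptions — not robustness
to alignment artifacts, coverage variation or normalization error in real
data.

## Problem sizes and numerical choices

Default analyses run on 300–500 genes; the permutation-null calibration
uses 200 transcripts × 200 permutations and the causal-localization check
20 independent replicates (n_do = 200, β = 2) — sizes chosen so the full
suite and the acceptance script each complete in minutes on one CPU while
keeping Monte-Carlo error well inside the asserted margins. Proportion
row-sums hold to 1e-9; imputation matches its triple-loop definition to
1e-12; the per-gene 95% CI coverage band is 95% ± 3 points. Weak effects
(|β| ≈ 0.5) are reliably recovered across genes but sit at the edge of
detection across strains at these sample sizes; the recovery conditions
therefore use |β| = 1 (across-gene and across-strain) and a strong
TSS-confined state (β = 10 on a ~0.03–0.1 proportion, i.e. ≈1 noise SD)
for positional-profile recovery.

## Known limitations

* The across-strain "standardized" transform and the ANOVA grouping for
  strain homogeneity are each one of several defensible readings; both are
  documented above and implemented in one fixed way.
* ChromHMM-style binned OverlapEnrichment can differ from per-base
  counting at segment edges; the per-base value is taken as the reference
  and no reconciliation is attempted.
* Empirical p-values have resolution 1/n_perm and, for coarse discrete
  features, residual conservatism from exact permutation ties is possible
  (see the block-variation discussion above).
* The gene body is a single interval; transcript isoforms are not
  resolved.
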