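# Methods

## Methylation inference from misincorporation

The quantity at the centre of the package is the alternative-allele
frequency (AAF) at eleven p9 coordinates of the mitochondrial reference.
The underlying biochemical model: a methylated template position blocks
reverse transcriptase, which with efficiency ρ writes an incorrect
nucleotide into the cDNA; sequencing adds an error floor ε per base. The
per-read probability of a non-reference call at a site with methylation
fraction m is therefore

    p_alt = m·ρ·(1 − ε) + (1 − m·ρ)·ε ,

so E[AAF] ≈ m when ρ = 1 and ε is small, and the method systematically
*under*-estimates m when ρ < 1. ρ is not identifiable from the data the
pipeline consumes; it is a simulator parameter (default 1) and the
inference itself reports plain AAF without attempting to de-bias it.

Parsing follows the samtools-mpileup base-string grammar. Decisions a
user should know about:

* "quality filtering at Phred 20" is implemented as *excluding* bases
  with Phred < 20 (`min_baseq`, default 20) — the conventional reading
  and the conservative direction for methylation inference;
* deletions (`*`), reference skips (`>`/`<`) and N calls are excluded
  from both numerator and denominator: the inference concerns
  substitutions only. A `count_deletions_in_depth` flag restores the
  alternative denominator convention because read-count tools differ
  here;
* a site with fewer than `min_depth` (default 10) kept reads is reported
  missing, never 0 — at depth 10 the AAF quantisation step is 0.1, which
  is already coarse relative to the 0.05 group effects of interest;
* coordinates are 1-based inclusive throughout, matching mpileup and
  rCRS numbering; the mitochondrial contig is named `chrM`.

## Group statistics

Methylation fractions are bounded, skewed quantities, so all group
comparisons are rank-based. Each site is treated as its own family: the
six pairwise two-group Kruskal–Wallis tests (identical to the
tie-corrected Wilcoxon rank-sum on the χ² scale; the suite asserts the
algebraic identity) are Bonferroni-corrected ×6 *within* the site, and
deliberately not across the 11 sites. The omnibus 4-group KW p and the
minimum adjusted pairwise p are both emitted, labeled, since a summary
"overall" column can reasonably mean either. Missing AAF cells are
dropped per site (complete-case within site), and a missing group
reduces the family to the available pairs with a flag. The KS normality
check fits the Normal's parameters from the sample, which makes it
conservative (Lilliefors situation) — adequate for a gross non-normality
gate, not a calibrated test.

## Gene-based association

The phenotype is log₁₀ AAF at one p9 site; zero cells (possible at
finite depth) are handled by an offset of half the smallest nonzero AAF
in the cohort, echoed into the run manifest. Covariates are age, sex
(0/1) and the top 10 genotype eigenvectors; eigenvectors are computed on
the LD-pruned SNP set with the usual (2p(1−p))^{−1/2} standardisation.
LD pruning is the greedy windowed algorithm (50-SNP window, step 5,
r² > 0.2 on mean-imputed composite dosage correlations; of a violating
pair the lower-MAF SNP is dropped, ties drop the later one).

Gene aggregation does **not** replicate MAGMA's multi-model statistic.
The default is a permutation-calibrated min-p test: the gene statistic is
the largest absolute partial correlation of its SNPs with the phenotype,
and its null is generated by permuting the covariate-residualised
phenotype (Freedman–Lane), which preserves the LD among the gene's SNPs.
Gene p = (1 + exceedances)/(1 + permutations), computed in batches with
an early stop once every gene has 50 exceedances; ties in the discrete
permutation p are ranked by the top SNP's parametric p. A Šidák closed
form, 1 − (1 − min p)^m, is the fast alternative and the two agree within
Monte-Carlo error when SNPs are independent (asserted in the suite).
Significance is declared at the Bonferroni threshold α/N_genes; one scan
per p9 site, with no additional cross-site correction.

## Expression screen and enrichment

TMM scaling factors follow the published trimmed-mean-of-M-values
definition exactly (reference library by 75th-percentile proximity to the
mean; M/A values on library-size-normalised proportions over genes
expressed in both libraries; 30%/5% two-sided trims on M/A; inverse
asymptotic-binomial-variance weights; factors rescaled to geometric mean
1). One behaviour worth knowing: because the precision weights are
computed on raw counts, the *weighted* factors are only asymptotically
invariant to rescaling a single library; the unweighted trimmed mean
(`weighted=False`) is exactly invariant. The implementation matches
edgeR's `calcNormFactors` to ~1e-8 on random matrices (asserted via an
Rscript oracle when R is available).

The correlation screen is Spearman per transcript against site-585 AAF
(midranks, t-approximation p, BH-FDR across non-constant transcripts),
"significant" meaning q < 0.05. The top-n set is ranked by |ρ| with p as
tie-break — the ranking statistic is a package choice, since magnitude is
the natural ordering for a correlation screen. Visualisation structures
mirror the ClustVis conventions: rows centred and scaled to unit
variance, 1 − Pearson r distance, average linkage, SVD-based sample PCA.

Overrepresentation uses Fisher's exact test per GMT term over a
background defined as the genes that entered the correlation screen (not
the whole genome — untested genes cannot be discoveries and would inflate
enrichment); a whole-genome background is a caller choice by passing a
different list. Two-sided p-values use the point-probability rule (sum of
tables with point mass ≤ observed); a one-sided "greater" option exists
because overrepresentation is directional. The screen filter keeps
fold > 2 (strict) and q < 0.05.

## The synthetic cohort

The generator emulates the statistical structure the analysis targets,
with defaults chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 40 (preset `study_sizes`: 74/82/83/27) | samples per diagnosis |
| `depth_mean` | 1000 | Poisson mean pileup depth per site |
| `methyl_base` | 0.10 | Beta mean of methylation, NC/PA |
| `methyl_shift` | 0.05 | additive mean shift in AD/PSP |
| `beta_conc` | 50 | Beta concentration (per-site SD ≈ 0.04) |
| `rho_misincorp` | 1.0 | P(non-ref base given methylated template) |
| `eps_err` | 0.001 | sequencing error floor |
| `n_snps` / `snps_per_gene` | 200 / 10 | independent SNPs tiled into 20 genes |
| `causal_beta` | 0.12 | additive effect on log₁₀ site-585 methylation |
| `n_transcripts` / `n_linked` | 2000 / 100 | screen size / methylation-driven subset |
| `link_beta` | 1.0 | log-scale effect of standardised m₅₈₅ |
| `nb_dispersion` | 0.1 | negative-binomial dispersion |
| `libsize_range` | 0.5–2.0 | multiplicative library-size spread |

Ages are truncated normals with group means/SDs matching the study's
demographics table; sexes alternate within group. Base qualities in the
synthetic pileups come from two spikes (Q10 and Q30, 15%/85%) so the
Phred filter is actually exercised; quality is independent of base
identity, so the filter does not bias the AAF. Misincorporated bases are
spread uniformly over the three non-reference bases (AAF is
base-agnostic, so the simplest exchangeable choice suffices). The causal
SNP's MAF is fixed at 0.3 — a common variant — so power calculations are
well-defined; other MAFs are U(0.1, 0.5).

What the generator does **not** emulate, and hence what green tests do
not certify about real data: cross-site correlation of methylation within
a sample (sites are conditionally independent given the group, whereas
real p9 methylation is strongly correlated across sites through shared
enzymology); LD between SNPs; strand bias, alignment artefacts and NUMT
contamination in pileups; batch structure and covariate–expression
confounding in counts.

## Repeated-simulation calibrations

`mtp9.studies` packages the operating-characteristic studies shared by
the test suite and the acceptance script, at these problem sizes: 200
null cohorts (default sizes) for pairwise type-I error; 100 cohorts at
the study's group sizes for the AD/PSP contrast recovery; 50 cohorts and
2000 permutations for causal-gene recovery; 100 null screens of 2000
transcripts for FDR calibration. Child seeds are spawned from one master
seed via `SeedSequence`.

For the causal-gene study, the planted effect is sized for 80% analytic
power of the full recovery event. The per-SNP SE is estimated empirically
by running 20 null cohorts through the actual covariate-adjusted scan
(this captures the heavy left tail of the log₁₀-Beta phenotype and the
~18% of dosage variance absorbed by the genotype eigenvectors, both of
which a closed-form SE misses); the significance level folds in the
Bonferroni gene threshold, the discreteness of a 2000-permutation
p-value, the within-gene min-p multiplicity (Šidák) and the requirement
of outranking every null gene; the power curve is the noncentral t via
the Johnson–Kotz normal approximation (scipy's `nct` loses precision at
large noncentrality), averaged over the calibration SEs.

## Numerical conventions

Midranks for all ties; eigenvector and PC signs fixed by making the
largest-magnitude loading positive; mergesort (stable) for every ranking
that can tie; permutation seeds recorded in the manifest; all file
outputs written with fixed float formats so reruns are byte-identical.
Degenerate inputs fail loudly: zero-variance vectors in the KS test,
all-identical values in KW, all-zero libraries in TMM, rank-deficient
covariates (the offending column is named), GMT lines without members.

## Known limitations

AAF conflates methylation with genuine heteroplasmy and low-level
contamination; the pipeline does not attempt to separate them. The gene
test's permutation calibration assumes exchangeability of residuals
(valid under the homoscedastic null, approximate otherwise). TMM assumes
most transcripts are not associated with the phenotype; the generator's
5% linked fraction respects that. Real-cohort effect sizes and hit lists
are not reproducible here by construction — the restricted source data
are replaced by the synthetic cohort, and every quantitative claim in
the test suite is about recovery of *planted* structure.
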