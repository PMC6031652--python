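# Methods

`kiv2cn` re-implements, as a tested pipeline over synthetic cohorts with
known truth, the analysis chain that links the kringle-IV-2 (KIV2) tandem
repeat in *LPA* to lipoprotein(a): read-depth copy-number (CN) estimation,
SNP-based CN imputation, CN-conditioned association and variant-by-CN
modifier scans, and CN-aware Mendelian-randomization (MR) instruments.

## Copy-number estimation

Diploid KIV2-CN is estimated from interval depth summaries with an affine
copy-ratio transform.  The diploid copy ratio is

    rho = 2 * mean depth(repeat interval) / mean depth(control intervals),

with the control mean pooled across control intervals weighted by length, so
a reference-structured diploid genome has rho = 2.  The domain count is

    KIV2-CN = rho * 6.354 - 0.708.

The two constants are configuration derived from the reference layout of the
repeat (full copies represented in the reference, minus the flanking exons
homologous to the repeat unit that an aggregate depth signal picks up); they
are never recomputed.  With the defaults, rho = 2 maps to 12 domains —
six per haplotype, the reference structure.  Negative estimates are kept and
flagged rather than clamped so regression diagnostics see the raw estimator.
The default repeat model uses the genotyping interval 6:161,032,614–161,067,851;
a slightly different repeat span (chr6:161,032,565–161,067,901) is also in
circulation, and the discrepancy is recorded rather than resolved — the
transform constants, not the interval bounds, carry the calibration.

Precision is quantified with sibling pairs identical-by-descent on both
haplotypes (IBD2) at the locus: a pair is IBD2 iff its genotype discordance
over a 1 Mb locus window is strictly below 1%, and the squared correlation of
pair-member CN estimates bounds estimator noise since true CN is shared.

## The synthetic-cohort generator

The generator is first-class, tested code; its defaults are the study
conditions, set once:

| parameter | default | why |
|---|---|---|
| diploid CN mean/SD | 38.5 / 7.4 (African ancestry), 43.7 / 6.2 (European) | observed population distributions |
| CN bounds | [12, 85] copies | observed range |
| CN phenotype effect | −0.07 SD per copy | observed inverse effect; with the African-ancestry CN SD this makes CN explain ≈26% of phenotype variance, and ≈18% with the European SD |
| SNP tagging of CN | r² = 0.60 over 15 tag SNPs | the variance a locus SNP panel explains in directly genotyped CN |
| CN-independent SNP effects | 5 causal SNPs, 20% of variance | so that genetic variance (CN + SNPs) totals ≈46–49% |
| sequencing depth | 30× mean, negative-binomial dispersion 3×10⁻⁵ | deep-coverage WGS; dispersion calibrated so sibling-pair estimate r² ≈ 0.99 at 30× |
| events | exponential times, administrative censoring at 10 y | incident-outcome follow-up |

**Haplotypes and LD.**  Each haplotype walks along a pool of 32 backbone
haplotypes with a per-site switch probability of 0.03 (a phenomenological
recombination analogue giving LD blocks of roughly a third of a megabase over
the simulated 4 Mb window) plus 1% per-site mutation noise.  LD is
phenomenological: no coalescent, recombination map, or mutation model.  A
small pool necessarily leaves weak long-range correlation (of order 1/pool
size) that a real panel of thousands of haplotypes would not show; pool size
and switch rate were chosen so this floor sits below the detection threshold
of the scans at the default sample sizes.

**Repeat alleles.**  Per-haplotype CN is mean/2 plus a scaled mix of a
genetic component and Gaussian noise, with the mix set so the SNP-explained
fraction of diploid CN variance equals the tagging target.  The genetic
component is a weighted sum of the haplotype's alleles at tag SNPs near the
repeat, chosen among common sites that have no strong LD proxy elsewhere in
the panel; this makes the tag linear in genotypes (so a sparse linear panel
can in principle recover it in full) and robust to the standard 50/5/0.25
LD pruning.  Diploid CN is clipped to the bounds with both alleles rescaled
proportionally; allelic CN is continuous by default (fractional estimates),
with an integer-allele option.

**Phenotypes.**  The latent phenotype is

    cn_effect·(CN − mean) + Σ β_j g_j + covariates + interactions + ε,

with the residual completing the latent variance to ≈1 by default so
SD-scale effects read directly as variance fractions.  The SNP component is
orthogonalized against diploid CN: the causal SNPs model CN-*independent*
pathways (exactly the signal a CN-adjusted scan and the GRS are meant to
capture), so without orthogonalization the LD between causal sites and the
repeat would leak CN signal into them.  Causal and modifier sites are drawn
away from the locus and restricted to quasi-independent sites (no strong LD
proxy), matching the "independent causal variants" scenario the recovery
analyses assume.  Concentrations are a scaled exponential of the latent
value — right-skewed like lipoprotein(a) — but all inference uses the
rank-normalized scale, so the back-transform is cosmetic.  Lp(a)-C is a
noisy linear companion of the same latent value.

**Families.**  A configurable fraction of samples form sibling pairs sharing
a ±1.2 Mb IBD2 segment around the repeat (both haplotypes) and identical
allelic CN.  The shared segment covers the CN tag SNPs so sibling CN stays
coherent with sibling genotypes; the rest of the genome is independent, which
is all the IBD2 precision analysis uses.

**Shared panels.**  Two cohorts built with the same `panel_seed` share
variant positions, site frequencies and the backbone pool (and effect sites,
chosen from panel-level frequencies and LD), while drawing independent
haplotypes — the setting cross-cohort meta-analysis assumes.

**Events.**  Event times are exponential with hazard
h₀·exp(γ·phenotype_SD), censored administratively.  An optional direct
SNP-score term on the log hazard models outcome pathways that bypass the
lipoprotein level.  This term is essential for the MR contrast: if the
hazard depends only on the phenotype, every instrument calibrated to "one
unit = one phenotype SD" estimates the same hazard ratio in expectation, so
the observed GRS > KIV2-CN ordering is evidence of phenotype-bypassing
variant effects, and the generator makes that mechanism explicit
(`event_snp_direct_loghr`, set to log 1.3 in the directional study).

## CN imputation panel

The protocol: a two-thirds / one-third split keeping sibling pairs in one
split; candidates restricted to a 4 Mb window with MAF > 0.001 and
imputation quality > 0.8; greedy sliding-window LD pruning (50-variant
window, step 5, r² > 0.25; the later variant of a violating pair is dropped
by default, with a lower-MAF tie-break option); a LASSO over 100 log-spaced
penalties spanning four decades down from the all-zero penalty, 10-fold
cross-validation choosing the CV-MSE minimizer, refit on the full training
set.  The training response is the read-depth CN estimate, not simulation
truth — truth appears only in test oracles.  Predictors are standardized
internally and coefficients reported on the dosage scale.  A random-forest
regression ranks the selected variants by importance (normalized to sum 1).
Validation is the Pearson correlation between imputed and depth-estimated CN
on the held-out third; it cannot exceed the generator's tagging r² plus
sampling noise, and at the default conditions it lands near the 0.60 target
(Pearson r ≈ 0.77 at n_train ≈ 1400).

## Association and heritability

Scans regress the rank-normalized phenotype (Φ⁻¹((rank−0.5)/n), average
ranks for ties, computed separately by cohort) on dosage with covariates and,
when requested, estimated CN.  The OLS engine is the closed-form
normal-equations solution, vectorized across variants by residualizing
against the covariate design.  The LMM engine eigen-rotates by the kinship
matrix, profiles the variance ratio once under the null by maximum
likelihood, and fits each variant by weighted least squares; with an identity
kinship it reduces exactly to OLS.  Iterative conditional analysis adds the
top variant as a covariate and rescans until the minimum p exceeds 5×10⁻⁸
(ties broken by position).  Meta-analysis is inverse-variance fixed-effects
with Cochran's Q heterogeneity.  Two sensitivity analyses mirror the CN
association checks: a partial-F test for adding 1/CN to the linear model, and
a group-by-CN interaction comparing near-homozygous (equal-allele) samples
with the rest.

Heritability is Haseman–Elston regression: phenotype cross-products of
covariate-residualized, standardized phenotypes regressed on off-diagonal
entries of a genomic relationship matrix built from standardized dosages
after MAF/missingness filters and 50/5/0.9 pruning (deterministic
index-thinning replaces random down-sampling), with a 20-block sample
jackknife SE and the point estimate clipped to [0, 1].  At n = 1000 the
per-run sampling SD is ≈0.08, so recovery checks average over a seed band.
REML would be more efficient; HE is closed-form and robust at these sizes.

## Modifier scan

Per variant with cohort minor-allele count above 20, OLS of
`phenotype ~ CN + variant + CN×variant + covariates`, with the interaction
Wald p reported (SD per allele per CN copy).  The interaction model uses
estimated CN and fixed effects only (no kinship term).  Multiplicity uses
greedy LD clumping (500 kb, p1 = p2 = 1, r² = 0.25) and a Bonferroni
threshold of 0.05 divided by the clump count; the worked examples 0.05/1373 =
3.64×10⁻⁵ and 0.05/566 = 8.83×10⁻⁵ are exact.  Sensitivity checks per hit:
squared Pearson correlation of dosage with CN below 0.1; marginal phenotype
association below 0.05; and re-estimation of the interaction conditioning on
the independent main-effect variants.  A *pure* planted interaction (the
generator centers CN in the interaction term) has no marginal effect, so
check (b) correctly fails for it; empirical modifiers typically carry both.

## Mendelian-randomization instruments

Three instruments per cohort: a GRS over LD-clumped (500 kb, r² 0.25) index
variants reaching p < 10⁻⁴ in the CN-adjusted scan, weighted by the
CN-adjusted effects (cohort-specific weights; a config switch could take
meta-analyzed ones); the estimated/imputed KIV2-CN itself; and their
combination.  Calibration reconstructs "one unit = one SD of phenotype": the
raw score is inverse-rank normalized, the scale factor is the OLS slope of
the rank-normalized phenotype on the normalized score (negative for the CN
score, since copy number is inversely related to the phenotype), and the
final instrument is scale × normalized score, making the post-hoc slope of
phenotype on instrument exactly 1 in the calibration cohort.  Instruments
serialize to JSON and transfer to other cohorts by re-applying the variant
weights and the stored scale factor.  Outcome models: Cox proportional
hazards (Breslow ties, via lifelines; an independent direct partial-
likelihood maximization serves as the test oracle) for events, OLS for
rank-normalized quantitative outcomes, with five genotype principal
components, age, sex and fasting status as covariates.

## Numerical choices and degenerate inputs

- Rank-normal transform: offset (rank−0.5)/n with average ranks for ties
  (the convention is unstated in the source protocol; this choice is
  symmetric and standard); all-constant input within a cohort is an error.
- Missing genotypes are masked and excluded per variant from allele
  statistics; inside scans and score construction they are mean-imputed
  (twice-MAF substitution for GRS dosages), logged.
- Monomorphic / rank-deficient variants are skipped with a flag, never
  silently zeroed.
- p-values are two-sided Wald, clipped away from exact zero; no genomic
  control is applied.
- The conditional scan has a 50-iteration guard; Cox fitting errors out on
  non-convergence; instruments with |calibration slope| < 0.01 are rejected
  as uninformative.
- LD pruning computes correlations on mean-imputed dosages (identical to
  complete-case Pearson when nothing is missing) and is deterministic given
  input order.

## Problem sizes

Tests and the acceptance analyses run at n = 600–4000 samples and 40–2200
variants: large enough that the recovery bands (±0.07 on tagging r², ±0.1 on
h², ±2 SE on effect sizes) are informative, small enough to re-run routinely.

## What passing tests do and do not show

The generator reproduces the moments, effect sizes and LD-tagging structure
the analyses assume, but not sequencing artifacts (GC bias, mapping error,
reference bias), fine-scale recombination, population admixture, allele-
frequency spectra of rare variation, or assay noise in lipid measurements.
Recovery of parameters here demonstrates that the estimators are correctly
implemented and calibrated under their assumed models — not that those
models capture every property of cohort sequencing data.  The GC-correction
hook in the estimator defaults to off because the synthetic depth has no GC
bias, and the high-LD-region mask for kinship construction defaults to empty
because the synthetic genome has no such regions.
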