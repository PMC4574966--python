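# Methods

## The multi-marker Rasch genetic score

A set of m bi-allelic SNPs, coded by minor-allele count (0 = aa, 1 = aA/Aa,
2 = AA), is treated as a set of polytomous items of an item-response model.
Under the Partial Credit Model (PCM) the probability that subject n responds
in category x of item i is

    Pr(X_ni = x) = exp( Σ_{k=0..x} (β_n − τ_ki) ) / Σ_{j=0..m_i} exp( Σ_{k=0..j} (β_n − τ_ki) ),

where β_n is the subject's latent genetic load, τ_ki the difficulty of
reaching category k of item i (the k = 0 term contributes zero), and m_i = 2
for bi-allelic SNPs.  The model assumes a single latent dimension,
sufficiency of the raw score r_n = Σ_i X_ni for β_n, conditional
independence of items given β, and a logistic response curve.  Genotypes
enter additively, which is the usual working assumption for complex traits.

The per-subject score used downstream is the maximum-likelihood estimate of
β_n given the estimated thresholds — one number per subject summarising the
subject's multi-marker genotype profile.

### Conditional maximum likelihood

Thresholds are estimated by CML: conditioning on the raw scores removes the
person parameters.  With ε_i[x] = exp(−Σ_{k≤x} τ_ki), the conditional
likelihood involves the elementary symmetric functions

    γ_r = Σ_{patterns with Σx_i = r} Π_i ε_i[x_i],

computed by the numerically stable summation algorithm (item-by-item
convolution), with per-item rescaling by max ε_i so that products of many
items cannot overflow.  The negative conditional log-likelihood is convex in
τ (each log γ_r is a log-sum-exp of linear functions), and is minimised by a
damped Newton iteration with the analytic gradient and Hessian obtained from
first and second ESF derivatives (leave-one-out and leave-two-out ESFs built
from contiguous products, never by deconvolution).  Convergence is declared
when max |gradient| < 1e-6 (iteration cap 100); failures are returned as
non-converged fits with a machine-readable reason, never as scores.

The conditional likelihood is invariant to adding a common constant to every
τ (and β), so one gauge constraint is needed: the sum of all τ_ki over items
and categories is zero.  During optimisation the gauge is pinned by a
quadratic penalty on Στ (which does not bias the estimate, because the
likelihood is flat along that direction); after convergence the solution is
recentred exactly.

Items observed at a single value carry no conditional information and are
dropped (recorded with a reason).  Items with unobserved intermediate
categories — e.g. a SNP seen only as {0, 2} — are collapsed to consecutive
codes before fitting, and the recode map is recorded.  Missing genotypes are
refused: imputation is a separate, upstream concern.

### Person scoring

For each attainable raw score r in 1..S−1 (S = Σ m_i), the ability solves
the expected-score equation Σ_i E[X_i | β] = r, a strictly monotone
one-dimensional root problem solved by Brent's method to 1e-10.  Subjects
with equal raw scores receive equal abilities (sufficiency).  The extreme
raw scores 0 and S have no maximum-likelihood solution; they are assigned
the solutions at pseudo-scores 0.25 and S − 0.25 (configurable via
`extreme_shift`) and flagged.  Any monotone-preserving convention works for
downstream regression — association p-values are unaffected by the gauge
and by the extreme-score convention; only the score values themselves are
defined up to these choices.

## Association testing

The score is tested against the trait with a logistic (binary) or ordinary
least-squares (quantitative) model, optionally with covariates; inference on
the score term uses the likelihood-ratio test, which is better calibrated
than the Wald test at these sample sizes.  Perfect separation triggers a
Rao score-test fallback, flagged on the result.

Comparator SNP-set tests operate on per-SNP p-values from the
Cochran–Armitage linear trend test (binary traits) or the regression slope
test (quantitative traits):

- **minP** returns the smallest per-SNP p-value with no multiplicity
  correction.  It is deliberately biased (anticonservative) and serves as a
  negative control: on m independent null SNPs its level is 1 − (1−α)^m.
- **Fisher** combines T = −2 Σ ln p_i against chi-square(2m).  **Brown**'s
  adjustment rescales to c·chi-square(df) with c = Var(T)/(2E(T)),
  df = 2E(T)²/Var(T), Var(T) = 4m + 2 Σ_{i<j} cov_ij, using the polynomial
  approximation cov_ij ≈ 3.263|r| + 0.710r² + 0.027|r|³ in the genotype
  correlation r.
- **GATES** is the extended Simes procedure
  P = min_j m_e · p_(j) / m_e(j), where m_e (and m_e(j) for the j smallest
  p-values) is the effective number of independent tests,
  m_e = M − Σ_{λ>1}(λ − 1), from eigenvalues of the p-value correlation
  matrix.  P-value correlation is approximated from genotype correlation by
  the declared sixth-order polynomial
  0.2982r⁶ − 0.0127r⁵ + 0.0588r⁴ + 0.0099r³ + 0.6281r² − 0.0009r.
  At identity correlation GATES reduces exactly to Simes; with perfectly
  correlated SNPs and equal p-values it returns that common p.
- **SKAT** computes Q = (y−μ̂)ᵀ G W Gᵀ (y−μ̂) under the null model
  (intercept + covariates).  The null distribution, a mixture of
  chi-squares weighted by the eigenvalues of the projected kernel, is
  evaluated by moment matching (mean/variance/kurtosis to a scaled,
  possibly noncentral chi-square).  Weights default to flat (common
  variants); Beta(1, 25) density weights on MAF are available to upweight
  rare variants.

Zero p-values are clamped to the smallest positive normal (the log and
Simes machinery require positive inputs), with a warning.

## The simulator

The generator emulates single-SNP case-control panels.  Genotype
frequencies follow Wright's inbreeding model,

    p0 = p_a² + F p_a(1−p_a),  p1 = 2p_a(1−p_a)(1−F),  p2 = (1−p_a)² + F p_a(1−p_a),

with F = 0 (Hardy–Weinberg) throughout the reference study.  Disease risk
acts through penetrances f_i = Pr(D | genotype i) with relative risks
RR_i = f_i/f_0; the additive mode sets RR_1 = (RR_2+1)/2, and
f_0 = K_p / (p0 + RR_1 p1 + RR_2 p2) fixes the population prevalence K_p
exactly.  Bayes' rule gives the case and control genotype frequencies

    pD_i = f_i p_i / K_p,    pH_i = (1 − f_i) p_i / (1 − K_p),

both proper distributions satisfying K_p·pD + (1−K_p)·pH = p.  Cases and
controls are drawn directly from pD and pH.

The reference design is 500 cases / 500 controls, K_p = 0.05, 24 SNPs of
which 12 are disease susceptibility loci (DSLs), DSL relative risk from 1
(null) to 2, α = 0.05, B = 1000 replicates (B = 500 where the per-replicate
cost includes a PCM fit).  Allele frequencies are redrawn per SNP per
replicate from Uniform(0.1, 0.5) — common-variant MAFs; the calibration
results are insensitive to this choice.

### Linkage-disequilibrium designs

The moderate-LD (r² in 0.4–0.7) and strong-LD (r² in 0.8–1.0) designs
attach one passenger SNP to each DSL (round-robin when counts differ)
through a synthetic two-locus haplotype pool: a target r² is drawn from the
design's range, the passenger's allele frequency is pinned to its DSL's so
every target up to r² = 1 is attainable under the haplotype-frequency
constraint D ≤ min(p_A(1−p_B), p_B(1−p_A)), and the 3×3 joint genotype
table follows from random union of haplotypes.  Passenger genotypes are
sampled from the conditional distribution given the realised DSL genotype,
so disease status acts on passengers only through their DSL: the null
propagates exactly when RR = 1, and LD is inherited from the pool.  Targets
keep a 0.035 interior margin from open range boundaries so that
finite-panel sample r², which fluctuates around the target, stays inside
the declared range (r² = 1 is closed — sample r² cannot exceed it).

What the pool does **not** emulate: real haplotype blocks with many
mutually correlated SNPs, cross-block LD, allele-frequency/LD coupling, or
population structure.  Calibration results under this pool therefore speak
to the two-SNP-block regime, not to arbitrary real LD architectures (see
Limitations).

### Monte-Carlo estimation

False-positive rate (RR = 1) and power (RR > 1) are estimated as
#(p ≤ α)/B with standard error sqrt(rate(1−rate)/B).  Replicates where a
method fails (e.g. a non-convergent PCM fit) are excluded from that
method's denominator and counted; a report with more than 2% failures is
flagged unreliable.  All draws are reproducible bit-for-bit from
(seed, config).

## Real-data machinery

PLINK BED/BIM/FAM triplets are read and written natively (SNP-major two-bit
codes; additive coding counts the BIM allele-1; fail-closed on magic-number
or length mismatches).  SNPs attach to a gene when within a 20 kb flank of
its interval (1-based, fully closed coordinates, matching BIM positions).
QC filters (MAF ≥ 0.01, per-SNP missingness ≤ 5%, HWE exact-test p ≥ 1e-6
in controls) are configuration, not doctrine.  Missing genotypes are
imputed by weighted k-nearest-neighbour voting (distance = mean squared
genotype difference over co-observed SNPs, weight = inverse distance,
rounded to {0,1,2}; observed entries are never altered).  LD pruning is the
greedy sliding-window rule (window 50 SNPs, step 5, drop the later SNP of
any pair with r² > 0.2) and is idempotent.  The per-gene scan fits the PCM
per gene, scores subjects, and runs the logistic LRT; per-gene failures are
reported as rows, never aborting the scan.  QQ summaries report
−log10 p against −log10((i−0.5)/n) and the genomic inflation factor
λ = median(χ²_obs)/0.4549.  Benjamini–Hochberg q-values are appended as a
clearly labelled extension.

## Numerical and design choices

- Gauge: sum of all τ_ki = 0; pinned by penalty during optimisation,
  recentred exactly afterwards.
- Extreme scores: pseudo-scores 0.25 / S − 0.25, flagged.
- Convergence: max |∇| < 1e-6, ≤ 100 Newton iterations, step halving on a
  convex objective; τ clipped to ±30 logits (beyond which category
  probabilities are numerically degenerate).
- Trend tests on degenerate (constant-genotype) SNPs return p = 1 with a
  flag rather than an error, so set-level combiners remain well defined.
- Brown and GATES polynomials are declared constants (`_BROWN_COEF`,
  `_GATES_COEF` in `association.py`); non-PSD p-value correlation matrices
  have negative eigenvalues clipped at zero with a warning.
- SKAT uses moment matching rather than exact mixture inversion; Monte-Carlo
  checks confirm nominal calibration at the study's design.

## Problem sizes

The test suite and the acceptance script run the reference design at
B = 1000 replicates for tests without a PCM fit and B = 500 (study
condition) or B = 1500 (shared strong-LD calibration checks, to keep
estimator noise well inside the acceptance bands) where each replicate
fits the PCM.  Parameter-recovery checks use 12 items at n = 200 and
n = 2000 subjects.

## Limitations

- The PCM assumes conditionally independent items; strong LD violates this.
  Under the null the score remains a trait-independent genotype summary, so
  the level of the score test is asymptotically unaffected, but power
  comparisons under LD should be read with the violated assumption in mind.
  A dependence-aware item model is future work.
- On two-SNP LD blocks the eigenvalue-based effective-number-of-tests
  correction in GATES under-corrects slightly: its realised null rate in
  the strong-LD design is ≈ 0.06 at α = 0.05 (confirmed on exact Gaussian
  pair-block statistics, so this is a property of the procedure on this
  block composition, not of the genotype generator).  On richer, more
  redundant real-data LD blocks GATES is typically conservative.
- The score test requires individual-level genotypes and complete data;
  summary statistics are not sufficient, and imputation quality bounds the
  scan's reliability.
- Non-additive inheritance modes and quantitative-trait simulation are out
  of scope; the quantitative association path is exercised with generic
  fixtures only.
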