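# Methods

`mrphewas` implements a phenome-wide two-sample Mendelian randomization (MR)
screen against a binary disease outcome, with the follow-up analyses such a
screen requires: reverse-direction MR, two-step mediation through a
circulating biomarker, a conditional scan for secondary regional signals,
and Bayesian colocalization. This note records the statistical model behind
each component, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions that
were genuinely open.

## Two-sample MR model

For instrument $i$, two independent GWAS supply the estimated per-allele
effect on the exposure, $\hat\beta_{X_i}$ (SD units for continuous traits),
and on the outcome, $\hat\beta_{Y_i}$ (log-odds for a binary trait), with
standard errors $\sigma_{X_i}, \sigma_{Y_i}$. Under the instrumental-variable
assumptions each ratio $\hat\beta_{Y_i}/\hat\beta_{X_i}$ estimates the causal
effect $\theta$ on the outcome scale.

* **Wald ratio** (single instrument): $\hat\theta = \hat\beta_Y/\hat\beta_X$
  with first-order delta-method SE $\sigma_Y/|\hat\beta_X|$. The exposure-side
  uncertainty is ignored, as is standard for strong instruments.
* **IVW**: weighted regression of $\hat\beta_{Y}$ on $\hat\beta_{X}$ through
  the origin with weights $1/\sigma_{Y_i}^2$, algebraically the
  $1/\mathrm{se}^2$-weighted mean of the Wald ratios. The residual dispersion
  $\hat\sigma$ may inflate the SE but never deflate it: the reported SE is the
  fixed-effect SE times $\max(\hat\sigma, 1)$ (equivalently, the regression SE
  divided by $\min(\hat\sigma, 1)$). This "multiplicative random effects"
  convention is declared explicitly because method names alone do not fix it.
* **MR-Egger**: the same regression with a free intercept. A non-zero
  intercept indicates directional horizontal pleiotropy; its two-sided normal
  p-value is the pleiotropy test. SEs carry the same $\max(\hat\sigma,1)$
  dispersion multiplier. At least 3 instruments are required; screens record
  a missing value below that, rather than failing. Instruments are not
  re-oriented before the regression.
* **Maximum likelihood**: the joint model
  $\hat\beta_{X_i}\sim N(\xi_i,\sigma_{X_i}^2)$,
  $\hat\beta_{Y_i}\sim N(\theta\xi_i,\sigma_{Y_i}^2)$ with per-instrument
  nuisance effects $\xi_i$. Profiling the $\xi_i$ analytically reduces the
  deviance to $Q(\theta)=\sum_i (\hat\beta_{Y_i}-\theta\hat\beta_{X_i})^2 /
  (\sigma_{Y_i}^2+\theta^2\sigma_{X_i}^2)$, minimised by Brent's method from
  the IVW start; the SE comes from the numerical curvature of the profile
  likelihood (observed information). The heterogeneity statistic is the
  likelihood-ratio against the saturated model that fits every instrument
  exactly, i.e. $Q(\hat\theta)$ on $k-1$ df. This LRT construction is the
  declared interpretation of "maximum-likelihood heterogeneity"; the
  literature names the method without printing formulas.
* **Cochran's Q**: $\sum_i w_i (r_i - \hat\theta_F)^2$ over Wald ratios
  $r_i$ with $w_i=(\hat\beta_{X_i}/\sigma_{Y_i})^2$ and the fixed-effect IVW
  estimate $\hat\theta_F$, referred to $\chi^2_{k-1}$.

All confidence intervals are symmetric normal at 95%
($\Phi^{-1}(0.975)=1.959964$) and all p-values two-sided normal. For the
binary outcome, log-odds are reported as log risk ratios and exponentiated
into risk ratios; at ~2% prevalence the rare-outcome approximation makes the
distinction negligible and no attenuation correction is applied.

## Harmonisation

Exposure and outcome records are aligned onto the exposure's effect allele.
Unambiguous mismatches (swapped allele order, opposite strand) are corrected
by flipping the outcome beta and complementing its allele frequency;
palindromic variants (A/T, C/G) are resolved by requiring both effect-allele
frequencies to fall outside $0.5 \pm 0.08$ (i.e. outside [0.42, 0.58]) and
flipping when they disagree about which side of 0.5 they are on. The window
width is a package convention — common MR practice, not a value fixed by the
screening literature. Palindromic variants with a missing frequency are
dropped (conservative). Harmonisation is idempotent and flip-involutive,
both enforced by property tests. Downstream p-values are recomputed from
beta/se as two-sided normal so the pipeline is internally consistent; the
file's p-value column is used only for instrument selection.

## Instrument selection, LD and proxies

Instruments are variants with $p < 5\times10^{-8}$ (strict inequality),
greedily LD-clumped against a reference dosage panel: retain the smallest
p-value, discard everything within ±10,000 kb on the same chromosome with
$r^2 > 0.001$, repeat. Ties break lexicographically by variant id, making
clumping deterministic. LD is the Pearson correlation of unphased allele
dosages. Variants absent from the panel are retained untested and logged —
retention is the less destructive default. Instruments missing from the
outcome GWAS are replaced by the best in-window proxy with $r^2 > 0.8$
(strict), ties broken by distance then id; the sign of $r$, after aligning
the proxy record to the panel's counted allele, orients the substituted
effect. Proxy substitution reuses the proxy's beta/se magnitudes — it is
bookkeeping, not re-estimation.

## Phenome-wide correction and reverse MR

The screen-wide threshold divides $\alpha = 0.05$ by the effective number of
independent traits, estimated from the spectral decomposition of the
trait–trait correlation matrix. The default estimator is Nyholt's
$M_{\mathrm{eff}} = 1 + (M-1)\,(1 - \mathrm{Var}(\lambda)/M)$; the Li–Ji
variant $\sum_j [\mathbb{1}(\lambda_j \ge 1) + (\lambda_j - \lfloor\lambda_j\rfloor)]$
is available. Both are bounded by $[1, M]$, so the corrected threshold never
falls below plain Bonferroni $\alpha/M$. Trait correlation is estimated from
the Pearson correlation of z-score columns over instruments shared by every
exposure's GWAS — a deliberate simplification of metaCCA/LD-score-based
inputs that is adequate for synthetic data, where all traits are measured
over a common variant set; with fewer than ~30 shared variants a warning is
logged and with fewer than 2 the Bonferroni threshold is used. Reverse MR
applies identical machinery with the roles swapped, the disease's own
genome-wide hits serving as instruments; a forward hit whose reverse
estimate also passes the (by default, forward) threshold is flagged as
possible reverse causation.

## Mediation

The two-step decomposition works on the beta (log-risk) scale: indirect
effect = step1 × step2 (exposure→mediator times mediator→outcome), with the
product delta-method SE $\sqrt{\beta_1^2\sigma_2^2 + \beta_2^2\sigma_1^2}$,
and proportion mediated = 100 × indirect / total. A mediator whose indirect
effect opposes the total effect is labelled inconsistent and gets no
proportion (an exactly zero indirect effect counts as consistent, mediating
0%). Proportions outside [0, 100]% are reported verbatim with a warning —
truncating would hide the weak-total-effect pathology that produces them. No
binary-scale (odds-ratio decomposition) mediation is attempted.

## Colocalization and the conditional scan

Each variant's evidence is a Wakefield approximate log Bayes factor: with
$V = \mathrm{se}^2$, prior effect variance $w$ and shrinkage
$\lambda = w/(V+w)$, $\log\mathrm{ABF} = \tfrac12[\log(1-\lambda) + z^2\lambda]$.
Per-variant priors are $p_1 = p_2 = 10^{-4}$ (trait-specific causal variant)
and $p_{12} = 10^{-5}$ (shared), the de facto standard defaults; the prior
effect SD is 0.2 on both trait scales. Hypothesis masses are
$[1,\; p_1 S_1,\; p_2 S_2,\; p_1 p_2 (S_1 S_2 - S_{12}),\; p_{12} S_{12}]$
with $S_1, S_2, S_{12}$ the sums of exponentiated (co-)log-ABFs, all
evaluated with log-sum-exp — no raw exponentials — and a numerically
negative H3 mass guarded to zero with a warning. The analysis region is
±250 kb around the index variant (a 500 kb window) and is restricted to
variants present in both datasets.

The conditional scan approximates a summary-statistic joint model: for
variant $j$ with panel LD $r$ to the index,
$z_{j|{\rm index}} = (z_j - r\,z_{\rm index})/\sqrt{1-r^2}$, over a 1 Mb
window (±500 kb). This assumes standardised effects and a well-matched LD
panel — a declared approximation of full stepwise joint modelling. Variants
with $|r| \ge 0.99$ are reported as skipped rather than errored; a region
has a secondary signal if any non-index, non-skipped variant remains below
$5\times10^{-8}$ after conditioning.

## Synthetic data generator

The generator draws individual-level cohorts so that every downstream
statistic is an honest estimate rather than a construction:

* **Genotypes**: independent `Binomial(2, MAF)` dosages, MAF ~ U(0.05, 0.5).
  Unlinked SNPs cycle across 22 chromosomes with same-chromosome neighbours
  20 Mb apart, outside any standard clump window — as truly independent GWAS
  instruments are in practice. Regional data instead use a latent Gaussian
  AR(1) process (adjacent-variant correlation ρ = 0.9) thresholded into two
  haplotypes per individual, giving LD that decays geometrically with
  distance (attenuated by dichotomisation, as in real dosage data).
* **Exposure**: unit-variance continuous trait; 30 causal SNPs jointly
  explain h² = 0.3, each an equal share with random sign so instrument
  strength is controlled by configuration rather than left to chance; a
  standard-normal confounder contributes effect 0.3.
* **Outcome**: Bernoulli from a logistic model with causal effect θ = 0.4
  per exposure SD (mirroring the adiposity effect size the package's worked
  examples use), confounder effect 0.2, optional balanced or directional
  pleiotropy on the instruments, and 10 outcome-specific risk loci (0.8
  log-odds per allele, comparable to major thrombophilia variants) so the
  reverse direction can be instrumented. The intercept is solved numerically
  (Brent) so the population prevalence is 2%, the case fraction of the
  motivating disease GWAS. Per-SNP summary statistics come from simple
  linear regressions (continuous traits) and per-SNP logistic regressions
  (intercept + dosage, Newton-iterated, vectorised across SNPs) —
  cross-checked against reference OLS/logit fits in the test suite.
* **Mediator triplet**: three disjoint cohorts; mediator = step1 × exposure
  + own genetic component (10 SNPs, h² = 0.2, so the mediator is
  instrumentable in its own right, as cis loci make circulating proteins) +
  noise; outcome combines a direct exposure effect and step2 × mediator.
  Defaults step1 = 0.17, step2 = 0.42, direct = 0.33 give a generative
  proportion mediated of step1·step2/(step1·step2 + direct) ≈ 17.8%.
* **Region pair**: one causal variant per trait (same variant iff sharing is
  "shared"; placed at 1/4 and 3/4 of the block when "distinct"), effect
  sized for an expected association z ≈ 8 at n = 10,000.

All randomness flows through `numpy.random.default_rng` (PCG64); a fixed
seed reproduces every output byte-for-byte. Truth records carry all
generative parameters, sufficient to recompute any recovery comparison.

**What the generator does not emulate**: realistic human LD maps and allele
frequency spectra, sample overlap between the two GWAS, winner's curse from
in-sample instrument discovery, population stratification, and assay-level
properties of protein measurements. Passing recovery tests therefore show
that the pipeline's logic and estimators behave correctly under a faithful
two-sample generative model — not that any particular real-data finding
would replicate.

## Problem sizes and experiment design

The packaged experiments use cohorts of 20,000 (5,000 for the 500-replicate
null calibration), 100 SNPs, regional blocks of 100 variants at n = 10,000
with 1,000-individual panels, 50 mediation replicates and 25 replicates per
regional scenario — sizes at which every summary in the acceptance report is
stable while the whole suite runs on a single CPU in minutes. The null
calibration uses the continuous-outcome generator: with only ~100 cases per
cohort at 2% prevalence and n = 5,000, per-SNP logistic estimates carry a
small-sample bias that would contaminate a test whose target is the
*estimators'* calibration; rare-binary behaviour is exercised separately by
the recovery experiments at n = 20,000. The directional (forward vs
reverse) discrimination test likewise uses a continuous outcome so that
direction, not rare-outcome power, is what is measured.

## Known limitations

* The IVW/Egger dispersion conventions (min/max with 1) are one of several
  in circulation; estimates are unaffected, only SEs.
* Wald-ratio SEs ignore exposure-side uncertainty (first-order delta only);
  weak single instruments therefore look more precise than they are — the
  motivation for the colocalization follow-up of single-SNP findings.
* The conditional scan is a one-index approximation; it does not iterate to
  a full joint model and can miss masked signals in strong LD.
* The proxy machinery assumes the panel represents both GWAS populations;
  no population matching is validated.
* Meff-based correction treats the shared-instrument z-correlation as the
  trait correlation; with few shared variants this is noisy, and the code
  falls back to Bonferroni rather than guessing.
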