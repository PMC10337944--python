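# Methods

## The design

Two-sample Mendelian randomization (MR) treats genetic variants as
instrumental variables for an exposure: if a SNP (i) is robustly associated
with the exposure, (ii) shares no confounders with the outcome, and (iii)
affects the outcome only through the exposure, then the ratio of its outcome
association to its exposure association estimates the causal effect. All
inputs are per-SNP association summaries (beta, SE, allele pair, EAF, p, N)
from non-overlapping samples; betas are per effect allele, in SD units for
continuous traits and log-odds for binary traits.

The network extension adds mediators. With exposure X, mediators M_k and
outcome Y, the univariable X→Y estimate is the **total** effect; the
coefficient of X in a multivariable MR (MVMR) jointly instrumenting X and the
mediator(s) is the **direct** effect; and the difference method gives

    indirect = total − direct,      PM = indirect / total.

PM is computed on the log-odds scale. The identity `total = direct +
indirect` holds to machine precision by construction. Negative PM or PM > 1
("inconsistent mediation", e.g. when single-mediator PMs overlap or direct
and total effects have opposite signs) is reported as-is with a warning,
never clipped.

## Instrument selection and harmonization

Instruments are variants with p < 5×10⁻⁸ for their exposure, greedily
clumped: repeatedly keep the smallest-p unassigned variant and discard
neighbours within 10,000 kb on the same chromosome (ties broken by
chromosome/position). LD-aware clumping (r² < 0.001) is available when the
caller supplies an r² matrix; no reference panel is bundled, so the default
is distance-only — deterministic and conservative.

Harmonization aligns every trait to the exposure's effect allele: swapped
alleles flip the beta sign and mirror the EAF; complementary alleles are
strand-corrected then aligned. Palindromic variants (A/T, C/G) cannot be
strand-resolved from alleles, so they are kept only when both EAFs lie
outside [0.42, 0.58] and, after alignment, agree on the minor allele;
otherwise (including whenever an EAF is missing) they are dropped with reason
`palindromic-ambiguous`. Every input variant ends up exactly once in the kept
set or the drop log. A stored p-value more than a factor of 10 from the
normal two-sided tail of beta/SE raises a warning only — published summary
files often truncate p-values.

For MVMR the instrument set is the union of each exposure's genome-wide
significant instruments, re-clumped jointly on the per-variant best p, then
harmonized across all traits (first exposure defines orientation).

## Estimators

All estimators regress outcome betas on exposure betas weighted by
w_j = 1/se_out_j².

* **IVW** — weighted regression through the origin;
  fixed-effect SE = (Σ w_j bx_j²)^(−1/2). The multiplicative random-effects
  model inflates the SE by max(1, √(Q/(J−1))) — it never deflates. The
  default `auto` model follows common practice: random effects exactly when
  Cochran's Q has p < 0.05.
* **MR-Egger** — same regression with a free intercept after orienting every
  SNP to bx ≥ 0. The slope is the causal estimate under InSIDE (instrument
  strength independent of direct effects); the intercept estimates the mean
  directional pleiotropy and its Wald test is the pleiotropy diagnostic.
  Both SEs carry the max(1, √(Q/(J−2))) inflation; statsmodels' WLS (which
  scales by √(Q/df) without the floor) is used in the tests as an
  independent check of the algebra.
* **Maximum likelihood** — observed (bx_j, by_j) are independent normals
  centred at (γ_j, θγ_j); the nuisance γ_j profile out in closed form,
  leaving −2logL(θ) = Σ (by_j − θbx_j)²/(sy_j² + θ²sx_j²). The optimum is
  found by bounded minimization on θ ∈ [−10, 10] polished by a derivative
  root (tolerance 1e-8, iteration cap 500, all configurable); the SE comes
  from the numerical curvature of the profile. With sx → 0 this reproduces
  fixed-effect IVW exactly (estimate and SE).
* **MR-RAPS** — solves Σ ψ(t_j)·∂t_j/∂θ = 0 with standardized residuals
  t_j = (by_j − θbx_j)/√(sy_j² + θ²sx_j² + τ²). ψ is the identity (l2) or a
  Huber clip at 1.345 (the standard 95%-efficiency constant). With
  overdispersion the moment condition mean(t_j²) = 1 pins τ² ≥ 0, alternated
  with the θ root until joint convergence. The root is bracketed on a
  201-point grid over [−10, 10] (the root nearest zero is refined by Brent's
  method); SEs use the sandwich formula, p-values the normal approximation.

Single-SNP analyses use the Wald ratio by/bx with first-order delta SE
sy/|bx|.

**MVMR** solves the weighted normal equations of by on the J×K exposure-beta
matrix without intercept; coefficient k is exposure k's direct effect. A
correlation > 0.9999 between any two columns (or rank deficiency) raises a
collinearity error naming the offending pair. Random-effects inflation uses
max(1, √(Q/(J−K))).

## Sensitivity battery

* **Cochran's Q** around the IVW line (df = J−1) or the Egger fit (df = J−2),
  upper-tail χ² p. The regression-residual form is used throughout.
* **MR-PRESSO.** Leave-one-out slopes θ̂(−j) give residuals
  r_j = by_j − θ̂(−j)bx_j and the observed weighted RSS. A parametric
  bootstrap (by*_j ~ N(θ̂(−j)bx_j, sy_j), bx*_j ~ N(bx_j, sx_j), default
  1000 replicates, mandatory seed) yields the global p with the plus-one
  correction (p ≥ 1/(n_sim+1), never zero). Per-SNP outlier p-values compare
  r_j² with its simulated counterparts, Bonferroni-multiplied by J; flagged
  SNPs (adjusted p < 0.05) feed the distortion test, which compares
  D = (θ̂_raw − θ̂_corrected)/|θ̂_corrected| against removing equally many
  random SNPs. The corrected estimate is IVW (auto) on the retained SNPs;
  the pipeline re-runs the whole estimator battery on that set, mirroring
  the "after removing outliers" workflow. A single pass is the default; an
  `iterate` flag re-tests after each removal. Weighted (1/sy²) residual sums
  are the default, the unweighted variant is a flag.
* **Steiger directionality.** Per-SNP r² = F/(F + n − 2) with F = (beta/se)²
  against each trait, summed over instruments; the direction is "correct"
  when the instruments explain strictly more variance in the exposure.
  The p-value is a two-sample z test on Fisher-transformed √r² with
  variances 1/(n−3). For the binary outcome this is the F-based
  approximation on the observed scale — an approximation, noted as such.
* **Leave-one-out.** J re-fits of IVW (auto), each excluding one SNP; a row
  is flagged when the sign changes or nominal significance is lost relative
  to the full fit.
* **Power.** For a binary outcome the IVW z statistic is approximately
  N(x, 1) with non-centrality x = √(n·r²·cf(1−cf))·|ln OR|, giving two-sided
  power Φ(x − z_{1−α/2}) + Φ(−x − z_{1−α/2}). The two-sided form is used
  because it equals α at OR = 1; a Monte-Carlo simulation of the full IVW
  z-test validates the constant to within 3 percentage points in the tests.

## The synthetic-data generator

`NetworkScenario` encodes a linear structural model on standardized scales:
SNP j carries exposure effect γ_j; mediator k responds α_k·X plus its own
instruments; the outcome liability is δ·X + Σ ρ_k·M_k plus optional per-SNP
pleiotropy η_j (none / balanced / directional). Implied per-SNP effects,
δ_total = δ + Σ α_k ρ_k and PM_k = α_k ρ_k / δ_total are computed exactly.
Per-trait estimates add independent N(0, se_j) noise with the closed-form
se_j = 1/√(2p_j(1−p_j)N), divided by √(cf(1−cf)) for the binary outcome's
log-odds scale — each trait from its own random stream, emulating
non-overlapping samples. Variants sit > 10,000 kb apart so distance clumping
is a no-op unless a test supplies LD.

Causal effects are drawn from N(0, σ) **conditioned on detectability**
(|true z| ≥ 7 by default): published instrument lists contain only
genome-wide-significant loci, and this truncation is the summary-level model
of that fact. Without it, effects pile up at the selection threshold and
winner's curse attenuates every ratio estimator by ~10%, which would
confound parameter-recovery checks with selection bias.

The default scenario reproduces the conditions of the education→MDD network
study the package is designed around: total effect ln(0.693) per SD of
schooling; four mediators (neuroticism, BMI, smoking, household income) with
α_k taken from the published education→mediator ORs (0.716, 0.672, 1.101,
1.927) and ρ_k solved so the single-path mediated proportions are
{52.92, 15.54, 31.86, 81.30}%; GWAS sample sizes 766,345 (exposure),
329,821 / 336,107 / 359,706 / 397,751 (mediators) and 173,005 with 34.6%
cases (outcome); ~256 exposure instruments (σ_γ = 0.025, per-SNP h² ≈
2.3×10⁻⁴, together ≈ 6% of variance) and {65, 262, 67, 40} mediator-specific
instruments. Those published proportions sum to 181.6%, which in a linear
model forces the direct effect (δ = +0.2993) to oppose the total effect —
the generator reproduces this faithfully and the joint decomposition is
reported as inconsistent mediation.

What the generator does *not* emulate: LD between instruments, sample
overlap, assortative mating, population stratification, individual-level
binary sampling (the log-odds scale uses a normal approximation whose error
is bounded by the z-calibration test), or winner's curse (deliberately, per
the truncation above). Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to those real-data
complications.

## Validation problem sizes

The test suite validates at sizes chosen to make each check sharp yet quick:
estimator recovery and mediation recovery run on the default scenario
(754 SNPs, 6 traits); null calibration uses 500 replicates of a 60-SNP null
edge (MR-PRESSO with 500 bootstrap draws each); outlier machinery uses 100
replicates of a 6-instrument edge, where a 10-sigma displacement shifts the
pooled estimate by ~4 SEs so that flagging and strict bias reduction are
near-certain — with many instruments the same displacement drowns in
baseline noise and strict improvement is not a property any method could
guarantee. Whole-suite runtime is well under a minute on one CPU.

## Numerical conventions and edge cases

* CIs are 95% normal; ORs and their CIs are exp-transformed from the log
  scale. p-values are two-sided normal tails of beta/SE throughout (χ² for
  Q, empirical with plus-one correction for MR-PRESSO).
* PM confidence intervals use the delta method treating total and direct
  estimates as independent, var(PM) ≈ (d²/t⁴)·var(t) + var(d)/t²; a
  parametric bootstrap is available. Independence is conservative here —
  the two estimates share the exposure-instrument outcome noise, so the
  delta-method CI overstates the spread.
* Zero total effect makes PM undefined (error); a zero exposure beta makes
  the Wald ratio undefined (error); estimators demand their minimum SNP
  counts (1/2/3/3/4 for IVW-fixed/IVW-random/Egger/RAPS/PRESSO) and raise
  otherwise.
* Coordinates are 1-based; the clump window test is
  |pos_i − pos_j| ≤ window_kb·1000 on the same chromosome.
* All simulation-based procedures take explicit seeds; identical
  config + seed gives byte-identical report bundles.
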