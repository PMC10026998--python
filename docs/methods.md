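# Methods

## The measurement model

All analyses use a four-indicator bifactor model: indicators 1–2 load a
specific factor f1, indicators 3–4 load f2, and all four load a general
factor g.  Latents are orthogonal with variance fixed to 1 (the scaling
convention that identifies the loadings), so the model-implied
covariance at moderator value m is

    Σ(m) = λg λgᵀ + c1(m) c1(m)ᵀ + c2(m) c2(m)ᵀ + Θ(m)

where c_p(m) holds the specific loadings λ_f0 + λ_f1·m of pair p and
Θ(m) is diagonal with entries max(θ0 + θ1·m, 10⁻⁶).  Moderation is
applied to one indicator at a time, in three variants: loading slope
free, residual slope free, or both.  The g-loadings and intercepts are
never moderated.  An optional log-linear residual link
θ(m) = θ0·exp(θ1 m) is available for sensitivity analysis; the linear
link is the default because it matches the constraint mechanism of the
commercial SEM programs this style of analysis is normally run in.

With two indicators per specific factor, the specific loadings are not
separately identified; the default constrains them equal within each
pair, giving 14 free parameters against the 14 first- and second-order
moments (df = 0, reported as such, with fit indices clamped to their
perfect-fit values).  A stricter `lambda_f_equality="all"` option (one
common specific loading) yields df = 1.  Degrees of freedom are always
computed from the actual parameter count, never assumed.

The pair-equality baseline is only *tetrad*-identified, and that
matters for inference near the null: the split of a pair's common
covariance between λg and λ_f0 rests on a near-flat likelihood ridge,
so on data with no true moderation the fitted λ_f0 is bimodal across
replications and the moderation slope's finite-sample spread runs
roughly twice its asymptotic (sandwich) standard error — Wald tests
over-reject even though the estimator and its standard errors are
correct (the information equality A = B holds at the truth, and the
optimum is reproducible across restarts).  Under the `"all"` constraint
the ridge disappears and slope Wald tests are calibrated (≈ 10%
two-sided rejections at the 5% level over 40 null fits, median
ΔBIC > 0).  Calibration claims in the test suite are therefore made
under the identified `"all"` parameterization; sign-pattern analyses,
which compare large systematic effects, use the default.

## Estimation

The likelihood is the product over cases of 4-variate normal densities
with per-case covariance Σ(m_i).  Likelihood and gradient are evaluated
in closed form with batched 4×4 Cholesky factorizations; for a
rank-one update dΣ = e_j cᵀ + c e_jᵀ the per-case score is
q_j(cᵀq) − (Pc)_j with P = Σ⁻¹ and q = P(y − ν), and residual-variance
derivatives are ½(q_j² − P_jj), masked where the variance floor is
active.  Optimization is L-BFGS-B from moment-based starts (moderated
fits start at the baseline solution with zero slopes), with 5 jittered
restarts by default (jitter SD 0.05, deterministic restart seeds),
followed by Newton polishing steps that reuse the finite-difference
Hessian.  Analytic gradients agree with central finite differences to
relative 1e−5 (verified in the test suite); the per-case likelihood
agrees with a brute-force density recomputation to better than 1e−8.

Convergence is declared when the per-case-average gradient norm falls
below 1e−5.  One genuine exception is handled explicitly: when a
positive residual slope drives θ0 + θ1·m below the floor for the most
extreme negative moderator values, the objective is kinked at the
optimum and no gradient criterion can be met; the fit is then accepted
on a no-ascent certificate (the Newton direction yields no improving
step) and flagged `at_variance_floor`.

Standard errors are sandwich estimates √diag(A⁻¹BA⁻¹)/n with A the
average negative Hessian (finite differences of the analytic gradient)
and B the average outer product of per-case score vectors.  No
likelihood-scaling correction beyond the sandwich is applied.  BIC is
−2·loglik + k·ln(n) exactly; a moderated model is called decisively
better when its BIC undercuts the baseline by more than 10.  RMSEA is
√(max(χ²−df,0)/(df·n)) with the 90% CI from noncentral-χ² inversion
(lower λ solves CDF(χ²; df, λ) = 0.95, upper 0.05), and CFI uses the
means-and-variances-only independence model.

## The synthetic cohorts

**Case selection.**  17,000 cases from a 4-variate standard normal with
r12 = .71, r34 = .66 and all four cross-pair correlations .57; the
12,218 cases with the lowest standardized first-principal-component
scores are retained.  The retained-count rule (rather than the nominal
0.3 threshold, which would retain ~62%) is the default because the
count — 71.87% — is the value jointly consistent with the
post-truncation correlations and skewness under closed-form
truncated-normal algebra; the oracle values are mean skewness −0.313,
r12 = .550, r34 = .485, between-pair mean .341, and the selection-score
variance 1 + αλ − λ² = 0.508.  The literal threshold rule remains
available behind a flag.

**Task density.**  A 4-variate normal with the real-battery correlation
matrix (.536/.464 within pairs, .289–.349 between), n = 11,338, passed
through the piecewise power map (left exponent 1.08, right 0.93).  The
map's population skewness by Gauss–Hermite quadrature is −0.19; the
large-n simulated value matches within 0.01.  This is the analytic
value for the stated exponents; stronger exponents would be needed to
reach ≈ −0.3, so the deformed cohort's skewness is checked against the
quadrature oracle, not a target of ≈ −0.3.

**True SLODR.**  y_j = λg·g + (λf0 + λf1·g)·f_pair(j) + e_j with
e_j | g ~ N(0, max(θ0 + θ1·g, 0.01)).  Defaults are calibrated by
moment matching: λg = √.33 ≈ 0.5745, λf0 ≈ 0.4471, λf1 = −0.10,
θ0 = 0.46 and θ1 = −2·λf0·λf1 ≈ 0.0894, giving unit variances,
within-pair correlation λg² + λf0² + λf1² = .54, between-pair
λg² = .33, and — because E[y³] = 3λg(2λf0λf1 + θ1) — exactly zero
population skewness.  The variance floor at 0.01 clips only below
g ≈ −5.1 (probability ~10⁻⁷).

**Item responses.**  Honest respondents follow the 2PL,
P(correct) = 1/(1+exp(−a(θ−b))); an injected guesser answers every item
correctly with probability 0.2 (random choice among five options),
regardless of ability.

What these generators do *not* emulate: integer sum scores (all scores
are continuous), battery sizes beyond four subtests, non-normal base
populations, and respondent-level dependence between subtests beyond
the factor structure.  Passing tests therefore demonstrate the
mechanics of the artifacts, not distributional realism of any
particular test battery.

## The moderator and its circularity

The moderator is the standardized first-principal-component score of
the same four indicators (correlation-matrix PCA, eigenvector oriented
to positive component sum).  Its population correlation with the
generating g at default true-SLODR parameters is
4λg/√(1ᵀΣ1) ≈ 0.775 — as high as a four-indicator battery allows, but
far from a perfect g proxy.

Because m is a function of y, the estimator's exogeneity assumption is
violated by construction — deliberately, since that is how the method
is used in practice.  One consequence is worth stating plainly: on
completely unmoderated multivariate-normal data, fitting with the
circular PC1 moderator produces strongly "significant" moderation
slopes (conditioning on m = wᵀy makes the conditional second moments
around a fixed ν quadratic in m, which the loading slopes absorb).
Estimator calibration is therefore assessed on data simulated from the
unmoderated model with an *exogenous* moderator, where slope Wald tests
reject at near-nominal rates and the BIC penalty dominates.  For the
case-selection design, the selection score is computed on the initial
17,000 and the analysis moderator is recomputed on the retained cohort
— two distinct quantities, never shared.

## The IRT stage

Each scale is fit separately by marginal-ML EM: 41 equally spaced
quadrature nodes on [−4, 4] weighted by the standard-normal density,
exact E-step, and per-item Newton M-steps with step-halving on the
item's expected complete-data log-likelihood so the observed-data
log-likelihood is monotone non-decreasing by construction (asserted on
every fit).  Abilities are EAP scores (bounded for perfect and zero
patterns); discriminations are clipped to [0.01, 8]; items answered
identically by everyone are dropped with a warning.  Convergence: the
per-case log-likelihood change falls below 1e−7, capped at 500 cycles.

Guesser flagging is strict on both constants: a flag requires predicted
probability strictly below 0.2 on a correct answer, and exclusion
requires strictly more than 10 flags within a single scale.  One
fit–flag–exclude–refit pass is the default; iterating to a fixed point
is available behind a flag.

A structural property of this rule, found during calibration and worth
knowing before using it: against flat random guessers it has
essentially **no power on difficulty-matched scales**.  Flags within a
scale are binomial with success 0.2 over the items whose predicted
probability is below 0.2, and the EAP estimate tracks the guesser's raw
score, so the expected flag count approximately equals the guesser's
expected score (~6 of 30) — far below the cutoff of 11; even in the
limiting all-items-eligible case, P(Binom(30, 0.2) ≥ 11) ≈ 2.6% per
scale.  Detection requires a bank geometry that decouples the ability
estimate from the hard-item successes: `make_detection_bank` pairs a
few highly discriminating easy anchors (a = 3, b ≈ −2; failing them
pins a random responder's ability far below the honest range) with a
long block of weakly discriminating hard items (a = 0.8, b ≈ 2.5–3.5;
all flag-eligible at that ability, contributing little upward pull).
On that battery the rule excludes ~80% of injected guessers with zero
false positives (exclusion rate ≈ 1.6% at 2% injected).  Detection
tests use this geometry; the no-power result on matched scales is a
property of the strict rule, not of the implementation.

## Problem sizes and numerical choices

Simulated studies run at the design's native sizes (17,000 → 12,218;
11,338; 10,000); repeated-seed test batteries use n = 10,000 with 5
seeds for sign patterns and 10 seeds for recovery and null calibration,
and 2 jittered restarts per fit (the grids are well-conditioned; the
package default remains 5).  Ties in the rank-inverse-normal transform
receive average ranks, preserving the mean of (R − 0.5)/N within tie
groups.  Skewness is always the adjusted Fisher–Pearson G1
(m3/m2^{3/2} · √(n(n−1))/(n−2)).  PCA sign ties are broken toward a
positive loading sum; selection ties at the retained-count boundary are
broken by row order.

## Known limitations

* The equality constraint behind the baseline's df is configurable but
  the df = 1 convention of some published baselines corresponds to an
  unstated extra constraint; comparisons of absolute fit indices across
  software should use the `lambda_f_equality="all"` setting.
* Sandwich SEs are plain; no small-sample or likelihood-scaling
  correction is applied.
* The moderated model is fit per indicator; simultaneous moderation of
  several indicators is out of scope, as are latent-moderator models,
  multi-group models, and missing data.
* The 2PL has no guessing asymptote; the guesser stage detects
  model-beating response patterns rather than modeling guessing (a 3PL
  would), which is exactly the procedure under study.
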