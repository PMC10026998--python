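# slodr-lab

Simulation and moderated bifactor analysis of scale-artifact signals of
**Spearman's Law of Diminishing Returns (SLODR)** — the classic claim
that cognitive subtest intercorrelations weaken as general ability
rises.

Modern SLODR detection fits a **moderated confirmatory factor analysis
(MCFA)**: a four-indicator bifactor model in which every subtest score
loads a general factor *g* plus one of two specific factors, and the
specific loadings λ<sub>f</sub> and residual variances θ are allowed to
depend linearly on an observed moderator *m* (the standardized first
principal-component score of the same four subtests):

    y | m  ~  N( ν, Σ(m) ),      Σ(m) = Λ(m) Λ(m)ᵀ + Θ(m)
    λ_f(m) = λ_f0 + λ_f1 · m,    θ(m) = θ0 + θ1 · m   (floored at 1e-6)

with all latent variances fixed to 1.  Negative λ<sub>f1</sub> and
positive θ<sub>1</sub> are read as ability differentiation.  The catch,
and the point of this package: **the same fingerprint can be
manufactured by measurement artifacts.**  slodr-lab generates three
cohorts with near-identical correlation matrices and skewness:

1. **true-slodr** — a generative bifactor model whose loadings really
   shrink and residuals really grow in *g*;
2. **task-density** — a plain multivariate normal whose marginal scales
   are deformed by a piecewise power map (x < 0 ↦ −(−x)^1.08,
   x > 0 ↦ x^0.93), mimicking an uneven spread of easy vs. hard items;
3. **case-selection** — a multivariate normal cohort of 17,000 truncated
   to its 12,218 lowest first-principal-component scores (skewed subject
   selection with no structural change at all);

plus the **rank-based inverse-normal transform**
φ⁻¹((R − 0.5)/N), which, applied to the case-selection cohort,
*converts a pure selection artifact into the true-SLODR signature* — a
false positive the moderation analysis cannot distinguish from the real
thing.  A two-parameter logistic IRT stage with the strict
guesser-exclusion rule (flag when a correct answer lands on an item
with predicted success probability below 0.2; exclude at more than 10
flags within one scale) rounds out the pipeline.

Everything is fit by full-information maximum likelihood with analytic
gradients, sandwich (robust) standard errors, BIC comparison against the
unmoderated baseline (|ΔBIC| > 10 counts as decisive), and the standard
covariance-structure fit indices (χ², RMSEA with noncentral-χ² 90% CI,
CFI).

## Worked example

```python
import slodrlab as sl

# selection-skewed cohort: 17,000 drawn, 12,218 lowest-PC1 retained
cohort = sl.apply_case_selection(
    sl.sample_mvn(sl.CorrelationSpec.case_selection_default(), 17_000, seed=1),
    sl.CaseSelectionParams(),
)
rep = sl.describe(cohort)
print(round(rep.mean_skewness, 3),
      {k: round(float(v), 2) for k, v in rep.within_pair.items()},
      round(rep.between_pair_mean, 2))

# rank-normalize, then run one joint moderation fit on indicator 1
norm = sl.normalize_cohort(cohort)
mod = sl.pc1_scores(norm)
base = sl.fit_mcfa(norm, mod)
fit = sl.fit_mcfa(norm, mod, sl.ModerationConfig(1, "both"), baseline=base)
print(round(fit.estimate(fit.loading_slope_name), 3),
      round(fit.estimate(fit.residual_slope_name), 3),
      round(sl.delta_bic(fit, base)[0], 1))
```

prints

```
-0.324 {'V11-V12': 0.55, 'V21-V22': 0.49} 0.35
-0.271 0.197 -282.7
```

The first line is the truncation fingerprint: mean skewness ≈ −0.32,
within-pair correlations pulled down from .71/.66 to ≈ .55/.49, and
between-pair mean ≈ .35.  The second line is the false positive: after
normalization the loading slope is strongly negative (−0.27) and the
residual slope strongly positive (+0.20) with a decisive BIC preference
for moderation (ΔBIC ≈ −283) — the textbook SLODR signature, produced
by a cohort in which no differentiation ever happened.

The full four-dataset study (true-slodr, task-density, case-selection
raw + normalized; 13 fits each) runs from the command line:

```bash
slodr-lab run --out results/ --seed 1
```

writing `report_<dataset>.csv`, `descriptives_<dataset>.json`,
`cohort_<dataset>.csv` and a reproducibility `manifest.json`.

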