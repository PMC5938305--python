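# Methods

`gambrct` implements the statistical analysis pipeline of a two-arm
randomized trial for problem gambling in which gambler/CSO (concerned
significant other) pairs are randomized as units to either couples therapy
(BCT, reference arm) or individual therapy for the gambler (CBT).  The
primary behavioral outcome is the Timeline-Followback for gambling
(TLFB-G): retrospective day-level net losses in SEK.  Questionnaire
outcomes (NODS, PHQ-9, GAD-7) are measured at four timepoints (pre, post,
3-month, 6-month follow-up).

## The two-part loss model

Day-level losses are aggregated to participant-week *average daily losses*
over the observed days of each week, so that a zero means "no gambling that
week" at every timepoint.  Weekly loss `y_it` for subject `i` in week `t`
is semicontinuous — a point mass at zero plus a skewed positive part — and
is modeled in two parts:

- occurrence: `z_it = 1{y_it > 0} ~ Bernoulli(p_it)`,
  `logit(p_it) = x_it' beta_occ + b_i1`;
- amount: `y_it | z_it = 1 ~ Gamma(alpha, mean mu_it)`,
  `log(mu_it) = x_it' beta_amt + b_i2`,

with correlated subject intercepts `(b_i1, b_i2) ~ N(0, Sigma)`,
`Sigma = [[sd_occ^2, rho sd_occ sd_amt], [. , sd_amt^2]]`.  The covariate
row `x_it` contains an intercept, a post-baseline dummy (0 only in week 0,
allowing the abrupt drop at treatment start), a restricted-cubic-spline
time basis with three knots at the 10th/50th/90th percentiles of the
observed weeks, and arm interactions with the post dummy and both spline
columns.  Spline columns are centered to vanish at week 0 and arm enters
only through post-baseline interactions, so the two arms share the baseline
mean *exactly* (randomized groups are equal in expectation at baseline);
the predicted arm contrast at week 0 is identically zero for every
posterior draw.  A config switch restricts the arm interaction to the post
dummy alone.

Week coding: the baseline month is week 0 (mean over up to 30 days);
treatment weeks are 1–10 by calendar position (a 12-week completion window
simply fills calendar weeks 11–12); post-treatment assessment is week 12,
and the 3-/6-month follow-ups are weeks 25 and 38.  Follow-up observations
enter the same continuous spline.

The marginal "overall" daily loss for a covariate row is obtained by
averaging over the two parts per posterior draw, `p * mu`, with the subject
intercepts set to zero — the interpretation is the average daily loss per
week for an individual with a median amount of random effects (the random
effects are deliberately not integrated out).  Arm contrasts (CBT − BCT)
and within-arm changes from baseline are computed per draw and summarized
as posterior medians with equal-tailed 95% credible intervals.

### Priors

All configurable; defaults:

| parameter | prior | rationale |
|---|---|---|
| fixed effects (link scale) | Normal(0, 10²) | effectively non-informative |
| sd_occ, sd_amt | half-Student-t(3, 0, 2.5) | weakly informative, standard for hierarchical SDs |
| rho | Uniform(−1, 1) | no prior direction |
| gamma shape | half-Normal(0, 5) | weakly informative, positive |

### Computation

No gradient-based PPL is used; the sampler is built from numerical
primitives:

1. **Marginalization.** The 2-D subject intercepts are integrated out with
   *adaptive* tensor-product Gauss–Hermite quadrature (default 9 nodes per
   dimension).  Node grids are centered per subject at the conditional mode
   of `(b_i1, b_i2)` with Laplace curvature scaling (computed once per fit
   at the posterior mode by a damped Newton iteration, inflated ×1.6), and
   the fixed proposal is importance-corrected exactly inside the quadrature
   sum.  Prior-centered grids were rejected: with ~14 observations per
   subject the conditional density is much narrower than, and shifted from,
   the prior, and a prior-scaled grid can miss it by thousands of log-lik
   units.  With the lower-triangular Cholesky parameterization the
   occurrence part depends only on the first node coordinate, and the gamma
   log-density separates into observation-only and node-only factors, so
   the evaluation never forms an (observations × full-grid) array.
2. **Mode finding.** The MAP of the marginal posterior is found with
   L-BFGS-B using batched forward-difference gradients (all perturbations
   evaluated in one vectorized call); the quadrature centers are refreshed
   at the first-pass mode and the optimization repeated.
3. **Sampling.** emcee's ensemble sampler with a move mixture: 50% an
   independence Metropolis–Hastings move proposing from the Laplace
   approximation at the mode (with the exact asymmetry correction — wherever
   the Laplace approximation is close to the posterior this decorrelates
   walkers in a handful of steps), plus differential-evolution and snooker
   moves for the non-Gaussian remainder; walkers are initialized from the
   same Laplace approximation.  The default configuration runs 4
   *independent* ensembles of 40 walkers (500 warmup + 750 retained steps);
   pooled per-ensemble draws act as chains for rank-normalized split R-hat
   and ESS (with a single ensemble, walker groups serve as pseudo-chains —
   a more optimistic diagnostic, used only in reduced simulation-study
   settings).  The convergence gate is R-hat < 1.01 for default settings
   and 1.1 for reduced ones; there is no divergence diagnostic because the
   sampler is not Hamiltonian, and that field is reported as not
   applicable.
4. **Subject intercepts** for posterior predictive simulation are recovered
   per retained draw by sampling-importance-resampling from each subject's
   conditional posterior, proposing from the same conditional Laplace
   approximations.

Missing weeks are simply absent likelihood terms, which is valid inference
under missing at random (MAR).

## Questionnaire models

NODS, PHQ-9 and GAD-7 totals are fit with Bayesian Gaussian linear mixed
models: timepoint as a categorical variable, an arm main effect, arm ×
timepoint interactions, and subject random intercepts, fit separately per
instrument and respondent role (NODS gambler-only).  In contrast to the
loss model, the baseline arm difference is freely estimated — the
assessment tables report a pre-treatment "difference from BCT" row.  The
subject intercept is integrated analytically (compound-symmetric marginal
covariance `sigma² I + tau² J` via the rank-one Woodbury identity) and the
10–12-dimensional posterior is sampled with the same ensemble machinery.
Priors mirror the loss model.  A Gaussian likelihood is used despite the
bounded scores; this matches ordinary linear mixed modeling practice for
such totals and is a documented approximation, not an oversight.

## Instruments and eligibility

Scoring is exact table lookup: PHQ-9 (0–27; bands 0–4 / 5–9 / 10–14 /
15–19 / 20–27), GAD-7 (0–21; 0–4 / 5–9 / 10–14 / 15–21), PGSI (0–27;
problem-gambling threshold total ≥ 8; standard 0 / 1–2 / 3–7 / 8+
interpretive bands attached), AUDIT (0–40; hazardous-use flag strictly
above 7 for men and above 5 for women; with unspecified sex the flag is
undefined, never silently false), and NODS (17 binary items onto 10 DSM-IV
criteria, two-item criteria either OR-combined or gated so each criterion
contributes at most one point; the published instrument's gating structure
is encoded as a table in `instruments.py`).  Pair eligibility: gambler
PGSI ≥ 8, CSO below the threshold, relationship ≥ 3 months, both adults,
no severe-psychiatric flag on either (the flag is supplied upstream; no
symptom inventory is modeled).

## Synthetic trials

Two generators with different jobs:

- `generate_from_model` draws weekly tables *exactly* from the two-part
  model — the correct tool for parameter recovery and coverage studies.
  Default truth is calibrated to the scale of the study conditions:
  baseline occurrence ≈ 0.7 and positive-week mean ≈ 1430 SEK/day (median-
  subject marginal ≈ 1000 SEK/day), a post-baseline jump collapsing
  occurrence to ≈ 0.2 and the mean to ≈ 210 SEK/day, mild continuing
  spline decline, zero arm effects, `shape 0.9`, `sd_occ 1.0`,
  `sd_amt 0.8`, `rho 0.5`.
- `generate_trial` builds a behaviorally realistic trial: 18 gambler/CSO
  pairs randomized 1:1 as units (eligible by construction), day-level
  losses alternating geometric abstinence runs with 1–3-day binges whose
  losses are lognormal (median 2000 SEK, sigma 1), treatment start
  stretching abstinence runs ×6 and shrinking binges ×0.4, a CSO-rated
  parallel series (noisy, occasionally missing small binges), and
  questionnaire item tables whose totals are drawn around configurable
  cell means and distributed across items by sampling unit slots without
  replacement (respecting per-item maxima; NODS items are constructed
  criterion-first so they re-score exactly).
- `apply_dropout` imposes monotone missing-at-random attrition: a
  per-pair weekly hazard `expit(logit(h0) + slope·log1p(last observed
  loss/1000))` that conditions only on observed history.  Default hazards
  are illustrative (the source trial reports attrition only
  qualitatively).

What the behavioral generator does **not** emulate: reporting error and
digit preference in self-reported losses, within-week day-level
correlation beyond the binge-run structure, therapist/module-completion
effects, intermittent (non-monotone) missingness by default, and any
between-arm difference unless configured.  Passing end-to-end tests on
these data therefore demonstrates internal consistency of the pipeline,
not robustness to real-data artifacts.

## Monte Carlo checks

- **Posterior predictive checks** compare four statistics of the pooled
  weekly losses — proportion of exact zeros, median, maximum, sample
  variance (n−1) — between observed data and replicates simulated per
  posterior draw (parameters and sampled subject intercepts).  Two-sided
  tail probabilities use ties-half counting with the add-one convention
  `(count+1)/(n_rep+1)`, so an observation beyond every replicate reports
  `2/(n_rep+1)` rather than zero.
- **Coverage.** `run_coverage` simulates from the model at fixed truth,
  refits with short-chain settings (one ensemble, 300 warmup + 400
  retained steps), and reports per-parameter empirical coverage of the
  equal-tailed 95% credible intervals with binomial Monte Carlo standard
  errors; replicates failing the R-hat gate are excluded and counted.  The
  default study shape is the trial's own scale, 18 subjects × 14 weekly
  observations.
- **Baseline comparison.** A two-sample t test from summary statistics
  (pooled-variance by default, Welch behind a switch) reproduces the
  pre-randomization screening comparison from printed means/SDs/ns.

### What the coverage study shows

At the trial's scale (18 subjects, 14 weeks, default truth) the mean
empirical coverage across the 14 fixed effects is ~0.93, with individual
parameters ranging roughly 0.88–0.97 at 100 replicates (binomial MCSE
0.022 per parameter).  Occurrence-part coefficients sit at or above 0.92;
amount-part coefficients cluster near 0.91–0.93.  Cross-checking identical
simulated datasets against glmmTMB's zero-inflated-gamma mixed model
(independent maximum-likelihood implementation, Wald intervals) gives
statistically indistinguishable coverage (~0.92 at 20 replicates), and the
Laplace approximation's own Wald intervals reach 0.94 at 200 subjects — so
the remaining few points below nominal for the amount part are a property
of this truth (a heavy-tailed gamma with shape < 1 leaves each subject a
handful of extreme positive weeks, and the replicate scatter of the
estimates slightly exceeds the posterior spread at fixed truth), not of
the implementation.  Coverage is exactly nominal only as a prior-averaged
guarantee for Bayesian intervals; at a single fixed truth, deviations of
this size at pilot sample sizes are expected for any well-coded
implementation, which is what the cross-checks demonstrate.

## Numerical choices and sizes

- Quadrature: 9 Gauss–Hermite nodes per dimension, center inflation 1.6;
  accuracy vs a 31-node grid at posterior draws is ~0.05–0.1 log-lik units
  typical.
- Default MCMC: 4 × 40 walkers, 500+750 steps, thinned to ≤ 4000 retained
  draws (≥ 1000 always).  Reduced simulation-study settings: 1 ensemble,
  300+400, ≤ 2000 draws.  Seeds are mandatory everywhere; identical seed +
  config reproduces draws bit-for-bit.
- Simulation-study sizes (coverage 100 × 18-subject fits, recovery 20 ×
  200-subject fits, MAR 20 × 40-subject fits) were chosen so the whole
  suite completes on a single CPU in well under half an hour.
- Degenerate inputs: all-zero loss vectors make the gamma part
  unidentified and are rejected with that explanation; fewer than three
  distinct weeks make the spline unidentifiable; a single observation
  makes the n−1 variance undefined in the PPC statistics.

## Known limitations

- No frequentist/MLE path, no random slopes, no model comparison — out of
  scope by design.
- The ensemble sampler's R-hat is conservative at default settings (4
  independent ensembles) but optimistic in single-ensemble reduced runs.
- The behavioral generator's binge process is a two-state renewal model; it
  reproduces excess zeros, skew, and the treatment-start drop, but not
  longer-range dependence in gambling behavior.
- Week coding assumes the calendar anchors above; trials with different
  schedules must supply their own week map.
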