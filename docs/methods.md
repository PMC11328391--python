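# Methods

## Scope and data model

The unit of analysis is the trial **arm**: a (events, total) pneumonia count
pair with a role (control / intervention), a category
(non-antimicrobial / antimicrobial / antimicrobial-duplex) and a
subcategory. Tables are one row per arm (CSV), so multi-arm trials need no
schema change; a duplicated control row of a multi-arm trial carries a
`shared_control_of` link to the study owning the physical control group.

Two deduplication modes resolve shared controls. `include_once` keeps each
physical control group exactly once and is used for arm-based pooling, where
the pooled object is the population of physical groups. `split` divides the
control's events and total as evenly as integers allow across the
comparisons sharing it (remainders to the earliest comparison in input
order — a deterministic tie-break) and is used for contrast-based pairing,
so control patients are never double-counted; it conserves both sums
exactly and refuses to split a control group across more comparisons than
it has patients.

Incidence-stratified subsetting (e.g. control incidence above/below 40%)
keeps whole studies strictly beyond the threshold. Studies exactly at the
threshold are excluded from both strata and counted in the log; the
convention is a package choice, made explicit because boundary studies do
occur with round group sizes.

## Arm-level proportion pooling

Each arm enters as y = logit(e/n) with variance v = 1/e + 1/(n−e). A 0.5
continuity correction is applied to both cells only when e = 0 or e = n;
interior counts are exact. Pooling is inverse-variance with a random effect:

* Cochran's Q uses fixed-effect weights (1/v), the standard definition.
* tau^2 is REML by default; DerSimonian–Laird is provided because its closed
  form makes an independent oracle for testing.
* I^2 = 100·tau^2/(tau^2 + s^2) with the Higgins–Thompson typical
  within-study variance s^2 = (k−1)Σw/((Σw)^2 − Σw^2), and
  H^2 = 1/(1 − I^2/100). This definition (rather than (Q−df)/Q) is the one
  under which reported I^2/H^2 pairs are mutually consistent, and the
  pairing is enforced by a property test.
* The summary and its SE use random-effects weights 1/(v + tau^2); the 95%
  prediction interval is mu ± t_{k−2,0.975}·sqrt(tau^2 + SE^2) (t rather
  than normal quantile, k−2 degrees of freedom; undefined below k = 3).

All results are back-transformed to percentages; back-transformation is
monotone, so interval endpoints map directly.

The contrast-based analysis pools the study log odds ratio
ln[(tp·tn)/(fn·fp)] with variance equal to the sum of reciprocal cells,
through the same pooling core (one implementation, two front ends). When any
cell is zero, 0.5 is added to all four cells; studies with no events in
either arm carry no OR information and are excluded with a log entry. The OR
is the only pooled contrast measure: it is what the arm-based framework uses
too, making the two frameworks directly comparable.

## Bivariate binomial–normal model

For study i with intervention counts (eI, nI) and control counts (eC, nC),

    eI ~ Bin(nI, expit(eta_I)),  eC ~ Bin(nC, expit(eta_C)),
    (eta_I, eta_C) ~ N2((mu_I, mu_C), Sigma),
    Sigma = [[sigma_I^2, rho sigma_I sigma_C],
             [rho sigma_I sigma_C, sigma_C^2]].

In the DTA mapping, expit(mu_I) is the summary "sensitivity" (intervention
incidence) and expit(mu_C) the summary "1 − specificity" (control
incidence); parameterising directly in incidence space avoids the sign
bookkeeping of the sens/spec convention. The summary odds ratio is
exp(mu_I − mu_C) with variance taken from the fixed-effect covariance block.

The marginal likelihood integrates the study random effects numerically:
per study, a Newton iteration (vectorised across studies) finds the mode of
the joint log-density, the local curvature rescales a tensor-product
Gauss–Hermite rule (order 7 by default), and the rule is evaluated at the
recentred nodes. Accuracy increases with order; an oracle-grade order of 15
matches dense brute-force trapezoid integration (step 0.01 over [−10,10]^2,
implemented as an independent slow path) to better than 1e-7 on toy data,
and order 7 stays within 1e-5 of order 15 at the random-effect scales seen
in this application (order 7 degrades toward ~4e-5 only for SDs above ~1.2,
which is why the oracle checks run at order 15).

Optimisation is L-BFGS-B on (mu_I, mu_C, log sigma_I, log sigma_C,
atanh rho) — log and Fisher-z scales keep the optimizer interior — followed
by a tight-simplex Nelder–Mead polish, because numeric-gradient L-BFGS-B
stalls a few 1e-4 from the optimum, which is visible in symmetry tests.
Starting values are the means of the empirical logits with sigma = 0.5 and
rho = 0. The fixed-effect covariance is the (mu_I, mu_C) block of the
inverse observed information, computed by central finite differences of the
full 5-parameter negative log-likelihood; a non-positive-definite numerical
Hessian is eigenvalue-projected with a warning. Below four studies the
variance components are weakly identified and the fit warns; |rho| at its
Fisher-z bound warns likewise.

Ellipses are built on the logit plane as
center + r·L·(cos t, sin t) with L a Cholesky factor of C and
r = sqrt(chi2_{2,0.95}): C is the fixed-effect covariance for the confidence
region and fixed-effect covariance + Sigma for the prediction region. An
optional small-sample scaling r^2 = 2·F_{2,k−2,0.95} is available; the
chi-square radius is the default. Paths are back-transformed pointwise, so
the regions are not elliptical on the incidence plane. The SROC curve is the
conditional-mean regression line
eta_I(eta_C) = mu_I + rho(sigma_I/sigma_C)(eta_C − mu_C) over the observed
control-incidence range; the Rutter–Gatsonis HSROC-parameter curve is not
implemented, and the parameterisation note on the returned curve records the
variant. With sigma_C = 0 the curve is undefined and a vertical reference
through the summary point is returned with a warning.

## Synthetic cohorts

The generator emulates an arm-level trial collection: group sizes are
log-normal (calibrated by matching the reported median and IQR per category,
floored at 10 patients to avoid degenerate logit variances); per study,
(logit control incidence, log OR) is bivariate normal with means
(mu_ctrl, mu_logOR), SDs (tau_ctrl, tau_logOR) and correlation rho; counts
are binomial. Six spillover conditions: (a) unexposed and (b) ineffective
intervention force the mean log OR to zero; (c) effective, no spillover;
(d)/(e) subtract/add delta/100 to every true control incidence on the
probability scale before sampling; (f) adds it to a seeded random subset of
half-away-rounded size fraction·k. Incidences pushed outside (0,1) clamp to
[0.005, 0.995] with a log entry. Everything is reproducible from the spec
seed.

The category defaults are calibrated so marginal summaries land near the
observed collection: 115/65/16 studies, size medians 44/58/39, control
incidences centred near 23% (non-antimicrobial), near 28% pre-spillover for
the antimicrobial category — condition f with delta = 20 in half the trials
lifts the marginal mean to ~39% and the marginal control logit variance to
~0.8–0.9 — and 20% for duplex trials; intervention ORs centre on
0.82/0.38/0.79. Negative rho (−0.35 to −0.6) makes the intervention-arm
dispersion smaller than the sum of its components, matching the observed
pattern in which intervention arms are *less* dispersed than control arms.
Monte-Carlo checks of the construction (no binomial noise) confirm the
marginal mean and variance targets.

The generator injects spillover on the **true-incidence** scale before
sampling; the simulation engine perturbs **observed counts** afterwards.
Both exist because they answer different questions: the generator encodes a
data-generating story for testing recovery and diagnosis, the engine
reproduces the count-perturbation experiment. What the generator does not
model: length-of-stay, age or publication-year covariates, non-binomial
outcome misclassification, or clustering beyond the study level — so
passing tests say nothing about confounding by those factors in real data.

## Spillover simulation engine

For each selected control arm, events change by
round_half_away(delta·n/100), clamped to [0, n]; totals and intervention
arms never change. Rounding is half-away-from-zero (a package convention;
the fractional-count handling is otherwise unspecifiable), and partial
coverage selects round(fraction·k) control groups without replacement from
the scenario seed, so a scenario is fully reproducible and uniform coverage
is seed-free. The grid runner recomputes the arm-based control summary, the
contrast-based OR and (optionally) the bivariate summary OR for the baseline
and every scenario.

## Diagnosis rule

The rule operationalises "higher and more dispersed control incidence" with
explicit, configurable defaults: *consistent_with_harmful* requires the
control tau^2 to exceed the same-category intervention tau^2 by more than
1.5x AND the reference-category control tau^2 by more than 1.2x AND the
control 95% prediction interval to reach above the benchmark range
(*beneficial* mirrors below the range; both ratios firing with the PI inside
the range is *indeterminate*; anything else is *no_spillover*). The
reference threshold is deliberately lower than the intervention threshold:
the reference comparison contrasts two control populations whose baseline
heterogeneity is shared, so a smaller relative excess is already
informative; at 1.2 the rule classifies the observed antimicrobial pattern
(control tau^2 0.87 vs intervention 0.499 and reference 0.671) as harmful,
which a uniform 1.5 would not. Condition f (uneven spillover) is reported
when the control I^2 also exceeds the intervention I^2, d for beneficial, c
for no spillover. The verdict is a pure function of the numbers recorded in
the report, which echoes its thresholds.

Without a reference category the verdict rests on the two remaining
criteria; it can still reach harmful/beneficial only when both fire, and is
otherwise capped at indeterminate.

## Standing experiments and their operating conditions

*Parameter recovery* fits the bivariate model to 100 replicate no-spillover
cohorts of k = 60 trials with the non-antimicrobial calibration and checks
that means and random-effect SDs come back within 3 Monte-Carlo SEs and
that the 95% confidence region covers the true means 95 ± 4% of the time.

*Discrimination* classifies 100 condition-c and 100 condition-f cohorts
(delta = 10 per 100 in half the trials) against an independent
ineffective-intervention reference. Its operating conditions — k = 150
trials, size median 120, tau_ctrl = 0.2, tau_logOR = 0.3, rho = −0.78 —
were fixed by a simulation-based power calibration: tau^2-ratio estimates
have ~40–60% sampling CV when within-study variance dominates, so at full
collection-scale heterogeneity (control tau^2 ~0.8) a +10/100 shift in half
the trials adds only ~0.06 logit-variance and conditions c and f are not
statistically distinguishable at any rule; the study therefore runs at the
moderate baseline heterogeneity of a homogeneous subcategory, where the
design has ~90% power per side. The corollary is worth stating plainly: at
collection-scale heterogeneity with ~65 trials, single-draw verdicts carry
substantial sampling variability (the example scripts say so), and the
dispersion pattern should be read alongside the SROC plots rather than as a
binary test.

*Spillover monotonicity* applies the uniform ±2.5/5/10 ladder to one fixed
115-trial no-spillover cohort and checks the directional responses of the
pooled OR and control summary.

Problem sizes throughout (100 replicates, k = 60–150, order-7 quadrature)
are the package's chosen defaults for these experiments; all are arguments
and can be scaled up.

## Known limitations

* The bivariate model is ML, not REML; with few studies the random-effect
  SDs are mildly shrunken (visible but within Monte-Carlo tolerance at
  k = 60).
* The diagnosis thresholds are calibrated heuristics, not a formal test;
  no p-value or error rate accompanies a single verdict.
* Publication bias, covariate adjustment, network structure and
  risk-ratio pooling are out of scope.
* The ellipse coverage statement is about the confidence region for the
  mean pair under the generating model, not about robustness to model
  misspecification.
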