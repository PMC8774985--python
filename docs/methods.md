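# Methods

## The biometric model

The classical twin design identifies additive genetic (A), shared
environmental (C) and non-shared environmental (E) variance from the
contrast between monozygotic pairs (additive-genetic correlation 1) and
dizygotic pairs (0.5; C correlates 1 in both). With path coefficients
a, c, e and grand mean μ, a pair's phenotype vector is bivariate normal
with variance a²+c²+e² and cross-twin covariance r_z·a²+c². The deviance
is the sum of per-pair −2 log densities; models (ACE, AE, CE, E) are
compared by likelihood-ratio χ² on the difference in estimated parameters.
Standardized components are A = a²/(a²+c²+e²) etc.

The DZ additive-genetic correlation is fixed at 0.5 for all DZ pairs,
including opposite-sex pairs; sex-limitation and dominance models are out
of scope.

## The moderation model

The extended univariate G×E model makes each twin's mean and paths linear
in that twin's *own* moderator value (a pair-mean coding is deliberately
not offered):

    mean_j = m + β_m·M_j
    A path_j = a + β_a·M_j,  C path_j = c + β_c·M_j,  E path_j = e + β_e·M_j

The implied pair covariance (r_z on the cross-product of the moderated A
paths, plus the cross-product of C paths) is positive semidefinite for all
real parameter values, so the likelihood is well defined wherever the
per-twin variances are positive; parameter points implying a non-positive
variance return +∞ to the optimizer.

Nested drop specifications fix moderation blocks at zero: `full` (AE base:
a, e, β_a, β_e, m, β_m — 6 parameters), `drop_mean` (β_m = 0; 5),
`drop_variance` (β_a = β_e = 0; 4), `drop_all` (3). Degrees of freedom are
2 × (number of pairs) − EP: the phenotype is pre-standardized and both
means are modelled, so each pair contributes two observed statistics.
`drop_all` is algebraically identical to the unmoderated AE model, and the
test suite verifies the two fits agree to 1e-4.

Because the published comparison tables follow the "AIC(df)" convention,
the primary information criterion is AIC = −2lnL − 2·df; the classic
−2lnL + 2·EP is reported alongside. A `saturated_reference` flag offsets
the reference by one extra free parameter purely to mirror published table
layouts whose saturated reference is not otherwise defined; it changes no
fit. p-values print as 2 decimals above 0.01, 3 decimals to 0.001 and
"<0.001" below.

## Covariates

Age and sex enter as covariates on the mean of the phenotype, implemented
by ordinary-least-squares residualization of the log-transformed,
standardized symptom score, followed by re-standardization. This keeps the
twin likelihood at exactly the parameter counts above (the full AE
moderation model estimates 6 parameters, with no age/sex slopes inside the
likelihood). The transform is y = log(raw + 1) — the only log convention
defined at zero counts — then z-scoring with the sample SD (n−1); the
ordering (standardize-then-residualize vs residualize-then-standardize) is
selectable and both end with mean-0/SD-1 output. Carrying age/sex as free
mean covariates inside the likelihood was considered and rejected: it
changes the parameter count of every model and duplicates the likelihood
surface for no additional tested behaviour.

## Dietary scores

Food-frequency categories (never … 3 times/day) convert to servings/day by
the midpoint convention (e.g. "1–2 times/week" → 1.5/7 ≈ 0.214); the
mapping is configuration, not doctrine. The high-sugar score sums 12
listed items and the unhealthy score 23; a missing item is an error, never
an implicit zero. Tertile boundaries (high-sugar 1.56/2.90, unhealthy
2.61/4.00 servings/day) assign the boundary values to the outer
categories (low: ≤ lower, high: ≥ upper). The continuous moderator coding
standardizes servings/day to mean 0/SD 1 before fitting; a 0/1/2 tertile
index coding is available.

## Optimization and confidence intervals

Models are parameterized by unconstrained path coefficients (smooth
likelihood, no boundary at zero); signs are canonicalized afterwards
(non-negative unmoderated paths, with each moderation coefficient flipped
jointly with its path). Fitting is L-BFGS-B with a multi-start grid over
{0.2, 0.6, 1.0} × sample SD, followed by a few damped Newton steps with a
finite-difference Hessian to polish the optimum. The convergence flag
requires the central-difference gradient norm to fall below
1e-6·(1 + |deviance|/1e4) — an absolute 1e-6 near deviances of order 10⁴
sits at the noise floor of finite-difference gradients, so the threshold
scales mildly with the objective. Simulation loops may request a single
moment-flavoured start (`n_starts=1`); the user-facing default is the full
grid.

Confidence intervals are profile-likelihood based: a 95% bound is the
parameter value at which the profile deviance rises 3.8415 above its
minimum, found by geometric bracketing and Brent root-finding. Standardized
shares are profiled directly via a constrained reparameterization (total
variance × fixed share); a profile that runs into the admissible region
(shares in [0, 1], paths ≥ 0 on the canonical branch) reports the boundary
with a flag. Intervals for a heritability of ~0.4 at 1518 pairs span about
±0.055, and simulated coverage sits in the low-to-mid 90s (verified at 200
replicates in the test suite).

## Intraclass correlations

The descriptive ICC is the double-entry Pearson correlation (each pair
contributes both orderings), which is invariant to twin labelling; the CI
uses the Fisher z transform with the number of pairs as effective n. The
estimator accepts two pairs (enough to define a correlation) though three
or more are needed for a non-degenerate CI. The ANOVA ICC agrees
asymptotically under exchangeability and is not separately implemented.

## The synthetic-cohort generator

The generator is the package's test bed and defines its study conditions:
1518 pairs (719 MZ / 799 DZ, 47.4% MZ), a continuous phenotypic liability
with AE structure and heritability 0.41 at the moderator mean, a dietary
moderator with AE structure (heritability 0.36, hence within-pair
correlations 0.36 MZ / 0.18 DZ), a weak phenotype–moderator genetic
correlation rg = 0.10, mean moderation β_m = 0.25, and variance moderation
solved in closed form so that the standardized genetic share equals 0.30
at the 10th and 0.51 at the 90th percentile of the standardized moderator
(a = √0.41, e = √0.59, β_a = 0.09908, β_e = −0.01250). The moderator's
servings/day scale uses mean 3.30 / SD 1.61 (unhealthy-food-like; the
secondary, non-moderating score uses 2.23 / 1.26), clipped at zero and
re-standardized within sample, so the analysis-side standardization
recovers the generating moderator exactly.

The rg knob is implemented by giving the phenotype's and moderator's
additive-genetic factors a within-person correlation rg (and r_z·rg across
co-twins). A consequence worth knowing: with rg > 0 the conditional mean
E[A | M] is nonzero, so the fitted mean-moderation coefficient absorbs the
gene–environment correlation (β̂_m ≈ β_m + a·rg·√(a²_mod) at large n).
This is the real confounding the extended *bivariate* model would address;
that model is out of scope here, and clean β_m recovery is asserted under
rg = 0.

Bounded 0–9 symptom counts are emitted for cosmetic realism by
quantile-matching the covariate-shifted liability to a Poisson(2.05)
count; analyses operate on the continuous liability, which generated
datasets carry pre-attached. The generator does not emulate: skewed or
zero-inflated symptom distributions, item-level FFQ responses, assortative
mating, rater effects, or missingness — passing tests therefore certify
the estimators under the stated generating model, not robustness to those
features of real questionnaire data. Given a config and seed the output is
bit-identical; distinct seeds give independent cohorts.

## Problem sizes in the test suite

Closed-form recovery checks run at 50k–100k pairs (one fit each);
replicate studies run at the cohort scale of 1518 pairs — 200 replicates
for moderated-heritability recovery and CI coverage, 500 for the
drop-variance type-I error (observed rejection ≈ 5% at α = 0.05), 100 for
power (> 80% for the generator's variance moderation). These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping the whole suite at a few minutes on one core.

## Known limitations

- No FIML for incomplete pairs: complete-pair analysis only.
- No sex-limitation, dominance, liability-threshold (ordinal) or bivariate
  G×E models; rg is a generator knob, not an estimated quantity.
- Profile CIs assume a unimodal profile; multimodality would need a wider
  bracket than the geometric search uses.
- The "saturated" reference mode mirrors a table layout only; it is not a
  fitted saturated model.
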