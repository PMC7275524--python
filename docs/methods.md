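# Methods

## Data model and assumptions

The unit of input is the aggregated paired-design table: eight non-negative
integer cells `(s11, s10, s01, s00, r11, r10, r01, r00)`, where `s_ij`
(`r_ij`) counts diseased (non-diseased) subjects with Test 1 result `i` and
Test 2 result `j`. The table is modelled as one multinomial sample of size
`n` over the eight cells; conditionally on disease status, each group is a
four-cell multinomial. All tests and intervals are asymptotic (first-order
normal); no continuity assumptions beyond the McNemar continuity correction
are made. Both tests must be informative: the estimated Youden index
`Se_i + Sp_i - 1` must be positive, or validation fails.

Under a case-control design (`design = case_control`) the group sizes `s`
and `r` are fixed by the investigator, so `s/n` does not estimate the
prevalence and the predictive values are not estimable; the package then
suppresses the prevalence and PV blocks with an explanatory note and still
compares accuracies and likelihood ratios, which are conditional on disease
status.

## Estimators

- `Se_i`, `Sp_i`: group-conditional proportions with binomial standard
  errors `sqrt(p(1-p)/group size)`.
- `PPV_i`, `NPV_i`: proportions over the pooled test margins (e.g.
  `PPV_1 = s_1./n_1.`), with SE `sqrt(a b/(a+b)^3)` for a margin of `a`
  diseased and `b` non-diseased subjects — the binomial SE of the margin
  proportion.
- `PLR_i`, `NLR_i`: count-ratio forms algebraically identical to
  `Se/(1-Sp)` and `(1-Se)/Sp`, with delta-method standard errors
  propagating the two group-conditional binomial variances.

## Confidence intervals

**Proportions** use the modified-Wilson interval (Yu, Guo and Xu): centre
`0.5 + (m + z^4/53)/(m + z^2) * (p - 0.5)`, half-width
`z/(m + z^2) * sqrt(m p(1-p) + z^2/4)`, clipped to [0, 1]. The shrink
factor's denominator `m + z^2` matches the half-width denominator; this
form reproduces this interval family's reference values and has the
documented coverage (the test suite checks ~95% empirical coverage at
p = 0.3, m = 50).

**Likelihood ratios** are ratios of two independent binomial proportions;
the interval is the Martín-Andrés & Álvarez-Hernández approximation to the
score method computed on margins adjusted by +0.5 (group totals +1), which
is defined for any observed zero pattern. When a limit falls outside its
admissible range (below `a/(n - b)`, above `(n - a)/b`, or on the wrong
side of the point estimate) it is replaced by the closed-form bound of the
corresponding one-proportion score problem. Intervals are floored at 0.

**Paired difference of proportions** (Se or Sp contrast) uses the Wald
interval with Bonett-Laplace adjustment — discordant counts +1 and group
total +2 — clipped to [-1, 1]. It has a closed form and behaves like the
Tango score interval asymptotically.

**Contrast intervals are oriented**: the reported difference is positive
(ratio above 1), and the output names the test whose parameter is larger.
They are only attached to individual hypotheses rejected by Holm, since a
retained homogeneity makes a difference interval uninteresting.

## Hypothesis tests and decision rules

Accuracy family. The individual Wald statistics are
`chi2_WSe = s (s10 - s01)^2 / (4 s10 s01 + (s11+s00)(s10+s01))` and its
Sp analogue; the global statistic is their sum (2 df). The deviance (LRT)
versions `2[a ln(2a/(a+b)) + b ln(2b/(a+b))]` require all discordant cells
positive and are reported alongside. Decision rules driven by prevalence
and sample size:

- prevalence <= 10% and n <= 100: no global test; the two individual Wald
  tests are solved directly with Holm at alpha ("rule a").
- otherwise: global Wald test at alpha; if significant, the causes are
  investigated with the individual Wald tests (n <= 100 or n >= 1000) or
  the McNemar tests with continuity correction (100 < n < 1000), both with
  Holm. The boundary n = 1000 uses the Wald branch.

The individual accuracy statistics are referred to chi-square with 1 df
(they are quadratic/deviance forms; a normal reference would be
inconsistent with their construction).

Likelihood-ratio family. `omega = (ln(PLR1/PLR2), ln(NLR1/NLR2))` with
delta-method covariance: conditional binomial variances
`Se_i(1-Se_i)/s`, `Sp_i(1-Sp_i)/r`, and within-group pairing through the
joint cells, `Cov(Se1, Se2) = (s11/s - Se1 Se2)/s` and
`Cov(Sp1, Sp2) = (r00/r - Sp1 Sp2)/r`; the two groups are independent. The
global statistic is `omega' Sigma^-1 omega` (2 df); the individual
statistics are `omega_k / sqrt(Sigma_kk)` (standard normal, signed
internally; reports print the magnitude). The PLR ratio interval is
log-scale (`ratio * exp(+-z sd)`); the NLR ratio interval is the Wald-type
`ratio * (1 +- z sd)` with `sd` the log-scale (relative) standard error.

Predictive-value family. The global test treats
`eta = (PPV1, PPV2, NPV1, NPV2)` as smooth functions of the eight
multinomial cell proportions (prevalence random) and applies the delta
method: `Sigma = J M J'/1` with `M = (diag(p) - p p')/n`; the statistic is
`(phi eta)' (phi Sigma phi')^-1 (phi eta)` with contrast matrix
`phi = [[1,-1,0,0],[0,0,1,-1]]` (2 df). Individually, Kosinski's weighted
generalized score statistic is used (1 df), with pooled value
`PPV_p = (2 s11 + s10 + s01)/(2 n11 + n10 + n01)` and pairing correction
`C_p^PPV = (s11 (1-PPV_p)^2 + r11 PPV_p^2)/(2 n11 + n10 + n01)`; the NPV
versions are the mirror images (in particular the C-term uses
`(1 - NPV_p)^2`, symmetric with the PPV form). The PV difference interval
inverts the WGS statistic: `diff +- z sqrt(variance term)`.

Holm step-down for two hypotheses: the smaller p-value is compared with
alpha/2 and, only if rejected, the larger with alpha. Adjusted p-values are
`min(1, 2 p_min)` and `min(1, max(p_max, 2 p_min))`.

## Monte Carlo power

When a family's estimates differ, the operating characteristic of the test
actually applied is estimated by resampling: `reps` (default 10,000)
multinomial tables of the observed size at the observed cell relative
frequencies; the family's global test is applied at the same alpha to each
replicate, and the rejection fraction is reported as power (observed test
significant) or its complement as the type-II-error probability (observed
test not significant). The alternative hypothesis targeted is thus exactly
the observed configuration. Replicates on which the statistic cannot be
computed (e.g. a zero denominator) are regenerated and counted in
`resampled`; a cap of `100 * reps` total draws guards pathological tables.
For a table analysed under rule (a), where no global statistic exists,
rejection means that Holm over the two individual Wald tests rejects at
least one hypothesis; the `test_used` field records which procedure was
simulated. Exactly equal observed estimates make the retrospective power
target undefined and are reported as such instead of simulated. The
generator is a seeded `numpy.random.Generator`; a fixed default seed makes
reports byte-reproducible, and the per-replicate statistics are fully
vectorized (10,000 replicates run in well under a second).

The same machinery drives the calibration checks in the test suite: under
a null configuration (both tests Se = 0.75, Sp = 0.85, prevalence 0.5,
positively correlated within pairs) at n = 500, each global test's
empirical type-I error is verified to stay within 1.5 percentage points of
the nominal 5% over 5,000 replicates. Those sizes keep the default test
run fast while leaving the Monte Carlo error well below the tolerance
being checked.

## Numerical choices and edge cases

- `0 ln 0 = 0` in the deviance terms.
- WGS statistic with a non-positive variance term: reported as the null
  value 0 when the PV difference is exactly 0 (perfectly concordant
  tests), otherwise as not computable.
- p-values below half of `10^-decip` are rendered `<0.001`-style rather
  than `0.000`.
- Proportion intervals are clipped to [0, 1], difference intervals to
  [-1, 1], ratio intervals floored at 0.
- Infeasible statistics never abort the run: the feasibility report marks
  them and the output carries a "not computable" note, so a single zero
  pattern does not discard the rest of the analysis.

## Limitations

- All tests are asymptotic; with very small samples or very sparse
  discordant cells the chi-square/normal references are approximate, and
  the package deliberately offers no exact alternative.
- The resampling power estimate conditions on the observed table being the
  truth; it is a retrospective, not a design-stage, quantity.
- Missing test results must be resolved (e.g. imputed) before tabulation;
  the package only consumes complete eight-cell tables.
- Subject-level covariates, more than two tests, and clustered samples are
  out of scope.
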