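# compbdt

Estimation and simultaneous comparison of two binary diagnostic tests
applied to the same subjects (paired design).

## The problem

Two binary diagnostic tests (e.g. an exercise stress test and a chest-pain
history for coronary artery disease) are applied, together with a gold
standard (e.g. coronary angiography), to every subject in one random sample.
The data form an eight-cell table: `s_ij` diseased and `r_ij` non-diseased
subjects with Test 1 result `i` and Test 2 result `j` (1 positive,
0 negative). From this table the package estimates, for each test,

- **sensitivity** `Se = P(T+ | D)` and **specificity** `Sp = P(T- | not D)`,
- **likelihood ratios** `PLR = Se/(1-Sp)` and `NLR = (1-Se)/Sp`,
- **predictive values** `PPV = P(D | T+)` and `NPV = P(not D | T-)`,

plus the disease prevalence, and compares the two tests *simultaneously*
within each parameter family through a global 2-df test

- accuracies: `H0: Se1 = Se2 and Sp1 = Sp2` (Wald and deviance statistics on
  the discordant pairs),
- likelihood ratios: `H0: PLR1 = PLR2 and NLR1 = NLR2` (Wald statistic
  `omega' Sigma^-1 omega` on the log-ratio vector, delta-method covariance),
- predictive values: `H0: PPV1 = PPV2 and NPV1 = NPV2` (contrast-matrix Wald
  statistic under the 8-cell multinomial).

When a global test is significant, the individual hypotheses are resolved
with the Holm step-down method and an oriented confidence interval is
reported for each rejected null (Bonett-Laplace difference interval for
Se/Sp, ratio intervals for the LRs, inverted weighted-generalized-score
intervals for the PVs). Single-parameter intervals use the modified-Wilson
interval of Yu, Guo and Xu for proportions and the Martín-Andrés &
Álvarez-Hernández approximate score interval for the likelihood ratios.
Finally, for each family the retrospective power (or the probability of a
type II error, when a null is retained) is estimated from 10,000 multinomial
replicates drawn at the observed cell frequencies.

Testing each hypothesis separately at level alpha is the classical but
error-prone route; the global-test-then-Holm procedure controls the
family-wise error rate, analogous to an ANOVA followed by post-hoc
comparisons.

## Worked example

The classic coronary-artery-disease data of Weiner et al. (1979): exercise
test (Test 1) and chest-pain history (Test 2) against angiography in 871
subjects.

```python
from compbdt import run_compbdt

report = run_compbdt(473, 29, 81, 25, 22, 46, 44, 151)
print(report.render())
```

or, from a shell, `compbdt 473 29 81 25 22 46 44 151 --out results/`.
Abridged output:

```
Estimated prevalence of the disease is 69.805% and its standard error is 0.016.
95% confidence interval for the prevalence of the disease is (66.681%; 72.768%).
...
Wald test statistic for the global hypothesis test H0: (Se1 = Se2 and Sp1 = Sp2) is 25.662. Global p-value is <0.001.
...
McNemar test statistic (with cc) for H0: Se1 = Se2 is 23.645 and the two-sided p-value is <0.001.
McNemar test statistic (with cc) for H0: Sp1 = Sp2 is 0.011 and the two-sided p-value is 0.916.
Applying the Holm method (to an alpha error of 5%), we reject the hypothesis H0: Se1 = Se2 and we do not reject the hypothesis H0: Sp1 = Sp2.
Sensitivity of Test 2 is significantly greater than sensitivity of Test 1.
95% confidence interval for the difference Se2 - Se1 is (5.192%; 11.857%).
...
Test statistic for H0: NLR1 = NLR2 is 4.663 and the two-sided p-value is <0.001.
...
95% confidence interval for the ratio NLR1 / NLR2 is (1.412; 2.554).
...
Wald test statistic for the global hypothesis test H0: (PPV1 = PPV2 and NPV1 = NPV2) is 25.944. Global p-value is <0.001.
...
95% confidence interval for the difference NPV2 - NPV1 is (8.041%; 19.363%).
```

Reading: the chest-pain history is significantly more sensitive (by 5 to 12
percentage points) and rules the disease out significantly better (its NLR
is 1.4 to 2.6 times smaller, its NPV 8 to 19 points higher), while the two
tests' specificities, PLRs and PPVs are statistically indistinguishable.
With `--out DIR` the three blocks are written to
`Results_Comparison_Accuracies.txt`, `Results_Comparison_LRs.txt` and
`Results_Comparison_PVs.txt`.

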