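# kincohort

Kin-cohort estimation of age-specific cancer penetrance in BRCA1/2
mutation carriers.

## The problem

Families in a hereditary breast–ovarian cancer registry enter through a
genotyped, affected proband. Her female first-degree relatives (mother,
sisters, daughters) form a retrospective cohort, but most of them were
never genotyped: a relative's mutation status is known only
probabilistically, through Mendelian transmission from the proband. This
package estimates the *penetrance* — the cumulative probability F(t) that
a mutation carrier develops breast (or ovarian) cancer by age t — from
exactly this kind of data, and pools the result with other published
estimates by random-effects meta-analysis.

## The method

For relative *i* with follow-up (t_i, δ_i) and carrier probability p_i
(the **mixing weight**: exact Mendelian conditional given the proband's
genotype and the relation, replaced by 0/1 when the relative herself was
genotyped), the marginal likelihood over nonparametric discrete-time
hazards λ_g(t_k) on the grid of distinct event ages is

    L = ∏_i [ p_i L_1(t_i, δ_i) + (1 − p_i) L_0(t_i, δ_i) ],
    L_g(t, δ) = λ_g(t)^δ ∏_{t_k < t} (1 − λ_g(t_k)) · (1 − λ_g(t))^{(1−δ)[t ∈ grid]}

with g = 1 for carriers, g = 0 for non-carriers. The hazards are fitted by
EM (E-step: posterior carrier probabilities π_i; M-step: π-weighted
occurrence/exposure updates), penetrance is F_g(t) = 1 − ∏(1 − λ_g(t_k))
accumulated from the reporting origin (age 20 for breast, 30 for
ovarian), and 95% confidence bands come from a nonparametric bootstrap
that resamples whole families. Study-level estimates are pooled with the
DerSimonian–Laird random-effects model on the logit scale, with Cochran's
Q heterogeneity test.

A synthetic registry generator with known truth (HWE founders, Mendelian
transmission, genotype-specific onset hazards, censoring by competing
cancer, risk-reducing surgery and loss to follow-up, affected-proband
ascertainment, partial relative genotyping) backs every estimator
property test.

## Worked example

Simulate the default registry (1,600 families, allele frequency q = 0.02,
carrier breast-cancer risk 50% by age 70 vs 16% for non-carriers, 30% of
relatives genotyped), then estimate penetrance:

```sh
kincohort simulate --config configs/registry_default.yaml --out demo
kincohort estimate demo/kincohort.csv --gene BRCA1 --outcome breast \
    --bootstrap 1000 --seed 11 --out demo/est
```

which prints (percent scale):

```
 gene outcome  age  F_carrier  ci_low_carrier  ci_high_carrier  F_noncarrier  ci_low_noncarrier  ci_high_noncarrier
BRCA1  breast 40.0        7.7             4.5             10.2           0.8                0.6                 1.2
BRCA1  breast 50.0       17.6            12.5             22.7           5.8                5.0                 6.6
BRCA1  breast 60.0       29.1            22.2             37.3          11.9               10.6                13.3
BRCA1  breast 70.0       50.7            38.4             63.8          15.4               13.7                17.2
```

The estimated carrier risk by age 70 (50.7%, 95% CI 38.4–63.8) recovers
the generating truth of 50%, and the non-carrier curve recovers 16%. The
run log records the plug-in allele frequency (q̂ = 0.0519, half the
carrier fraction among probands), the marginal log-likelihood, and the
EM iteration count.

Pooling the published Asian per-study estimates (bundled):

```sh
kincohort meta studies.csv --out demo/meta
```

```
 gene age_interval  k  pooled  ci_low  ci_high    Q  df  p_het  tau2 scale
BRCA1        20-50  3   14.38    9.20    21.77 1.51   2   0.47  0.00 logit
BRCA1        20-60  3   30.27   21.05    41.41 0.14   2   0.93  0.00 logit
BRCA1        20-70  3   44.50   32.75    56.89 1.52   2   0.47  0.00 logit
BRCA2        20-50  3   15.21    8.99    24.57 6.16   2   0.05  0.18 logit
BRCA2        20-60  3   29.12   22.77    36.40 0.34   2   0.85  0.00 logit
BRCA2        20-70  3   39.58   30.25    49.74 1.15   2   0.56  0.00 logit
```

The pooled breast cancer penetrance by age 70 is 44.5% (BRCA1) and 39.6%
(BRCA2) across the three available Asian cohorts, with no significant
between-study heterogeneity at age 70.

## Layout

- `kincohort.records` / `kincohort.tables` — domain records, the
  kin-cohort CSV format, outcome-specific censoring rules, incidence
  summaries
- `kincohort.mendelian` — HWE genotype frequencies, exact relative
  carrier probabilities, mixing weights, plug-in allele frequency
- `kincohort.penetrance` — marginal likelihood, EM fit, cumulative risk,
  family bootstrap
- `kincohort.meta` — CI-to-SE conversion, DerSimonian–Laird pooling
- `kincohort.simulate` — synthetic registry generator with truth sidecar
- `kincohort.cli` — `kincohort simulate | estimate | meta | incidence`

See `docs/methods.md` for modelling assumptions, defaults, and
limitations.
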