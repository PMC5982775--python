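# Methods

## Design and data model

The package analyses kin-cohort data: families ascertained through a
genotyped proband affected with breast cancer, contributing her female
first-degree relatives (mother, sisters, daughters) as a retrospective
cohort. One table row per individual records ages (whole years) of breast
and ovarian diagnoses, risk-reducing salpingo-oophorectomy (RRSO) and
mastectomy (RRM), and last follow-up or death. Male relatives and
second/third-degree kin are out of scope; rows with extended-kin roles are
dropped with a warning, and individuals without any usable follow-up age
are excluded with a logged count.

Follow-up runs from birth. For breast cancer the event is the breast
diagnosis, censored at the earliest of ovarian diagnosis (treated as a
competing censoring cause, not a competing-risks model), RRSO, RRM, or
last follow-up/death. For ovarian cancer the event is the ovarian
diagnosis, censored at the earliest of RRSO or last follow-up/death.
Within-year ties between an event and a censoring cause resolve in favour
of the event, so a diagnosis at the age of prophylactic surgery still
counts; this favours counting observed diagnoses and is the only
defensible choice once ages are coarsened to years.

## Mendelian mixing weights

Genotypes are pooled to a dominant two-class model (carrier vs
non-carrier); homozygote excess risk is ignored, which is standard for
rare high-penetrance alleles. For an untested relative the carrier
probability given the proband's class is computed exactly by enumerating
the joint genotype distribution under Hardy–Weinberg equilibrium at
allele frequency q: parent–offspring pairs via allele transmission with a
random HWE mate, siblings via both parents' HWE genotypes with
independent transmissions. Mother and daughter are symmetric; the sibling
conditional differs from the parent–offspring one for q > 0, so
relation-specific values are used (exactness costs nothing and is
testable against brute-force enumeration). A uniform "first-degree ≈ 1/2"
approximation is available behind `method="half"` for sensitivity
checks. Observed genotypes override the prior with weight exactly 0 or 1.
Relatives in mutation-negative families use the noncarrier-proband
conditional (small but positive for q > 0); an observed mutation-positive
relative in a negative family is handled by the override.

The plug-in allele frequency is q̂ = half the carrier fraction among
probands. In an ascertained registry this over-states the population
frequency, since affected probands are enriched for carriers; it is kept
as the pipeline default because it is the estimate such a registry can
actually compute, but `GenotypeModel` accepts any externally supplied q
(and the CLI exposes `--q`). Simulation-based consistency checks evaluate
the estimator at the generator's true q, since consistency is a property
of the correctly specified mixing weights. The E-step posterior updates
each relative's carrier probability from her own follow-up, which damps
the effect of moderate misspecification of q on the fitted curves.

## Marginal-likelihood EM

Hazards live on the grid of distinct observed event ages (ties pool at
the shared age). Each relative contributes a two-component mixture of
discrete-time survival likelihoods; relatives are treated as independent
given their genotype class, which ignores residual familial correlation
and the correlation of sisters' genotypes — the likelihood is therefore a
composite one, and interval estimation is delegated to the family
bootstrap rather than the information matrix.

The E-step computes each relative's posterior carrier probability from
her full follow-up; the M-step is a posterior-weighted occurrence/exposure
(actuarial) update per grid age, separately per class. When every
relative is genotyped the fit collapses to the stratified actuarial
estimator in one step. Initialization is the pooled (class-free)
occurrence/exposure estimate; convergence is declared when the marginal
log-likelihood improves by less than `tol` (default 1e-8, `max_iter`
5000). The log-likelihood trace is retained and asserted nondecreasing in
tests. Empty risk sets yield a zero hazard with a warning;
non-convergence is flagged on the returned state, never silent. Internally
identical (time, event, weight) rows are aggregated with multiplicities,
which makes the EM cost depend on the number of distinct patterns rather
than the cohort size.

Penetrance is reported as F(t) = 1 − ∏_{origin < t_k ≤ t}(1 − λ(t_k))
from an origin of 20 years (breast) or 30 (ovarian); hazards before the
origin are excluded from the product. No order constraint forces the
carrier curve above the non-carrier curve; crossing estimates are
reported with a warning.

## Family bootstrap

Confidence bands resample families — the clustering unit — with
replacement, refit, and take percentile 2.5/97.5 bounds of F at the
report ages; results are deterministic given the seed. Replicates with no
events are recorded as F ≡ 0 and counted. Replicate refits are
warm-started at the point estimate and run at a replicate tolerance
`boot_tol` = 1e-6 (the induced error in F is ~1e-3, an order of magnitude
below the Monte-Carlo noise of the band itself); all replicates iterate
as one vectorized batch, with converged replicates retired from the
working set. A genotype class with fewer than `min_events_for_ci`
(default 10) posterior-weighted events is reported as a point estimate
without a band, since so few cases do not permit reasonable interval
estimation. Percentile bounds are clipped to bracket the point estimate,
which matters only in degenerate tiny-sample cases.

## Meta-analysis

Published per-study estimates arrive as percentages with 95% CIs. The
standard error on a chosen transform scale is the full transformed CI
width divided by 2×1.96, which averages asymmetric intervals rather than
taking the wider half. The default transform is the logit: penetrance is
a proportion and the source intervals are strongly asymmetric on the raw
scale; log and identity scales are kept as sensitivity options since the
transformation used by some published pooled values is not stated.
Pooling is the DerSimonian–Laird moment estimator — Cochran's Q with
fixed inverse-variance weights, τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)),
random-effects weights 1/(se² + τ²) — with the pooled CI back-transformed
on the same scale (no bias correction). A bound sitting exactly at 0 or
100 cannot be logit/log-transformed; the error message asks for an
explicit continuity adjustment of the transcribed value rather than
silently perturbing data. Heterogeneity is tested against χ² on k−1
degrees of freedom.

## Synthetic registry generator

The generator emulates the structure of a hereditary breast–ovarian
cancer registry. Defaults (the shipped `configs/registry_default.yaml`):
allele frequency q = 0.02; 1,600 accepted families; every family has a
mother, sisters ~ categorical with median 2 (IQR 1–3) and daughters with
median 0 (IQR 0–1); fraction of relatives genotyped γ = 0.3; probands
always genotyped. True yearly hazards are piecewise-constant between
cumulative-risk anchors: carriers reach 10/16.3/30.5/50% breast risk by
ages 40/50/60/70 and non-carriers 1.1/6.3/11.8/16% (ovarian: 21.5% vs
1.4% by 70), registry-scale magnitudes. Follow-up ends at a role-specific
last-contact age (means 68 for mothers, 52 for probands/sisters, 30 for
daughters, SD 8–12, truncated to [12, 90]); RRSO occurs with probability
0.03 (uniform age 35–60) and RRM 0.01 (30–55); 10% of subjects are
recorded dead at last contact. These censoring settings are a plausible
registry profile chosen once, not fitted quantities.

Ascertainment keeps a candidate family iff the proband has a recorded
breast cancer diagnosis before her censoring ages; enrichment of carriers
among probands follows from the genotype-specific hazards alone.
High-risk referral criteria (triple-negative disease, family history) are
not modelled — the affected-proband condition approximates the entry
route, and any residual ascertainment difference is a documented
simplification. Other simplifications relative to real registries:
mothers share the daughters' hazard schedule (no birth-cohort effects),
no genotyping error, no de novo mutations, relatives' phenotypes are
independent given genotype (no shared environment or polygenic
background), and censoring is independent of genotype. Passing recovery
tests therefore demonstrates correctness of the estimator under its own
assumptions, not robustness to these real-data violations.

If fewer than 1 in 10⁴ candidates passes ascertainment the generator
aborts (e.g. with all-zero hazards no proband is ever affected).
Everything is driven by one integer seed; a rerun is bit-identical.

## Problem sizes in the test suite

Parameter-recovery uses 50 independent registries of 1,600 families
(mean carrier F(70) must fall within 0.05 of truth); bootstrap coverage
uses 200 registries with B = 200 replicates each (nominal 95% band must
cover truth 90–99% of the time); the efficiency check compares
Monte-Carlo SDs at γ = 0 versus γ = 0.3 on 50 paired registries masked
from a common γ = 1 draw (common random numbers). B = 1000 remains the
CLI default for data analysis; B = 200 in the coverage study trades a
slightly noisier percentile band for 5× fewer refits, and the batched EM
makes the whole study run in minutes on one core.

## Known limitations

- The composite likelihood ignores genotype correlation among siblings;
  point estimates remain consistent but naive information-based SEs would
  not — hence the family bootstrap is the only interval method offered.
- The plug-in q̂ from ascertained probands is biased upward for the
  population frequency; supply an external q when one is available.
- Ovarian analyses in carrier strata are frequently sparse; the
  `min_events_for_ci` guard declines to produce bands rather than emit
  unstable ones.
- Exact reproduction of published pooled values depends on the (unstated)
  transform those publications used; the logit default lands within ~1
  percentage point of the published pooled numbers, and the log/identity
  scales are provided to probe sensitivity.
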