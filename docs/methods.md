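# Methods

## Study design

`famrisk` implements a retrospective matched case-control familial-risk
design on a genealogy linked to longitudinal coded diagnoses. The unit of
analysis is the (index, relative) pair: for every case proband and every
matched control proband, all relatives at a given degree are enumerated and
the outcome is whether the relative satisfies the diagnosis rule. The
familial odds ratio at degree d contrasts relatives of cases with relatives
of controls. Relatives are deliberately counted once per proband, so a
person related to several probands contributes several rows — this mirrors
how such studies report relative totals and is the source of the dyadic
variance correction described below.

## Synthetic study population

The generator stands in for a restricted population database. It emulates:

- **Pedigree structure.** `n_founder_couples` (default 500) founder couples;
  discrete generations (default 4) spaced 25 years with ±5 years of uniform
  birth-year jitter, so the ±2.5-year matching window is genuinely
  exercised; offspring counts truncated-Poisson (mean 2.5, max 8); random
  within-generation mating restricted to pairs sharing no ancestor, with
  the further constraint that spouses of full siblings be mutually
  unrelated (kinship-0 mating alone would let two siblings marry two
  siblings, making their children double first cousins with kinship 1/8).
  Together these guarantee an outbred population in which every named
  degree-d pair has kinship exactly 2^−(d+1). Monogamy is enforced;
  unmarried people stay single.
- **Disease.** A liability-threshold model with unit total variance:
  additive fraction `h2` (default 0.65, matching twin-study heritability
  estimates of 65–75% for autoimmune hypothyroidism), shared-couple
  fraction `c2_couple` (default 0.10, the knob that produces spousal
  concordance), shared-sibship fraction `c2_sibling` (default 0, no
  published anchor), residual the remainder. Founders draw additive values
  from N(0, h2); children use the midparent rule with segregation variance
  h2/2. Unpartnered people receive a private couple deviate and founders a
  private sibship deviate so everyone's liability has variance 1.
  Thresholds are `Φ⁻¹(1 − prevalence_sex)` with defaults 6.6% (female) and
  2.4% (male): a 2.75:1 female excess around an overall ~4.5% lifetime
  risk, consistent with the ~2.7-fold excess such cohorts report. Sex is
  assigned 50/50 independently of liability; the female excess enters only
  through the thresholds.
- **Records.** An EHR observation window (default 1996–2021). Affected
  people receive qualifying codes in 2–6 distinct years with probability
  `p_record_given_affected` (default 0.9), otherwise in exactly one year —
  emulating people tested but never confirmed. Unaffected people pick up a
  single-year qualifying code with probability 0.02; anyone carries a
  Graves'-type exclusionary code with probability 0.01. Record years are
  bounded below by birth year.

**What the generator does not model:** mortality and censoring, migration,
remarriage/half-sibships (half-sibling classification exists for hand-built
pedigrees but never arises in simulation), assortative mating, dominance,
age-at-onset structure within the window, and sub-year diagnosis dates.
Passing tests therefore demonstrate that the pipeline recovers the
generative signal under these idealized conditions, not that the real-world
estimates would be unbiased under censoring or differential health-care
contact.

## Ascertainment

A case needs (i) qualifying codes (245.2/E06.3 autoimmune thyroiditis,
244.9/E03.9 unspecified hypothyroidism; configurable) in at least
`min_distinct_years` = 2 distinct calendar years, (ii) no exclusionary code
in any year (exclusion is lifetime), (iii) age ≥ 18 at the reference year
(age = reference year − birth year; records are year-resolution), and
(iv) ≥ 3 relatives of degree ≤ 3. Attrition is reported per filter in that
fixed order; membership is order-invariant. Whether both code families or
only the autoimmune codes may satisfy the two-year rule is ambiguous in
such designs, so it is a policy switch (`distinct_year_codes`, default
`any_qualifying`). Controls are adults with no qualifying and no
exclusionary code at all — a person with one single-year code falls out of
both pools. Relatives' outcomes use the same diagnosis rule but without the
pedigree-size filter (a relative-level filter would be circular) and
without control-style exclusion.

Prevalence is estimated two ways over a caller-supplied population:
single-diagnosis (≥ 1 qualifying code by the census year) and confirmed
(a qualifying code in a second, different year), the latter always a
subset.

## Matching

Greedy sequential matching in seed-randomized case order (ids sorted, then
shuffled, so the assignment is invariant to input order): each case draws
`ratio` = 2 controls uniformly without replacement from the eligible pool
in its exact stratum — same sex, pedigree-size bin (0-4/5-9/10+), maximum
relative degree and birth-place category — within |Δ birth year| ≤ 2
(the integer-year reading of ±2.5). Controls are never reused; cases with
an insufficient pool are reported unmatched and logged, not fatal. Optimal
maximum-cardinality matching was considered and rejected: the greedy scheme
is what such studies describe operationally, and unmatched cases are rare
at the default conditions (≈ 0.5%). Exact matching forces balance on the
stratum variables by construction; the demographic report's chi-squared
p-values verify it empirically.

## Estimation

The primary estimator is a marginal logistic regression fit by IRLS
(convergence: relative log-likelihood change < 1e-10 *and* Newton step
< 1e-9, max 100 iterations; |β| > 15 raises a separation error), with Wald
CIs on the log-odds scale. With a single binary predictor the fit equals
the 2×2 cross-product odds ratio exactly; `or_from_2x2` (Woolf CI,
Haldane–Anscombe 0.5 correction only when a cell is zero, undefined when a
margin is empty) is kept as an independent closed-form oracle and the test
suite verifies agreement to 1e-8 on random tables.

**Variance.** Outcomes of one proband's relatives are correlated (shared
genes/environment), so the variance is a cluster-robust sandwich with
clusters = index proband. That alone proved anti-conservative in this
design's own null simulations (measured type-I error ≈ 0.09–0.13 at the
~2,000-person scale): because people occur in multiple pedigrees, two
related probands contribute *reciprocal* rows — each appears, with an
outcome fixed by their own proband status, in the other's cluster — and at
small scale almost every affected case-arm row arises from such a pair.
The default variance is therefore the multiway estimator
`V(index) + V(unordered index-relative dyad) − V(row)`, which adds exactly
the reciprocal-dyad covariance and reduces to the plain index-clustered
sandwich whenever no relative is itself a proband. With it the null
type-I error is ≈ 0.04 and CI coverage ≈ 0.96 (500 replicates). No
small-sample CR correction or t-reference is applied beyond this; with
hundreds of clusters the effect is negligible.

A random-intercept-per-index logistic variant is available
(`fit_random_intercept_logistic`, marginal likelihood by adaptive
Gauss–Hermite quadrature with 15 nodes centered at each cluster's posterior
mode, BFGS over (β, log τ), finite-difference Hessian for SEs). It
estimates subject-specific ORs and is intentionally not the default: the
marginal + sandwich estimator targets the same population contrast, is an
order of magnitude faster at replicate scale, and has the calibration shown
above.

**Strata.** First-degree analyses can be refit per
(relationship × relative sex × index sex) stratum — e.g. sons of affected
vs unaffected fathers is `son|father-index` — with sex dropped from the
design inside single-sex strata. Spousal contrasts split by index sex
(husbands of case vs control wives; wives of case vs control husbands).
Degenerate strata (single-class outcome or separation) are skipped with a
recorded reason, never imputed. No multiple-testing adjustment is applied;
per-stratum CIs are reported as-is.

## Replicated self-checks and problem sizes

`famrisk.experiments` packages three replicated studies, also used by the
acceptance script:

- **Null calibration** — 500 replicates of ~2,000-person populations (180
  founder couples, 4 generations) with `h2 = c2 = 0`; type-I error of the
  first-degree Wald test and coverage of OR = 1.
- **Pattern recovery** — 100 replicates at the default conditions; the
  frequency of OR(FDR) > OR(SDR) > OR(TDR) > 1, median degree ORs, median
  female OR, and spousal ORs fitted on rows pooled across replicates
  (spouse pairs are too sparse per replicate — at most one spouse per
  proband — for stable per-replicate estimates).
- **Matching balance** — 20 replicates; total audit violations and the
  fraction of replicates with chi-squared p > 0.05 on every matching
  variable.

Replicate sizes are chosen so a few dozen cases arise per null replicate
and third-degree contrasts are estimable per pattern replicate. Replicate
seeds stride from a base seed; every random draw in the package flows
through `numpy.random.default_rng` seeded from explicit parameters, and the
pipeline derives per-stage seeds from one master seed by fixed offsets, so
identical configurations give byte-identical outputs.

## Numerical and edge-case choices

- Kinship uses the exact recursion on the later-born member, memoized per
  genealogy; founders are mutually unrelated. Gene-dropping simulation
  serves as the oracle in tests, never in the implementation.
- When a pair is related several ways (consanguinity; impossible under the
  simulator's mating rule but legal in hand-built data), the smallest
  degree wins with a fixed taxonomy order as tie-break, and the event is
  logged. Blood relatives beyond degree 3 classify as `other` and are
  excluded from analyses; consanguineous partners are excluded from the
  spousal analysis with a warning.
- The genealogy file is a tab-separated superset of the PLINK FAM
  convention with a header row; childless couple links are stored as
  `#couple` comment lines. Simulation-only liability fields are never
  persisted. Parse errors carry line numbers; dangling ids raise
  referential-integrity errors naming the id.
- Percentages in the demographic table print as whole percent at ≥ 10% and
  one decimal below, the convention of published cohort tables.

## Known limitations

- The estimator pair (marginal sandwich / random-intercept) brackets but
  does not exhaust what "mixed-effects clustered on the index" could mean;
  GEE with non-independence working correlation is not implemented.
- Cross-pedigree correlation between *different* related relatives (not
  reciprocal proband pairs) is still outside the variance model; its
  effect was not detectable in the null calibration at the tested scale.
- The matching audit checks stratum predicates and uniqueness, not
  optimality; pathological pool orders could leave more cases unmatched
  than an optimal assignment would.
- Simulated odds ratios at the default conditions are larger than those
  published from million-person databases (e.g. FDR ≈ 2.9–3.8 here): with
  full lifetime observation, no censoring and near-perfect recording, the
  realized familial signal is stronger than EHR-window ascertainment in a
  real population yields. The package recovers orderings and calibration,
  not the literal published magnitudes.
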