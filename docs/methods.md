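# Methods

## Model

Labour is treated as a staged process from onset `O` to birth `B`. An
*intervention protocol* is an ordered list of `n` interventions, least to most
invasive (default `A` = augmentation, `V` = ventouse, `C` = caesarean). Under
the sequential-protocol assumption a less invasive intervention, when it
occurs, precedes a more invasive one in time; emergencies appear as direct
transitions (e.g. `O→C`), not as reorderings. Each woman's labour is then
summarised by a binary path of length `n` (flag = 1 if the intervention was
received), and a cohort by the counts `N(path)` over the `2^n` paths.

Two points about this encoding are easy to miss. First, paths with both
`V = 1` and `C = 1` are legal and observed: a failed ventouse followed by
caesarean. Second, when raw amniotomy and oxytocin flags are both present in
per-woman input they are OR-merged into the single augmentation flag, because
only their merged version is comparable across wards that do and do not
impose an amniotomy-before-oxytocin ordering.

### Measures

With `E` total treatments in `N` women, `H = E/N` (overall treatment ratio,
in `[0, n]`) and `ILI = H/n` (in `[0, 1]`). Five algebraically equivalent
forms of `H` are implemented (treated-proportion split, type-specific sum,
treatment-count mean, path-distribution mean, progression-proportion
polynomial); the test suite asserts their agreement *exactly*, because all
ratio arithmetic is done in `fractions.Fraction` and converted to float only
at the reporting boundary. Rounding in rendered reports is half-away-from-zero,
3 decimals for ratio-scale quantities and 1 decimal for percentages.

### The Markov layer

The compartmental representation assigns to each ordered state pair
(`O` or an intervention → a strictly later intervention) the *progression
proportion* `p_st`: the fraction of women in `s` whose next treatment is `t`;
`1 − Σ_t p_st` exit to birth. The estimator is the history-pooled
maximum-likelihood estimator: the denominator for source `s` is every woman
who received `s` (or everyone, for `O`), regardless of how she got there.
This is the estimator under which the visit probabilities

```
v_j = p_Oj + Σ_{i<j} v_i · p_ij         (forward recursion)
```

satisfy `N·v_j = E_j` as an exact integer identity, so Form 5 agrees with
Forms 1–4 exactly whenever the proportions come from the same table. The
recursion is linear in the number of states and is validated in the tests
against a brute-force enumeration of all `2^n` paths up to `n = 5`.

States nobody reaches leave their outgoing proportions undefined. These are
reported as undefined and treated as zeros downstream, with a warning rather
than an error, so sparse cohorts remain analysable.

The Markov *property* — that progression out of a state does not depend on
the arrival route — is an assumption, and the package tests it: for every
state reachable by at least two distinct histories and every later target,
women are cross-classified as history × progressed-to-target and tested for
homogeneity. Fisher's exact test is used when exactly two histories are
observed (the counts in this setting are typically far below chi-square
validity thresholds; for `n = 3` the only testable state, `V`, always yields
a 2×2 table), and the chi-square test of homogeneity otherwise, with a note
attached. No multiplicity correction is applied by default; a Bonferroni
flag exists because a single run can emit many tests.

Path-level reconstruction from the fitted chain (product of transition
proportions times the exit probability from the last visited state) is
provided as a diagnostic: it reproduces the empirical path frequencies
exactly iff the history-specific proportions coincide with the pooled ones.

## Decompositions

**Multiplicative split.** `(H₂−H₁)/H₁ = ΔS/S₁ + ΔH_T/H_T₁ + (ΔS/S₁)(ΔH_T/H_T₁)`
— exact, asserted to 1e-12. Undefined when cohort 1 has no treated women.

**Stepwise replacement.** The functional (H, a single type-specific ratio,
or any sum of them) is written in cohort-1 proportions, which are replaced
one at a time by cohort-2 values; successive differences are the partial
contributions, and they sum to the total difference exactly for *every*
replacement order. The default order replaces transitions to less invasive
treatments first (source ascending, then target ascending). Scaled
contributions divide each partial difference by the absolute value of the
first one and multiply by 100, preserving sign, so the first step reads ±100;
they are reported as missing when the first step's difference is zero.
Intermediate replacement states mix two cohorts' proportions and are formal
polynomial arguments — they are deliberately exempt from the row-sum ≤ 1
validation that applies to genuine chains.

Because the attribution is order-dependent, `order_sensitivity` evaluates
all `k!` orders (capped; a seeded random sample beyond the cap) and
summarises each transition's min/mean/max contribution; the mean over all
orders is the Shapley attribution.

## Robson reporting and standardization

The ten-group report derives all four percentage columns from the integer
women/caesarean counts (the embedded reference tables are stored as counts
and every derived column is recomputed, which also resolves the small
rounding inconsistencies typical of typeset clinical tables). The class
vocabulary is fixed, including the IIa/IIb and IVa/IVb refinements; unknown
labels are rejected rather than coerced. Standardization is *direct*: a
fixed reference class distribution (default: the pooled class sizes of the
two cohorts) weights the class-specific functional values, making the
standardized value a convex combination of class values.

## Cohort comparison tests

Path distributions are compared with the chi-square test of homogeneity on
the 2×k path-count table. Because several of the `2^n` paths are rare, cells
are pooled before testing: the category with the smallest expected count is
merged into an `other` category until every expected count reaches the
threshold (default 5), and the merges are logged in the result for audit. A
Monte-Carlo calibration of the same statistic (resampling both cohorts from
the pooled distribution) is available for tables where the asymptotic
approximation is doubtful. Individual ratios are compared with the Pearson
chi-square test of equal proportions, without Yates continuity correction by
default (a flag enables it); at the cohort sizes of interest the correction
does not change any qualitative conclusion.

## Simulator

`simulate_cohort` draws each woman through the chain: at every visited state
one uniform variate decides the next transition against the cumulative
outgoing proportions, in protocol order, from a single `numpy` generator
seeded by the config — identical configs give bit-identical tables.
*History modifiers* deliberately break the Markov property: for women whose
earlier-treatment history matches a condition, a transition's probability is
multiplied on the odds scale and clipped to `[0, 1]`; configurations whose
effective outgoing probabilities could exceed 1 are rejected before sampling.

What the simulator emulates is the branching structure of staged
intervention and nothing more: no labour durations, no covariates, no
within-class heterogeneity, no Robson-class assignment mechanism (strata are
simulated independently). Passing recovery and power tests therefore shows
that the estimator and the homogeneity test behave correctly *under the
model*, not that real labour-ward data satisfy the model — that is exactly
what `markov_property_test` is for on real data.

Default study-scale parameters used in the validation suite: generative
proportions equal to those estimated from the embedded before-cohort
(p_OA = 215/637, p_OV = 10/637, p_OC = 25/637, p_AV = 17/215, p_AC = 38/215,
p_VC = 2/27); cohorts of 10^5 women for consistency checks (binomial
standard errors ≈ 10^-3); 200 replicates for the type-I-error check of the
Markov test and 60 for the power check against a doubled-odds violation at
N = 5000, with power > 0.8.

## Numerical and degenerate-input conventions

- `N = 0` tables are representable; every ratio raises a degenerate-input
  error instead of returning NaN. `S = 0` cohorts report `H_T` as missing.
- Identities (form equivalence, decomposition additivity, distribution
  normalisation) are exact in rational arithmetic and asserted at 1e-12
  after float conversion.
- Seeds: every stochastic routine takes an explicit seed; replicate seeds
  are spawned from it via `numpy.random.SeedSequence` and kept below 2^31.
- Tie-breaks in sparse-cell pooling are stable (first-by-canonical-order
  among equal expected counts).

## Known limitations

- No confidence intervals for H/ILI or for decomposition contributions;
  the framework is descriptive and the sampling theory is future work.
- The exact multinomial test for the full 2×2^n table is not implemented
  (combinatorially heavy); the Monte-Carlo option covers that need.
- Time-in-state, induction method and other covariates are outside the
  model; paths are time-ordered only through the protocol ordering.
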