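# Methods

## Gene dropping and reproductive value

The pedigree is a DAG of parent→offspring links. Every individual with at
least one unknown parent is a *lineage root*: founders (both parents
unknown) root two unique alleles, half-founders (one parent unknown) root
one unique allele on the unknown side and inherit the other from the known
parent. Gene dropping simulates neutral Mendelian transmission: in
topological order, each fully-parented individual receives one allele drawn
uniformly at random from each parent's two, independently per offspring and
per replicate (single locus, no linkage, no mutation, no selection).

Per replicate, root and year we count root-derived allele copies among
individuals **alive** that year (the interval `[birth_year, death_year]`,
juveniles included; an adults-only reference population is a trivial
variation and the alive-set is the package's default convention). The
reproductive value of a root in year Y is the mean copy count over
replicates — an absolute expected contribution, deliberately not divided by
population size. Allele survival probability is the fraction of replicates
with at least one copy in the final year; it is 0 exactly when the
final-year reproductive value is 0 on the same replicate set.

Because roots are also assigned to individuals with unknown parents born
*outside* the cohort window ("noncohort" roots), every allele in every
individual traces to some root, giving the conservation law used as a
structural test: per replicate and year, copy counts summed over all roots
equal twice the number of individuals alive.

Lineage longevity and the binary "lineage survived to the final year"
outcome used in the logistic regressions are *genealogical* (the root or
any pedigree descendant alive), which gives one deterministic outcome per
lineage; an allele-based alternative (survival probability > 0) is exposed
as `survival_definition="allele"`.

The stabilisation diagnostic correlates per-root reproductive values in
each year with those in the final year; theory predicts rank stabilisation
after about log₂(N) generations, i.e. G·log₂(N) years.

**Numerical choices.** Transmission is vectorised across replicates: one
`numpy` Generator seeded once drives all draws, and identical
(pedigree, roster, n_reps, seed) inputs reproduce results bit-for-bit.
Copy counts are stored as an `(n_reps, n_roots, n_years)` unsigned-integer
array; per-year tallies use a single `bincount` over root×replicate codes.
Years where the reproductive-value vector has zero variance yield a missing
stabilisation correlation rather than a fabricated value.

## Short-term proxies

*LRS* is a straight lifetime sum of a parent's per-year counts at one
stage (eggs, hatchlings, fledglings, recruits) or of broods; an individual
absent from the breeding table has LRS 0 (a valid zero-fitness founder).

*IGR* builds an L×L transition matrix over breeding ages 1..L with
L = death_year − birth_year (ages without records contribute zero
fecundity; individuals with L = 0 died as juveniles and are flagged
incomplete and excluded from founder analyses). The first row holds
per-age offspring counts halved — a parent passes on half of each
offspring's alleles — and the sub-diagonal holds 1s. IGR is the dominant
eigenvalue: by Perron–Frobenius it is real and nonnegative for this
nonnegative matrix, so we take the largest real eigenvalue among those with
negligible (≤ 1e-9) imaginary part, without assuming diagonalisability; a
zero fecundity row gives a nilpotent matrix and IGR 0, and such individuals
stay in the comparison samples.

*De-lifed fitness* is p_ti = (ξ_t(i) − w_t)/(N_t − 1). ξ counts the
individual's offspring born in year t that are alive as adults in year t+1
("recruits-to-be"), weighted by `offspring_weight`, plus 1 if the
individual itself survived to t+1. The default weight is 1 (each surviving
offspring counts fully for each parent, the verbatim definition);
weight 0.5 splits each offspring between its two parents and is the only
choice under which the values sum to zero across all adults each year
(Σξ = N_{t+1} then), which the tests assert exactly on synthetic data with
full parentage. The denominator reading (N_t − 1, not w_t·N_t − 1) follows
the original de-lifing construction. Lifetime de-lifed fitness sums annual
values over the adult years for which both t and t+1 are censused.

## Comparison layer

Pearson correlations between each proxy and final-year reproductive value
are computed across surviving lineages with complete life history, with
Fisher-z 95% CIs (z ± 1.96/√(n−3)) and two-sided p from the t
distribution with n−2 df. Correlation differences default to the
conservative CI-overlap criterion; Steiger's z for overlapping dependent
correlations is available when the predictor–predictor correlation is
supplied. Lineage survival is regressed on each z-scored proxy
(sample-SD z-scoring so slopes are comparable across proxies) by
maximum-likelihood logistic regression with Wald 95% CIs; this replaces a
Bayesian MCMC logistic fit with fixed residual variance — the sign and
significance of slopes, the quantities interpreted, are preserved, and the
substitution is recorded in run metadata. Complete separation is detected
(non-finite or exploding Wald SEs) and flagged instead of reporting
divergent estimates. Fisher's exact test uses the dominant two-sided
convention (sum of hypergeometric probabilities ≤ the observed table's);
the rank-sum test reports the Mann–Whitney W of the first sample with
midrank ties, exact for combined n ≤ 20 without ties and otherwise the
normal approximation with continuity correction. No multiple-testing
correction is applied anywhere, matching the analysis being emulated.

## Synthetic populations

The generator emulates a small, isolated, individually monitored passerine
population. Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| n_founders | 90 | ~100 lineage roots incl. half-founders, both sexes 1:1 |
| introduced_fraction | 0.2 | minority of founders carry an "introduced" origin label |
| years | 20 | two decades of monitoring |
| egg_rate | 8 eggs/female/yr | ≈ 24 lifetime eggs over a 3-year adult life below capacity |
| brood_rate | 2 broods/yr | ≈ 4 eggs per brood |
| egg_dispersion | 6 (negative binomial) | overdispersed clutch totals |
| p_hatch | 0.85 | observed hatching fraction |
| p_fledge_given_hatch | 881/1746 ≈ 0.505 | observed fledging fraction |
| p_recruit_given_fledge | 294/881 ≈ 0.334 | observed recruitment fraction; compounds to ≈ 14% egg→recruit |
| adult_annual_survival | 2/3 | geometric lifespan mean 3 years |
| carrying_capacity | 140 | census equilibrates near 125 adults |
| bottleneck | (2010, 0.4) | mid-study crash in adult survival |
| immigration_rate | 2/yr | half-founders arise as recruits with unidentified sires |

Pairing is monogamous with random annual re-pairing and no extra-pair
paternity, so parentage bookkeeping is exact. Density dependence acts on
fecundity (a logistic factor on mean eggs per pair as the census approaches
carrying capacity) rather than on recruit survival; this keeps the realised
stage fractions at their configured values — a property the tests exploit —
while still regulating recruitment through egg numbers, and produces the
fluctuating census with a controllable bottleneck. The pedigree records
adults only (founders and recruits); eggs, hatchlings and fledglings that
never recruited exist only as breeding-table counts, as in field pedigrees
built from reproducing individuals. A recruit born in year t enters the
adult census in year t+1. "Recruit" here means survived to enter the adult
pool, a slight relaxation of "went on to produce an egg".

What the generator does **not** model: extra-pair paternity, individual
quality or heritable fitness variation, observation error and imperfect
resighting, spatial structure, sex-biased survival, parentage-assignment
error. Passing tests therefore show that the estimators and comparisons
behave correctly when their demographic assumptions hold — not that a real
pedigree satisfies them. In particular, origin labels are demographically
neutral in the simulation, so origin contrasts on synthetic data carry no
systematic signal.

## Problem sizes

The test suite and the acceptance script use deliberately scaled runs: the
exact-enumeration gene-drop oracle covers pedigrees of ≤ 8 individuals
(≤ 2⁹ transmission outcomes) against 10,000 Monte-Carlo replicates; the
structural and conservation checks run 100–300 replicates on populations of
40–90 founders over 10–20 years; the headline recruit-vs-egg comparison
uses 20 seeded default populations at 200 replicates each. These sizes give
Monte-Carlo standard errors small enough for every asserted tolerance while
keeping a full run in tens of seconds.

## Known limitations

- Reproductive values are conditional on the realised pedigree; they are
  not realised genomic contributions, which vary around them through
  segregation and recombination.
- The alive-set reference population includes juveniles; analyses wanting
  the adult census as reference must currently post-filter years.
- The de-lifing zero-sum holds only with `offspring_weight = 0.5` and full
  censused parentage; with half-founders present the annual sums deviate by
  the unassigned parental halves.
- Single-locus, autosomal transmission only; no sex chromosomes.
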