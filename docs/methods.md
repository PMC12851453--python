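# Methods

This note documents the statistical models implemented in `culttrans`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real survey data.

## Data model

The unit of analysis is an egocentric network: one student plus any of
nine further roles (retest of the same student, mother, father, four
grandparents, two friends), each role at most once per network.  Scores
are factor scores on latent attitude/behaviour dimensions, centred so 0
is the factor mean; the eight default factor labels (Religiosity,
Politics, Environmentalism, Health, Music, Reading, Screen, Social) are
labels only — nothing in the code depends on their meaning.

Design choices:

- **Long-format CSV** (`network_id, role, factor, score`) is the
  canonical interchange format because network composition is ragged;
  an empty score field is a missing value.  Rows with roles outside the
  ten known ones (e.g. other relatives) are dropped with a logged
  count rather than rejected, since surveys routinely collect them.
- **Relationship averaging.** Parents are averaged into a Vertical
  component, friends into a Horizontal component, grandparents into a
  grandparental component.  When only one member of a relationship is
  present, that member's score passes through (mean of available
  members); when none is present the component is *undefined*, never
  zero.  This keeps single-parent networks in the analysis instead of
  discarding them.
- **Dichotomisation** at threshold 0 maps score ≥ 0 to "has the trait";
  the threshold is configurable but 0 is the principled default for
  mean-centred factor scores.  The ≥ convention means an exactly
  average individual, and a couple split one-each-way (component mean
  0), count as having the trait.
- **Imputation** is a pluggable interface with a factor-mean default.
  Expectation-maximisation imputation would also fit behind the same
  interface; with missingness around 2% of values the choice of imputer
  has negligible influence on any downstream statistic, so the simplest
  deterministic imputer is the default.
- Retest scores (`student_t2`) are kept for reliability reporting but
  never enter components, transmission or any resemblance pair except
  student-vs-retest.

Inclusion rules: `student_plus_any` (≥ 1 relation of any kind),
`parent_and_friend` (required by the additive model) and
`parent_friend_and_grandparent`; each reports retained/excluded counts
so the accounting of a run is auditable.

## Resemblance

For roles A, B and a factor, let r be the Pearson correlation over the
n networks containing both (pairwise deletion per role pair — this
maximises n per pair and mirrors how per-pair sample sizes vary in real
data).  The null is built by scrambling the pairing: B's vector is
permuted across networks `n_perm` times (default 10,000); only one side
is permuted because permuting both is redundant under exchangeability.
Then

    z = (r − mean(r_null)) / sd(r_null),    sd with ddof = 1.

A Monte-Carlo two-sided p-value is also reported with the
add-one correction `(#{|r_null| ≥ |r|} + 1) / (n_perm + 1)` so it can
never be exactly zero, alongside the parametric Pearson p-value (both
are emitted, labelled, since either convention is defensible for the
raw correlation matrix).

Edges are tiered at z > 1.96 and z > 3.3 and categorised by role
identity (direct vertical, indirect vertical, horizontal, other).  The
machine-readable edge list is the primary output; plots are optional
renderings of it.

Numerical notes: each (pair, factor) cell draws from an independent
child stream of the graph seed, so results do not depend on evaluation
order; permutations are generated by argsorting uniform variates in
chunks capped at ~5M elements to bound memory; degenerate cells (role
absent everywhere, < 3 complete pairs, zero variance) are recorded as
skipped with the reason rather than failing the whole graph.

Calibration: under an exchangeable null the |z| > 1.96 rejection rate
measured over 1,000 seeded datasets (n = 200 pairs, n_perm = 1,000)
sits at ≈ 5% (the acceptance suite asserts 0.05 ± 0.02).  The z-score
approach is mildly sensitive to the normality of the permutation null
of r; at the sample sizes used here the approximation is comfortably
adequate, and the exhaustive-enumeration check (n = 6, all 720
pairings) bounds the Monte-Carlo error of z itself at ≤ 0.15.

## Additive transmission and bias estimation

Networks passing `parent_and_friend` are classified by the dichotomised
(Vertical, Horizontal) component traits into parental types VH, Vh, vH,
vh; `B_i = N_i / P_i` with exact integer counts.  The opposite-trait
table is the complement on inverse types (VH↔vh, Vh↔vH): `P'_i =
P_inv(i)`, `N'_i = P_inv(i) − N_inv(i)`.  This complementarity is an
identity of the construction, not an estimate, and is asserted exactly
(on counts) in the tests.

**Bootstrap CIs.** Networks are resampled with replacement; since each
network contributes one of eight (type × student-trait) cells, the
resample is realised as a multinomial draw over those cells, which is
the identical resampling distribution and vectorises cleanly.  CIs are
2.5/97.5 percentiles of the resampled `B_i` (default 10,000 resamples).
Resamples in which a type comes out empty contribute no value for that
type; types empty in the original data get an undefined CI.  Percentile
CIs for proportions undercover slightly at small cell sizes
(discreteness); measured coverage at cells of ~250 is ≈ 94.5%.

**Bias model.** The four cells per polarity are binomial,
`N_i ~ Bin(P_i, p_i)` with `p_i = other + vertical·v_i + horizontal·h_i`
(v_i, h_i the type's indicators).  Vertical and Horizontal are shared
between the trait and its opposite — forced by complementarity — while
each polarity has its own Other.  That same complementarity makes the
opposite Other equal to `1 − other_trait − vertical − horizontal` when
the model fits exactly; the fit keeps it a free parameter so model
misfit is visible as a departure from that identity.

Three objectives are provided: negative binomial log-likelihood
(default — the cells are binomial counts, so this is the principled
maximum-likelihood reading), squared error on proportions, and squared
error on counts.  The wording "lowest amount of error" admits several
readings, and on the worked-example counts the three objectives give
visibly different optima; all three are therefore first-class and
reported, rather than guessing a single one.

**Search.** All four rates are constrained non-negative with
`other + vertical + horizontal ≤ 1` per polarity, so every cell
probability is a valid Bernoulli parameter.  The search is an
*exhaustive* scan of the grid (default resolution 0.01, refinable to
0.001): for fixed (vertical, horizontal) the trait-Other and
opposite-Other scans decouple, making the full scan cheap and
optimizer-free.  Ties are broken by the lexicographically smallest
(vertical, horizontal, other_trait, other_opposite) — grid plateaus do
occur (e.g. when only the VH and vh cells are populated, only
vertical + horizontal is identified) and the tie-break makes results
platform-reproducible.  Empty cells (P_i = 0) simply contribute nothing
to the objective.

Triangle-plot coordinates normalise (vertical, horizontal, other) to
sum 1 per polarity and place the point barycentrically; an all-zero
triple sits at the centroid.

## Synthetic populations

The generators exist so that every downstream statistic can be checked
against known truth; their defaults are chosen once to represent the
study conditions, not tuned to any test outcome.

**Binary generator** (additive-model ground truth).  Per network and
factor: the Vertical-component trait v ~ Bernoulli(p_v); the
Horizontal-component trait h copies v with probability
`parent_friend_corr` (a shared-mixture construction — one interpretable
knob that reproduces clustered-network correlation between parents and
friends; it requires equal component prevalences, which is enforced)
and is otherwise independent; the student adopts with probability
`other + vertical·v + horizontal·h`.  Parents realise v, friends h,
with a within-relationship concordance parameter (probability the
second member copies the first, else an independent draw).
Concordance defaults to 1: the additive model treats the couple as a
single Vertical agent, and with perfect concordance the realised
component trait equals the generating one, so the closed-form cell
expectations hold exactly and parameter-recovery tests test the
estimator, not classification noise.  Lower concordance is an explicit
robustness knob.  Traits are emitted as signed scores (+1/−1) so the
standard dichotomise-at-0 rule recovers them, ties resolving to "has
the trait" consistently with the ≥ 0 convention.  Grandparents, when
present, are independent background draws — they do not enter the
additive model.

**Continuous generator** (resemblance-structure ground truth).  Role
scores are standard normal with pairwise correlations set by a target
map (Gaussian copula: scores = z·Lᵀ with L a factor of the target
matrix, so targets are met exactly in expectation).  Unspecified pairs
get a small background correlation (default 0.10, representing weak
network-wide clustering).  Infeasible (non-PSD) target sets are
rejected naming the most implicated pair.  Default targets echo the
magnitudes seen in family-and-friend surveys: retest reliability 0.85,
within-couple 0.55–0.60, parent–student 0.30–0.35, friend–student 0.30,
grandparent–parent 0.30–0.35.

Two presets: a *recovery* preset (students, both parents and both
friends always present, no missingness — clean conditions for
parameter-recovery studies) and a *survey* preset (role presence
loosely calibrated to typical participation: mothers ≈ 44% of networks,
fathers ≈ 37%, friends ≈ 48% each, grandparents 5–14%, retest 50%, with
2% missingness completely at random).  The joint composition
distribution is not fitted to any dataset.

Randomness is hierarchical — each network draws from an independent
stream keyed by (seed, generator, network index) — so populations are
reproducible and extensible without reshuffling earlier networks.

**What the synthetic tests do not show.**  The generators emulate the
*statistical structure* the analysis assumes: additive adoption,
jointly normal scores, missingness completely at random, independent
networks.  Real survey data can violate all four (non-additive
interactions, skewed factor scores, informative nonresponse, shared
contexts linking networks).  Passing recovery and calibration tests
therefore certifies the estimators and their implementation, not the
substantive conclusions one would draw from any particular survey.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → filter → impute → resemblance →
transmission from a single config that must name a seed for every
stochastic stage; the config (plus package version) is copied into the
output directory, JSON is written with sorted keys, and CSV with fixed
float formatting, making artifacts byte-reproducible.  Stage failures
leave a `FAILED` marker naming the stage.  Plots are optional views of
the machine-readable outputs and carry no additional information.

## Problem sizes

Defaults follow the method's own conventions: 10,000 permutations for
Resemblance and 10,000 bootstrap resamples for CIs.  The simulation
studies use sizes chosen for tight Monte-Carlo error at interactive
cost: 1,000 replicates for null calibration (SE of the rejection rate
≈ 0.007), 5,000 networks for bias recovery (binomial SE per cell
≈ 0.013, comfortably inside the ±0.03 acceptance band), 500 replicates
× 1,000 networks for CI coverage, and a 200-network demo population.

## Known limitations

- Dichotomisation discards information by construction; coefficients
  near 0.5 are least informative about the underlying scores.
- The additive model ignores grandparents; they appear only in
  resemblance and filtering.
- Resemblance is symmetric and says nothing about direction: homophily,
  mutual influence and shared environment are observationally
  equivalent here.
- The opposite-trait cells are deterministic complements of the trait
  cells; fitting both polarities jointly (shared Vertical/Horizontal,
  separate Others) follows the model's structure but does not add
  independent data.
- Percentile-bootstrap CIs undercover slightly for extreme proportions
  and small cells; exact binomial intervals would be preferable when a
  single cell is of primary interest.
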