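# Methods

## The system being modelled

A single-school cohort of adolescent girls (N = 201, seven classrooms of
~29) named up to five close friends each, twice, five months apart, and
reported tooth-brushing frequency on an ordinal four-level scale
(1 = twice or more daily, 2 = once daily, 3 = a few times a week,
4 = never; *lower is better*). The naming data define a binary directed
friendship matrix `X` with `x_ij = 1` iff student *i* named student *j*;
"friends" throughout means out-neighbours, because that is what the
questionnaire records. Level-*n* friends are students at directed
shortest-path distance exactly *n*.

The package provides (i) the network statistics used to describe such
cohorts, (ii) two weekly-tick agent-based models of behaviour diffusion on
the friendship network, (iii) a grid-search calibration of their two free
probabilities against empirical-style targets, (iv) three week-0 training
interventions compared by simulation, and (v) a synthetic-cohort generator
so the full pipeline runs without the (unpublished) individual-level data.

## Network statistics

**Level-n matrices.** The level-*n* relation is *defined* here by exact
shortest-path distance: entry `(i, j)` of level *n* is 1 iff the shortest
directed path from *i* to *j* has length exactly *n*. The historical
construction by raw matrix powers marks every pair joined by a *walk* of
length *n*, including pairs that are actually closer; since the intended
reading is "distance of n links", the distance definition is the default
and the binarized power is available behind `raw=True`. Distances are
computed by `scipy.sparse.csgraph` BFS; the test suite checks equivalence
against an independent `networkx` BFS oracle on hundreds of random
digraphs.

**Turnover D.** `D = Σ_ij |y_ij − x_ij|` counts ordered pairs whose entry
differs between two assessments; it is a metric on these matrices with
range `0..N(N−1)`, and `201·8 = 1608` is the ceiling when every student
with four named friends replaces all of them.

**Mutuality.** A student's mutuality is the percentage of her named
friends who named her back, with denominator equal to her out-degree;
students who named nobody score 0% and stay in the cohort mean (the
alternative fixed denominator of five would only rescale the published
binned summaries, whose weighted means are denominator-independent).

**Cross-correlation CC_i.** For level *i*, `V_i(j)` is the mean score of
student *j*'s level-*i* friends (undefined when she has none; undefined
entries are excluded pairwise and the number of defined students is
reported per level). The literal statistic `Σ_j V0(j) V_i(j)` is a raw
inner product of 1–4 scores, dominated by scale; curves in that form are
not comparable across cohorts. The default mode is therefore the Pearson
correlation of the defined `(V0, V_i)` pairs; the raw sum remains
available via `mode="raw"`.

**Correlation length.** The deepest level *L* such that CC_m is
significant for every `m ≤ L`, assessed by a two-sided permutation test
that shuffles the score vector over students (default 999 permutations,
α = 0.05, no multiple-level correction — deliberately, to mirror how such
lengths are reported). Regression-based significance (the
proportional-odds fit below) remains available, but the permutation form
makes the measure self-contained.

**Ordinal association.** Associations of the four-level outcome with
friend-average, SES, or in-degree covariates are fitted as a
cumulative-logit (proportional-odds) model via
`statsmodels.miscmodels.OrderedModel`, reporting slopes, Wald standard
errors and p-values plus the three cut-points. A negative in-degree slope
means more-named (popular) students brush better. Perfectly separating
predictors are refused (diverging standard errors) rather than reported.

## The agent-based models

State: the friendship matrix plus each student's score in {1..4}, stepped
in weeks.

* **Behaviour step** (both models): each student with at least one named
  friend independently decides with probability `u` to move one level
  toward the unrounded mean score of her named friends; exact ties do not
  move; isolates never change. The update is synchronous (everyone
  compares to last week's scores), chosen so a week's outcome does not
  depend on student ordering. Comparisons use integer arithmetic
  (`friend_sum − score·degree`), so ties are exact.
* **Rewiring step** (dynamic model only): each student with at least one
  named friend independently decides with probability `p` to drop one
  uniformly chosen named friend and befriend a uniformly chosen student at
  directed distance exactly 2 in the post-removal network, excluding
  herself and her remaining friends; if no candidate exists the removal is
  reverted. Out-degree is conserved exactly; rewiring is applied in
  student-id order within the week, after the behaviour step. The
  just-dropped friend may be re-adopted if she sits at distance 2.

Each run consumes a single `numpy` Generator in fixed student-id order, so
trajectories are bit-reproducible from `(initial state, seed)`; ensemble
replicates use seeds spawned from one master `SeedSequence`.

Known dynamical facts, verified in tests: scores never leave {1..4};
the static model's network is bit-frozen; a configuration where everyone
equals her friends' mean is a fixed point; synchronous integer dynamics on
arbitrary digraphs can sustain limit cycles, so convergence of weekly
change counts to zero is only guaranteed (and only tested) on components
that can equilibrate, such as mutual pairs.

## Calibration

Two targets, fitted one parameter at a time in the study's narrative
order, both on ensemble-averaged simulations from the round-1 state over
the 22-week follow-up (5 months × 4.345 weeks/month, rounded):

1. `p` against the observed turnover `D` between the two rounds
   (empirically 628 of a possible 1608): for each grid value the dynamic
   model runs the follow-up horizon and `|mean D − target D|` is
   minimised. This objective is sharply monotone in `p` before saturation
   and recovers a known `p*` essentially always.
2. `u` against the follow-up correlation curve: sum of squared differences
   over levels defined in both curves, ties toward smaller `u`.

Reciprocal weeks give the natural reading of the calibrated values:
`u = 0.02 → one behaviour change per student every 50 weeks`,
`u = 0.023 → every 43 weeks`, `p = 0.2 → one rewiring every 5 weeks`.

Two ensemble-averaging orders for the curve are implemented, since either
could stand behind a reported ensemble curve: averaging per-replicate
Pearson curves (`average="curves"`, the default for descriptive output)
and correlating the ensemble-averaged `V0`/`V_i` vectors
(`average="vectors"`). The vector order is used for parameter-recovery
experiments: it has roughly eight times the sensitivity to `u` at a fifth
of the noise, because replicate-level sampling error in the per-replicate
correlations averages out before the statistic is formed. With the
per-replicate order, the objective's curvature in `u` sits below the noise
of any affordable target ensemble and recovery is unreliable; this is a
property of the statistic, not of the optimiser. Recovery experiments use
grids `p ∈ 0:0.5:0.05` and `u ∈ 0:0.06:0.01` with levels 1–3 (the deepest
level carries almost no signal and the most noise), a target ensemble of
200 and calibration ensembles of 12 (`p`) and 100 (`u`), sharing replicate
seeds across grid points so grid comparisons are common-random-number
smoothed. Under this design a known `(u*, p*) = (0.023, 0.2)` is recovered
within one grid step in ≥ 90% of repetitions.

## Training scenarios

At week 0 the selected students' scores are set to 1 and the dynamic model
runs at the calibrated `(u, p)`; the indicator is the ensemble-mean weekly
count of students at level 1. Selection: none, uniform without replacement
(redrawn per replicate), or the `n` highest in-degree students (fixed
across replicates; ties at the cutoff broken by a seeded draw). Default
`n = 10`, ensembles of 100, horizons of 100–150 weeks; curves plateau by
roughly week 100.

On synthetic cohorts with the default couplings, training always helps
(every trained curve dominates no-training) and random training retains
most of its initial dose at plateau. Popular-student training, however,
does **not** out-gain random training here: the popularity coupling strong
enough to make the in-degree association reliably significant at N = 201
also places most of the ten most-popular students at level 1 before
training, so the popular scenario injects a ~3-student dose against ~6 for
random, and the hubs' larger influence reach (measurable: with the
popularity coupling switched off, popular training gains ~5.6 versus ~3.7
for random at the same parameters) cannot overcome that deficit. An
empirically-weak coupling would free the hubs for training but is too weak
to be detected reliably at this cohort size — the two desiderata conflict
on this generator family, and the package reports the ordering its
simulations actually produce.

## Synthetic cohorts

`CohortSpec` defaults are the published round-1 marginals: 201 students,
7 classrooms, out-degree distribution with mean 4.06 (cap 5, 5.5%
isolates), mean mutuality target 35.6%, within-classroom edge probability
0.9 (clustering is classroom-dominated in the observed network; the true
cross-class rate is unpublished — an assumption), and brushing marginals
(79, 97, 21, 4)/201, mean 1.75.

Networks are built mutual-dyads-first: the number of dyads is set from the
reciprocity target (inflated by the share of positive-out-degree students,
since isolates count as 0% in the mean), laid down mostly within
classrooms, then remaining out-stubs become one-way edges that avoid
creating accidental reciprocity. Realised means over seeds: out-degree
≈ 4.04, mutuality ≈ 37.5%.

Behaviour scores conserve the marginal counts exactly at any coupling
strength: the fixed score multiset is assigned to students by the rank of
a latent propensity
`a · z(network-smoothed field) − c · z(in-degree) + residual noise`,
where the smoothed field blends each student's Gaussian draw with her
named friends' draws (adjacent students share latent mass → friend–friend
assortativity) and the in-degree term implements the popularity–behaviour
coupling with the observed sign. Rank assignment was chosen over iterative
score-swapping because swap hill-climbing drives both couplings to
near-maximal strength regardless of the requested weights, whereas the
latent weights modulate realised effect sizes smoothly. Defaults
`a = 0.8`, `c = 0.35` were fixed once against the qualitative round-1
targets: a clearly significant level-1 association (CC₁ ≈ 0.27), a
usually non-significant level-2 association, correlation length 1, and a
significantly negative in-degree slope (r ≈ −0.31) in essentially all
seeds. SES economy/education scores are independent ordinal 1–5 draws.

`emulate_study_pair` yields a paired fixture: round 1 generated, round 2
produced by the calibrated dynamic model (u = 0.023, p = 0.2, 22 weeks).
On seed average the pair reproduces the empirical directions: positive
turnover `D` (hundreds), a falling mean score, and (on many seeds) a
correlation length growing from 1 to 2.

### What the generator does and does not emulate

It matches the published marginals and association signs, not the real
school's joint structure: in-degree is binomial-like (no sociometric
superstars), SES is independent of behaviour, classroom sizes are
near-equal, and the friendship dynamics between rounds is exactly the
model's own rewiring process. Consequently, passing tests show the
pipeline is correct and the model's mechanics behave as designed on
realistic cohorts — not that the empirical effect sizes (e.g. the
regression coefficients, or D = 628 exactly) are reproduced. Two known
divergences between calibrated-model dynamics and the empirical account
are documented rather than hidden: at `(u, p) = (0.023, 0.2)` network
churn (≈ 4.4 rewires/student over 22 weeks) outpaces behaviour diffusion
(≈ 0.5 moves/student), so the ensemble-average correlation length does
not grow over the follow-up (the lengthening mechanism is demonstrated
where diffusion dominates, e.g. `u = 0.2` on a static network), and the
popular-versus-random training ordering reverses, as analysed above.

## Numerical choices

* Calibration ties break toward the smaller parameter; grids are sorted.
* Largest-remainder rounding turns the brushing distribution into exact
  integer counts.
* Permutation p-values use the `(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`
  estimator; an undefined CC at some level truncates the correlation
  length there.
* Degenerate inputs: empty networks are valid (all degrees 0, mutuality
  0%); out-degree > 5 and self-naming are rejected at construction;
  constant score vectors make normalized correlations undefined
  (signalled, not NaN-propagated).
* Problem sizes in tests and the acceptance script (ensembles of 12–200,
  horizons 22–150 weeks, 20–100 replicates per experiment) are scaled to
  single-CPU desk runs while keeping every ensemble comparison at ≥ 3σ
  resolution.

## Known limitations

* The proportional-odds model is the implementation *and* the reference
  for the association fits (no independent oracle in-suite beyond
  constructed-data sign checks).
* Calibration is one-dimensional twice, not a joint `(u, p)` fit.
* The rewiring rule never changes out-degree, so degree evolution between
  empirical rounds (observed mean 4.06 → 4.02) is outside the model.
* Training scenarios model a one-off week-0 level assignment; trained
  students revert under peer pressure like anyone else.
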