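# Methods

## The estimand: temporal contagion probabilities

The analysis treats gambling abstinence as a behaviour that may spread
along a directed comment network. The outcome per user is binary —
whether a relapse-reset day counter ever crossed 1095 days (three years
of continuous abstinence) — together with the calendar date the
three-year mark was reached.

Two families of conditional probabilities are estimated, at social
distances k = 1, 2, 3.

**Peers mode.** At distance 1 the denominator is every directed pair
(sender → recipient, connected by at least one comment) whose sender is
abstinent; the numerator adds the requirement that the recipient is
abstinent and achieved abstinence strictly later than the sender. Ties
in achievement dates are non-contagious ("earlier" is strict). At
distances 2 and 3, chains A→B→C(→D) are counted only when every prefix
link is itself contagious, which enforces the full temporal ordering
t0 < t1 < t2 (< t3) along the chain.

**Comments mode.** At distance 1 the denominator is every directed pair
with at least one comment, regardless of the sender's outcome; a pair
is contagious when the recipient is abstinent and the achievement date
falls after the sender's third year of forum attendance (first-post
date + 1095 days). This temporal clause admits a second reading —
abstinence achieved *within* the sender's three-year window — which is
implemented behind `reading="within"`; the default is `"after"`.
Repeated comments between one pair count once in the probability; their
multiplicity is exported separately (`pair_multiplicities`).

**Social distance** is shortest-path length in the simple undirected
projection of the comment multigraph. Distance 2 therefore certifies
that the endpoints have no direct comment in either direction, and
chains are simple (no repeated users) with the endpoint's shortest
distance required to equal chain length − 1 — a directly linked pair
can never collect distance-2 credit. Whether the original analysis used
the directed or undirected graph is not determinable; the undirected
projection is the package's choice and is applied consistently in both
the implementation and its enumeration oracle.

## The null model

Observed probabilities are compared with an attribute-randomisation
null that holds the network *structure* fixed — edge multiset, hence
every user's peer set and degree — while permuting, without
replacement: (a) the outcome record, with abstinent flag and
achievement date moving as one unit; (b) the first-participation date,
permuted independently; (c) per-edge comment attributes (timestamp and
category). Permutation rather than independent resampling preserves
every marginal attribute distribution exactly. Each of 1000 replicates
(default) recomputes the statistic; the 95% interval is the normal one,
mean ± 1.96 sd, with a percentile interval exported alongside for
robustness. Replicate r draws its random generator from a
counter-keyed substream of the master seed, so results are independent
of execution order. Per-category tests run the comments-mode statistic
on each category-restricted subgraph against that subgraph's own null.

Calibration is checked empirically: on a 60-user synthetic network,
when the "observed" records are themselves one draw of the permutation
scheme, the observed statistic falls inside the normal interval in
94–95% of 200 meta-replicates (binomial test against 0.95 passes at
α = 0.01). The fixture size matters: the statistic is a ratio of small
counts, and very small networks make it too discrete for the normal
interval to hold its level.

## The synthetic forum generator

The generator emulates the data-generating structure the analysis
assumes, at the scale of the motivating setting: ~1089 users over a
138-month span, a ~15% abstinent minority, two-sentence comment units,
username mentions, and six comment categories with a composition
matching observed received-comment proportions (change 0.045, sustain
0.005, general 0.365, acceptive 0.16, neutral 0.395, rejective 0.03).

- **Posting.** Users join at staggered months; posts arrive as a
  homogeneous per-user Poisson process (default 0.75 posts per
  user-month); each post holds a geometric number of two-sentence units
  (mean 2). Every user posts at least once. Timestamps are strictly
  increasing per user.
- **Mentions.** Each unit names another user with probability 0.7,
  drawn from a symmetric friendship graph (mean degree 4) with
  probability 0.95, otherwise uniformly. Friendships are few and sticky
  by design: a *close peer* requires k = 3 reciprocal comment
  exchanges, and with diffuse mentioning that threshold is rarely
  reached inside the 36-month trial window, which would leave the
  planted contagion channel inert.
- **Abstinence.** Per user and month, a Bernoulli trial on the log-odds
  scale: logit(base hazard) + peer_effect × (distinct close abstinent
  peers so far) + rejective_effect × (rejective comments received so
  far). Trials run only during the user's own first 36 months of
  participation, so the outcome does not depend on the join date —
  without this, early joiners would be both more often abstinent (more
  trial months) and poorer in peers (sparser young forum), inducing
  spurious association even with all effects off. A successful trial
  fixes the last-gamble date; the achievement date follows 1095 days
  later, and only runs whose achievement fits inside the corpus span can
  succeed. The default base hazard 0.0043 was calibrated once, at the
  default configuration, to an abstinent fraction of 0.148 (observed
  0.150 ± 0.013 across seeds).
- **Ground truth** records every user's latent log-odds trajectory and
  the (influencer, influencee) pairs for which the per-trial
  counterfactual (same uniform draw, peer term removed) flips the
  outcome. Counterfactuals are first-order: cascade effects of an
  earlier flip on third parties are not traced.

What the generator does *not* emulate: Japanese-language text (units
are templated English sentences with explicit delimiters), forum
rollover at post caps, calendar effects (weekday/holiday seasonality),
per-user popularity heterogeneity, and category assignment that depends
on the relationship. Passing tests therefore show that the pipeline
recovers structure *of this kind* — planted, homogeneous-rate,
window-limited contagion — not that it would detect any real-world
effect size.

**Strong-effect scenarios.** Recovery tests use an explicitly
contagion-dominated regime (150 users, 84 months, 1.0 posts per
user-month, peer_effect 3.0 with base hazard 0.0015; for the rejective
channel rejective_effect −1.0 with a raised rejective share 0.15 and
base hazard 0.01). These values were fixed from pilot simulations as
the definition of a "strong" planted effect; they are study conditions
of the tests, not defaults.

## Features and comparisons

Each user's observation window is half-open, [first post, first post +
1095 days), cut into 36 equal bins of 1095/36 ≈ 30.42 days so that
month 36 coincides exactly with the window. Four cumulative series are
built per user: distinct commenting peers; distinct *senior abstinent*
peers (senders whose achievement date strictly precedes the comment's
timestamp); received comments; received rejective comments. Monthly
counts are cumulative, consistent with monotone observed trajectories;
the 144-point vector used by the KNN is the feature-major concatenation
of the four 36-month series. Group comparisons report per-group means
and standard errors, Welch's t by default (pooled by flag), and Cohen's
d with the pooled-SD formula.

## Predictors

**PLS1.** Predictors are standardized (sd ddof = 1); the fit is NIPALS
PLS1; the component count is chosen to maximise mean out-of-fold AUC
over a seeded, stratified tenfold split (components 1–40, ties toward
fewer; folds reduced with a warning when the minority class is too
small). Reported per predictor: standardized β, adjusted odds ratio
exp(β), normal 95% interval, t = β/SE and p. Standard errors use the
Moore–Penrose pseudo-inverse of the predictor cross-product with
σ² = RSS/(n − c − 1): the PLS solution lives in a c-dimensional score
space, so these are approximations by construction and are documented
as such. AUC is the rank-based (midrank) form, identical to
Mann–Whitney U scaled by n₁n₀.

**KNN + LIME.** A K-nearest-neighbour classifier (default k = 5,
Euclidean, on the standardized 144-vector) is explained by a local
surrogate: per reference user, binary masks (each entry independently
kept or reverted to the training mean) generate perturbed inputs; the
KNN's predicted abstinence probability is regressed on the perturbed
*values* with a ridge surrogate (α = 1), weighted by an exponential
kernel on Euclidean distance (width 0.75·√144). Regressing on values
rather than masks is deliberate: mask coefficients flip sign with the
sign of the reference's feature value and cancel when averaged, whereas
value coefficients carry the feature's own orientation (positive =
larger value predicts abstinence) and aggregate coherently across
references. The attribution noise floor of an uninformative fit is
systematic KNN-surface roughness, so planted signals are judged against
that floor (observed ≈ 10× in tests), not against a zero baseline.
The scheme — 1000 perturbations by default, all users as references,
mean-masking, exponential kernel — is fully specified here because
"LIME for time series" admits many variants.

## Power analysis

Two-sided two-sample t tests with noncentrality d·√(n₁n₂/(n₁+n₂)) and
df = n₁+n₂−2, evaluated with the noncentral t distribution (normal
approximation available via `approx=True`). The minimal total sample
size at an allocation ratio r scans the larger group size n₂ upward
with n₁ = round(r·n₂) (floor 2) and returns the first total reaching
the target power; this rounding convention reproduces standard power
software. At d = 0.5, α = 0.05, power 0.95, r = 0.16 it gives
n₂ = 379, n₁ = 61, total 440; at the unbalanced sizes 161/928 the
minimum detectable effect with power ≥ 0.95 is d = 0.31
(power 0.9523).

## Numerical conventions and degenerate inputs

- Probabilities with zero denominators are reported as 0 with a
  `degenerate` flag; a null run where more than half the replicates are
  degenerate attaches a warning.
- Identical two-group samples return t = 0, d = 0, p = 1 exactly;
  groups with fewer than two observations suppress test statistics but
  keep descriptive means.
- Empty posts are skipped with a warning; comment edges whose endpoints
  lack records are dropped (or raise in strict mode).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; identical configurations
  are byte-identical on disk.
- Test problem sizes (≤ 8-node enumeration networks, 60–150-user
  corpora, 100–200 null replicates) are the package's chosen trade-off
  between statistical resolution and a test suite that runs in minutes;
  the estimators themselves have no size limits beyond memory.

## Known limitations

- Mention extraction is whole-token after NFKC normalisation; the
  original matching rule for real scraped text (substring vs token) is
  unknowable, and usernames embedded in compounds are missed by design.
- The comments-mode temporal clause is an interpretation of an
  ambiguous rule; both readings are implemented, and results at
  distance 1 can differ materially between them.
- Normal 95% intervals for the null are assumed, not derived; for very
  sparse categories the percentile interval is the safer summary.
- PLS standard errors (and hence stars on odds ratios) are
  pseudo-inverse approximations.
- The generator's counterfactual influence pairs are first-order only.
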