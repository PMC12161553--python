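# Methods

This note documents the modelling choices behind `hopforecast`: what each
stage computes, the parameters that matter, what the synthetic data does and
does not emulate, and the judgement calls made where the method leaves room.

## Indicator scoring

Each session log is scored on seven ordinal indicators.  Quotas ("6
moderate-intensity and 3 high-intensity bouts") are read as minimum counts:
exceeding a quota can never lower a score.  The speed cut-off, the
psychological stress test and the basic-skill standard are pass/fail
judgements made upstream by whoever fills in the log — the package does not
define physiological standards.  Recovery training is the one indicator
without a 0 level: recovery strictly slower than the group average earns 5
points, anything else (including exactly average) earns 10.  All level sets
are enforced at every boundary of the package (generation, file I/O,
encoding), so an out-of-range score is always a loud error naming the row
and column.

## Markov thresholds

From a V×K training score matrix S (V sessions, K = 7 indicators) the
one-step transition matrix is a row-normalised similarity matrix.  Two
constructions are available:

- `indicator_space` (default): always row-normalise the K×K Gram matrix
  SᵀS.  The chain's states are indicators, m = K = 7 matches the 7-neuron
  network, and the construction is linear in V.
- `shape`: dispatch on the shape of S — row-normalise S itself when square,
  SᵀS when K > V, and the V×V matrix SSᵀ when K < V (in which case m = V).

The shape-dispatching variant makes the neuron count equal the *number of
training rows* whenever rows outnumber indicators, which contradicts a
fixed 7-neuron network consuming 7-dimensional patterns; it is kept for
fidelity and for small matrices, but the default works in indicator space.
Both are exposed and tested; neither is silently altered.

The m-step matrix is the m-th matrix power of P(1) (Chapman–Kolmogorov).
The product form in which the construction is sometimes written reduces to
exactly this power, which is the only standard reading; users should be
aware it is an interpretive choice.  Rows are renormalised after powering
to absorb floating-point drift; stochasticity is asserted at 1e-9 absolute
per row.  A row that sums to zero before normalisation (possible when an
indicator column is all zero) carries no transition information and is
replaced by the uniform distribution.  The threshold of neuron i is the
maximum entry of row i of P(m); for a row-stochastic matrix it lies in
[1/m, 1], so every threshold is a valid activation probability.  In
practice a strictly positive 7×7 chain is close to stationary after 7
steps, so the seven thresholds come out nearly equal.

## Hopfield dynamics

States are bipolar with sgn(0) = +1.  The printed form of the net input
places the threshold inside the sum over neurons, which would scale it by
the network size; the implementation subtracts it once,
net_j = Σ_i w_ij x_i − λT_j, the standard form in which a threshold is
comparable to the O(1) Hebbian net input.  Likewise "w_ij = 0" is read as a
zero diagonal (no self-coupling) — zero for all pairs would make the
dynamics vacuous.  Updates are asynchronous in ascending index order by
default (a seeded per-sweep shuffle is available); asynchronous updates of
a symmetric zero-diagonal network never increase the energy, giving finite
convergence, and the test suite asserts descent along every recorded trace
and cross-checks fixed points against exhaustive enumeration for n ≤ 4.

λ (`threshold_scale`, default 1) bridges the probability-scale thresholds
(≤ 1) and the Hebbian weights; λ = 0 recovers the classic zero-threshold
network used in the unit tests of pattern recall.  "Activated with
probability T_i" is implemented, in stochastic mode, as accepting the
computed update of neuron i with probability T_i per visit, with a seeded
generator; per-sweep participation and sigmoidal firing laws are plausible
alternative readings that are not implemented.  Convergence is declared
when a full sweep flips nothing; in stochastic mode a flipless sweep can
also reflect rejected updates, so `j_max` (default 1000) always bounds the
run.

## Classifier construction

A Hopfield network is an associative memory, not a classifier.  The bridge
used here is the minimal standard one: encode each row as a 7-bit bipolar
pattern (score ≥ 5 → +1, i.e. at least partial completion), store one
prototype per class — the elementwise sign of the class's mean encoded
pattern, ties to +1 — with the Hebbian outer-product rule, and classify a
row by the class of the prototype nearest (Hamming) to the attractor
reached from its encoding, ties toward the first class label.  The
continuous analogue used by the importance analysis is the signed Hamming
margin between the two prototype distances, scaled by the neuron count.

Note the consequences: with two stored prototypes the reachable attractors
are essentially the prototypes and their negations, so prediction behaves
like a (dynamics-smoothed) nearest-prototype vote over the encoded bits.
Bits on which both prototypes agree cancel; the recovery indicator, whose
two levels both encode +1, never votes.

The 60/20/20 split shuffles rows with a seeded generator and sizes the
parts by largest-remainder rounding, which reproduces 1440/480/480 on the
default 2400-row table exactly.  The test split is evaluated and reported;
nothing is tuned on it.  Metrics with zero denominators are reported as 0
and flagged.  G-score is taken as the geometric mean of precision and
recall, the standard reading of that name alongside F1.  The binary target
for unlabelled tables is total score ≥ cutoff (default 40 of the 0–70
range).

## Synthetic squad generator

The generator emulates the study design — 20 athletes × 30 days × 4
sessions/day, 2400 rows × 7 ordinal columns — with a two-level latent
structure:

- athlete ability a ~ N(0, ability_sd²), persistent across the month
  (default ability_sd = 1.0);
- session readiness η ~ N(0, session_sd²), shared by all indicators of one
  session — the athlete's good or bad day (default session_sd = 1.5);
- unit-variance indicator-specific noise.

The latent value a + η + e is cut at fixed population quantiles into the
indicator's levels: three-level indicators score 0/5/10 with frequencies
45/10/45 % (full or no completion dominate; partial completion is the rare
middle ground), two-level indicators split at the median.  Every allowed
level keeps probability ≥ 0.05.  The session readiness factor is what makes
the seven scores of one row strongly inter-correlated, as scores produced
by one athlete on one day would be; a purely athlete-level factor cannot do
this without quantising the label on the 20 ability draws, and day-to-day
readiness swings are a well-documented feature of training data.

The continuous outcome is Σ_k weight_k · score_k + N(0, noise_sd²) and the
binary label splits outcomes at the within-dataset median (so classes are
balanced by construction).  Default weights are (1, 1, 0.5, 0.5, 0.5, 0.5,
1): concentrated on strength, speed and basic skill at twice the weight of
the rest, which reproduces the strong/moderate/weak correlation profile the
importance analysis is meant to recover while keeping every indicator
genuinely informative.  Default outcome noise is noise_sd = 2.0 on the 0–70
total-score scale; the "high-signal" regime used in the forecastability
tests lowers it to 0.5.

What the generator does *not* emulate: within-athlete temporal dynamics
(fatigue accumulation, periodisation), missing sessions, scorer
disagreement, or multi-sport heterogeneity.  Passing tests therefore show
that the pipeline recovers structure of this latent-factor form, not that
real squad data has that form.

## Importance analysis

Each indicator column is correlated (Pearson) with a forecast outcome —
by default the fitted model's continuous decision margin, optionally the
binary prediction — and indicators are ranked by |r|.  Pearson correlation
on a near-binary pair is legal but coarse, which is why the margin is the
default target.  The seven correlation values are then grouped by k-means
with k = 3 (strong / moderate / weak), run as 1-D k-means with 20 seeded
restarts; for ≤ 8 points in one dimension the optimal partition is
contiguous in sorted order, and the tests verify the returned partition
against an exhaustive search over contiguous 3-partitions.  Clusters are
relabelled in descending centroid order so cluster 0 is always the
strongest group.  A constant indicator column yields a NaN correlation and
ranks last rather than raising, since a degenerate column is an empirical
fact of the sample.

## Problem sizes and determinism

All simulation-backed tests run at the study's native scale (2400 rows,
7 neurons) or below; the full suite completes in a few seconds on one CPU.
Every source of randomness — the generator, the split, shuffled update
order, stochastic acceptance, k-means restarts — flows from explicit seeds,
and fixed-seed runs are bit-reproducible, which the tests assert.

## Known limitations

- Two-class design: prototypes, margins and metrics assume a binary target.
- With 7 neurons and 2 stored prototypes the network is far below Hopfield
  capacity, which is the intended regime; storing many classes would
  degrade recall.
- The indicator-space Markov construction yields nearly equal thresholds on
  realistic score matrices, so the thresholds act mostly as a uniform bias
  rather than per-neuron structure.
- The equal-weight Hamming vote cannot express unequal indicator
  importance; datasets whose labels depend very unevenly on the indicators
  will be classified below the information-theoretic ceiling of the
  encoded bits.
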