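# Methods

## The model

`cogtrace` treats longitudinal cognitive diagnosis as a hidden Markov
process observed through a neural classifier.

**States.** For K skills there are 2^K mastery patterns α ∈ {0,1}^K. The
canonical integer encoding takes the first listed attribute as the most
significant bit (000, 001, …, 111). A student's state at wave t is their
pattern; the hidden process is a first-order Markov chain over patterns.
Per-attribute states are the chain's bit-wise marginals.

**Measurement model (SSOM).** The observation layer is a supervised
self-organizing map. The input layer has one node per item; the competition
layer is a rectangular grid of m neurons with input weights W_in (J × m);
the output layer has one node per pattern class with weights W_out
(m × 2^K). A response vector x activates the neuron g minimizing the
Euclidean distance ‖x − W_in[:, g]‖ (on binary inputs this is monotone in
Hamming distance, which is why Euclidean is used); the predicted class is
argmax_k W_out[g, k], ties to the lowest class index.

Training presents every row of the training set once per pass, in a seeded
shuffle. For winner g at presentation step t, all neurons within Chebyshev
radius r(t) of g on the grid are updated on both layers:

    W_in  ← W_in  + f · η1(t) (x − W_in)
    W_out ← W_out + f · η2(t) (y − W_out)

with y the one-hot of the true class and f = 1 when the winner's current
predicted class equals the true class, f = μ otherwise.

The training set consists of *ideal responses*: the deterministic DINA
response η_j(α) = ∏_k α_k^{q_jk} of each pattern, labeled by the pattern.
No item parameters are needed — this is what makes the workflow
nonparametric. Pattern frequencies in the training set follow either a
uniform enumeration or the population's pattern distribution (see
"Training-set policy").

**Transition model.** Classified chains feed maximum-likelihood counts:
π is the wave-1 class frequency; each transition row is the normalized
count of moves out of that state. Rows never observed are reported as NaN
rather than an invented distribution, so sparse 64 × 64 pattern tables show
their gaps honestly. Optional additive smoothing (default 0) is available
for sparse pattern matrices. No Baum–Welch or Viterbi machinery is used:
the two-step procedure classifies first and counts second, and the
observation model is never re-estimated.

**Accuracy criteria.** ACCR is the per-attribute agreement rate between
true and estimated mastery bits; PCCR requires the whole pattern to match,
so PCCR ≤ min_k ACCR_k identically. Transition recovery is scored two ways,
because "the estimated transitions are correct" admits two readings:

- *pairwise*: the fraction of examinees whose estimated ordered pair
  (pattern_t, pattern_{t+1}) equals the true pair. This is the stricter,
  individual-level reading; it is bounded above by per-wave PCCR.
- *matrix*: 1 − mean |A_est − A_true| over rows occupied in both chains,
  where A_true is estimated from the true chains of the same examinees.
  This compares the transfer probabilities themselves and is the quantity a
  reporting table of transition matrices supports. With many states and
  concentrated occupancy it runs high even when individual classification
  is poor — both numbers are always reported side by side so the user can
  match either reading.

## Assumptions

- Conjunctive (DINA) response process: an item is answerable only when all
  required attributes are mastered, up to slip/guess noise.
- Responses at each wave are conditionally independent given that wave's
  profile (no item memory between waves).
- Attributes evolve independently given the current state, each through its
  own 2 × 2 row-stochastic matrix per wave interval.
- Examinee rows are aligned across waves (enforced on IDs at model
  construction).

## The synthetic-data generator

`simulate_longitudinal` emulates a multi-wave administration of a fixed
form:

- **Wave-1 profiles** come from an exchangeable Gaussian copula: latent
  Z_k = √ρ·F + √(1−ρ)·E_k, attribute k mastered iff Z_k exceeds the
  (1 − p_k) normal quantile. Marginal mastery rates are exactly p_k and all
  latent pairs correlate at ρ. The built-in study designs use
  p = (0.4, 0.4, 0.2) for K=3, p = (0.4, 0.4, 0.3, 0.3, 0.2, 0.2) for K=6,
  and ρ = 0.5. `pattern_distribution` integrates the shared factor out by
  Gauss–Hermite quadrature (64 nodes) to give the exact implied pattern
  probabilities; it doubles as the oracle for the wave-1 estimates.
- **Transitions** follow the built-in per-attribute matrices (two intervals,
  three waves). One deliberate property of the K=3 design is that the third
  attribute is frequently *lost* between waves.
- **Responses** are cell-wise Bernoulli draws from the DINA kernel, with
  slip/guess either fixed to the built-in 20-item table or drawn uniformly
  from the regime's range — U(0, 0.2) for high discrimination, U(0, 0.4)
  for mixed. 40-item forms stack the 20-item Q matrix twice (the reference
  design defines no 40-item Q matrix; stacking preserves the
  attribute-coverage profile) and always redraw slip/guess.

All randomness flows from one root seed through named `numpy` SeedSequence
substreams (profiles / transitions / responses / training draw / network
init), so any wave or replication is independently reproducible and equal
seeds give bit-identical output.

What the generator does **not** emulate: polytomous items or attributes,
covariate- or ability-driven transitions, item-position or practice
effects, local item dependence, and any non-DINA response process. Passing
simulation tests therefore shows the pipeline recovers DINA-generated
growth, not that real classroom data satisfy these assumptions.

## Tunable parameters

| Parameter | Default | Notes |
| --- | --- | --- |
| grid_shape | 10×10 (K=3), 20×20 (K=6), 9×9 empirical | ≈4–10 neurons per pattern class |
| iterations | 2 (K=3), 4 (K=6) | passes over the training set; `select_iterations` finds the plateau empirically |
| η1, η2 | linear 0.5 → 0.01 | per-layer learning rates over all presentation steps |
| μ | +0.5 | mismatch damping; see below |
| radius | max(grid)/2 → 0 over the first half of steps | Chebyshev neighborhood; zero thereafter |
| training policy | population (simulation), uniform (empirical) | pattern weights of the ideal-response training set |
| train_size | examinee count | rows in the training set |
| correlation ρ | 0.5 | copula latent correlation |
| replications | 30 design default, 10 in acceptance runs | acceptance uses 10 with standard errors for desk-scale runtime |

## Numerical choices

**Sign of μ.** With a *learned* output layer, an LVQ2-style repulsive
mismatch update (μ < 0) never converges from random initialization: early
predictions are random, so a fraction (1 − 2^−K) of all updates repel, the
map cannot order, and training accuracy stalls near chance even on
perfectly separable data. With μ ∈ (0, 1) mismatched samples still organize
the map but reinforce their class more weakly than confirmed ones; training
then reaches 100% on separable ideal-response sets and the ceiling imposed
by Q-matrix collisions otherwise. μ is configurable, including negative
values, but +0.5 is the default for this reason.

**Radius schedule.** The neighborhood must vanish well before training
ends. Because every training row of a pattern is the *same* ideal vector,
prototypes converge exactly onto the ideal vectors only during the
zero-radius phase; a radius that stays positive until the last step leaves
prototypes smeared toward neighboring clusters and costs several PCCR
points against the nearest-prototype oracle. The default decays linearly to
zero over the first half of the presentation steps (ordering phase) and
stays at zero for the second half (fine tuning).

**Dead neurons and ties.** Test-time competition is restricted to neurons
that won at least one training sample in the final pass; the others retain
essentially random prototypes and labels and would otherwise capture noisy
responses. Squared-distance ties (slack 0.25 — distinct binary profiles
differ by at least 1.0) resolve toward the neuron with the larger receptive
field, i.e. more training wins. Ties are not rare: with 20 binary items a
third or more of noisy responses are exactly equidistant between two ideal
vectors, and resolving them toward the a-priori more frequent pattern is
worth ~8 PCCR points, bringing the classifier to within one point of the
Bayes rate under the generating model. Both choices are properties of
`classify`; `find_winner` itself always scans the full map.

**Q-matrix completeness.** Completeness is checked by brute-force
enumeration of all 2^K ideal responses; colliding pattern groups are
reported as a warning, never an error, because the built-in K=3 design is
itself incomplete (no item isolates the third attribute, so 000 and 001
are indistinguishable — an intrinsic PCCR ceiling, not an implementation
artifact). The K=6 design has six collision groups covering 28 of 64
patterns, capping pattern identifiability near 0.74 under the study's
population weights; its much lower PCCR is again structural.

**Training-set policy.** Population-weighted training (patterns drawn from
the copula-implied distribution) labels each collision group's shared
prototype with the group's majority pattern and matches the deployment
distribution, so it is the simulation default. Uniform enumeration is the
empirical default, where the population distribution is unknown. With
uniform weights and a size divisible by 2^K the patterns are enumerated
exactly, not sampled.

**Degenerate inputs.** Zero-noise items (s = g = 0) reproduce ideal
responses exactly and propagate to perfect ACCR/PCCR/transition recovery;
s = g = 0.5 reduces every cell to Bernoulli(0.5) regardless of profile.
Identity transitions leave profiles fixed. Empty assignment vectors, ragged
or non-binary matrices, non-stochastic rows and out-of-range probabilities
raise validation errors naming the offending row where applicable.

## Known limitations

- The forward (Chapman–Kolmogorov) mastery trajectory implied by the
  built-in K=3 transition matrices gives A1 mastery 0.658 at wave 2; the
  built-in design's companion summary of mastery growth rounds differently
  (0.63) and cannot be reproduced exactly from the transition matrices. The
  transition matrices are treated as the generator of record.
- Wave-1 PCCR for the K=6/20-item design tops out near 0.47 under the
  population pattern distribution: the Bayes-optimal classifier given the
  true kernel and prior reaches only 0.57 there, so most of the shortfall
  is information-theoretic, not algorithmic.
- The per-examinee pairwise transition rate is necessarily below per-wave
  PCCR; users comparing against matrix-style transition tables should use
  the matrix agreement score.
- No polytomous support, no DINO/compensatory kernels, no covariates, no
  higher-order latent structure, and no Q-matrix estimation beyond the
  structural completeness check.
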