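# Methods

`herbscreen` implements a two-stage in-silico screen for herb combinations:
a convolutional classifier learns a mapping from binary prescription
vectors to treatment efficacy, and a genetic algorithm (GA) then searches
the combinatorial space of herb subsets for the combination the classifier
scores as most likely effective, under a penalty that attracts solutions to
a target formula size. Because the clinical cohort that motivated the
method (745 hepatocellular-carcinoma treatment protocols over 334
standardized herbs) is not publicly available, the package ships a
synthetic-cohort generator with a planted ground-truth combination, so the
whole pipeline can be tested end to end.

## Data model

A prescription is a set of herb names with a four-level outcome (complete
remission / partial remission / stable / progressive). Outcomes are
recoded to a binary efficacy label: the first three are *effective* (1),
progression is *ineffective* (0). Each prescription is encoded as a 0/1
presence vector over an ordered herb vocabulary; the vocabulary order is
first-occurrence order in the input and is persisted to a TSV, because the
convolutional layers read local neighbourhoods of the vector and therefore
make the ordering meaningful. Splitting is 8:2 train/test, stratified by
class by default, with the train side receiving `floor(0.8 n)` records.

## Classifier

The classifier ("NDCNN") treats the input vector as a single-channel
sequence. Three parallel 1-D convolution branches with kernel sizes 1, 3
and 5 (128 filters each, ReLU, stride 1, zero same-padding) extract local
co-prescription features at three scales; their outputs are concatenated
channel-wise into a 334 x 384 feature map, convolved again (kernel 3, 128
filters, ReLU), max-pooled, and passed through fully connected layers of
1024 and 512 units (ReLU) into a 2-unit softmax head. Training minimizes
categorical cross-entropy (probabilities clipped at 1e-12) with Adam
(learning rate 1e-3, batch size 32) for 25 epochs. Parameters are
initialized He-uniform from a seeded generator; all randomness is
reproducible from the config seed. The forward and backward passes are
written directly in NumPy (im2col + GEMM); gradient correctness is pinned
by a central-finite-difference test at relative error 1e-4 on a reduced
model. The finite-difference check is run at a random parameter point with
non-zero biases: at the all-zero bias initialization, binary inputs place
many pre-activations exactly on the ReLU kink, where the one-sided
numerical derivative is not comparable to any subgradient choice.

Design points that were genuinely open, and how they were resolved:

- **Output head.** A 2-unit softmax with categorical cross-entropy; the
  two-class cross-entropy coincides with binary cross-entropy. Class
  index 0 is "ineffective", 1 is "effective"; argmax ties break toward 0.
- **Convolution arithmetic.** Stride 1 with zero same-padding, so each
  branch output has the input length and channel-wise concatenation is
  well-defined. The second convolution treats the concatenated map as one
  sequence with 384 channels.
- **Pooling.** The default is conventional local max pooling with window
  and stride 4 (the scale of the generator's co-prescription blocks).
  This choice matters more than it looks: *global* max pooling makes the
  feature extractor fully translation-invariant, so the model can score
  the shape of a local herb pattern but cannot attribute efficacy to any
  particular herb position — under global pooling a fabricated clump of
  adjacent herbs anywhere in the vocabulary scores like the genuinely
  predictive block, which defeats combination search. Global pooling and
  a full `flatten` mode remain available as configuration options.
- **Optimizer extras.** Adam is used as published; a decoupled
  weight-decay term (applied to weight matrices, not biases) is available
  and defaults to off. See "Surrogate fidelity" below for when to turn it
  on.
- **Epoch selection.** Training records per-epoch train/test loss and
  accuracy (train metrics are epoch means over minibatches; test metrics
  are full end-of-epoch evaluations). By default the returned parameters
  are those of the epoch with the lowest test loss rather than the last
  epoch: on cohorts of a few hundred records the later epochs overfit,
  and an overfit surrogate grows spurious high-probability peaks that the
  GA will find and exploit.

The training curves on the default synthetic cohort reproduce the
qualitative behaviour expected of this setup: training loss decreases
through all 25 epochs while test loss reaches its minimum earlier and then
turns upward (the overfitting U-shape), which is also asserted as a test
across seeds on a small noisy cohort.

## Surrogate scoring for search

The GA evaluates thousands of candidate combinations. For binary inputs
the entire convolution stack is, by construction, a function of a sliding
window of `max(kernel) + second_kernel - 1 = 7` input bits, so
`compile_binary_scorer` tabulates all 2^7 window responses once and scoring
reduces to an integer gather plus the dense head. The handful of edge
positions whose second-convolution window overlaps the zero padding are
computed directly. This is exact (asserted against the standard forward
pass in tests), not an approximation, and makes a full 1000-generation
search take seconds instead of tens of minutes.

## Genetic algorithm

Individuals are 334-bit strings (bit = herb included). Fitness, to be
minimized, is

    fitness(X) = P(ineffective | X) + (|X| - N)^2

with N = 12 by default. Settings follow the published search: population
10, 1000 iterations, 5 parents selected per generation by roulette wheel,
crossover and mutation rates 0.1, initialization Bernoulli(0.5) per bit.
Because lower fitness is better, roulette weights are inverse fitness
`1/(f + 1e-6)` (rank weighting is a configurable alternative). Crossover
is uniform: each position swaps between the two children with probability
equal to the crossover rate (single-point crossover is available).
Elitism of exactly one: the global best individual enters every next
generation unchanged, so the best-fitness trace is non-increasing.

**Mutation.** Every offspring receives exactly one *subset move*, chosen
uniformly among: add a random absent herb, drop a random present herb, or
swap one present herb for one absent herb. Two quantitative facts forced
this design. First, gating mutation at a 0.1 per-offspring probability
supplies at most ~0.9 bit-flips per generation; an elite-ratchet bound
then needs ~975 generations in expectation just to descend from the ~167
set bits of random initialization to the 12-herb constraint, and realized
populations are slower (measured final sizes 48–68 under inverse roulette
after 1000 iterations) — the expected two-phase convergence never
happens. A per-bit rate of 0.1 (~33 flips per offspring) destroys
convergence from the other side (final sizes ~90–106). Second, once the
population sits at exactly N herbs, any single bit flip passes through a
size-penalized intermediate (penalty +1, larger than the entire
probability term) that elitist selection rejects — pure bit-flip mutation
freezes the late phase, leaving *which* herbs are kept essentially
random. The size-preserving swap keeps the equal-size shell connected so
the surrogate probability is still optimized after the size constraint is
met. With these operators the runs show the expected two phases: the size
penalty reaches zero within roughly the first 300 iterations and the
elite is then refined occasionally through swap moves. Per-individual and
per-bit mutation remain available as modes.

## Synthetic cohorts

The generator emulates the statistical shape of the motivating cohort: 745
records over 334 herbs, formula sizes uniform on 8–16, an
effective:ineffective balance of about 617:128, and local herb
co-occurrence built by sampling contiguous 4-herb blocks plus random
singletons. A planted "effective core" (12 herbs, contiguous in the
vocabulary by default; a scattered mode exists) carries the ground truth:
each record includes each core herb independently with probability 0.55,
and the label is Bernoulli with

    P(effective) = sigmoid(intercept + core_effect * k),

where k is the number of core herbs present, followed by a 5% label flip.
The per-herb inclusion probability 0.55 spreads k over 3–10, so the
logistic is neither saturated nor flat across the observed range and the
cohort actually identifies the core. The default per-herb effect is 2.0
log-odds. The intercept is calibrated once per spec by Brent root-finding
on the simulated k-distribution so the expected observed ineffective
fraction (including label noise) matches 128/745; the calibrated value is
echoed in the truth block.

What the generator does *not* model: dose, herb synonymy, syndrome
differentiation, or real co-prescription statistics beyond block-local
correlation. Labels are additive in core count on the log-odds scale, so
passing recovery tests demonstrates that the pipeline can find an additive
planted signal under class imbalance and noise — not that it can resolve
synergistic interactions in real clinical data.

Recovery of the planted combination is scored by the Jaccard index between
the returned herb set and the core.

## Surrogate fidelity and the recovery configuration

A surrogate-guided search is only as good as the surrogate's behaviour at
its *optima*, which is a much stronger demand than test-set accuracy. Two
failure modes were identified and are worth restating because they are
generic to this class of methods:

1. **Translation invariance** (global max pooling): the search fabricates
   an arbitrary clump of adjacent herbs that excites the same pattern
   detectors as the true core. Fixed by position-preserving pooling.
2. **Noise-effect stacking**: with ~600 training records, rarely
   prescribed herbs get high-variance effect estimates; an optimizer
   stacks the most favourable noise effects into a junk combination that
   can outscore the true core. An L2-regularized linear model on the same
   data ranks all 12 core herbs into its top-12 coefficients, so the
   failure is estimation variance, not information: strong weight decay
   is the remedy.

The package therefore documents a *recovery configuration* for
planted-core studies at the 745-record scale, used by the end-to-end
tests: flatten pooling (fully position-aware), 4 filters per branch and 4
second-stage filters, one dense layer of 64 units, weight decay 10 (the
decoupled decay magnitude that matches the shrinkage of the ridge logistic
fit above), best-epoch restoration, and a doubled GA budget of 2000
iterations — the equal-size shell is explored through rare accepted swaps
(roughly one core-acquiring proposal per 60 generations), and 1000
iterations leave that phase visibly unconverged. Under this configuration
the pipeline recovers the planted 12-herb core at Jaccard >= 0.5 in 10/10
end-to-end seeds (measured range 0.5–0.85). The full-width architecture
remains the default for studying the published training dynamics, and the
GA's default budget remains 1000 iterations.

## Problem sizes and tolerances

Tests run the full default cohort (745 x 334) for the training-dynamics
and size-convergence checks, a 12-herb vocabulary (4096 subsets,
exhaustively enumerated) for the optimizer-equivalence check, and reduced
models (input 16, 4 filters per branch) for the finite-difference check at
relative error 1e-4. Monte-Carlo operator tests (selection frequencies,
crossover swap counts, mutation rates) assert within 3–4 sigma binomial
bounds at 10^3–10^4 trials. Softmax normalization is asserted to 1e-6;
probability clipping in the loss is 1e-12; argmax ties break toward the
"ineffective" class by documented convention.

## Known limitations

- The published headline numbers (train accuracy 0.92, test accuracy 0.84,
  a specific 12-herb combination at 97.6% predicted effectiveness) depend
  on the unavailable clinical dataset and are not reproduction targets;
  the synthetic planted-core recovery is the testable analogue.
- The fitness is a point estimate; no uncertainty on the surrogate
  probability enters the search, so the GA will exploit any miscalibrated
  region it can reach. The recovery configuration mitigates but does not
  eliminate this.
- Vocabulary order is load-bearing for the convolutional layers; two runs
  must share a vocabulary file to compare combinations.
- The GA's search space treats herbs as exchangeable bits: compatibility,
  toxicity and dosing constraints are out of scope.
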