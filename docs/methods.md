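# Methods

This note records the model, the numerical and design choices behind
`mldbn`, and what the synthetic benchmark does and does not establish.

## Model

**Binary relevance.** A Q-label problem is transformed into Q independent
binary tasks; label q's classifier never sees any other label column. This
is the simplest problem-transformation approach and deliberately ignores
label correlations. Internally labels are {0, 1}; the {+1, −1} coding used
in some formulations is an exact relabelling (1 ↔ +1, 0 ↔ −1).

**RBM.** Each pair of adjacent layers is a restricted Boltzmann machine with
binary visible and hidden units, energy
E(v, h) = −b_v·v − b_h·h − vᵀWh, so both conditionals are products of
logistic units. Visible units are binary because the features are 0/1
symptom indicators; Gaussian visible units are out of scope.

**CD-k pretraining.** Weights are trained by contrastive divergence with
k = 1 Gibbs steps by default (k is a config field). Positive statistics use
(v₀, P(h|v₀)); the single sampled quantity is h₀, which drives the
reconstruction; negative statistics use the reconstruction *probabilities*
on both sides. This probabilities-where-possible convention reduces update
variance without biasing the weight gradient's direction. The update is

    velocity ← momentum·velocity + lr·(⟨vhᵀ⟩₀ − ⟨vhᵀ⟩₁)/B − lr·λ·W
    W ← W + velocity

with momentum 0.5 ("smooth") and L2 decay λ = 2·10⁻⁴ ("damping factor") —
the standard reading of those two knobs; both are config fields so the
interpretation is overridable. Decay applies to weights only, not biases.
Weight init is Gaussian(0, 0.01²), biases zero.

**Stacking and fine-tuning.** RBM ℓ is trained on the hidden-probability
representation of RBM ℓ−1 (greedy layer-wise). The stack is then unrolled
into a feed-forward network: hidden layers copy RBM weights and hidden
biases; a fresh logistic output unit (Gaussian(0, 0.01²) weights, zero bias)
is attached, so untrained outputs sit near 0.5. Fine-tuning is mini-batch
gradient descent on binary cross-entropy with the *same* hyperparameters as
pretraining (one parameter set governs the whole procedure), updating all
layers; hidden activations are mean-field probabilities, never samples, so
prediction is deterministic. Cross-entropy is the natural pairing for a
logistic output; no early stopping or validation split — iteration counts
are fixed (100 pretraining + 100 fine-tuning epochs by default; the two
counts are exposed separately).

**Default architecture.** One hidden layer of 80 units. In the width sweep
this is where performance peaks, and beyond ~30 units the measures change
little; deeper stacks are supported by `layer_sizes` but not part of the
default protocol.

## Evaluation measures

All ranking measures derive from per-instance ranks of label scores
(rank 1 = highest; ties broken by ascending label index, a documented
determinism choice — the measures are then invariant under strictly
increasing transforms of the scores).

* average precision: mean over instances (with non-empty relevant set) of
  the average over relevant labels y of
  |{y′ relevant : rank(y′) ≤ rank(y)}| / rank(y).
* coverage: mean of (max rank over relevant labels − 1), **divided by Q**.
  The conventional definition ranges 0..Q−1; the normalized 0–1 form is
  used here so values are comparable across label-set sizes (the raw value
  is available via `normalize=False`).
* ranking loss: fraction of relevant × irrelevant pairs with
  f(relevant) ≤ f(irrelevant), averaged over instances with a non-trivial
  split (ties count as mis-ordered).
* hamming loss: fraction of instance–label cells misclassified after
  thresholding (normalized symmetric difference); uses *all* instances.
* one-error: fraction of instances whose top-ranked label is irrelevant.

Instances with an empty relevant set are skipped by the four ranking
measures (ranking loss also skips full sets) and counted in `n_skipped`;
if every instance is degenerate the measure raises rather than returning an
arbitrary number. Thresholding uses 0.5 with ties mapping to 1 (score ≥
threshold), exposed in `RunConfig`.

Cross-validation reports the mean and the *population* standard deviation
of the per-fold values. Per-label "recognition accuracy" is the fraction of
held-out instances whose thresholded prediction equals the truth for that
label, in percent, computed from the BR outputs — reasonable readings of
this quantity differ (a ranking rule could be used instead); this package's
definition is fixed here and used consistently.

## Reproducibility

All randomness flows through `numpy.random.Generator` seeded via
`SeedSequence`. Per-label streams are keyed on (run seed, CRC-32 of the
label name), which makes each label's fit independent of label column order
and of which other labels are present — the harness asserts both
bit-exactly. Fold assignments and per-fold model seeds derive from the
experiment seed; folds are reused across grid points and models so every
comparison is paired.

## ML-kNN baseline

k = 10 neighbours, Euclidean distance, Laplace smoothing s = 1 (the
conventional default; nothing in the protocol pins it). Training excludes
self-neighbours; distance ties break by ascending training index so
predictions are exactly reproducible. The implementation vectorises the
all-pairs distances; the test suite holds it to exact (1e-12) agreement
with an independent pure-loop reference.

## Synthetic data generator

The generator emulates the *structure* of clinical inquiry data — which is
not publicly deposited — not any particular cohort:

* **Labels** come from a pairwise log-linear model
  P(s) ∝ exp(Σ θ_q s_q + Σ_{q<r} C_qr s_q s_r). The pairwise boosts C make
  syndromes genuinely co-occur (so the BR independence assumption is
  actually stressed); the unary terms θ are calibrated by fixed-point
  iteration (tolerance 1e-10, capped iterations, explicit
  `CalibrationError` on failure) so marginal prevalences hit their targets
  exactly. Q ≤ 10 keeps the 2^Q enumeration exact — no MCMC error.
* **Symptoms** follow noisy-OR: symptom i fires unless the background
  process (rate 0.05) and every active syndrome's factor (loading
  L[q, i]) all independently fail. This is the simplest generative reading
  of the symptom ← factor ← syndrome hierarchy; factors are merged into
  labels for generation.
* **Observation noise**: each recorded symptom flips with probability 0.02.

The default profile (`default_cg_profile`) has n = 919, p = 113, Q = 6 with
the six common chronic-gastritis syndrome names. Prevalences
(0.32, 0.28, 0.30, 0.07, 0.33, 0.22) are heterogeneous with one rare
pattern (spleen–stomach deficiency cold), matching the qualitative spread
of per-syndrome recognition rates in such cohorts; true per-syndrome
prevalences are not published, so these are declared assumptions recorded
in the JSON sidecar the generator emits. Each syndrome loads on a block of
13–18 symptoms with loadings drawn once from a fixed stream (0.3–0.6;
0.5–0.75 for the rare pattern, which is infrequent but distinctive);
the two damp-related syndromes share five symptoms and carry the largest
pairwise boost; 25 symptoms are background-only distractors. Under these
settings ~46 % of instances carry ≥ 2 labels.

**What the benchmark shows and does not show.** The profile preserves the
dimensions, binarity, label co-occurrence and hierarchical symptom
structure of inquiry data, but it is cleaner than reality: symptoms are
conditionally independent given the syndromes, noise is homogeneous, and
there are no rater effects, missing data or redundant near-duplicate items.
Its Bayes ceiling is high (≈ 0.998 average precision), so absolute metric
values exceed anything achievable on clinical data; conclusions supported
here are qualitative — that the pipeline learns, that pretraining + 
fine-tuning recovers the structure, that performance saturates with enough
hidden units, and how methods order — not absolute performance claims.

Because the generative law is explicit, `bayes_scores` computes the exact
posterior P(label | symptoms) by 2^Q enumeration (flip noise folded into
the emission probabilities). It is the ceiling in bracket tests: random
scorers floor every measure, the Bayes scorer tops them, and trained models
must land in between.

## Numerical choices

* Logistic functions use `scipy.special.expit`; free energy uses
  `logaddexp`/`logsumexp` — no overflow up to |pre-activation| ≥ 700.
* Exact RBM likelihood/gradient oracles enumerate visible states and refuse
  beyond p_vis + p_hid = 16.
* CD raises `FloatingPointError` with the epoch index if an update goes
  non-finite (exploding weights).
* Mini-batches: rows shuffled each epoch; last batch may be short; with
  n = 250 and batch 100 an epoch performs exactly 3 updates (100/100/50).
* CSV round trips are bit-exact (`float_precision="round_trip"` on read;
  repr-precision on write); model JSON likewise restores weights to full
  precision behind a format/version tag.
* Missing values are rejected, not imputed — incomplete records are assumed
  excluded upstream, as in the inquiry protocol this emulates.

## Problem sizes used in the automated checks

The acceptance script and heavy tests run the full-scale default profile
(919 × 113 × 6, hid = 80, 100 + 100 epochs — a few seconds per label on one
CPU) for learnability, and a scaled sweep ({5, 10, 20, 30, 50, 80}, 20 + 20
epochs, 5-fold CV) for the width-saturation pattern; oracle equivalence and
gradient checks use enumerable sizes (Q ≤ 5, RBMs of 3 × 2, networks up to
three hidden layers). These sizes were chosen as the smallest that exercise
each property cleanly.

## Known limitations

* BR ignores label correlations by design; the generator purposely includes
  them, so there is headroom a correlation-aware method could exploit.
* One fixed threshold (0.5) serves all labels; rare labels might warrant
  calibrated thresholds.
* CD-1 is a biased gradient estimator; the tests check directional
  agreement with the exact gradient on small models, not convergence to a
  maximum-likelihood solution.
* The generator's conditional-independence and homogeneous-noise
  assumptions understate the messiness of real inquiry data (see above).
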