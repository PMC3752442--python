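# Methods

## The model

`dualpath` implements a dual-pathway simple-recurrent (Elman) network of
spoken-word repetition, comprehension and speech production. Five layers
form two routes from sound to articulation:

- **dorsal**: `Auditory -> iSMG -> SpeechMotor` — the direct
  sound-to-motor mapping (the arcuate-fasciculus analogue);
- **ventral**: `Auditory -> aSTG_STS -> vATL -> SpeechMotor` — the
  sound-meaning-motor mapping through the semantic hub (vATL), which also
  serves as the semantic input layer (speaking) and semantic output layer
  (comprehension);
- **cross-pathway link**: `vATL -> iSMG`, the point below the motor output
  where ventral (semantic) activation interacts with the dorsal route.
  This link is a deliberate architectural choice: without it the dorsal
  hidden layer receives no signal at all during speaking (the auditory
  input is silent), so its lesion noise disproportionately destroys
  production from meaning — the opposite of the conduction-aphasia profile,
  where naming is relatively preserved.  Default layer widths: iSMG 100,
  aSTG/STS 45, vATL = semantic dimension (50).

Every non-input layer carries an Elman context: a trainable self-recurrent
projection from its own previous-event activation. Time is discrete; a
trial spans 3, 6 or 9 events. Within one event, activation flows through
the whole depth in topological order, so a target can co-occur with its
input at the same event (as the speaking and comprehension tasks require).
Units are logistic sigmoids; the context is initialized to the neutral
resting value 0.5 at event 1; initial weights are uniform in [-0.1, 0.1].

Words are sequences of exactly 3 morae. A mora is presented or produced as
a binary feature vector, one mora per event; the default coding is localist
one-hot over the inventory (a distributed binary coding is selectable).
Word meanings are sparse random binary vectors (default 50 dimensions at
20% sparsity), pairwise distinct; nonwords have no semantics.

## Tasks and schedules

Development phase, per word per epoch: 1 repetition (hear events 1-3,
reproduce events 4-6), 3 comprehension (hear 1-3, semantic target on vATL
at 1-3), 2 speaking (semantic clamp on vATL 1-3, produce 1-3), in seeded
random order. Recovery phase adds 1 conduite d'approche trial (hear 1-3,
target a *second* repetition at 7-9, events 4-6 unsupervised) and extends
the comprehension target to events 1-9 so the meaning is maintained for the
duration of a 9-event trial. Nonwords never appear in training.

Training is online backpropagation through time over the whole trial, with
cross-entropy loss summed over exactly the (layer, event) pairs where the
trial defines a target. Learning rate 0.1, multiplicative weight decay
1e-7 per update.

### Numerical stabilizers

Two choices depart from the textbook update and are deliberate:

1. **Error signal at supervised units.** The delta at a supervised unit is
   `output - target` (the standard sigmoid/cross-entropy cancellation).
   With output noise off this *is* the exact gradient (verified against
   central finite differences to < 1e-4 relative error). With Gaussian
   output noise on, the naive chain rule through the clipped noisy output
   produces unbounded deltas (~1/eps when noise pins a unit near 0 or 1)
   and destroys the network within one epoch; the cancellation form keeps
   the error bounded by 1 per unit and is the conventional treatment in
   this model family.
2. **Per-trial gradient-norm cap** (`max_grad_norm`, default 10). The
   9-event semantic-maintenance trials enter the recovery phase with
   summed-CE gradients of L2 norm up to ~900 — an order of magnitude above
   any gradient seen in development (median 25-60 early, ~1-10 late). At
   learning rate 0.1 a single such trial moves weights by ~90 and training
   diverges; even a cap of 50 lets the dense recovery schedule erode the
   developed solution. Capping each trial's gradient at global L2 norm 10
   slows early development slightly (the budget below absorbs it) and
   keeps both phases stable.

## Lesions

The conduction-aphasia lesion removes 20% of the individual
`iSMG -> SpeechMotor` weight entries (round-half-up, sampled without
replacement, masked to zero permanently — masks survive all subsequent
training) and adds Gaussian noise (SD 0.2) to iSMG unit outputs at every
event, clipped to [0, 1]. The noise is chronic: it stays on during
recovery training and all probing.

Diagnostic ventral lesioning uses 20 equal-interval severity levels:
level k has output-noise SD 0.01k on vATL and 0.005k on aSTG/STS, and
prunes 0.5k% of the entries of every weight matrix incoming to vATL and
0.25k% of those incoming to aSTG/STS. "Incoming" includes the layer's
Elman self-recurrence (a literal reading of links targeting the layer).
Levels are independent doses applied to fresh copies of the recovered
network, not progressive damage.

## Probing and statistics

A double-repetition probe presents an item at events 1-3 and free-runs to
event 9. Each SpeechMotor event is decoded to the nearest inventory mora
(Euclidean; ties to the lowest id); an attempt is correct only if all three
morae match in order (no partial credit). The conduite d'approche rate is
`#(attempt-1 wrong and attempt-2 right) / #(attempt-1 wrong)`, undefined
(never 0/0) when there are no first-attempt errors. Each network is probed
5 times per item with fresh noise; the per-network rate pools those probes,
and networks are the unit of analysis.

Two-level repeated-measures contrasts report `F = t^2` for the paired t
statistic, with p from F(1, n-1) and Cohen's d on the paired differences
(d_z). The 2x2 lexicality-by-damage interaction is the paired t^2 of the
per-network double difference. Zero-variance differences with nonzero mean
are flagged as infinite F with p = 0. Networks with undefined rates are
excluded pairwise with a logged warning.

Comprehension is scored by nearest-neighbour match of the vATL pattern at
event 3 against all trained word meanings; naming by decoding SpeechMotor
events 1-3 under a semantic clamp.

## Synthetic materials

The generator emulates the study materials, which are not deposited: an
artificial mora inventory, a training vocabulary (default 300 words;
100 at desk scale) with sparse semantic vectors, a 51-word probe set drawn
from the vocabulary, and 108 nonwords whose pooled position-free
mora-bigram histogram matches the probe words' histogram (symmetric
chi-square distance <= 0.05 by default). Nonwords are built by sampling a
first-order Markov chain fitted to the word bigram profile and refined by
coordinate descent (enumerating candidate forms with incremental
chi-square updates); forms never collide with any trained word. A
categorical accent-class label (4 classes, echoing Japanese 3-mora pitch
accent types) is matched in distribution between the sets but is purely
bookkeeping — it is not encoded in the input vectors. Miniature test
corpora use proportionally looser matching tolerances because integer
histograms over a few dozen bigrams cannot reach the study-scale tolerance.

What the generator does *not* emulate: real Japanese phonotactics, word
frequency distributions, feature-based mora similarity structure, and
age-of-acquisition effects. Passing tests therefore show that the
*mechanism* (lesion-induced loss, recovery-driven self-correction, a
lexicality effect carried by the semantic route) emerges in this model
class, not that the simulation quantitatively reproduces Japanese
psycholinguistics.

## Scales and presets

The full-scale preset (`paper_config`) uses a 300-word vocabulary,
10 replicate networks, 200 development epochs, 20 recovery epochs,
51/108 probe sets and 5 noise probes. The desk preset (`desk_config`) —
used by the test suite and the acceptance script — reduces to a 150-word
vocabulary and 2 networks, keeping the probe sets, lesion recipe,
development and recovery lengths and all training constants at their full
values. The vocabulary size matters qualitatively, not just in runtime:
with too few words the ventral route lexically absorbs repetition during
recovery and the first-attempt error pool that the self-correction
statistic conditions on empties out. Replicate seeds are derived from the master seed via
`numpy.random.SeedSequence` with fixed integer tags, so every stage
(corpus, initialization, trial order, lesion draws, probe noise) is
independently reproducible and the whole experiment is deterministic under
a fixed master seed.

## Known limitations

- Layer sizes (iSMG 100, aSTG/STS 60, vATL 50) were chosen for desk-scale
  trainability; the behavioral directions, not the absolute rates, are the
  robust output.
- The produced speech is not fed back as auditory input between the two
  attempts; the second attempt is driven purely by internal recurrent
  state. Error monitoring through articulatory or auditory feedback is out
  of scope.
- Self-corrections that deviate away from the target, repeated (ad
  infinitum) approximation attempts, and spontaneous-speech self-correction
  are not modelled.
- With 2 desk-scale networks the repeated-measures F tests have df (1, 1)
  and are reported for completeness; directions, not p-values, are the
  meaningful desk-scale output.
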