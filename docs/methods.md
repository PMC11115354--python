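# Methods

This note documents the models, defaults and design choices behind
`cochmat`, and what the synthetic study conditions do and do not show.

## The simulated system

A spoken-word recognizer is modeled as a cochlear front-end feeding a
convolutional classifier.  The front-end converts a 1 s, 16 kHz waveform
into a 100 x 100 cochleagram: 100 gammatone band-pass filters with center
frequencies uniformly spaced on the ERB-number scale between 50 and 7500 Hz
(Glasberg–Moore mapping E(f) = 21.4 log10(1 + 0.00437 f)), half-wave
rectification, envelope extraction by averaging into 100 equal time bins,
and power-law compression with exponent 0.3.  All front-end constants are
exposed in `CochleagramConfig`.

Cochlear immaturity is modeled as a normalized box filter of shape (1, y)
applied to the cochleagram image along the frequency (vertical) axis with
reflective borders; y = 1 is the identity.  Reflective borders avoid
edge-darkening that would otherwise act as a spurious class cue.  The blur
is applied to the compressed image (the image is the object the maturation
schedule manipulates); whether the original full-scale study blurred before
or after compression is not recoverable, and the choice only rescales
contrast.

Maturation schedules over n training epochs:

* **control** — y = 1 at every epoch; tested at y = 1.
* **regular** — linear integer descent 25 -> 1 over the first
  ceil(0.7 n) epochs (epoch 7 of 10), then 1; tested at y = 1.
* **delay** — linear integer descent 25 -> 16 over all epochs; tested at
  its final y = 16, because its cochlea never matures.

Only the endpoints and the epoch-7 anchor of these schedules are
constrained by the emulated design; linear integer descent is the simplest
interpolation and both schedules are config-overridable.  Testing each
condition at its own final resolution is a design choice (the alternative,
probing every condition at y = 1, answers a different, counterfactual
question about a delayed system suddenly given sharp input).

## Networks and training

Two architectures share one numpy layer framework (im2col convolutions with
explicit backpropagation, float32, single-threaded, hence bit-reproducible):

* `reduced` — four 3x3 conv-ReLU-maxpool blocks (8/16/32/32 channels) and a
  linear classifier; the desk-scale workhorse.
* `resnet18` — an 18-layer residual network whose 20 convolutional layers
  (initial 7x7, sixteen block convolutions, three 1x1 projection shortcuts)
  are exposed for layerwise probing; kept for structural fidelity with
  full-scale replication runs.  Batch normalization is omitted: training
  uses batch size 1, where batch statistics degenerate, and probing needs
  deterministic activations.

Training is plain SGD (learning rate 0.01, no scheduler) on the
cross-entropy loss, one update per exposure (batch size 1), 10 epochs at
full scale and 6 by default at desk scale (the scaled-down profile admits
5–10; 6 keeps the three-condition, three-replicate experiment near two
minutes on one CPU while letting the regular schedule reach full resolution
with epochs to spare).  Optimizer and learning rate are not constrained by
the emulated design and are config surface.  Matched structure is enforced
by construction: per replicate, the three conditions' networks are clones of
one initialization, and the per-epoch exemplar sample depends only on
(corpus, epoch, replicate seed), so the execution traces differ only in the
blur kernel height, which is logged per epoch.

## The synthetic corpus: what it emulates

The generator stands in for a large natural keyword corpus (35 word types,
~10^5 one-second tokens).  Its defaults define the study conditions:

* **Lexicon** — 10 words, transcriptions of 4 symbols over an 8-symbol
  alphabet, 2 designed neighbor pairs.  Pairwise similarity is controlled on
  two levels: neighbor pairs sit at OSA distance exactly 1 via a
  single *adjacent-band* substitution (genuinely confusable competitors, the
  tree/three analogue), while all other pairs are rejection-sampled to OSA
  distance >= 2 *and* acoustic separation (>= 2 differing symbol slots,
  summed band offset >= 4 steps).  Without the acoustic constraint, random
  lexica occasionally contain near-homophones that cap even control
  performance and wash out the condition contrast.
* **Acoustics** — each symbol maps to a narrow frequency band; the 8 bands
  are geometrically spaced 800–2000 Hz, just under 1 ERB apart (~3 channels
  of the 100-channel axis).  A y = 16 box kernel spans ~5 ERB, so immature
  hearing merges several adjacent symbol bands while mature hearing resolves
  them — the discriminative information sits exactly at the spatial scale
  the manipulation removes.  Words are four 0.225 s chirp segments (per-symbol
  slopes of a few hundred Hz/s) inside a 1 s clip.
* **Production variability** — per exemplar: multiplicative band jitter
  (±6%, ~0.6 ERB, "speaker" variation), per-segment gain jitter (±60%,
  emphasis), segment-duration and onset jitter (±10%, speaking rate), and
  additive white noise at 0.3 of signal RMS.  The jitters are deliberately
  *blur-robust*: a frequency-axis box filter cannot average away gain or
  timing variation, just as it cannot remove speaker variation from natural
  speech.  This matters for the manifold analyses — white noise alone is
  *removed* by the blur (it averages across channels), which would make the
  delayed condition's inputs artificially clean and invert the
  representational contrast.  With blur-robust variability dominating, the
  delayed networks' failure to compress within-class variation is visible.
* **Frequencies** — per-word exemplar counts follow a Zipf law with
  exponent 1 (configurable); the realized rank-frequency slope is checked
  at about −1.

What the generator does **not** emulate: formant structure, coarticulation,
prosody, semantics, and the temporal fine structure of natural speech.
Consequently, passing tests show that the pipeline detects the consequences
of scheduled frequency-resolution deprivation under controlled spectral
statistics; they do not show that the same effect sizes arise for natural
speech.  Effect sizes here are somewhat larger than the full-scale reference
outcomes (which are subtle, a few accuracy points) because a three-replicate
desk-scale study must resolve the condition orderings above replicate noise.

## Behavioral measures

Predictive entropy is Shannon entropy in bits of the softmax output, the
model's word-finding-uncertainty proxy; maximum probability is its
confidence.  Both are reported over all trials and over hits only.
Misclassification tables rank off-diagonal confusion *cells* (true,
predicted) by cell count as a proportion of the true word's total
misclassifications — a word can contribute several rows; ties break by
lexicon order, proportions are reported to 2 decimals, rounding half away
from zero.  The accuracy differential is per-word regular minus delay
accuracy in percentage points (positive = regular advantage).

## Item regression

Per-word accuracy (as %) is modeled as skew-normal with location
ξ = β0 + β_f z_freq + β_d z_dist + condition offsets and interactions,
scale ω and shape α.  Frequency is the number of times the word appeared in
the sampled training data; phonological distance is the mean OSA distance
to all other words; both are z-scored across words.  Priors:
β ~ N(0, 10), ω ~ halfN(10), α ~ N(0, 4) — weakly informative on the
percent scale.  Sampling uses the affine-invariant ensemble sampler with
differential-evolution moves (48 walkers, 8000 steps, half discarded),
initialized around the least-squares solution; rhat and effective sample
size are computed with walkers as chains, and any rhat > 1.05 flags the fit
(returned with a warning, never silently).  The OSA distance itself is the
restricted Damerau–Levenshtein dynamic program (insertions, deletions,
substitutions, adjacent transpositions, no substring edited twice) — note
it is not a true metric (d("CA","ABC") = 3), which the test suite checks
against an exhaustive edit-script search.

## Manifold analysis

For each probed layer, each word's activation vectors form a manifold.
After optional seeded Gaussian random projection (default 500 dimensions at
desk scale, applied only when the layer is wider), each class is expressed
in its intra-manifold basis plus the centroid direction, scaled by the
centroid norm.  For each of n_t = 300 Gaussian direction samples t, the
projection of t onto the polar cone of the manifold's margin constraints is
found by nonnegative least squares (a general bounded quadratic program
when the margin κ > 0; default κ = 0); the residual defines the anchor
point.  Per class, the inverse capacity is the mean squared residual, the
anchor radius R_M the root-mean-square intra-manifold anchor norm, and the
anchor dimension D_M the mean squared alignment of t with the anchor
direction; layer capacity is the inverse mean of per-class inverse
capacities.  SVD axis signs are canonicalized so results are exactly
invariant to exemplar ordering.  For zero-extent manifolds at κ = 0 the
capacity reduces to the classical perceptron value 2, and the
implementation is validated against a brute-force oracle that bisects the
neuron count for 50% probability of linear separability of random ±1 class
dichotomies (feasibility LP, homogeneous hyperplane).

Two estimator properties worth knowing: (1) the anchor dimension is
downward-biased when a manifold's convex hull is sampled by few exemplars —
it converges to the latent dimension only as the hull fills in, so the
recovery validation uses densely sampled isotropic shells (200 points on a
5-sphere in 100 ambient dimensions); (2) manifold statistics need a common,
adequate number of exemplars per class, so the pipeline probes geometry on
a dedicated class-balanced probe set drawn fresh from the corpus
distribution (the Zipf-skewed test split leaves the rarest words with only
a handful of tokens).  Probe stimuli are blurred at each condition's own
test resolution, and condition-level geometry is the median over the three
replicate networks.

## Reproducibility and numerics

All randomness derives from one master seed through named substreams
(lexicon, templates, corpus, per-replicate init, per-epoch sampling, test
sample, probe set, MCMC, manifold directions), so stages can be re-run in
isolation and identical configurations produce bit-identical logs and
output hashes (verified in the suite).  Softmax and entropy are computed in
float64; network arithmetic is float32.  Degenerate inputs fail loudly:
non-finite waveforms or losses, Nyquist violations, unnormalized
probability vectors, rank-0 manifolds, infeasible lexicon requests.

## Known limitations

* The numpy networks are single-threaded; the full-scale profile
  (ResNet-18, 4000 exposures x 10 epochs x 9 networks) is supported but
  meant for replication runs with the real corpus, not for routine use.
* The box-filter maturation model degrades only spectral resolution; the
  temporal axis is untouched, and temporal-degradation contrasts are out of
  scope.
* The item regression's coefficients on the synthetic corpus are not
  comparable in magnitude to the full-scale reference values (different
  predictor variances and accuracy ranges); only signs and orderings
  transfer.
* Manifold anchor dimension at desk scale (12 probe exemplars per class)
  is a coarse statistic; condition differences of ~0.1 are meaningful only
  as medians over replicates.
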