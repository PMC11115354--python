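# cochmat

Simulating cochlear maturation schedules in spoken-word classification
networks.

## The scientific problem

Auditory perceptual deficits are common in developmental language disorder
(DLD), and one candidate mechanism is a disruption to the maturation of the
basilar membrane: if cochlear frequency tuning sharpens too slowly during the
first years of life, the downstream auditory pathway optimizes to blurred
spectral input and may settle into representations that make speech
recognition and retrieval inefficient — even after behavior looks nearly
normal.  `cochmat` implements that hypothesis as a controlled simulation for
computational neuroscientists and psycholinguists: identical convolutional
word classifiers are trained on cochleagram input whose frequency resolution
matures at different rates, and the behavioral and representational
consequences are measured.

The pipeline:

1. **Synthetic corpus** (`cochmat.synthgen`): W word classes with
   symbol-string transcriptions, designed phonological neighbor pairs at
   optimal-string-alignment (OSA) distance 1, Zipf-distributed exposure
   counts, and per-production variability (band jitter, emphasis jitter,
   speaking-rate jitter, noise).  Real 16 kHz WAV corpora in a
   `<word>/<id>.wav` layout can be substituted.
2. **Cochlea front-end** (`cochmat.cochlea`): 100x100 cochleagrams from an
   ERB-spaced gammatone filterbank with power-law compression.  Maturation is
   a normalized box filter of shape (1, y) along the frequency axis whose
   height y shrinks per epoch: control y = 1 throughout; regular 25 -> 1 by
   epoch 7 of 10; delay 25 -> 16, never reaching full resolution.
3. **Matched training** (`cochmat.training`): per replicate, three networks
   with element-wise identical initializations see identical per-epoch
   exemplar samples; only the blur differs.  Updates are SGD on the
   cross-entropy loss after every exposure (batch size 1).
4. **Behavior** (`cochmat.behavior`): accuracy, maximum assigned probability,
   predictive entropy H(p) = -Σ p_i log2 p_i (overall and hits-only),
   confusion tables, ranked misclassification cells, and the per-word
   regular-minus-delay accuracy differential.
5. **Item effects** (`cochmat.lexstats`): accuracy% regressed on standardized
   training frequency and mean OSA phonological distance, in interaction with
   condition, under a skew-normal likelihood with weakly informative priors
   (ensemble MCMC; rhat/ESS diagnostics).
6. **Manifold geometry** (`cochmat.manifolds`): mean-field-theoretic manifold
   analysis of per-layer activations — per-class anchor dimensionality D_M,
   radius R_M and linear classification capacity α_C (α_C = 2 for point
   classes at zero margin), validated against a brute-force linear-separability
   oracle.
7. **Orchestration** (`cochmat.pipeline`): conditions x replicates from one
   master seed, with bit-reproducible outputs and a results manifest.

## Worked example

`python examples/07_full_experiment.py` (about two minutes on one CPU) trains
the default scaled-down profile — 10 synthetic words, 200 exposures per epoch
for 6 epochs, 3 replicates per condition — and prints, among other things:

```
           accuracy  mean_max_probability  mean_entropy_bits  ...
control      0.9300                0.9375             0.2884
regular      0.8900                0.8893             0.5373
delay        0.8667                0.8417             0.7776

median final-epoch training accuracy: {'control': 0.93, 'delay': 0.875, 'regular': 0.89}

final-layer manifold geometry (median over replicates):
  control  D_M 3.360  capacity 0.743
  regular  D_M 3.369  capacity 0.730
  delay    D_M 3.436  capacity 0.653
```

Reading the numbers: networks whose cochlea matured late classify less
accurately (86.7% vs 93.0%), are less confident when they answer (mean max
probability 0.84 vs 0.94), and spread probability over more of the lexicon
(0.78 vs 0.29 bits of predictive entropy — the model's analogue of
word-finding uncertainty).  Their final-layer word manifolds are higher
dimensional and support a lower linear classification capacity: the delayed
system optimized to blur and never untangled its speech representations,
despite having seen exactly the same training exemplars.

The other examples (`examples/01...06`) each demonstrate one capability:
corpus synthesis, the maturation blur, matched training, the behavioral
metrics, the item regression, and the manifold oracles.

A thin CLI wraps the pipeline for shell use:

```
cochmat run --seed 1 --out results/      # full experiment, writes CSV/JSON
cochmat report --out results/            # print the summary of a run
```

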