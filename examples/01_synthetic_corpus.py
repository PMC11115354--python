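"""Build a synthetic spoken-word corpus and inspect its structure.

Creates a 10-word lexicon with two designed neighbor pairs (one-symbol
substitutions, the synthetic analogue of tree/three), draws a Zipf-weighted
train/test corpus, and renders one waveform.  The printed string distances
show that neighbors sit at edit distance 1 and everything else at >= 2.
"""

from cochmat.lexstats import osa_distance
from cochmat.synthgen import make_lexicon, make_templates, sample_corpus

lexicon = make_lexicon(n_words=10, n_neighbor_pairs=2, seed=1)
templates = make_templates(lexicon, seed=1)
corpus = sample_corpus(lexicon, templates, n_train=200, n_test=100, zipf_exponent=1.0, seed=1)

print("words:", " ".join(lexicon.words))
print("neighbor pairs (edit distance 1, one adjacent frequency band apart):")
for a, b in lexicon.neighbor_pairs:
    print(f"  {a} ~ {b}   OSA distance {osa_distance(a, b)}")

print("\nper-word exemplar counts (Zipf, most frequent first):")
ranked = sorted(corpus.counts.items(), key=lambda kv: -kv[1])
for w, c in ranked:
    print(f"  {w}: {c}")

wav = corpus.render(corpus.exemplars[0])
print(f"\nfirst exemplar: word={corpus.exemplars[0].word}, "
      f"{wav.size} samples at {corpus.sample_rate} Hz, peak {abs(wav).max():.3f}")
print("The counts follow a rank-frequency power law; every exemplar is a fresh")
print("random production (band, gain and timing jitter plus noise) of its word.")
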