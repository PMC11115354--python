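import numpy as np
import pytest

from cochmat.lexstats import osa_distance
from cochmat.synthgen import (
    LexiconInfeasibleError,
    WordTemplate,
    make_lexicon,
    make_templates,
    read_corpus_manifest,
    sample_corpus,
    synth_waveform,
    write_corpus,
)


def _pairs(lexicon):
    words = lexicon.words
    return [(a, b) for i, a in enumerate(words) for b in words[i + 1 :]]


def test_lexicon_neighbor_structure(lexicon10):
    assert len(set(lexicon10.words)) == 10
    assert len(lexicon10.neighbor_pairs) == 2
    neighbor_sets = {frozenset(p) for p in lexicon10.neighbor_pairs}
    tr = dict(zip(lexicon10.words, lexicon10.transcriptions))
    for a, b in _pairs(lexicon10):
        d = osa_distance(tr[a], tr[b])
        if frozenset((a, b)) in neighbor_sets:
            assert d == 1
        else:
            assert d >= 2


def test_lexicon_determinism_and_edges():
    assert make_lexicon(10, 2, seed=7) == make_lexicon(10, 2, seed=7)
    assert make_lexicon(10, 2, seed=7) != make_lexicon(10, 2, seed=8)
    lex2 = make_lexicon(2, 0, seed=0)
    assert osa_distance(lex2.transcriptions[0], lex2.transcriptions[1]) >= 2
    with pytest.raises(ValueError):
        make_lexicon(4, 3, seed=0)
    with pytest.raises(ValueError):
        make_lexicon(4, 0, alphabet="abc", seed=0)
    # explicit failure (not silent relaxation) when placement cannot succeed
    with pytest.raises(LexiconInfeasibleError):
        make_lexicon(40, 0, alphabet="abcd", seed=0, max_tries=60)


def test_templates_mirror_transcription_similarity(lexicon10, templates10):
    tr = dict(zip(lexicon10.words, lexicon10.transcriptions))
    neighbor_sets = {frozenset(p) for p in lexicon10.neighbor_pairs}
    for a, b in _pairs(lexicon10):
        ca, cb = templates10[a].band_centers, templates10[b].band_centers
        diffs = sum(x != y for x, y in zip(ca, cb)) + abs(len(ca) - len(cb))
        if frozenset((a, b)) in neighbor_sets:
            assert diffs == 1
        else:
            assert diffs >= 2
    assert make_templates(lexicon10, seed=1) == templates10  # determinism
    for w, t in templates10.items():
        assert sum(t.segment_durations) <= 1.0


def test_waveform_contract():
    t = WordTemplate("x", (1000.0,), (0.0,), (0.9,), (1.0,))
    a = synth_waveform(t, speaker_shift=0.0, noise_level=0.0, seed=1)
    b = synth_waveform(t, speaker_shift=0.0, noise_level=0.0, seed=99)
    np.testing.assert_array_equal(a, b)  # no stochastic components remain
    assert a.shape == (16000,)
    assert np.max(np.abs(a)) <= 1.0
    noisy = synth_waveform(t, noise_level=0.5, seed=1)
    assert np.max(np.abs(noisy)) <= 1.0
    with pytest.raises(ValueError):
        synth_waveform(WordTemplate("x", (9000.0,), (0.0,), (0.9,), (1.0,)), sample_rate=16000)
    with pytest.raises(ValueError):
        synth_waveform(t, noise_level=1.5)


def test_waveform_spectral_peak_at_band_center():
    t = WordTemplate("x", (1000.0,), (0.0,), (0.9,), (1.0,))
    w = synth_waveform(t, noise_level=0.0)
    spec = np.abs(np.fft.rfft(w))
    freqs = np.fft.rfftfreq(w.size, d=1 / 16000)
    peak = freqs[np.argmax(spec)]
    assert abs(peak - 1000.0) <= freqs[1]  # within one DFT bin


def test_corpus_counts_and_determinism(lexicon10, templates10):
    c = sample_corpus(lexicon10, templates10, n_train=200, n_test=100, zipf_exponent=1.0, seed=5)
    assert sum(c.counts.values()) == 300
    assert len(c.exemplars) == 300
    assert {e.word for e in c.exemplars} <= set(lexicon10.words)
    train_ids = {e.exemplar_id for e in c.split_exemplars("train")}
    test_ids = {e.exemplar_id for e in c.split_exemplars("test")}
    assert not train_ids & test_ids
    assert len(train_ids) + len(test_ids) == 300
    c2 = sample_corpus(lexicon10, templates10, n_train=200, n_test=100, zipf_exponent=1.0, seed=5)
    assert [e.seed for e in c2.exemplars] == [e.seed for e in c.exemplars]
    with pytest.raises(ValueError):
        sample_corpus(lexicon10, templates10, n_train=5, n_test=100)


def test_zipf_exponent_realized(lexicon10, templates10):
    # exponent 0: per-word counts equal up to rounding
    flat = sample_corpus(lexicon10, templates10, n_train=200, n_test=100, zipf_exponent=0.0, seed=1)
    train_counts = {}
    for e in flat.split_exemplars("train"):
        train_counts[e.word] = train_counts.get(e.word, 0) + 1
    assert max(train_counts.values()) - min(train_counts.values()) <= 1
    # exponent 1: realized rank-frequency slope ~ -1 on log-log axes
    zipf = sample_corpus(lexicon10, templates10, n_train=1000, n_test=100, zipf_exponent=1.0, seed=1)
    counts = {}
    for e in zipf.split_exemplars("train"):
        counts[e.word] = counts.get(e.word, 0) + 1
    ordered = sorted(counts.values(), reverse=True)
    slope = np.polyfit(np.log(np.arange(1, 11)), np.log(ordered), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.15)


def test_wav_roundtrip(tmp_path, corpus_small):
    manifest = write_corpus(corpus_small, tmp_path)
    seen = list(read_corpus_manifest(manifest))
    assert len(seen) == len(corpus_small.exemplars)
    wav, sr, word, split = seen[0]
    assert sr == corpus_small.sample_rate
    assert wav.dtype == np.float64 and np.max(np.abs(wav)) <= 1.0
    assert word in corpus_small.lexicon.words and split in ("train", "test")
    # layout mirrors <word>/<id>.wav
    assert (tmp_path / corpus_small.exemplars[0].word).is_dir()
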