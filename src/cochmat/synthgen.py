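"""Synthetic spoken-word corpora.

The analyses in this package assume a corpus with the statistical structure of
a large keyword data set: a fixed lexicon of word types, some of which are
close phonological neighbors (tree/three-style competitors), Zipf-distributed
exposure frequencies, and exemplar-to-exemplar variability from speaker and
noise effects.  This module generates such corpora from scratch so the whole
pipeline runs with no external download, and reads/writes the per-word WAV
directory layout (``<word>/<id>.wav``) so a real data set can be substituted.

Waveforms are sums of narrow-band components with linear frequency
trajectories plus white noise, with speaker-like band jitter, per-segment
emphasis (gain) jitter and speaking-rate (timing) jitter across productions.
This is deliberately not naturalistic speech: the analyses only require
class-distinctive spectro-temporal contours that a cochlear filterbank
resolves, that frequency-axis blurring degrades, and within-class
variability that survives such blurring the way natural speaker variation
does.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from ._seeds import child_seed, substream
from .lexstats import osa_distance

__all__ = [
    "Lexicon",
    "WordTemplate",
    "Exemplar",
    "Corpus",
    "LexiconInfeasibleError",
    "make_lexicon",
    "make_templates",
    "synth_waveform",
    "sample_corpus",
    "write_corpus",
    "read_corpus_manifest",
]

#: Frequency range (Hz) of the transcription-symbol bands.  Symbols map to
#: bands just under 1 ERB apart in a formant-like region, so that
#: transcription similarity (shared symbols) implies acoustic similarity
#: (shared bands), fine spectral resolution is genuinely needed to tell
#: symbols apart, and a wide frequency-axis blur merges adjacent symbol
#: bands the way immature cochlear tuning would.
SYMBOL_BAND_LO_HZ = 800.0
SYMBOL_BAND_HI_HZ = 2000.0

DEFAULT_ALPHABET = "abcdefgh"
TRANSCRIPTION_LENGTH = 4
WORD_DURATION_S = 0.9  # voiced portion; remainder of the 1 s clip is silence


class LexiconInfeasibleError(RuntimeError):
    """Requested neighbor-pair structure could not be realized."""


@dataclass(frozen=True)
class Lexicon:
    """Word labels, their symbol-string transcriptions, and designed neighbors.

    Invariants: labels are unique; every designed neighbor pair is at OSA
    distance exactly 1; every other pair is at OSA distance >= 2.
    """

    words: tuple[str, ...]
    transcriptions: tuple[str, ...]
    neighbor_pairs: tuple[tuple[str, str], ...]

    def transcription(self, word: str) -> str:
        return self.transcriptions[self.words.index(word)]


@dataclass(frozen=True)
class WordTemplate:
    """Spectro-temporal recipe for one word.

    One narrow-band segment per transcription symbol: ``band_centers`` in Hz,
    per-segment linear frequency slopes in Hz/s, segment durations in seconds
    (summing to <= 1 s) and relative gains.
    """

    label: str
    band_centers: tuple[float, ...]
    band_trajectories: tuple[float, ...]
    segment_durations: tuple[float, ...]
    amplitude_profile: tuple[float, ...]


@dataclass(frozen=True)
class Exemplar:
    """One synthetic token: rendered lazily from its template and seed."""

    word: str
    split: str  # "train" | "test"
    seed: int
    exemplar_id: str


@dataclass
class Corpus:
    lexicon: Lexicon
    templates: dict[str, WordTemplate]
    exemplars: list[Exemplar]
    sample_rate: int = 16000
    duration: float = 1.0
    speaker_shift: float = 0.06
    noise_level: float = 0.3
    amplitude_jitter: float = 0.6
    timing_jitter: float = 0.1
    counts: dict[str, int] = field(default_factory=dict)

    def split_exemplars(self, split: str) -> list[Exemplar]:
        return [e for e in self.exemplars if e.split == split]

    def render(self, exemplar: Exemplar) -> np.ndarray:
        """Synthesize the waveform for one exemplar."""
        return synth_waveform(
            self.templates[exemplar.word],
            speaker_shift=self.speaker_shift,
            noise_level=self.noise_level,
            sample_rate=self.sample_rate,
            duration=self.duration,
            seed=exemplar.seed,
            amplitude_jitter=self.amplitude_jitter,
            timing_jitter=self.timing_jitter,
        )


def _symbol_frequencies(alphabet: str) -> dict[str, float]:
    """Assign each symbol a band center, geometrically spaced in frequency."""
    n = len(alphabet)
    freqs = np.geomspace(SYMBOL_BAND_LO_HZ, SYMBOL_BAND_HI_HZ, n)
    return dict(zip(alphabet, freqs))


def _min_osa_to_all(s: str, others: list[str]) -> int:
    return min((osa_distance(s, o) for o in others), default=99)


def _acoustically_separated(a: str, b: str, symbols: list[str]) -> bool:
    """Non-neighbor words must differ in at least two symbol slots with a
    summed band offset of >= 4 symbol steps, so that full-resolution hearing
    can always tell them apart despite speaker jitter; without this check a
    random lexicon occasionally contains near-homophones (e.g. two one-step
    substitutions) that cap even the control condition's accuracy."""
    idx = {s: i for i, s in enumerate(symbols)}
    diffs = [abs(idx[x] - idx[y]) for x, y in zip(a, b) if x != y]
    return len(diffs) >= 2 and sum(diffs) >= 4


def make_lexicon(
    n_words: int,
    n_neighbor_pairs: int,
    alphabet: str = DEFAULT_ALPHABET,
    seed: int = 0,
    max_tries: int = 20000,
) -> Lexicon:
    """Random lexicon with exactly ``n_neighbor_pairs`` distance-1 pairs.

    Pairwise similarity is controlled on two levels.  Transcriptions: every
    designed neighbor pair is at OSA distance exactly 1 and every other pair
    at distance >= 2.  Acoustics: a designed neighbor differs from its
    partner by a single adjacent-band substitution (a genuinely confusable
    competitor), while all other pairs are rejection-sampled to be
    acoustically well separated (>= 2 differing slots, summed band offset
    >= 4 steps).  Raises :class:`LexiconInfeasibleError` rather than
    silently relaxing the structure if the request cannot be met.
    """
    if len(set(alphabet)) < 4:
        raise ValueError("alphabet must contain at least 4 distinct symbols")
    if 2 * n_neighbor_pairs > n_words:
        raise ValueError("need 2 * n_neighbor_pairs <= n_words")
    rng = substream(seed, "lexicon")
    symbols = sorted(set(alphabet))
    n_base = n_words - n_neighbor_pairs

    base: list[str] = []
    tries = 0
    while len(base) < n_base:
        tries += 1
        if tries > max_tries:
            raise LexiconInfeasibleError(
                f"could not place {n_base} base words at mutual OSA distance >= 2"
            )
        cand = "".join(rng.choice(symbols, size=TRANSCRIPTION_LENGTH))
        if _min_osa_to_all(cand, base) >= 2 and all(
            _acoustically_separated(cand, w, symbols) for w in base
        ):
            base.append(cand)

    transcriptions = list(base)
    pairs: list[tuple[str, str]] = []
    idx = {s: i for i, s in enumerate(symbols)}
    for k in range(n_neighbor_pairs):
        anchor = base[k]
        placed = False
        for _ in range(max_tries):
            pos = int(rng.integers(TRANSCRIPTION_LENGTH))
            step = int(rng.choice([-1, 1]))
            j = idx[anchor[pos]] + step
            if not 0 <= j < len(symbols):
                continue
            cand = anchor[:pos] + symbols[j] + anchor[pos + 1 :]
            others = [t for t in transcriptions if t != anchor]
            if (
                osa_distance(cand, anchor) == 1
                and _min_osa_to_all(cand, others) >= 2
                and all(_acoustically_separated(cand, w, symbols) for w in others)
            ):
                transcriptions.append(cand)
                pairs.append((anchor, cand))
                placed = True
                break
        if not placed:
            raise LexiconInfeasibleError(
                f"could not place neighbor pair {k + 1} at OSA distance 1"
            )

    # Labels are the transcriptions themselves (unique by construction).
    words = tuple(transcriptions)
    return Lexicon(words=words, transcriptions=tuple(transcriptions), neighbor_pairs=tuple(pairs))


def make_templates(lexicon: Lexicon, seed: int = 0) -> dict[str, WordTemplate]:
    """One template per word; band centers are the symbol band frequencies.

    Because band centers are a fixed function of the transcription symbols,
    designed neighbor pairs (single-symbol substitutions) share all but one
    band center, mirroring their transcription similarity.  Slopes and gains
    are deterministic functions of (symbol, position) so templates depend only
    on (lexicon, seed).
    """
    rng = substream(seed, "templates")
    sym_freq = _symbol_frequencies("".join(sorted({c for t in lexicon.transcriptions for c in t})))
    # Per-symbol slope sign/magnitude, shared across words (seeded once).
    slopes = {s: float(rng.uniform(150.0, 450.0)) * (1 if i % 2 == 0 else -1)
              for i, s in enumerate(sorted(sym_freq))}
    templates: dict[str, WordTemplate] = {}
    for word, tr in zip(lexicon.words, lexicon.transcriptions):
        n_seg = len(tr)
        durs = tuple([WORD_DURATION_S / n_seg] * n_seg)
        centers = tuple(sym_freq[c] for c in tr)
        traj = tuple(slopes[c] for c in tr)
        amps = tuple(1.0 if i % 2 == 0 else 0.85 for i in range(n_seg))
        templates[word] = WordTemplate(
            label=word,
            band_centers=centers,
            band_trajectories=traj,
            segment_durations=durs,
            amplitude_profile=amps,
        )
    return templates


def synth_waveform(
    template: WordTemplate,
    speaker_shift: float = 0.0,
    noise_level: float = 0.0,
    sample_rate: int = 16000,
    duration: float = 1.0,
    seed: int = 0,
    amplitude_jitter: float = 0.0,
    timing_jitter: float = 0.0,
) -> np.ndarray:
    """Render one exemplar of a word template.

    ``speaker_shift`` is the maximum fractional multiplicative jitter applied
    to every band center (one draw per segment); ``noise_level`` is additive
    white noise RMS relative to the signal RMS; ``amplitude_jitter`` is the
    maximum fractional gain jitter per segment (emphasis variation across
    productions); ``timing_jitter`` is the maximum fractional jitter of each
    segment's duration plus a random onset shift of the voiced portion
    (speaking-rate variation).  Amplitude and timing jitter are deliberately
    blur-robust variability: frequency-axis smoothing cannot average either
    away.  Samples are clipped to [-1, 1].  With all jitters and the noise
    level at 0 no random draws influence the output, so all seeds produce
    the same waveform.
    """
    if not 0 <= noise_level < 1:
        raise ValueError("noise_level must be in [0, 1)")
    max_f = max(
        abs(c) * (1 + speaker_shift) + abs(tr) * d
        for c, tr, d in zip(
            template.band_centers, template.band_trajectories, template.segment_durations
        )
    )
    if sample_rate < 2 * max_f:
        raise ValueError(
            f"sample rate {sample_rate} violates Nyquist for band at {max_f:.0f} Hz"
        )
    rng = substream(seed, "waveform")
    n_total = int(round(duration * sample_rate))
    out = np.zeros(n_total)
    durations = list(template.segment_durations)
    if timing_jitter > 0:
        durations = [
            d * (1.0 + rng.uniform(-timing_jitter, timing_jitter)) for d in durations
        ]
        scale = min(1.0, (duration - 0.02) / sum(durations))
        durations = [d * scale for d in durations]
    # Center the voiced portion in the clip (jittered onset when timing varies).
    slack = duration - sum(durations)
    t0 = slack / 2
    if timing_jitter > 0 and slack > 0:
        t0 = slack * rng.uniform(0.25, 0.75)
    pos = int(round(t0 * sample_rate))
    for center, slope, dur, amp in zip(
        template.band_centers,
        template.band_trajectories,
        durations,
        template.amplitude_profile,
    ):
        n = int(round(dur * sample_rate))
        if speaker_shift > 0:
            center = center * (1.0 + rng.uniform(-speaker_shift, speaker_shift))
        if amplitude_jitter > 0:
            amp = amp * (1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter))
        t = np.arange(n) / sample_rate
        phase = 2 * np.pi * (center * t + 0.5 * slope * t**2)
        seg = amp * np.sin(phase)
        # raised-cosine onset/offset ramps (10 ms) to avoid clicks
        ramp = min(int(0.01 * sample_rate), n // 2)
        if ramp > 0:
            win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            seg[:ramp] *= win
            seg[-ramp:] *= win[::-1]
        out[pos : pos + n] += seg[: max(0, n_total - pos)]
        pos += n
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.9 / max(peak, 0.9 / 0.999)  # headroom for additive noise
    if noise_level > 0:
        sig_rms = float(np.sqrt(np.mean(out**2)))
        out = out + rng.standard_normal(n_total) * (noise_level * sig_rms)
    return np.clip(out, -1.0, 1.0)


def _zipf_counts(n_words: int, total: int, exponent: float) -> np.ndarray:
    """Integer per-word counts following rank^-exponent, summing to ``total``.

    Every word receives at least one exemplar; the remainder is apportioned by
    largest remainders so the realized rank-frequency curve tracks the law.
    """
    ranks = np.arange(1, n_words + 1, dtype=float)
    weights = ranks ** (-exponent)
    weights /= weights.sum()
    base = np.ones(n_words, dtype=int)
    rest = total - n_words
    if rest < 0:
        raise ValueError("total must be >= n_words")
    ideal = weights * rest
    counts = base + np.floor(ideal).astype(int)
    short = total - counts.sum()
    frac = ideal - np.floor(ideal)
    for idx in np.argsort(-frac)[:short]:
        counts[idx] += 1
    return counts


def sample_corpus(
    lexicon: Lexicon,
    templates: dict[str, WordTemplate],
    n_train: int = 200,
    n_test: int = 100,
    zipf_exponent: float = 1.0,
    seed: int = 0,
    sample_rate: int = 16000,
    duration: float = 1.0,
    speaker_shift: float = 0.06,
    noise_level: float = 0.3,
    amplitude_jitter: float = 0.6,
    timing_jitter: float = 0.1,
) -> Corpus:
    """Draw a train/test corpus with Zipf-distributed per-word counts.

    Word ranks follow lexicon order (first word most frequent).  Train and
    test exemplars are disjoint (distinct seeds).  Deterministic given seed.
    """
    n_words = len(lexicon.words)
    if n_train < n_words or n_test < n_words:
        raise ValueError("need n_train and n_test >= number of words")
    exemplars: list[Exemplar] = []
    counts: dict[str, int] = {}
    for split, total in (("train", n_train), ("test", n_test)):
        per_word = _zipf_counts(n_words, total, zipf_exponent)
        for word, c in zip(lexicon.words, per_word):
            counts[word] = counts.get(word, 0) + int(c)
            for k in range(int(c)):
                ex_id = f"{word}_{split}_{k:05d}"
                exemplars.append(
                    Exemplar(
                        word=word,
                        split=split,
                        seed=child_seed(seed, "exemplar", ex_id),
                        exemplar_id=ex_id,
                    )
                )
    return Corpus(
        lexicon=lexicon,
        templates=templates,
        exemplars=exemplars,
        sample_rate=sample_rate,
        duration=duration,
        speaker_shift=speaker_shift,
        noise_level=noise_level,
        amplitude_jitter=amplitude_jitter,
        timing_jitter=timing_jitter,
        counts=counts,
    )


def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write 16-bit PCM mono WAVs in ``<word>/<id>.wav`` layout plus manifest.

    Returns the manifest path (CSV with columns path, word, split).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "word", "split"])
        for ex in corpus.exemplars:
            wav = corpus.render(ex)
            rel = Path(ex.word) / f"{ex.exemplar_id}.wav"
            (out_dir / ex.word).mkdir(exist_ok=True)
            wavfile.write(out_dir / rel, corpus.sample_rate, np.round(wav * 32767).astype(np.int16))
            writer.writerow([str(rel), ex.word, ex.split])
    return manifest


def read_corpus_manifest(manifest: str | Path):
    """Read a manifest written by :func:`write_corpus` (or user-supplied).

    Yields ``(waveform, sample_rate, word, split)`` tuples; waveforms are
    rescaled to float in [-1, 1].
    """
    manifest = Path(manifest)
    root = manifest.parent
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sr, data = wavfile.read(root / row["path"])
            if data.dtype == np.int16:
                data = data.astype(np.float64) / 32768.0
            yield data, sr, row["word"], row["split"]
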