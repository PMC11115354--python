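"""Reference results of the full-scale simulation study.

The scaled-down synthetic profile in this package emulates a full-scale
design: nine ResNet-18 networks (three maturation conditions x three
replicates) trained at batch size 1 on 4,000 one-second natural spoken-word
exemplars per epoch for 10 epochs, drawn from a 35-word keyword corpus, and
tested on 1,000 matched exemplars.  The constants below are the published
outcomes of that design.  They are directional references: the desk-scale
synthetic profile reproduces the qualitative pattern (condition orderings,
confusion structure, item effects), not these exact numbers, which depend on
the natural-speech corpus and full-scale training.
"""

from __future__ import annotations

import math

import numpy as np

from .behavior import ConfusionTable

#: The 35-word keyword lexicon of the full-scale corpus.
SPEECH_COMMANDS_WORDS = (
    "backward", "bed", "bird", "cat", "dog", "down", "eight", "five",
    "follow", "forward", "four", "go", "happy", "house", "learn", "left",
    "marvin", "nine", "no", "off", "on", "one", "right", "seven", "sheila",
    "six", "stop", "three", "tree", "two", "up", "visual", "wow", "yes",
    "zero",
)

#: Top-10 confusion cells at test, regular condition:
#: (true word, total misclassifications of that word, predicted word,
#:  cell count, cell count as % of the word's total misclassifications).
REGULAR_TOP_CONFUSIONS = (
    ("tree", 66, "three", 17, 25.76),
    ("no", 141, "go", 26, 18.44),
    ("follow", 54, "four", 7, 12.96),
    ("go", 78, "no", 10, 12.82),
    ("up", 72, "off", 9, 12.5),
    ("house", 75, "off", 8, 10.67),
    ("four", 69, "forward", 7, 10.14),
    ("five", 123, "on", 10, 8.13),
    ("one", 90, "nine", 7, 7.78),
    ("off", 93, "on", 7, 7.53),
)

#: Top-10 confusion cells at test, delay condition.  Note that "no"
#: contributes two rows (competitors "go" and "down"): the ranked unit is the
#: confusion cell, not the word.
DELAY_TOP_CONFUSIONS = (
    ("tree", 66, "three", 17, 25.76),
    ("no", 141, "go", 30, 21.28),
    ("go", 78, "no", 13, 16.67),
    ("four", 69, "forward", 10, 14.49),
    ("five", 123, "on", 16, 13.01),
    ("on", 132, "five", 16, 12.12),
    ("right", 108, "five", 10, 9.26),
    ("two", 114, "go", 10, 8.77),
    ("three", 114, "eight", 9, 7.89),
    ("no", 141, "down", 9, 6.38),
)

#: Full-scale aggregate outcomes by condition (control, regular, delay).
FULL_SCALE = {
    "train_accuracy_pct": {"control": 85.3, "regular": 80.6, "delay": 76.8},
    "test_accuracy_pct": {"control": 85.1, "regular": 83.9, "delay": 79.6},
    "mean_max_probability_pct": {"control": 86.7, "regular": 81.5, "delay": 78.6},
    "mean_entropy_bits": {"control": 0.443, "regular": 0.612, "delay": 0.693},
    "hits_mean_max_probability_pct": {"control": 91.4, "regular": 87.2, "delay": 85.3},
    "hits_mean_entropy_bits": {"control": 0.306, "regular": 0.449, "delay": 0.496},
    # per-word regular-minus-delay accuracy differential extremes
    "differential_max_pct": 24.6,  # "cat"
    "differential_min_pct": -11.11,  # "wow"
    # item-regression posterior means (reference magnitudes)
    "beta_frequency": 2.11,
    "beta_distance": 2.82,
    "uniform_entropy_bits": round(math.log2(35), 4),  # 5.1293
}


def reconstruct_confusion(rows, labels=SPEECH_COMMANDS_WORDS, hits_per_word=200) -> ConfusionTable:
    """A confusion table consistent with a printed top-confusion list.

    Each listed cell is placed exactly; the remainder of each listed word's
    total misclassifications is spread across unlisted competitors in counts
    strictly below the smallest listed proportion, so the listed cells are
    exactly the table's top cells.  Words without listed rows are given no
    misclassifications.  Used to recompute the printed proportions through
    the package's own ranking arithmetic.
    """
    from fractions import Fraction

    index = {w: i for i, w in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    p_min = min(Fraction(r[3], r[1]) for r in rows)  # exact smallest listed proportion
    totals: dict[str, int] = {}
    placed: dict[str, list[str]] = {}
    for word, total, competitor, cell, _ in rows:
        totals[word] = total
        counts[index[word], index[competitor]] = cell
        placed.setdefault(word, []).append(competitor)
    for word, total in totals.items():
        # largest cell count strictly below the smallest listed proportion
        bound = p_min * total
        cap = int(bound) - 1 if bound.denominator == 1 else int(bound)
        if cap < 1:
            raise ValueError(f"cannot spread remainder for {word!r} below {p_min}")
        remainder = total - sum(
            counts[index[word], index[c]] for c in placed[word]
        )
        fillers = [w for w in labels if w != word and w not in placed[word]]
        k = 0
        while remainder > 0:
            take = min(cap - counts[index[word], index[fillers[k]]], remainder)
            counts[index[word], index[fillers[k]]] += take
            remainder -= take
            k += 1
            if k >= len(fillers):
                raise ValueError(f"remainder for {word!r} does not fit below {p_min}%")
    for w in labels:
        counts[index[w], index[w]] = hits_per_word
    return ConfusionTable(counts=counts, labels=tuple(labels))
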