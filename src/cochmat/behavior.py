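"""Behavioral outcome measures.

Accuracy, maximum assigned probability and predictive-distribution entropy
(overall and hits-only), confusion tables, ranked misclassification summaries
and the regular-minus-delay per-word accuracy differential.  High-entropy,
low-max-probability predictive distributions operationalize word-finding
uncertainty: more of the lexicon is active when a classification is made.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "entropy_bits",
    "summarize_test",
    "confusion",
    "top_misclassifications",
    "accuracy_differential",
    "per_word_accuracy",
    "ConfusionTable",
    "MisclassRow",
]


def entropy_bits(p, tol: float = 1e-6) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < -tol):
        raise ValueError("negative probabilities")
    s = p.sum()
    if abs(s - 1.0) > max(tol, 1e-6):
        raise ValueError(f"probabilities sum to {s}, not 1")
    p = np.clip(p, 0.0, None)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def summarize_test(results, labels) -> tuple[pd.DataFrame, dict]:
    """Per-trial records and aggregate certainty metrics.

    Parameters
    ----------
    results:
        Sequence of :class:`cochmat.training.PredictiveDistribution`.
    labels:
        True word per trial (same length as ``results``).

    Returns
    -------
    (trials, aggregates):
        ``trials`` has columns true_word, predicted_word, max_probability,
        entropy_bits, hit.  ``aggregates`` reports accuracy, mean max
        probability and mean entropy over all trials and over hits only.
    """
    if len(results) != len(labels):
        raise ValueError("results and labels must have equal length")
    rows = []
    for r, true in zip(results, labels):
        rows.append(
            dict(
                true_word=true,
                predicted_word=r.predicted_word,
                max_probability=r.max_probability,
                entropy_bits=entropy_bits(r.probabilities),
                hit=r.predicted_word == true,
            )
        )
    trials = pd.DataFrame(rows)
    hits = trials[trials["hit"]]
    aggregates = {
        "accuracy": float(trials["hit"].mean()) if len(trials) else float("nan"),
        "mean_max_probability": float(trials["max_probability"].mean()),
        "mean_entropy_bits": float(trials["entropy_bits"].mean()),
        "hits_mean_max_probability": float(hits["max_probability"].mean()) if len(hits) else float("nan"),
        "hits_mean_entropy_bits": float(hits["entropy_bits"].mean()) if len(hits) else float("nan"),
        "n_trials": int(len(trials)),
        "n_hits": int(len(hits)),
    }
    return trials, aggregates


@dataclass(frozen=True)
class ConfusionTable:
    """W x W count matrix indexed (true word, predicted word)."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def row_total_misclassifications(self) -> dict[str, int]:
        off = self.counts - np.diag(np.diag(self.counts))
        return {w: int(t) for w, t in zip(self.labels, off.sum(axis=1))}


def confusion(true_words, predicted_words, labels) -> ConfusionTable:
    """Counts of (true, predicted) pairs over a fixed label order."""
    index = {w: i for i, w in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_words, predicted_words):
        if t not in index or p not in index:
            raise KeyError(f"unknown label in trial ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionTable(counts=counts, labels=tuple(labels))


@dataclass(frozen=True)
class MisclassRow:
    word: str
    total_misclassifications: int
    misclassified_as: str
    count: int
    proportion_percent: float


def _round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def top_misclassifications(table: ConfusionTable, k: int = 10) -> list[MisclassRow]:
    """Top-``k`` off-diagonal confusion cells ranked by proportion.

    Each row reports one (true word, predicted word) confusion cell: the true
    word's total misclassification count, the competitor, the cell count, and
    the cell count as a percentage of the word's total misclassifications
    (2 decimals).  A word can therefore contribute more than one row when
    several of its competitors rank highly.  Cells with zero count (and words
    never misclassified) are excluded; ties are broken by lexicon order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = table.row_total_misclassifications()
    rows = []
    for i, w in enumerate(table.labels):
        if totals[w] == 0:
            continue
        for j, comp in enumerate(table.labels):
            if i == j or table.counts[i, j] == 0:
                continue
            c = int(table.counts[i, j])
            rows.append(
                MisclassRow(
                    word=w,
                    total_misclassifications=totals[w],
                    misclassified_as=comp,
                    count=c,
                    proportion_percent=_round2(100.0 * c / totals[w]),
                )
            )
    rows.sort(key=lambda r: (-r.proportion_percent, table.labels.index(r.word), table.labels.index(r.misclassified_as)))
    return rows[:k]


def per_word_accuracy(trials: pd.DataFrame) -> dict[str, float]:
    """Percent correct per true word on one set of trial records."""
    grouped = trials.groupby("true_word")["hit"].mean() * 100.0
    return {w: float(v) for w, v in grouped.items()}


def accuracy_differential(
    per_word_acc_regular: dict[str, float], per_word_acc_delay: dict[str, float]
) -> dict[str, float]:
    """Regular minus delay per-word accuracy, in percentage points.

    Positive values mark a regular-condition advantage.
    """
    if set(per_word_acc_regular) != set(per_word_acc_delay):
        raise KeyError("regular and delay accuracy maps must share the same words")
    return {w: per_word_acc_regular[w] - per_word_acc_delay[w] for w in per_word_acc_regular}
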