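import math

import numpy as np
import pytest

from cochmat.behavior import (
    accuracy_differential,
    confusion,
    entropy_bits,
    per_word_accuracy,
    summarize_test,
    top_misclassifications,
)
from cochmat.training import PredictiveDistribution


@pytest.mark.parametrize(
    "p, expected",
    [
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.5, 0.0, 0.0], 1.0),
        (np.full(35, 1 / 35), math.log2(35)),
        ([0.25] * 4, 2.0),
    ],
)
def test_entropy_closed_forms(p, expected):
    assert entropy_bits(p) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_invalid_input():
    with pytest.raises(ValueError):
        entropy_bits([0.5, 0.6])
    with pytest.raises(ValueError):
        entropy_bits([1.2, -0.2])


def _pd(probs, labels):
    probs = np.asarray(probs, dtype=float)
    return PredictiveDistribution(
        probabilities=probs, labels=tuple(labels), predicted_word=labels[int(np.argmax(probs))]
    )


def test_summarize_test_hand_fixture():
    labels = ["a", "b", "c"]
    results = [
        _pd([1.0, 0.0, 0.0], labels),  # hit on a, H=0, maxp=1
        _pd([0.5, 0.5, 0.0], labels),  # tie -> a predicted; true b -> miss, H=1
        _pd([0.1, 0.8, 0.1], labels),  # hit on b
        _pd([1 / 3, 1 / 3, 1 / 3], labels),  # uniform, true c -> miss
    ]
    trials, agg = summarize_test(results, ["a", "b", "b", "c"])
    assert agg["accuracy"] == pytest.approx(0.5)
    h_unif = math.log2(3)
    h_08 = entropy_bits([0.1, 0.8, 0.1])
    assert agg["mean_entropy_bits"] == pytest.approx((0 + 1 + h_08 + h_unif) / 4)
    assert agg["mean_max_probability"] == pytest.approx((1.0 + 0.5 + 0.8 + 1 / 3) / 4)
    assert agg["hits_mean_max_probability"] == pytest.approx((1.0 + 0.8) / 2)
    assert agg["hits_mean_entropy_bits"] == pytest.approx((0 + h_08) / 2)
    assert agg["n_hits"] == 2
    assert (trials["hit"] == [True, False, True, False]).all()
    with pytest.raises(ValueError):
        summarize_test(results, ["a"])


def test_confusion_counts():
    labels = ["a", "b", "c"]
    t = confusion(["a", "b", "a"], ["a", "c", "b"], labels)
    expected = np.array([[1, 1, 0], [0, 0, 1], [0, 0, 0]])
    np.testing.assert_array_equal(t.counts, expected)
    assert t.counts.sum() == 3
    perfect = confusion(labels, labels, labels)
    assert np.all(perfect.counts == np.eye(3, dtype=int))
    with pytest.raises(KeyError):
        confusion(["a"], ["z"], labels)


def test_top_misclassifications_ranking_and_rounding():
    labels = ["tree", "three", "no", "go", "up"]
    trials_true, trials_pred = [], []

    def add(true, pred, n):
        trials_true.extend([true] * n)
        trials_pred.extend([pred] * n)

    add("tree", "three", 17)
    add("tree", "no", 49)  # spread as one competitor for simplicity
    add("no", "go", 26)
    add("no", "up", 115)
    add("up", "go", 1)
    table = confusion(trials_true, trials_pred, labels)
    rows = top_misclassifications(table, k=10)
    as_tuples = [(r.word, r.misclassified_as, r.total_misclassifications, r.count, r.proportion_percent) for r in rows]
    # ranked by proportion descending; a word may appear more than once
    assert as_tuples[0] == ("up", "go", 1, 1, 100.0)
    assert ("tree", "no", 66, 49, 74.24) in as_tuples
    assert ("no", "up", 141, 115, 81.56) in as_tuples
    assert ("tree", "three", 66, 17, 25.76) in as_tuples
    assert ("no", "go", 141, 26, 18.44) in as_tuples
    props = [r.proportion_percent for r in rows]
    assert props == sorted(props, reverse=True)
    for r in rows:
        assert r.count <= r.total_misclassifications
    with pytest.raises(ValueError):
        top_misclassifications(table, k=0)


def test_top_misclassifications_excludes_clean_words():
    labels = ["a", "b", "c"]
    table = confusion(["a", "b", "c"], ["a", "b", "c"], labels)
    assert top_misclassifications(table, k=5) == []


def test_accuracy_differential():
    assert accuracy_differential({"w": 80.0}, {"w": 80.0}) == {"w": 0.0}
    assert accuracy_differential({"w": 80.0}, {"w": 60.0}) == {"w": 20.0}
    d = accuracy_differential({"w": 50.0}, {"w": 61.11})
    assert d["w"] == pytest.approx(-11.11)
    with pytest.raises(KeyError):
        accuracy_differential({"w": 1.0}, {"v": 1.0})


def test_per_word_accuracy():
    labels = ["a", "b"]
    results = [_pd([1, 0], labels), _pd([1, 0], labels), _pd([0, 1], labels)]
    trials, _ = summarize_test(results, ["a", "b", "b"])
    acc = per_word_accuracy(trials)
    assert acc == {"a": 100.0, "b": 50.0}
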