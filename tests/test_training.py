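import copy
import dataclasses

import numpy as np
import pytest

from cochmat._net import ReducedNet, cross_entropy_grad
from cochmat.cochlea import make_schedule
from cochmat.synthgen import make_lexicon, make_templates, sample_corpus
from cochmat.training import (
    CochleagramCache,
    NetworkSpec,
    TrainConfig,
    build_matched_networks,
    build_network,
    epoch_sample,
    extract_activations,
    predict,
    train_condition,
)


def _params_equal(a, b):
    return all(np.array_equal(p1, p2) for (p1, _), (p2, _) in zip(a.parameters(), b.parameters()))


def test_matched_networks_are_identical():
    spec = NetworkSpec("reduced", n_classes=5, init_seed=11)
    nets = build_matched_networks(spec, 3)
    assert len(nets) == 3
    assert _params_equal(nets[0], nets[1]) and _params_equal(nets[0], nets[2])
    x = np.random.default_rng(0).random((100, 100))
    dists = [predict(n, x, [f"w{i}" for i in range(5)]) for n in nets]
    for d in dists[1:]:
        np.testing.assert_array_equal(d.probabilities, dists[0].probabilities)
    # same seed -> same build; different seed -> at least one differing parameter
    assert _params_equal(build_network(spec), nets[0])
    other = build_network(dataclasses.replace(spec, init_seed=12))
    assert not _params_equal(other, nets[0])


def test_predict_contract():
    net = build_network(NetworkSpec("reduced", n_classes=6, init_seed=0))
    labels = [f"w{i}" for i in range(6)]
    d = predict(net, np.random.default_rng(1).random((100, 100)), labels)
    assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(d.probabilities >= 0)
    assert d.probabilities[labels.index(d.predicted_word)] == d.probabilities.max()


def test_predict_argmax_breaks_ties_by_lowest_index():
    class Stub:
        def forward_probes(self, x, probes=False):
            return np.array([[1.0, 2.0, 2.0, 0.0]]), {}

    d = predict(Stub(), np.zeros((100, 100)), ["a", "b", "c", "d"])
    assert d.predicted_word == "b"


def test_epoch_sample_is_matched_and_epoch_dependent(corpus_small):
    s1 = epoch_sample(corpus_small, epoch=1, n=10, master_seed=5)
    s2 = epoch_sample(corpus_small, epoch=1, n=10, master_seed=5)
    assert [e.exemplar_id for e in s1] == [e.exemplar_id for e in s2]
    s3 = epoch_sample(corpus_small, epoch=2, n=10, master_seed=5)
    assert [e.exemplar_id for e in s1] != [e.exemplar_id for e in s3]
    full = epoch_sample(corpus_small, epoch=1, n=24, master_seed=5)
    assert sorted(e.exemplar_id for e in full) == sorted(
        e.exemplar_id for e in corpus_small.split_exemplars("train")
    )
    with pytest.raises(ValueError):
        epoch_sample(corpus_small, epoch=1, n=25, master_seed=5)


@pytest.fixture(scope="module")
def two_word_setup():
    lex = make_lexicon(2, 0, seed=4)
    tpl = make_templates(lex, seed=4)
    corpus = sample_corpus(lex, tpl, n_train=20, n_test=2, zipf_exponent=0.0, seed=4)
    return corpus, CochleagramCache(corpus)


def test_zero_epochs_leaves_network_unchanged(two_word_setup):
    corpus, cache = two_word_setup
    net = build_network(NetworkSpec("reduced", n_classes=2, init_seed=0))
    before = copy.deepcopy(net)
    cfg = TrainConfig(n_epochs=0, n_train_per_epoch=20, n_test=2, master_seed=0)
    net, logs = train_condition(net, corpus, make_schedule("control", 0), cfg, cache=cache)
    assert logs == []
    assert _params_equal(net, before)


def test_training_overfits_small_corpus(two_word_setup):
    corpus, cache = two_word_setup
    net = build_network(NetworkSpec("reduced", n_classes=2, init_seed=0))
    cfg = TrainConfig(n_epochs=30, n_train_per_epoch=20, n_test=2, master_seed=0)
    net, logs = train_condition(net, corpus, make_schedule("control", 30), cfg, cache=cache)
    assert logs[-1].train_accuracy >= 0.9
    assert logs[-1].mean_loss < logs[0].mean_loss


def test_training_is_deterministic(two_word_setup):
    corpus, cache = two_word_setup
    cfg = TrainConfig(n_epochs=2, n_train_per_epoch=20, n_test=2, master_seed=9)
    sched = make_schedule("regular", 2)
    runs = []
    for _ in range(2):
        net = build_network(NetworkSpec("reduced", n_classes=2, init_seed=3))
        runs.append(train_condition(net, corpus, sched, cfg, cache=cache))
    (n1, l1), (n2, l2) = runs
    assert l1 == l2
    assert _params_equal(n1, n2)


def test_class_count_mismatch_rejected(two_word_setup):
    corpus, cache = two_word_setup
    net = build_network(NetworkSpec("reduced", n_classes=7, init_seed=0))
    cfg = TrainConfig(n_epochs=1, n_train_per_epoch=20, n_test=2)
    with pytest.raises(ValueError):
        train_condition(net, corpus, make_schedule("control", 1), cfg, cache=cache)


def test_extract_activations_bookkeeping():
    net = build_network(NetworkSpec("reduced", n_classes=3, init_seed=0))
    rng = np.random.default_rng(2)
    stim = [rng.random((100, 100)) for _ in range(3)]
    stim.append(stim[0].copy())  # duplicate stimulus
    acts = extract_activations(net, stim, ["a", "b", "c", "a"])
    assert acts.layer_ids == net.conv_layer_ids == ["conv1", "conv2", "conv3", "conv4"]
    for layer in acts.layer_ids:
        assert acts.activations[layer].shape[0] == 4
        np.testing.assert_array_equal(acts.activations[layer][0], acts.activations[layer][3])
    with pytest.raises(KeyError):
        extract_activations(net, stim, ["a", "b", "c", "a"], layer_ids=["conv9"])


def test_resnet_variant_exposes_twenty_conv_layers():
    net = build_network(NetworkSpec("resnet18", n_classes=35, init_seed=0))
    assert len(net.conv_layer_ids) == 20
    assert net.conv_layer_ids[-1] == "conv20"
    x = np.random.default_rng(0).random((100, 100))
    acts = extract_activations(net, [x], ["w"])
    assert set(acts.activations) == set(net.conv_layer_ids)
    # conv20 is the final post-activation response before the classifier
    assert acts.activations["conv20"].shape[1] == 512 * 4 * 4


def test_backprop_matches_numeric_gradient():
    net = ReducedNet(3, init_seed=0, widths=(2, 3), input_hw=(12, 12))
    x = np.random.default_rng(0).standard_normal((2, 1, 12, 12)).astype(np.float32)
    targets = np.array([0, 2])

    def loss():
        logits, _ = net.forward_probes(x, probes=False)
        return cross_entropy_grad(logits, targets)[0]

    logits, _ = net.forward_probes(x, probes=False)
    _, dlogits = cross_entropy_grad(logits, targets)
    net.zero_grad()
    net.backward(dlogits)
    rng = np.random.default_rng(1)
    eps = 1e-3
    for p, g in net.parameters():
        flat, gflat = p.ravel(), g.ravel()
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[i]) <= 2e-2 * max(1.0, abs(num))
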