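"""Matched-network training under maturation schedules.

Three identical-initialization classifiers are trained, one per maturation
condition.  Within a training epoch all conditions see the same random sample
of exemplars in the same order; the only cross-condition difference in the
execution trace is the height ``y`` of the frequency-axis blur kernel applied
to each cochleagram before it enters the network.  Weights are updated by
plain SGD after every exposure (batch size 1) on the cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import _net
from ._seeds import child_seed, substream
from .cochlea import Cochleagram, CochleagramConfig, MaturationSchedule, cochleagram, kernel_height
from .synthgen import Corpus, Exemplar

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "PredictiveDistribution",
    "EpochLog",
    "CochleagramCache",
    "build_network",
    "build_matched_networks",
    "epoch_sample",
    "train_condition",
    "predict",
    "extract_activations",
    "ActivationSet",
]


@dataclass(frozen=True)
class NetworkSpec:
    architecture: str = "reduced"  # "reduced" | "resnet18"
    n_classes: int = 10
    init_seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """Training regime; defaults mirror the full-scale study design."""

    n_epochs: int = 10
    n_train_per_epoch: int = 4000
    n_test: int = 1000
    batch_size: int = 1
    learning_rate: float = 0.01
    optimizer: str = "sgd"
    master_seed: int = 0
    n_replicates: int = 3


@dataclass(frozen=True)
class PredictiveDistribution:
    """Probability vector over the lexicon plus its argmax word."""

    probabilities: np.ndarray
    labels: tuple[str, ...]
    predicted_word: str

    @property
    def max_probability(self) -> float:
        return float(self.probabilities.max())


@dataclass(frozen=True)
class EpochLog:
    condition: str
    replicate: int
    epoch: int
    kernel_height: int
    train_accuracy: float
    mean_loss: float


@dataclass
class ActivationSet:
    """Per-layer flattened post-activation matrices with stimulus labels."""

    activations: dict[str, np.ndarray]  # layer id -> (n_stimuli, n_features)
    labels: list[str]
    layer_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.layer_ids:
            self.layer_ids = list(self.activations)


def build_network(spec: NetworkSpec):
    if spec.architecture == "reduced":
        return _net.ReducedNet(spec.n_classes, init_seed=spec.init_seed)
    if spec.architecture == "resnet18":
        return _net.ResNet18(spec.n_classes, init_seed=spec.init_seed)
    raise ValueError(f"unknown architecture {spec.architecture!r}")


def build_matched_networks(spec: NetworkSpec, n_conditions: int = 3):
    """Networks with element-wise identical parameters at creation."""
    proto = build_network(spec)
    return [proto] + [proto.clone() for _ in range(n_conditions - 1)]


class CochleagramCache:
    """Computes each exemplar's cochleagram once; serves blurred copies.

    Blurring is applied to the (compressed) cochleagram image with a
    normalized box kernel along the frequency axis, matching
    :func:`cochmat.cochlea.blur`.
    """

    def __init__(self, corpus: Corpus, config: CochleagramConfig | None = None):
        self.corpus = corpus
        self.config = config or CochleagramConfig()
        self._store: dict[str, np.ndarray] = {}

    def image(self, exemplar: Exemplar) -> np.ndarray:
        arr = self._store.get(exemplar.exemplar_id)
        if arr is None:
            c = cochleagram(self.corpus.render(exemplar), self.corpus.sample_rate, self.config)
            arr = c.values.astype(np.float32)
            self._store[exemplar.exemplar_id] = arr
        return arr

    def batch(self, exemplars: list[Exemplar], y: int) -> np.ndarray:
        """(B, 1, n_channels, n_frames) stack blurred with kernel height y."""
        stack = np.stack([self.image(e) for e in exemplars])[:, None]
        if y > 1:
            stack = uniform_filter1d(stack, size=int(y), axis=2, mode="reflect")
        return stack


def epoch_sample(corpus: Corpus, epoch: int, n: int, master_seed: int) -> list[Exemplar]:
    """The matched training sample for one epoch.

    Depends only on ``(corpus, epoch, n, master_seed)``, so every condition
    trained with the same master seed sees the identical ordered sample.
    Sampling is without replacement.
    """
    train = corpus.split_exemplars("train")
    if n > len(train):
        raise ValueError(f"requested {n} exemplars from a training split of {len(train)}")
    rng = substream(master_seed, "epoch-sample", epoch)
    idx = rng.choice(len(train), size=n, replace=False)
    return [train[i] for i in idx]


def test_sample(corpus: Corpus, n: int, master_seed: int) -> list[Exemplar]:
    """Matched test sample (shared across conditions and replicates)."""
    test = corpus.split_exemplars("test")
    if n > len(test):
        raise ValueError(f"requested {n} exemplars from a test split of {len(test)}")
    rng = substream(master_seed, "test-sample")
    idx = rng.choice(len(test), size=n, replace=False)
    return [test[i] for i in idx]


def train_condition(
    network,
    corpus: Corpus,
    schedule: MaturationSchedule,
    config: TrainConfig,
    replicate: int = 1,
    cache: CochleagramCache | None = None,
) -> tuple[object, list[EpochLog]]:
    """Train one network under one maturation schedule.

    Every sampled exemplar is cochleagram-transformed, blurred with the
    epoch's kernel height, forward-passed, and the cross-entropy loss
    backpropagated per batch (default batch size 1).  Returns the trained
    network and one :class:`EpochLog` per epoch.  Fully reproducible given
    ``config.master_seed``.
    """
    labels = list(corpus.lexicon.words)
    index = {w: i for i, w in enumerate(labels)}
    if getattr(network, "n_classes", None) != len(labels):
        raise ValueError("network class count does not match lexicon size")
    cache = cache or CochleagramCache(corpus)
    logs: list[EpochLog] = []
    for epoch in range(1, config.n_epochs + 1):
        y = kernel_height(schedule, epoch)
        sample = epoch_sample(corpus, epoch, config.n_train_per_epoch, config.master_seed)
        hits, losses = 0, []
        bs = max(1, config.batch_size)
        for start in range(0, len(sample), bs):
            chunk = sample[start : start + bs]
            x = cache.batch(chunk, y)
            targets = np.array([index[e.word] for e in chunk])
            logits, _ = network.forward_probes(x, probes=False)
            loss, dlogits = _net.cross_entropy_grad(logits, targets)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, exposure {start} "
                    f"(condition {schedule.condition})"
                )
            hits += int(np.sum(logits.argmax(axis=1) == targets))
            losses.append(loss)
            network.zero_grad()
            network.backward(dlogits)
            network.sgd_step(config.learning_rate)
        logs.append(
            EpochLog(
                condition=schedule.condition,
                replicate=replicate,
                epoch=epoch,
                kernel_height=y,
                train_accuracy=hits / max(1, len(sample)),
                mean_loss=float(np.mean(losses)) if losses else float("nan"),
            )
        )
    return network, logs


def predict(network, c, labels) -> PredictiveDistribution:
    """Predictive distribution for one cochleagram (argmax, lowest-index ties)."""
    values = c.values if isinstance(c, Cochleagram) else np.asarray(c)
    if values.ndim != 2:
        raise ValueError("expected a single 2-D cochleagram")
    logits, _ = network.forward_probes(values[None, None], probes=False)
    p = _net.softmax(logits)[0]
    return PredictiveDistribution(
        probabilities=p, labels=tuple(labels), predicted_word=labels[int(np.argmax(p))]
    )


def extract_activations(network, stimuli, labels, layer_ids=None) -> ActivationSet:
    """Flattened post-activation responses, one row per stimulus per layer."""
    layer_ids = list(layer_ids or network.conv_layer_ids)
    bad = [l for l in layer_ids if l not in network.conv_layer_ids]
    if bad:
        raise KeyError(f"unknown layer ids {bad}; available: {network.conv_layer_ids}")
    rows: dict[str, list[np.ndarray]] = {l: [] for l in layer_ids}
    for c in stimuli:
        values = c.values if isinstance(c, Cochleagram) else np.asarray(c)
        _, acts = network.forward_probes(values[None, None], probes=True)
        for l in layer_ids:
            rows[l].append(acts[l][0])
    return ActivationSet(
        activations={l: np.stack(rows[l]) for l in layer_ids},
        labels=list(labels),
        layer_ids=layer_ids,
    )


def derive_init_seed(master_seed: int, replicate: int) -> int:
    """Weight-init seed for a replicate (shared across conditions)."""
    return child_seed(master_seed, "init", replicate)
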