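import dataclasses

import numpy as np
import pytest

from cochmat.pipeline import CorpusConfig, ExperimentConfig
from cochmat.synthgen import make_lexicon, make_templates, sample_corpus
from cochmat.training import NetworkSpec, TrainConfig


@pytest.fixture(scope="session")
def lexicon10():
    return make_lexicon(10, 2, seed=1)


@pytest.fixture(scope="session")
def templates10(lexicon10):
    return make_templates(lexicon10, seed=1)


@pytest.fixture(scope="session")
def corpus_small():
    """Small 4-word corpus for unit tests (cheap to render)."""
    lex = make_lexicon(4, 1, seed=2)
    tpl = make_templates(lex, seed=2)
    return sample_corpus(lex, tpl, n_train=24, n_test=8, zipf_exponent=0.5, seed=2)


def tiny_config(master_seed=3, analyses=("behavior",), n_replicates=1, n_epochs=2):
    """A minutes-scale-free configuration for pipeline bookkeeping tests."""
    return ExperimentConfig(
        corpus=CorpusConfig(n_words=4, n_neighbor_pairs=1, n_train=24, n_test=8),
        network=NetworkSpec(architecture="reduced", n_classes=4),
        train=TrainConfig(
            n_epochs=n_epochs, n_train_per_epoch=24, n_test=8, n_replicates=n_replicates
        ),
        manifold_exemplars_per_class=2,
        analyses=tuple(analyses),
        master_seed=master_seed,
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    from cochmat.pipeline import run_experiment

    return run_experiment(tiny_config())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
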