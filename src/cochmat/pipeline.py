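"""Experiment orchestration: conditions x replicates, analyses, outputs.

``run_experiment`` draws one synthetic corpus, trains matched networks under
the three maturation schedules (matched initializations per replicate,
matched per-epoch samples across conditions), evaluates each network on the
matched test sample at its condition's test-time resolution, and runs the
behavioral, item-level and manifold analyses.  All randomness flows from the
single ``master_seed`` through named substreams, so identical configurations
reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior
from ._seeds import child_seed
from .cochlea import CONDITIONS, CochleagramConfig, make_schedule
from .lexstats import RegressionPosterior, SamplerConfig, build_item_table, fit_item_regression
from .manifolds import ManifoldGeometry, MFTMAConfig, layer_trajectory
from .synthgen import make_lexicon, make_templates, sample_corpus
from .training import (
    CochleagramCache,
    NetworkSpec,
    TrainConfig,
    build_matched_networks,
    derive_init_seed,
    test_sample,
    train_condition,
)
from ._net import softmax

log = logging.getLogger("cochmat")

__all__ = ["CorpusConfig", "ExperimentConfig", "ResultBundle", "run_experiment", "compare_conditions"]


@dataclass(frozen=True)
class CorpusConfig:
    n_words: int = 10
    n_neighbor_pairs: int = 2
    n_train: int = 200
    n_test: int = 100
    zipf_exponent: float = 1.0
    speaker_shift: float = 0.06
    noise_level: float = 0.3
    amplitude_jitter: float = 0.6
    timing_jitter: float = 0.1
    sample_rate: int = 16000
    duration: float = 1.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Scaled-down profile by default; see :func:`paper_scale_config`."""

    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(architecture="reduced", n_classes=10))
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(n_epochs=6, n_train_per_epoch=200, n_test=100)
    )
    mftma: MFTMAConfig = field(default_factory=lambda: MFTMAConfig(random_projection_dim=500))
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    y_start: int = 25
    y_delay_end: int = 16
    manifold_exemplars_per_class: int = 12
    analyses: tuple[str, ...] = ("behavior", "items", "manifolds", "regression")
    master_seed: int = 0
    output_dir: str | None = None

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, cls in [
            ("corpus", CorpusConfig),
            ("network", NetworkSpec),
            ("train", TrainConfig),
            ("mftma", MFTMAConfig),
            ("sampler", SamplerConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = cls(**kwargs[key])
        if "analyses" in kwargs:
            kwargs["analyses"] = tuple(kwargs["analyses"])
        return ExperimentConfig(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def paper_scale_config(master_seed: int = 0) -> ExperimentConfig:
    """The full-scale replication profile of the original study design.

    ResNet-18 on a 35-word lexicon, 10 epochs of 4,000 exposures at batch
    size 1, 1,000 test trials, 3 replicates.  This profile needs the real
    spoken-word data set and long runtimes; it is provided as a named
    configuration, not a default.
    """
    return ExperimentConfig(
        corpus=CorpusConfig(n_words=35, n_neighbor_pairs=4, n_train=8000, n_test=2000),
        network=NetworkSpec(architecture="resnet18", n_classes=35),
        train=TrainConfig(n_epochs=10, n_train_per_epoch=4000, n_test=1000, n_replicates=3),
        mftma=MFTMAConfig(random_projection_dim=5000),
        manifold_exemplars_per_class=50,
        master_seed=master_seed,
    )


@dataclass
class ResultBundle:
    config: ExperimentConfig
    lexicon: object
    epoch_logs: pd.DataFrame
    test_trials: pd.DataFrame
    aggregates: pd.DataFrame  # one row per condition
    confusions: dict[str, behavior.ConfusionTable]
    top_misclass: dict[str, list[behavior.MisclassRow]]
    per_word_accuracy: dict[str, dict[str, float]]
    differential: dict[str, float]
    item_table: pd.DataFrame | None = None
    regression: RegressionPosterior | None = None
    manifolds: dict[str, ManifoldGeometry] = field(default_factory=dict)  # per-condition medians
    manifolds_by_replicate: dict[tuple[str, int], ManifoldGeometry] = field(default_factory=dict)
    corpus: object | None = None
    networks: dict[str, list] = field(default_factory=dict)  # condition -> per-replicate nets
    train_counts: dict[str, int] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)


def _evaluate(network, images: np.ndarray, labels: list[str], lexicon_words) -> pd.DataFrame:
    logits, _ = network.forward_probes(images, probes=False)
    probs = softmax(logits)
    rows = []
    for p, true in zip(probs, labels):
        k = int(np.argmax(p))
        nz = p[p > 0]
        rows.append(
            dict(
                true_word=true,
                predicted_word=lexicon_words[k],
                max_probability=float(p[k]),
                entropy_bits=float(-np.sum(nz * np.log2(nz))),
                hit=lexicon_words[k] == true,
            )
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig | None = None) -> ResultBundle:
    config = config or ExperimentConfig()
    cc = config.corpus
    seed = config.master_seed
    log.info("corpus: %d words, %d train / %d test", cc.n_words, cc.n_train, cc.n_test)
    lexicon = make_lexicon(cc.n_words, cc.n_neighbor_pairs, seed=child_seed(seed, "lexicon"))
    templates = make_templates(lexicon, seed=child_seed(seed, "templates"))
    corpus = sample_corpus(
        lexicon,
        templates,
        n_train=cc.n_train,
        n_test=cc.n_test,
        zipf_exponent=cc.zipf_exponent,
        seed=child_seed(seed, "corpus"),
        sample_rate=cc.sample_rate,
        duration=cc.duration,
        speaker_shift=cc.speaker_shift,
        noise_level=cc.noise_level,
        amplitude_jitter=cc.amplitude_jitter,
        timing_jitter=cc.timing_jitter,
    )
    if config.network.n_classes != cc.n_words:
        raise ValueError("network n_classes must equal corpus n_words")

    cache = CochleagramCache(corpus, CochleagramConfig())
    schedules = {c: make_schedule(c, config.train.n_epochs, config.y_start, config.y_delay_end) for c in CONDITIONS}
    test_ex = test_sample(corpus, config.train.n_test, seed)
    test_labels = [e.word for e in test_ex]
    test_images = {}  # per distinct y_test
    for sch in schedules.values():
        if sch.y_test not in test_images:
            test_images[sch.y_test] = cache.batch(test_ex, sch.y_test)

    words = list(lexicon.words)
    all_logs, all_trials = [], []
    train_counts: dict[str, int] = {w: 0 for w in words}
    nets_by_condition: dict[str, list] = {c: [] for c in CONDITIONS}

    for rep in range(1, config.train.n_replicates + 1):
        init_seed = derive_init_seed(seed, rep)
        spec = dataclasses.replace(config.network, init_seed=init_seed)
        nets = build_matched_networks(spec, len(CONDITIONS))
        rep_cfg = dataclasses.replace(config.train, master_seed=child_seed(seed, "train", rep))
        for cond, net in zip(CONDITIONS, nets):
            log.info("training replicate %d, condition %s", rep, cond)
            net, logs = train_condition(net, corpus, schedules[cond], rep_cfg, replicate=rep, cache=cache)
            all_logs.extend(dataclasses.asdict(l) for l in logs)
            trials = _evaluate(net, test_images[schedules[cond].y_test], test_labels, words)
            trials.insert(0, "condition", cond)
            trials.insert(1, "replicate", rep)
            all_trials.append(trials)
            nets_by_condition[cond].append(net)
        # matched sampling: identical across conditions, so count once per replicate
        from .training import epoch_sample

        for epoch in range(1, rep_cfg.n_epochs + 1):
            for e in epoch_sample(corpus, epoch, rep_cfg.n_train_per_epoch, rep_cfg.master_seed):
                train_counts[e.word] += 1

    epoch_logs = pd.DataFrame(all_logs)
    test_trials = pd.concat(all_trials, ignore_index=True)

    agg_rows, confusions, top_misclass, pwa = [], {}, {}, {}
    for cond in CONDITIONS:
        sub = test_trials[test_trials["condition"] == cond]
        hits = sub[sub["hit"]]
        agg_rows.append(
            dict(
                condition=cond,
                accuracy=float(sub["hit"].mean()),
                mean_max_probability=float(sub["max_probability"].mean()),
                mean_entropy_bits=float(sub["entropy_bits"].mean()),
                hits_mean_max_probability=float(hits["max_probability"].mean()),
                hits_mean_entropy_bits=float(hits["entropy_bits"].mean()),
                n_trials=int(len(sub)),
            )
        )
        confusions[cond] = behavior.confusion(sub["true_word"], sub["predicted_word"], words)
        top_misclass[cond] = behavior.top_misclassifications(confusions[cond], k=10)
        pwa[cond] = behavior.per_word_accuracy(sub)
    aggregates = pd.DataFrame(agg_rows).set_index("condition")
    differential = behavior.accuracy_differential(pwa["regular"], pwa["delay"])

    bundle = ResultBundle(
        config=config,
        lexicon=lexicon,
        epoch_logs=epoch_logs,
        test_trials=test_trials,
        aggregates=aggregates,
        confusions=confusions,
        top_misclass=top_misclass,
        per_word_accuracy=pwa,
        differential=differential,
        train_counts=train_counts,
        corpus=corpus,
        networks=nets_by_condition,
    )

    if "items" in config.analyses or "regression" in config.analyses:
        acc_by_cond = {c: pwa[c] for c in ("regular", "delay")}
        bundle.item_table = build_item_table(acc_by_cond, train_counts, lexicon)
    if "regression" in config.analyses:
        log.info("fitting item regression")
        sampler = dataclasses.replace(config.sampler, seed=child_seed(seed, "sampler"))
        bundle.regression = fit_item_regression(bundle.item_table, sampler)
    if "manifolds" in config.analyses:
        m_stimuli, m_labels = _manifold_stimuli(corpus, config, seed)
        mft = dataclasses.replace(config.mftma, seed=child_seed(seed, "mftma"))
        for cond in CONDITIONS:
            log.info("manifold analysis, condition %s", cond)
            imgs = list(cache.batch(m_stimuli, schedules[cond].y_test)[:, 0])
            frames = []
            for rep_idx, net in enumerate(nets_by_condition[cond], start=1):
                geom = layer_trajectory(net, imgs, m_labels, mft)
                bundle.manifolds_by_replicate[(cond, rep_idx)] = geom
                frames.append(geom.to_frame().set_index("layer"))
            med = pd.concat(frames).groupby(level=0, sort=False).median()
            med = med.loc[frames[0].index]  # keep forward layer order
            bundle.manifolds[cond] = ManifoldGeometry(
                layers=list(med.index),
                dimension=med["D_M"].to_dict(),
                radius=med["R_M"].to_dict(),
                capacity=med["capacity"].to_dict(),
            )

    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def _manifold_stimuli(corpus, config: ExperimentConfig, seed: int):
    """Class-balanced held-out probe set for the manifold analyses.

    Exemplars are drawn fresh from the corpus's generative distribution
    (disjoint seed substream, so they overlap neither split).  A balanced
    probe set is used rather than the Zipf-skewed test split because manifold
    statistics need the same, sufficiently large number of exemplars per
    class; the rarest test words would otherwise contribute manifolds
    estimated from a handful of points.
    """
    from .synthgen import Exemplar

    m = config.manifold_exemplars_per_class
    if m < 2:
        raise ValueError("need at least 2 probe exemplars per word for manifold analysis")
    chosen, labels = [], []
    for w in corpus.lexicon.words:
        for k in range(m):
            ex_id = f"{w}_probe_{k:05d}"
            chosen.append(
                Exemplar(word=w, split="probe", seed=child_seed(seed, "probe", ex_id), exemplar_id=ex_id)
            )
            labels.append(w)
    return chosen, labels


def compare_conditions(bundle: ResultBundle) -> dict:
    """Per-condition summary in the structure of the study's reporting.

    Returns a dict with the aggregate table (overall and hits-only columns),
    the per-word regular-minus-delay differential, the per-condition top-10
    misclassification tables, and final-epoch training accuracies.
    """
    final_epoch = bundle.epoch_logs["epoch"].max() if len(bundle.epoch_logs) else 0
    final = bundle.epoch_logs[bundle.epoch_logs["epoch"] == final_epoch]
    final_train = final.groupby("condition")["train_accuracy"].median().to_dict()
    top_tables = {
        cond: pd.DataFrame([dataclasses.asdict(r) for r in rows])
        for cond, rows in bundle.top_misclass.items()
    }
    return {
        "aggregates": bundle.aggregates,
        "final_train_accuracy": final_train,
        "differential": dict(sorted(bundle.differential.items(), key=lambda kv: -kv[1])),
        "top_misclassifications": top_tables,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: ResultBundle, out_dir) -> dict[str, str]:
    """Write all tables and a manifest of sha256 hashes; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.epoch_logs.to_csv(out / "epoch_logs.csv", index=False)
    bundle.test_trials.to_csv(out / "test_trials.csv", index=False)
    bundle.aggregates.to_csv(out / "aggregates.csv")
    for cond, tab in bundle.confusions.items():
        tab.to_frame().to_csv(out / f"confusion_{cond}.csv")
    for cond, rows in bundle.top_misclass.items():
        pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
            out / f"top_misclassifications_{cond}.csv", index=False
        )
    pd.Series(bundle.differential).rename("differential_pct").to_csv(out / "differential.csv")
    if bundle.item_table is not None:
        bundle.item_table.to_csv(out / "item_table.csv", index=False)
    if bundle.regression is not None:
        bundle.regression.summary.to_csv(out / "regression_summary.csv")
    for cond, geom in bundle.manifolds.items():
        geom.to_frame().to_csv(out / f"manifold_geometry_{cond}.csv", index=False)
    summary = {
        "aggregates": bundle.aggregates.to_dict(orient="index"),
        "differential": bundle.differential,
        "final_train_accuracy": compare_conditions(bundle)["final_train_accuracy"],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + [out / "summary.json"]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle.manifest = manifest
    return manifest
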