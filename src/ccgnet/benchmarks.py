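"""Reproducible desk-scale benchmark experiments on the synthetic family.

These drive the bundled quantitative checks: learnability of the planted
rule under realistic class imbalance and label noise, the feature-ablation
comparison, the order-swap augmentation property, and the transfer-learning
protocol on the shifted family. All problem sizes (library of 240
molecules, 600 labeled pairs at ~6.5:1 imbalance with 2% label noise,
3-fold cross-validation, a ~240-pair shifted set) and the compact
architecture are fixed here so tests and the acceptance script run the
same study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .graphdata import CCGraph, FeaturizerCache, stratified_kfold
from .network import CCGNetConfig
from .synthetic import (
    DEFAULT_RULE,
    SHIFTED_RULE,
    molecule_library,
    pairs_to_graphs,
    planted_pairs,
)
from .training import (
    TrainConfig,
    compute_metrics,
    cross_validate,
    evaluate,
    order_sensitivity,
    train,
)
from .transfer import TransferSpec, domain_shift_benchmark

__all__ = [
    "BENCH_ARCH",
    "bench_train_config",
    "benchmark_samples",
    "shifted_samples",
    "learnability_cv",
    "augmentation_experiment",
    "pretrain_models",
    "transfer_experiment",
]

# compact architecture for CPU-scale studies: same topology as the default,
# graph branch kept narrow because at hundreds of pairs it is the dominant
# overfitting source (see docs/methods.md)
BENCH_ARCH = dict(
    conv_widths=(4, 4, 4, 4),
    global_widths=(16, 16, 32, 32),
    attention_heads=2,
    attention_hidden=4,
    dense_head=(64, 32, 2),
)

LIBRARY_SIZE = 50
LIBRARY_SEED = 7
N_PAIRS = 600
LABEL_NOISE = 0.02
SHIFTED_PAIRS = 240
SHIFTED_TEST_PAIRS = 160


def bench_train_config(seed: int, mode: str = "MG+2D+3D", epochs: int = 30,
                       **over) -> TrainConfig:
    base = dict(epochs=epochs, batch_size=32, learning_rate=1e-3,
                weight_decay=1e-4, graph_weight_decay=2e-2,
                descriptor_jitter=0.0, seed=seed, feature_mode=mode, k_folds=3)
    base.update(over)
    return TrainConfig(**base)


def _library(cache: FeaturizerCache) -> list[str]:
    return molecule_library(LIBRARY_SIZE, seed=LIBRARY_SEED)


def benchmark_samples(cache: FeaturizerCache | None = None,
                      noise: float = LABEL_NOISE,
                      pair_seed: int = LIBRARY_SEED) -> list[CCGraph]:
    """The standard labeled benchmark set: 600 pairs, ~6.5:1, 2% label noise."""
    cache = cache or FeaturizerCache()
    rule = replace(DEFAULT_RULE, noise=noise)
    pairs = planted_pairs(_library(cache), N_PAIRS, rule=rule, seed=pair_seed,
                          cache=cache)
    return pairs_to_graphs(pairs, cache)


def shifted_samples(cache: FeaturizerCache | None = None, seed: int = 11,
                    m: int = SHIFTED_PAIRS, noise: float = 0.0) -> list[CCGraph]:
    """A domain-shifted labeled set drawn with the re-weighted rule."""
    cache = cache or FeaturizerCache()
    rule = replace(SHIFTED_RULE, noise=noise)
    pairs = planted_pairs(_library(cache), m, rule=rule, seed=seed, cache=cache)
    return pairs_to_graphs(pairs, cache)


def learnability_cv(samples: list[CCGraph], seed: int, mode: str = "MG+2D+3D",
                    epochs: int = 30) -> dict:
    """3-fold CV of the compact model on the benchmark set; returns the summary."""
    cfg = bench_train_config(seed, mode=mode, epochs=epochs)
    arch = CCGNetConfig(seed=seed, feature_mode=mode, **BENCH_ARCH)
    return cross_validate(samples, cfg, arch=arch)


def augmentation_experiment(samples: list[CCGraph], seed: int,
                            epochs: int = 25) -> dict:
    """Order-swap sensitivity with vs without augmentation on one split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(samples))
    split = int(0.8 * len(samples))
    tr = [samples[i] for i in idx[:split]]
    va = [samples[i] for i in idx[split:]]
    out = {}
    for label, aug in (("with_augmentation", True), ("without_augmentation", False)):
        cfg = bench_train_config(seed, epochs=epochs, augment=aug)
        model, _ = train(tr, cfg, arch=CCGNetConfig(seed=seed, **BENCH_ARCH))
        out[label] = order_sensitivity(model, va)
    return out


def pretrain_models(samples: list[CCGraph], n_models: int = 10, seed: int = 0,
                    epochs: int = 12) -> list:
    """Pretrained pool for transfer: bagged models over fold subsets."""
    folds = stratified_kfold(samples, max(2, n_models // 2), seed=seed)
    models = []
    for i in range(n_models):
        hold = i % folds.k
        tr = [s for s in samples if folds.fold_of(s) != hold]
        cfg = bench_train_config(seed + 100 + i, epochs=epochs)
        model, _ = train(tr, cfg, arch=CCGNetConfig(seed=seed + 100 + i, **BENCH_ARCH))
        models.append(model)
    return models


def transfer_experiment(pretrained: list, seed: int,
                        cache: FeaturizerCache | None = None,
                        finetune_epochs: int = 5) -> dict:
    """Direct-transfer vs finetuned-ensemble BACC on the shifted family."""
    cache = cache or FeaturizerCache()
    ft_set = shifted_samples(cache, seed=11 + seed, m=SHIFTED_PAIRS)
    test_set = shifted_samples(cache, seed=1100 + seed, m=SHIFTED_TEST_PAIRS)
    spec = TransferSpec(folds=5, ensemble_size=10, epochs=finetune_epochs,
                        batch_size=32, learning_rate=3e-4)
    return domain_shift_benchmark(pretrained, ft_set, test_set, spec=spec, seed=seed)
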