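"""Transfer learning for domain-shifted cocrystal families.

Protocol: take models pretrained on the large conventional-cocrystal (CC)
dataset, keep the CCGBlock, attention-readout and early dense weights as
initialization, randomly re-initialize the *last two* dense layers, and
finetune **all** weights (nothing frozen) on the small target-domain set.
Each of the 10 pretrained models is finetuned under 5-fold random
cross-validation, giving 50 candidate models; the 10 with the lowest
validation loss form the screening ensemble.

The bundled benchmark emulates the target-domain shift with a synthetic
family whose planted labeling rule re-weights the descriptors, and compares
direct application of the pretrained ensemble against the finetuned one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphdata import CCGraph, stratified_kfold
from .network import CCGNet, CCGNetConfig, _glorot
from .training import EnsembleModel, TrainConfig, ensemble_rank, evaluate, train

__all__ = [
    "TransferSpec",
    "transfer_weights",
    "finetune_ensemble",
    "domain_shift_benchmark",
]


@dataclass(frozen=True)
class TransferSpec:
    """How weights are transferred and the finetuned ensemble selected."""

    layers_to_reinit: int = 2     # trailing dense layers re-initialized
    finetune_all: bool = True     # every parameter stays trainable
    folds: int = 5
    ensemble_size: int = 10
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4   # reduced for finetuning


def transfer_weights(pretrained: CCGNet, spec: TransferSpec, seed: int) -> CCGNet:
    """Clone a pretrained model, re-initializing its last dense layers.

    Every layer except the trailing ``spec.layers_to_reinit`` dense layers
    is copied bitwise (input scalers included); the re-initialized layers
    draw fresh weights from ``seed``. All parameters remain trainable.
    """
    model = CCGNet.from_state(pretrained.state())
    n_dense = len(model.config.dense_head)
    if spec.layers_to_reinit > n_dense:
        raise ValueError("cannot re-initialize more dense layers than exist")
    rng = np.random.default_rng(seed)
    for j in range(n_dense - spec.layers_to_reinit, n_dense):
        W = model.params[f"dense{j}.W"]
        model.params[f"dense{j}.W"] = _glorot(rng, W.shape, W.shape[0], W.shape[1])
        model.params[f"dense{j}.b"] = np.zeros_like(model.params[f"dense{j}.b"])
    return model


def finetune_ensemble(
    pretrained: list[CCGNet],
    samples: list[CCGraph],
    spec: TransferSpec = TransferSpec(),
    seed: int = 0,
) -> dict:
    """Finetune every (pretrained model, fold) combination and select an ensemble.

    Produces ``len(pretrained) * spec.folds`` candidates; the
    ``spec.ensemble_size`` with the lowest validation loss are selected
    (ties broken by pretrained index then fold index). Per-candidate
    validation losses are returned for audit.
    """
    n_candidates = len(pretrained) * spec.folds
    if n_candidates < spec.ensemble_size:
        raise ValueError(
            f"{n_candidates} candidates cannot fill an ensemble of {spec.ensemble_size}"
        )
    candidates = []
    for pi, base in enumerate(pretrained):
        folds = stratified_kfold(samples, spec.folds, seed=seed + pi)
        for fold in range(spec.folds):
            tr = [s for s in samples if folds.fold_of(s) != fold]
            va = [s for s in samples if folds.fold_of(s) == fold]
            model = transfer_weights(base, spec, seed=seed * 1000 + pi * spec.folds + fold)
            cfg = TrainConfig(
                epochs=spec.epochs, batch_size=spec.batch_size,
                learning_rate=spec.learning_rate,
                seed=seed + pi * spec.folds + fold,
                feature_mode=model.config.feature_mode,
                k_folds=spec.folds,
            )
            model, _ = train(tr, cfg, model=model)
            val_loss = _val_loss(model, va)
            candidates.append({"pretrained": pi, "fold": fold,
                               "val_loss": val_loss, "model": model})
    ranked = sorted(candidates, key=lambda c: (c["val_loss"], c["pretrained"], c["fold"]))
    selected = ranked[: spec.ensemble_size]
    return {
        "ensemble": EnsembleModel(members=[c["model"] for c in selected]),
        "selected": [(c["pretrained"], c["fold"], c["val_loss"]) for c in selected],
        "candidates": [
            {"pretrained": c["pretrained"], "fold": c["fold"], "val_loss": c["val_loss"]}
            for c in candidates
        ],
    }


def _val_loss(model: CCGNet, samples: list[CCGraph]) -> float:
    from .training import _padded

    return model.loss(_padded(samples))


def domain_shift_benchmark(
    pretrained: list[CCGNet],
    finetune_samples: list[CCGraph],
    test_samples: list[CCGraph],
    spec: TransferSpec = TransferSpec(),
    seed: int = 0,
) -> dict:
    """Direct-transfer vs finetuned performance on a shifted family.

    Evaluates (i) the pretrained models applied unchanged as an ensemble and
    (ii) the finetuned, loss-selected ensemble on the same held-out shifted
    test set. Reports both BACCs, the ranked tables, and the per-candidate
    validation losses.
    """
    direct = EnsembleModel(members=list(pretrained))
    direct_table = ensemble_rank(test_samples, direct)
    from .training import compute_metrics

    direct_metrics = compute_metrics(
        direct_table["true_label"], direct_table["predicted_label"]
    )
    ft = finetune_ensemble(pretrained, finetune_samples, spec=spec, seed=seed)
    ft_table = ensemble_rank(test_samples, ft["ensemble"])
    ft_metrics = compute_metrics(ft_table["true_label"], ft_table["predicted_label"])
    return {
        "direct_bacc": direct_metrics.BACC,
        "finetuned_bacc": ft_metrics.BACC,
        "direct_metrics": direct_metrics,
        "finetuned_metrics": ft_metrics,
        "candidates": ft["candidates"],
        "selected": ft["selected"],
    }
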