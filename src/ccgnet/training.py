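"""Training, cross-validation, metrics, and ensemble screening.

The classification task is imbalanced (experimentally reported cocrystal
pairs outnumber failures roughly 6.5:1), so performance is tracked with the
per-class rates and their mean:

    TPR = TP / (TP + FN)        (sensitivity)
    TNR = TN / (FP + TN)        (specificity)
    BACC = (TPR + TNR) / 2      (balanced accuracy)

The loss is plain two-class softmax cross-entropy without class weighting;
robustness to the imbalance is carried by the feature representation and
architecture, not by loss reweighting. For screening, the fold models are
combined into an ensemble: candidate pairs are ranked by the summed
positive-class score over members and labeled by majority vote of the
members' b > a decisions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .graphdata import CCGraph, augment, pad_batch, stratified_kfold
from .network import CCGNet, CCGNetConfig

__all__ = [
    "Metrics",
    "TrainConfig",
    "EnsembleModel",
    "compute_metrics",
    "balanced_accuracy",
    "Adam",
    "train",
    "cross_validate",
    "evaluate",
    "score_pairs",
    "ensemble_rank",
    "order_sensitivity",
]


@dataclass
class Metrics:
    TP: int
    FP: int
    TN: int
    FN: int
    TPR: float | None
    TNR: float | None
    BACC: float | None

    def as_percent(self) -> dict:
        pct = lambda x: None if x is None else 100.0 * x
        return {"TPR": pct(self.TPR), "TNR": pct(self.TNR), "BACC": pct(self.BACC)}


def compute_metrics(y_true, y_pred) -> Metrics:
    """Confusion counts and per-class rates, exact before float conversion.

    A class absent from ``y_true`` leaves its rate (and hence BACC)
    undefined (``None``) rather than silently zero.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("need equal-length, non-empty label vectors")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tpr = float(Fraction(tp, tp + fn)) if tp + fn > 0 else None
    tnr = float(Fraction(tn, fp + tn)) if fp + tn > 0 else None
    bacc = (tpr + tnr) / 2.0 if tpr is not None and tnr is not None else None
    return Metrics(TP=tp, FP=fp, TN=tn, FN=fn, TPR=tpr, TNR=tnr, BACC=bacc)


def balanced_accuracy(tpr: float, tnr: float) -> float:
    """BACC from per-class rates (same scale in as out, e.g. percent)."""
    return (tpr + tnr) / 2.0


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    # the graph-convolution/attention branch has far more parameters per unit
    # of signal than the 12-descriptor path and overfits small pair sets, so
    # it carries its own (stronger) decay
    graph_weight_decay: float = 2e-3
    # optional train-time Gaussian jitter on the global-state descriptors, in
    # units of each descriptor's std (off by default: it blurs decision
    # boundaries that run close to descriptor thresholds)
    descriptor_jitter: float = 0.0
    seed: int = 0
    feature_mode: str = "MG+2D+3D"
    k_folds: int = 10
    augment: bool = True

    def __post_init__(self):
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")


class Adam:
    """Adam optimizer over a flat parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay: float = 0.0, graph_weight_decay: float | None = None):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.graph_weight_decay = (
            weight_decay if graph_weight_decay is None else graph_weight_decay
        )
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    @staticmethod
    def _is_graph_weight(key: str) -> bool:
        return key.endswith((".h", ".W0")) or (key.startswith("head") and key.endswith(".W1"))

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            # decoupled decay; biases excluded
            if not k.endswith((".b", ".bu", ".b1", ".b2")):
                wd = self.graph_weight_decay if self._is_graph_weight(k) else self.weight_decay
                if wd:
                    params[k] -= self.lr * wd * params[k]


def _padded(samples: list[CCGraph], n_max: int | None = None) -> dict:
    n_max = n_max or max(g.num_nodes for g in samples)
    return pad_batch(samples, n_max=n_max)


def train(
    samples: list[CCGraph],
    cfg: TrainConfig,
    arch: CCGNetConfig | None = None,
    val_samples: list[CCGraph] | None = None,
    model: CCGNet | None = None,
) -> tuple[CCGNet, dict]:
    """Train a model on (optionally augmented) samples; returns (model, history).

    Deterministic given ``cfg.seed``: weight initialization, shuffling and
    hence the loss trajectory are all driven by one generator. A NaN loss
    aborts with a diagnostic rather than training on.
    """
    if any(s.label is None for s in samples):
        raise ValueError("training requires labeled samples")
    train_set = augment(samples) if cfg.augment else list(samples)
    n_max = max(
        g.num_nodes for g in train_set + (val_samples or [])
    )
    batch = _padded(train_set, n_max)
    if model is None:
        arch = arch or CCGNetConfig()
        arch.feature_mode = cfg.feature_mode
        arch.seed = cfg.seed
        model = CCGNet(arch)
        model.fit_scalers(batch)
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
               graph_weight_decay=cfg.graph_weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(train_set)
    u_std = batch["U"].reshape(-1, batch["U"].shape[2]).std(axis=0)
    history = {"loss": [], "val": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            mini = {
                k: (batch[k][idx] if isinstance(batch[k], np.ndarray) else
                    [batch[k][i] for i in idx])
                for k in batch
            }
            # crop padding to the largest graph in this minibatch; predictions
            # are padding-invariant so this is exact
            nb = int(mini["n_nodes"].max())
            mini["V"] = mini["V"][:, :nb]
            mini["A"] = mini["A"][:, :nb, :nb]
            mini["mask"] = mini["mask"][:, :nb]
            mini["comp"] = mini["comp"][:, :nb]
            if cfg.descriptor_jitter > 0 and model.has_global:
                mini["U"] = mini["U"] + cfg.descriptor_jitter * u_std * rng.standard_normal(
                    mini["U"].shape
                )
            loss, grads = model.loss_and_grads(mini)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}, step {start // cfg.batch_size}"
                )
            opt.step(model.params, grads)
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if val_samples:
            history["val"].append(evaluate(model, val_samples))
    return model, history


def evaluate(model: CCGNet, samples: list[CCGraph]) -> Metrics:
    batch = _padded(samples)
    _, pred = model.predict(batch)
    return compute_metrics([s.label for s in samples], pred)


def score_pairs(model: CCGNet, samples: list[CCGraph]) -> np.ndarray:
    """Positive-class probabilities for a list of samples."""
    scores, _ = model.predict(_padded(samples))
    return scores[:, 1]


def cross_validate(
    samples: list[CCGraph],
    cfg: TrainConfig,
    arch: CCGNetConfig | None = None,
) -> dict:
    """k-fold cross-validation with order-swap augmentation of training folds.

    Folds are stratified over the original samples; each fold's model is
    trained on the other k-1 folds (augmented when ``cfg.augment``) and
    evaluated on its own unaugmented fold. Returns models, per-fold metrics
    and a mean +/- sd summary of the per-class rates.
    """
    folds = stratified_kfold(samples, cfg.k_folds, seed=cfg.seed)
    models, fold_metrics = [], []
    for fold in range(cfg.k_folds):
        tr = [s for s in samples if folds.fold_of(s) != fold]
        va = [s for s in samples if folds.fold_of(s) == fold]
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + fold)
        arch_i = None
        if arch is not None:
            arch_i = CCGNetConfig(**{**arch.__dict__})
        model, _ = train(tr, fold_cfg, arch=arch_i)
        models.append(model)
        fold_metrics.append(evaluate(model, va))
    summary = {}
    for key in ("TPR", "TNR", "BACC"):
        vals = [getattr(m, key) for m in fold_metrics if getattr(m, key) is not None]
        summary[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    return {"models": models, "fold_metrics": fold_metrics, "summary": summary,
            "folds": folds}


@dataclass
class EnsembleModel:
    """Ordered member models voting on candidate pairs."""

    members: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        layouts = {m.config.atom_features for m in self.members}
        if len(layouts) != 1:
            raise ValueError("ensemble members disagree on feature layout")


def ensemble_rank(samples: list[CCGraph], ensemble: EnsembleModel) -> pd.DataFrame:
    """Rank candidate pairs by summed positive-class score over the ensemble.

    One row per pair: summed score, per-member scores, majority-vote label,
    and rank (descending score; ties keep input order via stable sort).
    """
    batch = _padded(samples)
    member_scores, member_votes = [], []
    for m in ensemble.members:
        scores, votes = m.predict(batch)
        member_scores.append(scores[:, 1])
        member_votes.append(votes)
    S = np.stack(member_scores, axis=1)  # (n, members)
    votes = np.stack(member_votes, axis=1)
    summed = S.sum(axis=1)
    majority = (votes.sum(axis=1) * 2 > votes.shape[1]).astype(int)
    df = pd.DataFrame(
        {
            "id": [s.sample_id for s in samples],
            "sum_positive_score": summed,
            "member_scores": [list(map(float, row)) for row in S],
            "predicted_label": majority,
            "true_label": [s.label for s in samples],
        }
    )
    df = df.sort_values("sum_positive_score", ascending=False, kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def order_sensitivity(model: CCGNet, samples: list[CCGraph]) -> float:
    """Mean |score(A,B) - score(B,A)| over a sample list."""
    fwd = score_pairs(model, samples)
    rev = score_pairs(model, [s.swapped() for s in samples])
    return float(np.mean(np.abs(fwd - rev)))
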