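"""Training protocol and evaluation metrics for multi-label detection.

Training minimizes the mean binary cross-entropy over the 17 outputs with
the Adam optimizer and a linear learning-rate decay from the base rate to 0
over the epochs (lr_e = base * (1 - e / n_epochs)). Evaluation follows the
molecular convention: per-group F1 over molecules, perfect-match analysis
(all 17 bits correct) bucketed by the number of true groups, and per-sample
false positive / false negative rates bucketed the same way. Protocols:
plain 5-fold cross-validation and a 70-20-10 holdout in which the five fold
models are all scored on the untouched 10% test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import GROUP_NAMES, N_GROUPS
from .errors import TrainingDivergenceError
from .preprocess import DatasetRecord
from .split_net import SplitNet, SplitNetConfig, _sigmoid

__all__ = [
    "TrainConfig",
    "EvalReport",
    "kfold_split",
    "train",
    "per_group_f1",
    "macro_f1",
    "perfect_match_table",
    "fpr_fnr_table",
    "cross_validate",
    "holdout_protocol",
    "records_to_arrays",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    base_lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base learning rate must be > 0")


@dataclass
class EvalReport:
    """Cross-validation summary: per-group F1 and error tables."""

    f1_mean: np.ndarray  # length 17, NaN where undefined in every fold
    f1_sd: np.ndarray
    perfect_match: pd.DataFrame  # index: n true groups; n_samples, n_perfect, ratio
    fpr_fnr: pd.DataFrame  # index: n true groups; fpr, fnr, n_samples
    fold_f1: np.ndarray = field(default=None)  # (k, 17)

    @property
    def macro_f1(self) -> float:
        return float(np.nanmean(self.f1_mean))

    def to_dict(self) -> dict:
        return {
            "per_group_f1": {
                name: {
                    "mean": None if np.isnan(m) else float(m),
                    "sd": None if np.isnan(s) else float(s),
                }
                for name, m, s in zip(GROUP_NAMES, self.f1_mean, self.f1_sd)
            },
            "macro_f1": self.macro_f1,
            "perfect_match": self.perfect_match.reset_index().to_dict(orient="records"),
            "fpr_fnr": self.fpr_fnr.reset_index().to_dict(orient="records"),
        }


def records_to_arrays(records: list[DatasetRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([r.spectrum.intensities for r in records]).astype(np.float32)
    y = np.stack([r.labels for r in records]).astype(np.float32)
    return x, y


def kfold_split(n: int, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random K-fold partition of ``range(n)``; validation folds within +-1 of n/k."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least {k} records for {k}-fold CV")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    return [
        (np.sort(np.concatenate(folds[:i] + folds[i + 1 :])), np.sort(folds[i]))
        for i in range(k)
    ]


try:  # single fused pass over the big parameter tensors; ~3x faster than numpy
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_kernel(p, g, m, v, b1, b2, bc1, bc2, eps, lr):  # pragma: no cover
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)

except ImportError:  # pragma: no cover

    def _adam_kernel(p, g, m, v, b1, b2, bc1, bc2, eps, lr):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


class _Adam:
    """Adam with in-place updates; the update runs as one fused pass because
    the input-layer weight tensors are large and the step is memory-bound."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [(p.reshape(-1), g.reshape(-1)) for p, g in params]
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            f = p.dtype.type  # keep the kernel in the parameters' precision
            _adam_kernel(p, g, m, v, f(b1), f(b2), f(bc1), f(bc2), f(self.eps), f(lr))


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Linear decay: base * (1 - epoch / epochs), epoch counted from 0."""
    return config.base_lr * (1.0 - epoch / config.epochs)


def _bce(logits: np.ndarray, y: np.ndarray) -> float:
    # softplus(z) - y*z is the per-element BCE written on logits (stable)
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def train(
    data: list[DatasetRecord] | tuple[np.ndarray, np.ndarray],
    net: SplitNet,
    config: TrainConfig | None = None,
) -> list[float]:
    """Optimize *net* in place; returns the per-epoch mean training loss.

    Raises :class:`TrainingDivergenceError` naming the epoch if the loss
    becomes non-finite.
    """
    config = config or TrainConfig()
    if isinstance(data, tuple):
        x, y = data
    else:
        if not data:
            raise ValueError("empty training set")
        x, y = records_to_arrays(data)
    x = x.astype(np.float32, copy=False)
    y = y.astype(np.float32, copy=False)
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    adam = _Adam(net.parameters())
    history: list[float] = []
    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n)
        losses = []
        weights = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.forward_logits(xb, training=True)
            loss = _bce(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            losses.append(loss)
            weights.append(len(idx))
            # loss is a mean over batch*17 elements, hence the 1/size factor
            dlogits = (_sigmoid(logits) - yb) / logits.size
            net.backward(dlogits.astype(np.float32))
            try:
                adam.step(lr)
            except (ZeroDivisionError, FloatingPointError) as e:
                raise TrainingDivergenceError(
                    epoch, f"non-finite gradients at epoch {epoch}"
                ) from e
        history.append(float(np.average(losses, weights=weights)))
    return history


# ---------------------------------------------------------------------------
# metrics


def _check_shapes(predictions: np.ndarray, labels: np.ndarray):
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have identical shape")
    if predictions.ndim != 2 or predictions.shape[1] != N_GROUPS:
        raise ValueError(f"expected (n, {N_GROUPS}) arrays")
    return predictions.astype(bool), labels.astype(bool)


def per_group_f1(predictions: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """F1_g = 2TP / (2TP + FP + FN) per group; NaN when TP=FP=FN=0.

    Undefined groups (never present and never predicted) are reported as NaN
    and must be excluded from macro averages rather than imputed as 0.
    """
    pred, lab = _check_shapes(predictions, labels)
    tp = (pred & lab).sum(axis=0).astype(float)
    fp = (pred & ~lab).sum(axis=0).astype(float)
    fn = (~pred & lab).sum(axis=0).astype(float)
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), np.nan)


def macro_f1(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean of the defined per-group F1 scores."""
    return float(np.nanmean(per_group_f1(predictions, labels)))


def perfect_match_table(predictions: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Perfect-match counts and ratios bucketed by the number of true groups.

    A sample is a perfect match iff the entire 17-bit prediction equals the
    ground truth. Bucket counts partition the evaluated samples.
    """
    pred, lab = _check_shapes(predictions, labels)
    n_true = lab.sum(axis=1)
    perfect = (pred == lab).all(axis=1)
    rows = []
    for g in np.unique(n_true):
        mask = n_true == g
        rows.append(
            {
                "n_groups": int(g),
                "n_samples": int(mask.sum()),
                "n_perfect": int(perfect[mask].sum()),
                "ratio": float(perfect[mask].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("n_groups")


def fpr_fnr_table(predictions: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Mean per-sample FPR and FNR bucketed by the number of true groups.

    For one sample, FPR = FP/(FP+TN) over its 17 bits (undefined when it has
    no true negatives) and FNR = FN/(FN+TP) (undefined when it has no true
    positives); bucket means are taken over the defined samples only.
    """
    pred, lab = _check_shapes(predictions, labels)
    fp = (pred & ~lab).sum(axis=1).astype(float)
    tn = (~pred & ~lab).sum(axis=1).astype(float)
    fn = (~pred & lab).sum(axis=1).astype(float)
    tp = (pred & lab).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fpr = np.where(fp + tn > 0, fp / (fp + tn), np.nan)
        fnr = np.where(fn + tp > 0, fn / (fn + tp), np.nan)
    n_true = lab.sum(axis=1)
    rows = []
    for g in np.unique(n_true):
        mask = n_true == g
        rows.append(
            {
                "n_groups": int(g),
                "n_samples": int(mask.sum()),
                "fpr": float(np.nanmean(fpr[mask])) if np.any(np.isfinite(fpr[mask])) else np.nan,
                "fnr": float(np.nanmean(fnr[mask])) if np.any(np.isfinite(fnr[mask])) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("n_groups")


# ---------------------------------------------------------------------------
# protocols


def _fit_fold(
    x: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    model_config: SplitNetConfig,
    train_config: TrainConfig,
    grid: np.ndarray,
    fold: int,
) -> SplitNet:
    cfg = replace(model_config, seed=model_config.seed + fold)
    net = SplitNet(cfg, grid)
    train((x[train_idx], y[train_idx]), net, replace(train_config, seed=train_config.seed + fold))
    return net


def cross_validate(
    records: list[DatasetRecord],
    model_config: SplitNetConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    return_models: bool = False,
):
    """K-fold CV: per-group F1 mean +- sd over folds and pooled error tables."""
    model_config = model_config or SplitNetConfig()
    train_config = train_config or TrainConfig()
    x, y = records_to_arrays(records)
    grid = records[0].spectrum.grid
    fold_f1 = []
    pooled_pred, pooled_lab = [], []
    models = []
    for fold, (tr, va) in enumerate(kfold_split(len(records), k, train_config.seed)):
        net = _fit_fold(x, y, tr, model_config, train_config, grid, fold)
        pred = net.predict(x[va])
        fold_f1.append(per_group_f1(pred, y[va]))
        pooled_pred.append(pred)
        pooled_lab.append(y[va])
        if return_models:
            models.append(net)
    fold_f1 = np.stack(fold_f1)
    pred = np.concatenate(pooled_pred)
    lab = np.concatenate(pooled_lab)
    report = EvalReport(
        f1_mean=np.nanmean(fold_f1, axis=0),
        f1_sd=np.nanstd(fold_f1, axis=0),
        perfect_match=perfect_match_table(pred, lab),
        fpr_fnr=fpr_fnr_table(pred, lab),
        fold_f1=fold_f1,
    )
    return (report, models) if return_models else report


def holdout_protocol(
    records: list[DatasetRecord],
    model_config: SplitNetConfig | None = None,
    train_config: TrainConfig | None = None,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    k: int = 5,
):
    """70-20-10 holdout: fix the 10% test set, run K-fold CV on the rest,
    then score all K fold models on the test set.

    Returns (report, test_indices) where the report's F1 mean/sd are over the
    K fold models evaluated on the same test samples.
    """
    model_config = model_config or SplitNetConfig()
    train_config = train_config or TrainConfig()
    if len(records) < 10:
        raise ValueError("need at least 10 records for a 70-20-10 protocol")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(records)
    rng = np.random.default_rng(train_config.seed)
    perm = rng.permutation(n)
    n_test = int(round(ratios[2] * n))
    test_idx = np.sort(perm[:n_test])
    rest_idx = np.sort(perm[n_test:])
    x, y = records_to_arrays(records)
    grid = records[0].spectrum.grid
    fold_f1 = []
    pooled_pred, pooled_lab = [], []
    for fold, (tr, _) in enumerate(kfold_split(len(rest_idx), k, train_config.seed)):
        net = _fit_fold(x, y, rest_idx[tr], model_config, train_config, grid, fold)
        pred = net.predict(x[test_idx])
        fold_f1.append(per_group_f1(pred, y[test_idx]))
        pooled_pred.append(pred)
        pooled_lab.append(y[test_idx])
    fold_f1 = np.stack(fold_f1)
    pred = np.concatenate(pooled_pred)
    lab = np.concatenate(pooled_lab)
    report = EvalReport(
        f1_mean=np.nanmean(fold_f1, axis=0),
        f1_sd=np.nanstd(fold_f1, axis=0),
        perfect_match=perfect_match_table(pred, lab),
        fpr_fnr=fpr_fnr_table(pred, lab),
        fold_f1=fold_f1,
    )
    return report, test_idx
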