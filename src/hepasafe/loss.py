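"""Asymmetric "weighted liver loss" and the comparator losses.

Under-predicting the safe resection volume risks leaving diseased tissue
behind (clinically dangerous), while over-predicting merely errs toward a
conservative margin, so the loss weights squared errors asymmetrically:

    L = (1/N) * sum_i (w_i * SE_i + SE_i),   SE_i = (y_pred_i - y_true_i)^2

with w_i = under_penalty when y_pred_i < y_true_i and over_penalty
otherwise (a tie takes the over branch). An optional logarithmic term
``log_coeff * log(1 + e_i)`` for over-predicted samples (e_i >= 0)
additionally penalizes large over-predictions; it is off by default so the
plain weighted sum is the default behavior.

Every loss here returns ``(value, grad)`` with ``grad`` the derivative with
respect to ``y_pred``, which is what the network trainer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "per_sample_weight",
    "weighted_liver_loss",
    "weighted_liver_loss_grad",
    "mse_loss",
    "mae_loss",
    "huber_loss",
    "LOSS_REGISTRY",
    "get_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Penalty weights of the asymmetric loss.

    under_penalty : weight applied to squared error when the model
        under-predicts (default 10).
    over_penalty : weight when it over-predicts or is exact (default 1).
    log_coeff : coefficient of the optional logarithmic over-prediction
        term (default 0 = disabled).
    """

    under_penalty: float = 10.0
    over_penalty: float = 1.0
    log_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.under_penalty < 0 or self.over_penalty < 0 or self.log_coeff < 0:
            raise ValueError("loss penalties must be non-negative")


def _validate_batch(y_pred, y_true) -> tuple[np.ndarray, np.ndarray]:
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_pred.shape != y_true.shape:
        raise ValueError(f"length mismatch: {y_pred.shape} vs {y_true.shape}")
    if y_pred.size == 0:
        raise ValueError("empty batch")
    if not (np.all(np.isfinite(y_pred)) and np.all(np.isfinite(y_true))):
        raise ValueError("non-finite values in batch")
    return y_pred, y_true


def per_sample_weight(pred: float, true: float, cfg: LossConfig) -> float:
    """Branch weight w_i: under_penalty if pred < true, else over_penalty."""
    return cfg.under_penalty if pred < true else cfg.over_penalty


def weighted_liver_loss(y_pred, y_true, cfg: LossConfig = LossConfig()) -> float:
    """Mean of (w_i + 1) * squared error, plus the optional log term."""
    y_pred, y_true = _validate_batch(y_pred, y_true)
    err = y_pred - y_true
    w = np.where(err < 0, cfg.under_penalty, cfg.over_penalty)
    total = (w + 1.0) * err**2
    if cfg.log_coeff > 0:
        over = err >= 0
        total = total + np.where(over, cfg.log_coeff * np.log1p(err * over), 0.0)
    return float(total.mean())


def weighted_liver_loss_grad(y_pred, y_true, cfg: LossConfig = LossConfig()):
    """Value and d/d(y_pred) of :func:`weighted_liver_loss`.

    The gradient exists everywhere except exactly at the branch point
    err = 0, where the over-branch one-sided derivative is used.
    """
    y_pred, y_true = _validate_batch(y_pred, y_true)
    n = y_pred.size
    err = y_pred - y_true
    w = np.where(err < 0, cfg.under_penalty, cfg.over_penalty)
    value = ((w + 1.0) * err**2)
    grad = 2.0 * (w + 1.0) * err / n
    if cfg.log_coeff > 0:
        over = err >= 0
        value = value + np.where(over, cfg.log_coeff * np.log1p(err * over), 0.0)
        grad = grad + np.where(over, cfg.log_coeff / (1.0 + err * over), 0.0) / n
    return float(value.mean()), grad


def mse_loss(y_pred, y_true, cfg: LossConfig | None = None):
    y_pred, y_true = _validate_batch(y_pred, y_true)
    err = y_pred - y_true
    return float((err**2).mean()), 2.0 * err / err.size


def mae_loss(y_pred, y_true, cfg: LossConfig | None = None):
    y_pred, y_true = _validate_batch(y_pred, y_true)
    err = y_pred - y_true
    return float(np.abs(err).mean()), np.sign(err) / err.size


def huber_loss(y_pred, y_true, cfg: LossConfig | None = None, delta: float = 1.0):
    y_pred, y_true = _validate_batch(y_pred, y_true)
    err = y_pred - y_true
    small = np.abs(err) <= delta
    value = np.where(small, 0.5 * err**2, delta * (np.abs(err) - 0.5 * delta))
    grad = np.where(small, err, delta * np.sign(err)) / err.size
    return float(value.mean()), grad


def _weighted_liver(y_pred, y_true, cfg: LossConfig | None = None):
    return weighted_liver_loss_grad(y_pred, y_true, cfg or LossConfig())


LOSS_REGISTRY = {
    "weighted_liver": _weighted_liver,
    "mse": mse_loss,
    "mae": mae_loss,
    "huber": huber_loss,
}


def get_loss(name: str):
    """Look up a loss by name; valid names are the comparators plus ours."""
    try:
        return LOSS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown loss {name!r}; valid: {sorted(LOSS_REGISTRY)}"
        ) from None
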