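"""Regressor registry: the comparator models plus the residual network.

Every entry honours the minimal fit/predict contract used by the K-fold
evaluator. Classical models are scikit-learn estimators (wrapped in
scaling pipelines where the algorithm needs it); the two ``resection_net_*``
entries wrap the NumPy residual network trained with MSE or with the
asymmetric weighted liver loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .loss import LossConfig
from .network import Network, NetworkConfig, TrainConfig, build_network, train

__all__ = ["RegressorSpec", "RESECTION_NET_MODELS", "VALID_MODEL_NAMES", "make_baseline"]

VALID_MODEL_NAMES = (
    "linear", "poly2", "poly3", "poly4", "svr", "decision_tree",
    "random_forest", "ffnn", "resection_net_mse", "resection_net_liver_loss",
)
RESECTION_NET_MODELS = ("resection_net_mse", "resection_net_liver_loss")


@dataclass(frozen=True)
class RegressorSpec:
    """A named model plus hyperparameter overrides."""

    name: str
    seed: int = 0
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VALID_MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; valid: {list(VALID_MODEL_NAMES)}"
            )

    def with_seed(self, seed: int) -> "RegressorSpec":
        return RegressorSpec(self.name, seed=seed, hyperparameters=dict(self.hyperparameters))


class ResectionNetRegressor:
    """fit/predict wrapper around the residual network trainer."""

    def __init__(
        self,
        loss: str = "weighted_liver",
        loss_config: LossConfig | None = None,
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ):
        self.seed = seed
        self.loss = loss
        self.loss_config = loss_config or LossConfig()
        self.network_config = network_config
        self.train_config = train_config
        self.net_: Network | None = None
        self.history_: list[float] | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        net_cfg = self.network_config or NetworkConfig(input_dim=X.shape[1], seed=self.seed)
        train_cfg = self.train_config or TrainConfig(
            loss=self.loss, loss_config=self.loss_config, seed=self.seed
        )
        self.net_ = build_network(net_cfg)
        self.net_, self.history_ = train(self.net_, X, y, train_cfg)
        return self

    def predict(self, X):
        if self.net_ is None:
            raise RuntimeError("fit before predict")
        return self.net_.predict(np.asarray(X, dtype=float))


def make_baseline(spec: RegressorSpec):
    """Instantiate a fit/predict regressor from its spec.

    Polynomial variants expand features to the stated degree before an
    ordinary least-squares fit; SVR and the feedforward net get z-scored
    inputs (they are scale-sensitive), tree models do not need scaling.
    """
    name, seed, hp = spec.name, spec.seed, dict(spec.hyperparameters)
    if name == "linear":
        return LinearRegression(**hp)
    if name in ("poly2", "poly3", "poly4"):
        degree = int(name[-1])
        return make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=degree, include_bias=False),
            LinearRegression(),
        )
    if name == "svr":
        return make_pipeline(StandardScaler(), SVR(**hp))
    if name == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if name == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, **hp)
    if name == "ffnn":
        # two hidden layers of 64, the plain feedforward comparator
        hp.setdefault("hidden_layer_sizes", (64, 64))
        hp.setdefault("max_iter", 2000)
        return make_pipeline(StandardScaler(), MLPRegressor(random_state=seed, **hp))
    if name == "resection_net_mse":
        return ResectionNetRegressor(loss="mse", seed=seed, **hp)
    if name == "resection_net_liver_loss":
        return ResectionNetRegressor(loss="weighted_liver", seed=seed, **hp)
    raise ValueError(f"unknown model {name!r}; valid: {list(VALID_MODEL_NAMES)}")
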