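"""Comparison learners: per-drug ridge regression (single-task baseline),
the shared-latent multi-task network (GO-MTL-style: l1 on the task
combiners, l2 on the shared bases), and the loss-weighted autoencoder
multi-task network (AMTFL-style: transfer from high-loss tasks to the
shared features is sparsified).

The two network baselines reuse the main training machinery with the
uncertainty gating switched off — all models share the same architecture
up to the prediction layer, so differences are purely in regularization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet

from .datasets import DrugResponseDataset
from .model import ModelConfig, ModelParameters
from .training import TrainReport, train_mtl

__all__ = [
    "BaselineSpec",
    "fit_stl_ridge",
    "predict_linear",
    "fit_stl_elastic_net",
    "fit_stl_all",
    "fit_shared_latent_mtl",
    "fit_loss_weighted_mtl",
    "RidgePanel",
]


@dataclass
class BaselineSpec:
    """Which baseline to run and with what hyperparameters."""

    kind: str  # "stl_ridge" | "shared_latent" | "loss_weighted_ae"
    hyperparameters: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("stl_ridge", "shared_latent", "loss_weighted_ae"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if any(v < 0 for v in self.hyperparameters.values()
               if isinstance(v, (int, float))):
            raise ValueError("hyperparameters must be non-negative")


def fit_stl_ridge(
    data: DrugResponseDataset, task_index: int, penalty: float
) -> tuple[np.ndarray, float]:
    """Closed-form ridge for one drug on its observed rows.

    The intercept is unpenalized (fit on centered data); a constant target
    yields zero slopes and intercept = mean(y).
    """
    obs = data.mask[:, task_index]
    if obs.sum() < 2:
        raise ValueError("task needs at least 2 observed samples")
    X = data.expression[obs]
    y = data.response[obs, task_index]
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    d = X.shape[1]
    w = np.linalg.solve(Xc.T @ Xc + penalty * np.eye(d), Xc.T @ yc)
    b = y_mean - x_mean @ w
    return w, float(b)


def predict_linear(X: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    return np.asarray(X, float) @ w + b


def fit_stl_elastic_net(
    data: DrugResponseDataset,
    task_index: int,
    alpha: float,
    l1_ratio: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Elastic-net single-task variant (l1 + l2 penalized linear model)."""
    obs = data.mask[:, task_index]
    X = data.expression[obs]
    y = data.response[obs, task_index]
    est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000)
    est.fit(X, y)
    return est.coef_.copy(), float(est.intercept_)


def fit_stl_all(
    data: DrugResponseDataset, penalty: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge for every drug; returns weights (d, T) and intercepts (T,)."""
    W = np.zeros((data.n_genes, data.n_tasks))
    b = np.zeros(data.n_tasks)
    for t in range(data.n_tasks):
        W[:, t], b[t] = fit_stl_ridge(data, t, penalty)
    return W, b


class RidgePanel:
    """Per-drug ridge wrapped in the fit/predict interface the nested-CV
    harness expects."""

    def __init__(self, penalty: float):
        self.penalty = penalty
        self.W = None
        self.b = None

    def fit(self, data: DrugResponseDataset) -> "RidgePanel":
        self.W, self.b = fit_stl_all(data, self.penalty)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.W + self.b


def fit_shared_latent_mtl(
    data: DrugResponseDataset,
    mu: float,
    lam: float,
    config: ModelConfig | None = None,
    **overrides,
) -> tuple[ModelParameters, TrainReport]:
    """Shared-latent-basis MTL: plain MSE per drug, l1 on s_t, l2 on L.

    No uncertainty machinery, no autoencoder, no dropout — the W = L S
    factorization is the only coupling between drugs.
    """
    base = config or ModelConfig()
    cfg = base.with_(
        mu=mu, lam=lam, gamma=0.0, alpha=0.0, lam_adv=0.0,
        transfer_mode="none", task_loss="mse", dropout_rate=0.0,
        **overrides,
    )
    return train_mtl(data, cfg)


def fit_loss_weighted_mtl(
    data: DrugResponseDataset,
    mu: float,
    lam: float,
    gamma: float,
    alpha: float,
    config: ModelConfig | None = None,
    form: str = "prose",
    **overrides,
) -> tuple[ModelParameters, TrainReport]:
    """Loss-weighted autoencoder MTL: the task loss (instead of the
    uncertainty) scales the sparsity pressure on each decoder row, so
    high-loss tasks transfer less into the shared features.

    ``form`` picks the weighting reading: "prose" = 1 + alpha * loss_t *
    ||a_t||_1, "printed" = (1 + alpha * ||a_t||_1) * loss_t.
    """
    base = config or ModelConfig()
    cfg = base.with_(
        mu=mu, lam=lam, gamma=gamma, alpha=alpha, lam_adv=0.0,
        transfer_mode="loss", loss_weight_form=form, task_loss="mse",
        dropout_rate=0.0, **overrides,
    )
    return train_mtl(data, cfg)
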