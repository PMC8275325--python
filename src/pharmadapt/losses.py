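"""Objective components: heteroscedastic task losses, uncertainty-gated
transfer weights, the latent autoencoder penalty and the adversarial
domain-confusion term.

Each component is exposed on its own so it can be checked against a naive
loop oracle; :func:`mtl_loss` composes them into a :class:`LossBreakdown`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ModelConfig, ModelParameters, forward

__all__ = [
    "LossBreakdown",
    "aleatoric_loss",
    "task_mse",
    "bnn_task_loss",
    "transfer_weight",
    "reconstruction_loss",
    "adversarial_loss",
    "total_loss",
    "mtl_loss",
]

_PROB_EPS = 1e-7


@dataclass
class LossBreakdown:
    """All terms of the composite objective, reported separately.

    ``total`` is sum_t [ transfer_weight_t * per_task_loss_t + l1_s_t ]
    + recon + l2_L + lam_adv * adv.
    """

    per_task_bnn: np.ndarray     # (T,) heteroscedastic (or plain) task loss
    transfer_weight: np.ndarray  # (T,) the (1 + w_t) gating factor
    l1_s: np.ndarray             # (T,) mu * ||s_t||_1
    recon: float                 # gamma * ||Z - relu(Z S A)||_F^2
    l2_L: float                  # lam * ||L||_F^2
    adv: float                   # domain-confusion cross-entropy
    total: float                 # full weighted objective

    def mtl_total(self) -> float:
        return float(
            np.sum(self.transfer_weight * self.per_task_bnn)
            + np.sum(self.l1_s) + self.recon + self.l2_L
        )

    def to_record(self) -> dict:
        """JSON-serializable record for the epoch-wise training log."""
        return {
            "per_task_bnn": self.per_task_bnn.tolist(),
            "transfer_weight": self.transfer_weight.tolist(),
            "l1_s": self.l1_s.tolist(),
            "recon": float(self.recon),
            "l2_L": float(self.l2_L),
            "adv": float(self.adv),
            "total": float(self.total),
        }


def aleatoric_loss(mse_t: float, sigma_t: float) -> float:
    """Noise-attenuated task loss mse/(2 sigma^2) + log sigma.

    For fixed mse the minimizer over sigma is sqrt(mse): the learnable
    scale absorbs irreducible noise, down-weighting noisy tasks.
    """
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    if mse_t < 0:
        raise ValueError("mse_t must be non-negative")
    return mse_t / (2.0 * sigma_t**2) + np.log(sigma_t)


def task_mse(pred: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-task mean squared error over observed entries (0 where none)."""
    mask = np.asarray(mask, bool)
    resid = np.where(mask, pred - np.where(mask, y, 0.0), 0.0)
    counts = mask.sum(axis=0)
    mse = np.zeros(pred.shape[1])
    ok = counts > 0
    mse[ok] = (resid**2).sum(axis=0)[ok] / counts[ok]
    return mse


def bnn_task_loss(
    pred: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    log_sigma: np.ndarray,
) -> np.ndarray:
    """Per-task heteroscedastic loss from one stochastic pass.

    mse_t over observed entries, attenuated by the learnable noise scale:
    mse_t / (2 sigma_t^2) + log sigma_t. All-masked tasks contribute 0
    (flagged with a warning).
    """
    mask = np.asarray(mask, bool)
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        warnings.warn(
            f"all-masked tasks contribute 0 loss: "
            f"{np.flatnonzero(counts == 0).tolist()}",
            stacklevel=2,
        )
    mse = task_mse(pred, y, mask)
    sigma2 = np.exp(2.0 * np.asarray(log_sigma, float))
    out = mse / (2.0 * sigma2) + np.asarray(log_sigma, float)
    out[counts == 0] = 0.0
    return out


def transfer_weight(
    U: np.ndarray, A_weights: np.ndarray, mode: str = "product"
) -> np.ndarray:
    """Uncertainty gate on task-to-feature transfer.

    product (default): 1 + U_t * ||a_t||_1 — the epistemic uncertainty
    scales how strongly the decoder row is penalized, so unreliable tasks
    transfer less into the shared space. sum: 1 + U_t + ||a_t||_1, the
    purely additive variant.
    """
    U = np.asarray(U, float)
    if np.any(U < 0):
        raise ValueError("U must be non-negative")
    a1 = np.abs(np.asarray(A_weights, float)).sum(axis=1)
    if mode == "product":
        return 1.0 + U * a1
    if mode == "sum":
        return 1.0 + U + a1
    raise ValueError("mode must be 'product' or 'sum'")


def reconstruction_loss(
    Z: np.ndarray, S_weights: np.ndarray, A_weights: np.ndarray, gamma: float
) -> float:
    """Latent autoencoder penalty gamma * ||Z - relu((Z S) A)||_F^2."""
    Z = np.asarray(Z, float)
    recon = np.maximum((Z @ S_weights) @ A_weights, 0.0)
    return float(gamma * np.sum((Z - recon) ** 2))


def adversarial_loss(p_source: np.ndarray, p_target: np.ndarray) -> float:
    """Domain-discriminator cross-entropy (to be min-maxed through the GRL).

    -mean log p_source - mean log(1 - p_target); probabilities are clamped
    to [1e-7, 1 - 1e-7] before the logs.
    """
    ps = np.clip(np.asarray(p_source, float), _PROB_EPS, 1 - _PROB_EPS)
    pt = np.clip(np.asarray(p_target, float), _PROB_EPS, 1 - _PROB_EPS)
    return float(-np.mean(np.log(ps)) - np.mean(np.log(1.0 - pt)))


def total_loss(mtl_total: float, adv: float, lam_adv: float) -> float:
    """Full objective: supervised multi-task total + lam_adv * adversarial."""
    return float(mtl_total) + float(lam_adv) * float(adv)


def _per_task_loss(
    pred: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
) -> np.ndarray:
    if config.task_loss == "bnn":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bnn_task_loss(pred, y, mask, params.log_sigma)
    return task_mse(pred, y, mask)


def compute_transfer_weight(
    params: ModelParameters,
    config: ModelConfig,
    U: np.ndarray | None,
    task_loss_value: np.ndarray | None = None,
) -> np.ndarray:
    """Transfer weight under the configured gating mode.

    In loss mode the detached per-task loss stands in for the uncertainty;
    ``task_loss_value`` must then be provided.
    """
    T = params.n_tasks
    if config.transfer_mode == "none":
        return np.ones(T)
    if config.transfer_mode == "uncertainty":
        U = np.zeros(T) if U is None else np.asarray(U, float)
        return transfer_weight(U, params.A, mode=config.transfer_weighting)
    # loss mode
    if task_loss_value is None:
        raise ValueError("loss mode requires the per-task loss values")
    a1 = np.abs(params.A).sum(axis=1)
    if config.loss_weight_form == "prose":
        return 1.0 + config.alpha * np.asarray(task_loss_value) * a1
    return 1.0 + config.alpha * a1  # printed: (1 + alpha ||a_t||_1) * loss


def mtl_loss(
    batch,
    params: ModelParameters,
    config: ModelConfig,
    U: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> LossBreakdown:
    """Full supervised objective on one batch, component by component.

    ``batch`` is (X, y, mask) or any object with expression/response/mask
    attributes. Stochastic (dropout) evaluation happens iff ``rng`` is
    given and the dropout rate is positive.
    """
    if hasattr(batch, "expression"):
        X, y, mask = batch.expression, batch.response, batch.mask
    else:
        X, y, mask = batch
    pred, cache = forward(X, params, config, rng=rng)
    per_task = _per_task_loss(pred, y, mask, params, config)
    w = compute_transfer_weight(params, config, U, task_loss_value=per_task)
    l1_s = config.mu * np.abs(params.S).sum(axis=0)
    recon = reconstruction_loss(cache["Zd"], params.S, params.A, config.gamma)
    l2 = float(config.lam * np.sum(params.L**2))
    tot = float(np.sum(w * per_task) + np.sum(l1_s) + recon + l2)
    return LossBreakdown(
        per_task_bnn=per_task, transfer_weight=w, l1_s=l1_s,
        recon=recon, l2_L=l2, adv=0.0, total=tot,
    )
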