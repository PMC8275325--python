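"""Hand-derived reverse-mode gradients for the shallow network.

The model is small enough (three linear maps, one ReLU, elementwise
penalties) that writing the backward pass explicitly is simpler and far
more transparent than dragging in an autodiff framework. Every gradient
here is validated against central finite differences in the test suite.

Conventions
-----------
* The transfer weight w_t and the epistemic uncertainty U_t are treated as
  constants during backpropagation (they gate the loss, they are not
  targets); the decoder rows a_t still receive the gradient of the
  weighting term through ||a_t||_1.
* The adversarial gradients already include the sign flip of the gradient
  reversal layer on the encoder path: applying a plain descent step to the
  returned arrays makes the discriminator better and the encoder more
  domain-confusing simultaneously.
"""

from __future__ import annotations

import numpy as np

from .losses import (
    LossBreakdown,
    adversarial_loss,
    compute_transfer_weight,
    reconstruction_loss,
)
from .model import (
    ModelConfig,
    ModelParameters,
    discriminate,
    forward,
    grl_backward,
)

__all__ = ["supervised_loss_and_grads", "adversarial_loss_and_grads"]


def _zero_grads(params: ModelParameters) -> dict[str, np.ndarray]:
    return {
        "L": np.zeros_like(params.L),
        "bL": np.zeros_like(params.bL),
        "S": np.zeros_like(params.S),
        "bS": np.zeros_like(params.bS),
        "A": np.zeros_like(params.A),
        "log_sigma": np.zeros_like(params.log_sigma),
        "D_w": np.zeros_like(params.D_w),
        "D_b": np.zeros(1),
    }


def supervised_loss_and_grads(
    params: ModelParameters,
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    config: ModelConfig,
    U: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    masks=None,
) -> tuple[LossBreakdown, dict[str, np.ndarray]]:
    """Supervised objective on one minibatch plus gradients for all params.

    One stochastic pass is used (fresh dropout masks per call), matching
    standard MC-dropout training; ``masks`` pins the dropout multipliers
    for gradient checking.
    """
    mask = np.asarray(mask, bool)
    y = np.asarray(y, float)
    pred, cache = forward(X, params, config, rng=rng, masks=masks)
    n, T = pred.shape
    counts = mask.sum(axis=0)
    ok = counts > 0
    safe_counts = np.where(ok, counts, 1)

    resid = np.where(mask, pred - np.where(mask, y, 0.0), 0.0)
    mse = (resid**2).sum(axis=0) / safe_counts
    mse[~ok] = 0.0

    sigma2 = np.exp(2.0 * params.log_sigma)
    if config.task_loss == "bnn":
        per_task = mse / (2.0 * sigma2) + params.log_sigma
        dldmse = 1.0 / (2.0 * sigma2)
        dldls = 1.0 - mse / sigma2
    else:
        per_task = mse.copy()
        dldmse = np.ones(T)
        dldls = np.zeros(T)
    per_task = np.where(ok, per_task, 0.0)

    w = compute_transfer_weight(params, config, U, task_loss_value=per_task)

    grads = _zero_grads(params)

    # --- prediction path -------------------------------------------------
    dpred = (2.0 * w * dldmse / safe_counts) * resid  # (n, T), masked
    dpred[:, ~ok] = 0.0
    Zd = cache["Zd"]
    grads["S"] += Zd.T @ dpred
    grads["bS"] += dpred.sum(axis=0)
    dZd = dpred @ params.S.T
    grads["log_sigma"] += np.where(ok, w * dldls, 0.0)

    # --- latent autoencoder ---------------------------------------------
    recon_val = reconstruction_loss(Zd, params.S, params.A, config.gamma)
    if config.gamma > 0:
        Pn = Zd @ params.S
        E = Pn @ params.A
        Zhat = np.maximum(E, 0.0)
        delta = Zd - Zhat
        g2 = 2.0 * config.gamma
        dZd += g2 * delta
        dE = (-g2 * delta) * (E > 0)
        grads["A"] += Pn.T @ dE
        dPn = dE @ params.A.T
        grads["S"] += Zd.T @ dPn
        dZd += dPn @ params.S.T

    # --- transfer-weight term acting on the decoder rows ----------------
    if config.transfer_mode == "uncertainty":
        Uv = np.zeros(T) if U is None else np.asarray(U, float)
        if config.transfer_weighting == "product":
            c = Uv * per_task
        else:
            c = per_task
        grads["A"] += c[:, None] * np.sign(params.A)
    elif config.transfer_mode == "loss":
        if config.loss_weight_form == "prose":
            c = config.alpha * per_task**2
        else:
            c = config.alpha * per_task
        grads["A"] += c[:, None] * np.sign(params.A)

    # --- elementwise penalties ------------------------------------------
    l1_s = config.mu * np.abs(params.S).sum(axis=0)
    grads["S"] += config.mu * np.sign(params.S)
    l2 = float(config.lam * np.sum(params.L**2))
    grads["L"] += 2.0 * config.lam * params.L

    # --- back through encoder -------------------------------------------
    dZ = dZd if cache["m_z"] is None else dZd * cache["m_z"]
    dH = dZ * (cache["H"] > 0)
    grads["L"] += cache["Xd"].T @ dH
    grads["bL"] += dH.sum(axis=0)

    tot = float(np.sum(w * per_task) + np.sum(l1_s) + recon_val + l2)
    breakdown = LossBreakdown(
        per_task_bnn=per_task, transfer_weight=w, l1_s=l1_s,
        recon=recon_val, l2_L=l2, adv=0.0, total=tot,
    )
    return breakdown, grads


def adversarial_loss_and_grads(
    params: ModelParameters,
    X_source: np.ndarray,
    X_target: np.ndarray,
    config: ModelConfig,
    lam_adv: float,
    rng: np.random.Generator | None = None,
    masks_source=None,
    masks_target=None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Domain-confusion loss and descent directions for one paired batch.

    The discriminator receives +d(loss)/d(D): stepping down makes it
    classify domains better. The encoder receives the lam_adv-scaled
    gradient passed through the reversal layer (sign flipped), so the same
    descent step pushes the latent features toward domain confusion. This
    realizes the min-max in a single backward sweep.
    """
    grads = _zero_grads(params)
    _, cache_s = forward(X_source, params, config, rng=rng, masks=masks_source)
    _, cache_t = forward(X_target, params, config, rng=rng, masks=masks_target)
    Zs, Zt = cache_s["Z"], cache_t["Z"]
    ps = discriminate(Zs, params)
    pt = discriminate(Zt, params)
    loss = adversarial_loss(ps, pt)

    ns, nt = len(ps), len(pt)
    gs = -(1.0 - ps) / ns     # d loss / d logit, source rows
    gt = pt / nt              # d loss / d logit, target rows

    # discriminator descends its cross-entropy (unscaled; its own step
    # size is set by the trainer)
    grads["D_w"] += Zs.T @ gs + Zt.T @ gt
    grads["D_b"] += gs.sum() + gt.sum()

    # encoder path: through the gradient reversal layer
    for cache, g in ((cache_s, gs), (cache_t, gt)):
        dZ = grl_backward(np.outer(g, params.D_w), scale=lam_adv)
        dH = dZ * (cache["H"] > 0)
        grads["L"] += cache["Xd"].T @ dH
        grads["bL"] += dH.sum(axis=0)
    return loss, grads
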