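"""Optimization loops: supervised multi-task training and transductive
adversarial domain adaptation.

Both loops share one code path; domain adaptation interleaves a
supervised step on a labeled source minibatch with an adversarial step on
paired source/target minibatches. Target responses are never read — the
interface does not even accept them. All randomness flows from the single
seed in the config, and the default mode is single-threaded numpy, so runs
are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import DrugResponseDataset
from .gradients import adversarial_loss_and_grads, supervised_loss_and_grads
from .losses import LossBreakdown
from .model import (
    ModelConfig,
    ModelParameters,
    StochasticPrediction,
    TaskUncertainty,
    init_model,
    mc_forward,
    task_epistemic,
)

__all__ = ["TrainReport", "train_mtl", "train_da", "predict"]


@dataclass
class TrainReport:
    """Per-epoch loss components plus the final task uncertainties."""

    loss_history: list[LossBreakdown] = field(default_factory=list)
    final_uncertainty: TaskUncertainty | None = None
    epochs_run: int = 0
    best_epoch: int = 0
    val_mse_history: list[float] = field(default_factory=list)
    seed: int = 0
    config: ModelConfig | None = None

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for epoch, (bd, vmse) in enumerate(
                zip(self.loss_history, self.val_mse_history)
            ):
                rec = {"epoch": epoch, "val_mse": vmse, **bd.to_record()}
                if self.final_uncertainty is not None and epoch == self.epochs_run - 1:
                    rec["U"] = self.final_uncertainty.epistemic.tolist()
                    rec["sigma"] = self.final_uncertainty.aleatoric.tolist()
                fh.write(json.dumps(rec) + "\n")


class _Adam:
    """Plain Adam; one slot pair per named parameter array."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: ModelParameters, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if name == "D_b":
                params.D_b = float(params.D_b - upd[0])
            else:
                setattr(params, name, getattr(params, name) - upd)


def _masked_mse(pred: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() == 0:
        return float("nan")
    resid = (pred - np.where(mask, y, 0.0))[mask]
    return float(np.mean(resid**2))


def _mean_breakdown(parts: list[LossBreakdown], adv_vals: list[float],
                    lam_adv: float) -> LossBreakdown:
    bd = LossBreakdown(
        per_task_bnn=np.mean([p.per_task_bnn for p in parts], axis=0),
        transfer_weight=np.mean([p.transfer_weight for p in parts], axis=0),
        l1_s=np.mean([p.l1_s for p in parts], axis=0),
        recon=float(np.mean([p.recon for p in parts])),
        l2_L=float(np.mean([p.l2_L for p in parts])),
        adv=float(np.mean(adv_vals)) if adv_vals else 0.0,
        total=0.0,
    )
    bd.total = bd.mtl_total() + lam_adv * bd.adv
    return bd


def _train(
    source: DrugResponseDataset,
    target_expression: np.ndarray | None,
    config: ModelConfig,
) -> tuple[ModelParameters, TrainReport]:
    X_all, Y_all, M_all = source.expression, source.response, source.mask
    if np.any(M_all.sum(axis=0) == 0):
        raise ValueError("every task needs at least one observed response")
    if target_expression is not None:
        target_expression = np.asarray(target_expression, float)
        if target_expression.shape[1] != source.n_genes:
            raise ValueError(
                f"target has {target_expression.shape[1]} genes, source has "
                f"{source.n_genes}"
            )

    rng = np.random.default_rng(config.seed)
    params = init_model(config, source.n_genes, source.n_tasks)
    opt = _Adam(config.learning_rate)

    n = source.n_samples
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation split leaves no training samples")
    Xtr, Ytr, Mtr = X_all[tr_idx], Y_all[tr_idx], M_all[tr_idx]
    if n_val > 0:
        Xva, Yva, Mva = X_all[val_idx], Y_all[val_idx], M_all[val_idx]
    else:
        Xva, Yva, Mva = Xtr, Ytr, Mtr

    use_adv = target_expression is not None and config.lam_adv > 0
    T = source.n_tasks
    U = np.zeros(T)
    report = TrainReport(seed=config.seed, config=config)
    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    since_best = 0

    for epoch in range(config.n_epochs):
        if config.transfer_mode == "uncertainty" and config.dropout_rate > 0:
            sp = mc_forward(Xtr, params, config, rng=rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                U = task_epistemic(sp, Mtr)

        order = rng.permutation(len(tr_idx))
        if use_adv:
            t_order = rng.permutation(len(target_expression))
            t_pos = 0
        parts, adv_vals = [], []
        lam_adv_eff = config.lam_adv
        if use_adv and config.ganin_schedule:
            prog = epoch / max(config.n_epochs - 1, 1)
            lam_adv_eff = config.lam_adv * (2.0 / (1.0 + np.exp(-10 * prog)) - 1.0)

        for step, start in enumerate(range(0, len(order), config.batch_size)):
            idx = order[start:start + config.batch_size]
            bd, grads = supervised_loss_and_grads(
                params, Xtr[idx], Ytr[idx], Mtr[idx], config, U=U, rng=rng
            )
            if not np.isfinite(bd.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss "
                    f"(total={bd.total!r}); lower the learning rate"
                )
            parts.append(bd)
            grads.pop("D_w"), grads.pop("D_b")
            opt.step(params, grads)

            if use_adv and step % config.adv_ratio == 0:
                for _ in range(config.adv_steps):
                    bsz = min(config.batch_size, len(t_order))
                    if t_pos + bsz > len(t_order):
                        t_order = rng.permutation(len(target_expression))
                        t_pos = 0
                    t_idx = t_order[t_pos:t_pos + bsz]
                    t_pos += bsz
                    adv, agrads = adversarial_loss_and_grads(
                        params, Xtr[idx], target_expression[t_idx], config,
                        lam_adv=lam_adv_eff, rng=rng,
                    )
                    if not np.isfinite(adv):
                        raise RuntimeError(
                            f"adversarial loss diverged at epoch {epoch}"
                        )
                    # The min-max game uses plain SGD (the supervised loss
                    # keeps Adam): adaptive step-size normalization lets
                    # the encoder overshoot the discriminator and flip
                    # domains instead of aligning them. l2 decay keeps the
                    # discriminator's logits bounded so the reversed
                    # gradient into the encoder never saturates to zero.
                    agrads["D_w"] += 2.0 * config.disc_l2 * params.D_w
                    params.L -= config.adv_lr * agrads["L"]
                    params.bL -= config.adv_lr * agrads["bL"]
                    params.D_w -= config.disc_lr * agrads["D_w"]
                    params.D_b = float(
                        params.D_b - config.disc_lr * agrads["D_b"][0]
                    )
                    adv_vals.append(adv)

        report.loss_history.append(
            _mean_breakdown(parts, adv_vals, config.lam_adv)
        )

        # deterministic validation pass (dropout off)
        from .model import forward as _fwd
        val_pred, _ = _fwd(Xva, params, config, rng=None)
        vmse = _masked_mse(val_pred, Yva, Mva)
        report.val_mse_history.append(vmse)
        if vmse < best_val - 1e-12:
            best_val = vmse
            best_params = params.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if config.patience is not None and since_best > config.patience:
            break

    report.epochs_run = len(report.loss_history)
    report.best_epoch = best_epoch

    if config.dropout_rate > 0:
        sp = mc_forward(Xtr, best_params, config, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            U_final = task_epistemic(sp, Mtr)
    else:
        U_final = np.zeros(T)
    report.final_uncertainty = TaskUncertainty(
        epistemic=U_final, aleatoric=best_params.sigma()
    )
    return best_params, report


def train_mtl(
    data: DrugResponseDataset, config: ModelConfig
) -> tuple[ModelParameters, TrainReport]:
    """Supervised multi-task training (no domain alignment).

    Minibatch Adam on the uncertainty-weighted objective; the per-task
    epistemic uncertainty is refreshed once per epoch from MC-dropout
    passes over the training split. Returns the parameters of the best
    validation epoch.
    """
    return _train(data, None, config)


def train_da(
    source: DrugResponseDataset,
    target_expression: np.ndarray,
    config: ModelConfig,
) -> tuple[ModelParameters, TrainReport]:
    """Transductive domain adaptation: supervised steps on the labeled
    source interleaved with adversarial domain-confusion steps on paired
    source/target minibatches.

    All unlabeled target samples are used; target labels are never part of
    the interface. With lam_adv = 0 this reduces exactly to
    :func:`train_mtl` (same seed schedule, identical weights).
    """
    return _train(source, np.asarray(target_expression, float), config)


def predict(
    X: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
    P: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MC-dropout prediction: mean and per-sample epistemic variance.

    With dropout 0 the mean equals the deterministic forward pass and the
    variance is identically zero; with P = 1 the population variance of a
    single pass is zero by construction.
    """
    sp: StochasticPrediction = mc_forward(X, params, config, P=P, rng=rng)
    return sp.mean, sp.variance
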