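"""Uncertainty-aware multi-task network with adversarial domain alignment.

The architecture is deliberately shallow: a shared encoder L (one fully
connected layer, ReLU), a task layer S mapping the k latent features to T
drug responses, a decoder A (T -> k, no bias) that closes the
task-to-feature autoencoder loop, a learnable per-task log noise scale
(aleatoric uncertainty), and a single-layer logistic domain discriminator
on the latent features. Dropout is applied at train *and* test time
(MC dropout), so repeated stochastic passes sample an approximate weight
posterior; the spread of those passes is the epistemic uncertainty.

Everything is plain numpy; gradients are derived by hand in
:mod:`pharmadapt.gradients` and cross-checked against finite differences
in the test suite.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "StochasticPrediction",
    "TaskUncertainty",
    "init_model",
    "encode",
    "forward",
    "mc_forward",
    "task_epistemic",
    "discriminate",
    "grl_forward",
    "grl_backward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the model and its training loop.

    Parameters
    ----------
    n_latent : int
        Width k of the shared feature space Z.
    dropout_rate : float in [0, 1)
        Variational dropout probability (applied to the encoder input and,
        if ``dropout_task_layer``, to Z before the task layer).
    n_passes : int
        Number of stochastic forward passes P for prediction/uncertainty.
    mu : float
        l1 penalty on the task-layer columns s_t.
    lam : float
        l2 (Frobenius) penalty on the encoder weights L.
    gamma : float
        Weight of the latent autoencoder reconstruction term.
    lam_adv : float
        Weight of the adversarial domain-confusion term.
    alpha : float
        Loss-weighted transfer coefficient (used by the loss-weighted
        autoencoder baseline; ignored in uncertainty mode).
    transfer_mode : {"uncertainty", "none", "loss"}
        How the per-task transfer weight is formed: from epistemic
        uncertainty (the full model), not at all (shared-latent baseline),
        or from the task loss (autoencoder baseline).
    transfer_weighting : {"product", "sum"}
        In uncertainty mode, 1 + U_t * ||a_t||_1 (product, default) or
        1 + U_t + ||a_t||_1 (sum).
    loss_weight_form : {"prose", "printed"}
        In loss mode, 1 + alpha * loss_t * ||a_t||_1 versus
        (1 + alpha * ||a_t||_1) * loss_t.
    task_loss : {"bnn", "mse"}
        Heteroscedastic loss with learnable sigma_t, or plain MSE.
    dropout_task_layer : bool
        Apply a dropout mask to Z before S as well as to the input.
    """

    n_latent: int = 8
    dropout_rate: float = 0.1
    n_passes: int = 30
    mu: float = 1e-4
    lam: float = 1e-4
    gamma: float = 1e-3
    lam_adv: float = 0.0
    alpha: float = 0.0
    transfer_mode: str = "uncertainty"
    transfer_weighting: str = "product"
    loss_weight_form: str = "prose"
    task_loss: str = "bnn"
    dropout_task_layer: bool = True
    learning_rate: float = 1e-2
    n_epochs: int = 150
    batch_size: int = 64
    val_fraction: float = 0.1
    patience: int | None = None
    adv_ratio: int = 1
    adv_steps: int = 1
    ganin_schedule: bool = False
    disc_l2: float = 0.05
    adv_lr: float = 0.02
    disc_lr: float = 0.1
    u_aggregation: str = "train_set"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_latent < 1 or self.n_passes < 1:
            raise ValueError("n_latent and n_passes must be positive")
        for name in ("mu", "lam", "gamma", "lam_adv", "alpha"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and non-negative")
        if self.transfer_mode not in ("uncertainty", "none", "loss"):
            raise ValueError("unknown transfer_mode")
        if self.transfer_weighting not in ("product", "sum"):
            raise ValueError("unknown transfer_weighting")
        if self.loss_weight_form not in ("prose", "printed"):
            raise ValueError("unknown loss_weight_form")
        if self.task_loss not in ("bnn", "mse"):
            raise ValueError("unknown task_loss")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1 or self.batch_size < 1:
            raise ValueError("n_epochs and batch_size must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass
class ModelParameters:
    """All learnable arrays of the network."""

    L: np.ndarray            # (d, k) encoder weights
    bL: np.ndarray           # (k,)
    S: np.ndarray            # (k, T) task layer; column t is s_t
    bS: np.ndarray           # (T,)
    A: np.ndarray            # (T, k) decoder; row t is a_t, no bias
    log_sigma: np.ndarray    # (T,) log aleatoric noise scale
    D_w: np.ndarray          # (k,) discriminator weights
    D_b: float = 0.0

    _FIELDS = ("L", "bL", "S", "bS", "A", "log_sigma", "D_w", "D_b")

    @property
    def n_genes(self) -> int:
        return self.L.shape[0]

    @property
    def n_latent(self) -> int:
        return self.L.shape[1]

    @property
    def n_tasks(self) -> int:
        return self.S.shape[1]

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            L=self.L.copy(), bL=self.bL.copy(), S=self.S.copy(),
            bS=self.bS.copy(), A=self.A.copy(),
            log_sigma=self.log_sigma.copy(), D_w=self.D_w.copy(),
            D_b=float(self.D_b),
        )

    def sigma(self) -> np.ndarray:
        """Aleatoric noise scales sigma_t = exp(log_sigma_t)."""
        return np.exp(self.log_sigma)


@dataclass
class StochasticPrediction:
    """P MC-dropout passes with their per-entry mean and spread.

    ``variance`` uses the population (1/P) normalization: the epistemic
    uncertainty of a prediction is the second central moment of the pass
    distribution, not an unbiased sample-variance estimate.
    """

    passes: np.ndarray    # (P, n, T)
    mean: np.ndarray      # (n, T)
    variance: np.ndarray  # (n, T)


@dataclass
class TaskUncertainty:
    """Per-task epistemic (U_t) and aleatoric (sigma_t) uncertainty."""

    epistemic: np.ndarray  # (T,)
    aleatoric: np.ndarray  # (T,)


def init_model(config: ModelConfig, n_genes: int, n_tasks: int) -> ModelParameters:
    """Fan-in-scaled Gaussian initialization; sigma_t starts at 1.

    The task-specific columns of S and rows of A start identical (one
    shared random vector each): every drug begins from the same prior
    predictor, so training is equivariant to the ordering of the drug
    columns. The per-task gradients break the symmetry at the first step.
    """
    if n_genes < 1 or n_tasks < 1:
        raise ValueError("n_genes and n_tasks must be >= 1")
    k = config.n_latent
    rng = np.random.default_rng(config.seed)
    s0 = rng.normal(0.0, np.sqrt(1.0 / k), size=k)
    a0 = rng.normal(0.0, np.sqrt(1.0 / n_tasks), size=k)
    params = ModelParameters(
        L=rng.normal(0.0, np.sqrt(2.0 / n_genes), size=(n_genes, k)),
        bL=np.zeros(k),
        S=np.tile(s0[:, None], (1, n_tasks)),
        bS=np.zeros(n_tasks),
        A=np.tile(a0[None, :], (n_tasks, 1)),
        log_sigma=np.zeros(n_tasks),
        D_w=rng.normal(0.0, np.sqrt(1.0 / k), size=k),
        D_b=0.0,
    )
    return params


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with prob rate, else 1/(1-rate)."""
    keep = 1.0 - rate
    return (rng.random(shape) < keep) / keep


def encode(
    X: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent features Z = ReLU(X L + b), with input dropout if stochastic.

    Pass ``rng`` to draw a dropout mask (stochastic/MC mode); omit it for
    the deterministic forward pass. With dropout_rate = 0 both modes agree.
    """
    X = np.asarray(X, float)
    if X.shape[1] != params.n_genes:
        raise ValueError(
            f"X has {X.shape[1]} genes, model expects {params.n_genes}"
        )
    if rng is not None and config.dropout_rate > 0:
        X = X * _dropout_mask(rng, X.shape, config.dropout_rate)
    return np.maximum(X @ params.L + params.bL, 0.0)


def forward(
    X: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    masks: tuple[np.ndarray | None, np.ndarray | None] | None = None,
) -> tuple[np.ndarray, dict]:
    """One forward pass; returns predictions (n, T) and a cache for backprop.

    ``masks`` fixes the dropout multipliers explicitly (used by the
    finite-difference gradient checks); otherwise they are drawn from
    ``rng`` when given.
    """
    X = np.asarray(X, float)
    if X.shape[1] != params.n_genes:
        raise ValueError(
            f"X has {X.shape[1]} genes, model expects {params.n_genes}"
        )
    m_in = m_z = None
    if masks is not None:
        m_in, m_z = masks
    elif rng is not None and config.dropout_rate > 0:
        m_in = _dropout_mask(rng, X.shape, config.dropout_rate)
        if config.dropout_task_layer:
            m_z = _dropout_mask(
                rng, (X.shape[0], params.n_latent), config.dropout_rate
            )
    Xd = X if m_in is None else X * m_in
    H = Xd @ params.L + params.bL
    Z = np.maximum(H, 0.0)
    Zd = Z if m_z is None else Z * m_z
    pred = Zd @ params.S + params.bS
    cache = {"X": X, "Xd": Xd, "H": H, "Z": Z, "Zd": Zd,
             "m_in": m_in, "m_z": m_z}
    return pred, cache


def mc_forward(
    X: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
    P: int | None = None,
    rng: np.random.Generator | None = None,
) -> StochasticPrediction:
    """P stochastic passes; mean and population (1/P) variance per entry."""
    P = config.n_passes if P is None else int(P)
    if P < 1:
        raise ValueError("P must be >= 1")
    if config.dropout_rate == 0:
        # deterministic network: identical passes, exactly zero spread
        out, _ = forward(X, params, config)
        passes = np.broadcast_to(out, (P, *out.shape)).copy()
        return StochasticPrediction(
            passes=passes, mean=out.copy(), variance=np.zeros_like(out)
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = np.asarray(X).shape[0]
    passes = np.empty((P, n, params.n_tasks))
    for p in range(P):
        passes[p], _ = forward(X, params, config, rng=rng)
    mean = passes.mean(axis=0)
    variance = passes.var(axis=0)  # ddof=0: population form
    return StochasticPrediction(passes=passes, mean=mean, variance=variance)


def task_epistemic(pred: StochasticPrediction, mask: np.ndarray) -> np.ndarray:
    """Per-task epistemic uncertainty U_t.

    The per-sample MC-dropout variance is averaged over the observed
    samples of each task. A task with no observed sample gets U_t = 0 and
    a warning.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != pred.variance.shape:
        raise ValueError("mask shape must match prediction shape")
    counts = mask.sum(axis=0)
    U = np.zeros(mask.shape[1])
    ok = counts > 0
    if not np.all(ok):
        warnings.warn(
            f"tasks with no observed samples get U_t = 0: "
            f"{np.flatnonzero(~ok).tolist()}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        sums = np.where(mask, pred.variance, 0.0).sum(axis=0)
    U[ok] = sums[ok] / counts[ok]
    return U


def discriminate(Z: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Probability that each latent row comes from the source domain."""
    Z = np.asarray(Z, float)
    if Z.shape[1] != params.n_latent:
        raise ValueError(
            f"Z has {Z.shape[1]} columns, discriminator expects {params.n_latent}"
        )
    logits = Z @ params.D_w + params.D_b
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    return np.clip(p, eps, 1.0 - eps)


def grl_forward(Z: np.ndarray) -> np.ndarray:
    """Gradient reversal layer, forward: the identity."""
    return np.asarray(Z)


def grl_backward(grad_output: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Gradient reversal layer, backward: negate (and optionally scale)."""
    return -scale * np.asarray(grad_output)


# ---------------------------------------------------------------------------
# Checkpoint container: JSON manifest + raw little-endian float64 segments.
# Avoids zip timestamps so identical states serialize to identical bytes.
# ---------------------------------------------------------------------------

_MAGIC = b"PHADCKPT1\n"


def save_checkpoint(
    path,
    params: ModelParameters,
    config: ModelConfig,
    rng_state: dict | None = None,
) -> None:
    arrays = {
        "L": params.L, "bL": params.bL, "S": params.S, "bS": params.bS,
        "A": params.A, "log_sigma": params.log_sigma, "D_w": params.D_w,
        "D_b": np.asarray([params.D_b]),
    }
    manifest = {
        "config": config.to_dict(),
        "rng_state": rng_state,
        "arrays": {k: list(v.shape) for k, v in arrays.items()},
    }
    buf = io.BytesIO()
    buf.write(_MAGIC)
    head = json.dumps(manifest, sort_keys=True).encode()
    buf.write(len(head).to_bytes(8, "little"))
    buf.write(head)
    for k in sorted(arrays):
        buf.write(np.ascontiguousarray(arrays[k], dtype="<f8").tobytes())
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> tuple[ModelParameters, ModelConfig, dict | None]:
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(_MAGIC):
        raise ValueError(f"{path} is not a model checkpoint")
    off = len(_MAGIC)
    hlen = int.from_bytes(raw[off:off + 8], "little")
    off += 8
    manifest = json.loads(raw[off:off + hlen].decode())
    off += hlen
    arrays = {}
    for k in sorted(manifest["arrays"]):
        shape = tuple(manifest["arrays"][k])
        size = int(np.prod(shape)) if shape else 1
        arrays[k] = np.frombuffer(
            raw, dtype="<f8", count=size, offset=off
        ).reshape(shape).copy()
        off += size * 8
    params = ModelParameters(
        L=arrays["L"], bL=arrays["bL"], S=arrays["S"], bS=arrays["bS"],
        A=arrays["A"], log_sigma=arrays["log_sigma"], D_w=arrays["D_w"],
        D_b=float(arrays["D_b"][0]),
    )
    config = ModelConfig.from_dict(manifest["config"])
    return params, config, manifest.get("rng_state")
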