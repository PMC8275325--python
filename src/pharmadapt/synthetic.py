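"""Synthetic multi-task / multi-domain pharmacogenomic data.

The generator emulates the statistical structure that shared-latent-basis
multi-task learners exploit: per-drug weight vectors w_t = L* s*_t lying in
a common low-rank subspace, per-task heteroscedastic Gaussian noise, a few
"outlier" drugs whose weights ignore the shared bases, drugs with very
small cohorts, and a second (target) domain whose expression marginals are
shifted and where a subset of drugs violates the covariate-shift
assumption (their conditional P(Y|X) differs between domains).

Expression is emitted already standardized (iid standard normal per gene);
no attempt is made to simulate realistic transcriptomic covariance, batch
effects or tissue structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import DrugResponseDataset

__all__ = [
    "MtlScenario",
    "DaScenario",
    "GroundTruth",
    "DaGroundTruth",
    "generate_mtl",
    "generate_da",
]


@dataclass
class MtlScenario:
    """Configuration of a multi-task generative scenario.

    Parameters
    ----------
    n_genes : int
        Input dimensionality d.
    n_latent : int
        Rank k of the ground-truth weight matrix W* = L* S*.
    n_tasks : int
        Number of drugs T.
    samples_per_task : sequence of int
        Observed cohort size N_t for each drug; the dataset has
        max(N_t) samples and drug t is observed on the first N_t of them
        (block missingness, mirroring per-drug cohort sizes), unless
        ``random_mask`` is set.
    noise_sd_per_task : sequence of float
        True aleatoric noise scale sigma*_t of each drug.
    outlier_tasks : set of int
        Drugs whose weight vector is drawn densely and independently of the
        shared bases (conditionally unrelated tasks — the generative model
        of negative-transfer sources).
    sparsity : float in [0, 1)
        Fraction of entries of S* forced to zero.
    weight_scale : float
        Std of nonzero entries of L* and S* (and of outlier weights).
    signal_sd : float or None
        If set (default 3.0), every task's weight vector is rescaled so the
        noiseless signal X w*_t has exactly this standard deviation under
        standard-normal expression — mirroring response matrices whose
        per-drug scale is comparable after preprocessing. None keeps the
        raw w*_t = L* s*_t scale.
    random_mask : bool
        If True, observed entries are a uniform random subset of size N_t
        per drug rather than the leading block.
    seed : int
    """

    n_genes: int = 50
    n_latent: int = 8
    n_tasks: int = 10
    samples_per_task: Sequence[int] = ()
    noise_sd_per_task: Sequence[float] = ()
    outlier_tasks: frozenset = frozenset()
    sparsity: float = 0.3
    weight_scale: float = 1.0
    signal_sd: float | None = 3.0
    random_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples_per_task:
            self.samples_per_task = [200] * self.n_tasks
        if len(self.noise_sd_per_task) == 0:
            self.noise_sd_per_task = [0.5] * self.n_tasks
        self.samples_per_task = list(self.samples_per_task)
        self.noise_sd_per_task = list(self.noise_sd_per_task)
        self.outlier_tasks = frozenset(self.outlier_tasks)
        if self.n_genes < 1 or self.n_latent < 1 or self.n_tasks < 1:
            raise ValueError("n_genes, n_latent and n_tasks must be positive")
        if self.n_latent > self.n_genes:
            raise ValueError("n_latent must not exceed n_genes")
        if len(self.samples_per_task) != self.n_tasks:
            raise ValueError("samples_per_task length must equal n_tasks")
        if len(self.noise_sd_per_task) != self.n_tasks:
            raise ValueError("noise_sd_per_task length must equal n_tasks")
        if any(n <= 0 for n in self.samples_per_task):
            raise ValueError("sample counts must be positive")
        if any(s < 0 for s in self.noise_sd_per_task):
            raise ValueError("noise SDs must be non-negative")
        if not self.outlier_tasks <= set(range(self.n_tasks)):
            raise ValueError("outlier_tasks must be valid task indices")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")


@dataclass
class DaScenario:
    """A source scenario plus a shifted, partially violated target domain.

    The target domain draws expression from the same latent process and
    applies a per-gene affine transform ``x -> scale * x + shift``.
    Drugs in ``violated_tasks`` have different weight vectors in the target
    domain (conditional shift: P(Y|X) changes), so no amount of marginal
    alignment can make source predictors correct for them.
    """

    base: MtlScenario = field(default_factory=MtlScenario)
    n_target: int = 200
    shift: Sequence[float] | float = 0.0
    scale: Sequence[float] | float = 1.0
    violated_tasks: frozenset = frozenset()
    violation: str = "negate"  # "negate" or "fresh"
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.base.n_genes
        self.shift = np.broadcast_to(np.asarray(self.shift, float), (d,)).copy()
        self.scale = np.broadcast_to(np.asarray(self.scale, float), (d,)).copy()
        self.violated_tasks = frozenset(self.violated_tasks)
        if self.n_target < 1:
            raise ValueError("n_target must be positive")
        if np.any(self.scale <= 0):
            raise ValueError("scale entries must be positive")
        if not self.violated_tasks <= set(range(self.base.n_tasks)):
            raise ValueError("violated_tasks must be valid task indices")
        if self.violation not in ("negate", "fresh"):
            raise ValueError("violation must be 'negate' or 'fresh'")


@dataclass
class GroundTruth:
    """Hidden parameters behind a generated dataset."""

    L: np.ndarray          # (d, k) shared bases
    S: np.ndarray          # (k, T) combination vectors
    weights: np.ndarray    # (d, T) effective per-task weights (incl. outliers)
    noise_sd: np.ndarray   # (T,)
    outlier_tasks: frozenset


@dataclass
class DaGroundTruth:
    """Hidden target-domain evaluation truth (never fed to training)."""

    response: np.ndarray          # (n_target, T) noiseless-free? see generate_da
    responder: np.ndarray         # (n_target, T) bool, per-task median split
    weights: np.ndarray           # (d, T) target-domain weights
    violated_tasks: frozenset


def _draw_truth(scenario: MtlScenario, rng: np.random.Generator) -> GroundTruth:
    d, k, T = scenario.n_genes, scenario.n_latent, scenario.n_tasks
    sc = scenario.weight_scale
    L = rng.normal(0.0, sc / np.sqrt(k), size=(d, k))
    S = rng.normal(0.0, sc, size=(k, T))
    if scenario.sparsity > 0:
        S *= rng.random(size=S.shape) >= scenario.sparsity
        # keep every column informative
        for t in range(T):
            if not np.any(S[:, t]):
                S[rng.integers(k), t] = rng.normal(0.0, sc)
    W = L @ S
    # outlier drugs: dense weights independent of the shared bases, matched
    # in per-entry magnitude to the in-subspace tasks
    w_sd = sc * sc * np.sqrt(max(1.0 - scenario.sparsity, 1e-12))
    for t in sorted(scenario.outlier_tasks):
        W[:, t] = rng.normal(0.0, w_sd, size=d)
    if scenario.signal_sd is not None:
        # per-drug signal scale is fixed: ||w_t|| = signal_sd, so the
        # noiseless response has the same SD for every drug
        W *= scenario.signal_sd / np.linalg.norm(W, axis=0, keepdims=True)
    return GroundTruth(
        L=L,
        S=S,
        weights=W,
        noise_sd=np.asarray(scenario.noise_sd_per_task, float),
        outlier_tasks=scenario.outlier_tasks,
    )


def generate_mtl(
    scenario: MtlScenario,
) -> tuple[DrugResponseDataset, GroundTruth]:
    """Draw a multi-task dataset with shared low-rank task structure.

    Expression entries are iid standard normal. For a non-outlier drug t,
    y_t = X L* s*_t + eps_t with eps_t ~ N(0, sigma*_t^2); outlier drugs use
    an independent dense weight vector. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(scenario.seed)
    truth = _draw_truth(scenario, rng)
    n = int(max(scenario.samples_per_task))
    T = scenario.n_tasks
    X = rng.standard_normal((n, scenario.n_genes))
    signal = X @ truth.weights
    noise = rng.standard_normal((n, T)) * truth.noise_sd
    Y = signal + noise
    mask = np.zeros((n, T), dtype=bool)
    for t, n_t in enumerate(scenario.samples_per_task):
        if scenario.random_mask:
            idx = rng.choice(n, size=int(n_t), replace=False)
            mask[idx, t] = True
        else:
            mask[: int(n_t), t] = True
    resp = np.where(mask, Y, np.nan)
    data = DrugResponseDataset(expression=X, response=resp, mask=mask)
    return data, truth


def generate_da(
    scenario: DaScenario,
) -> tuple[DrugResponseDataset, np.ndarray, DaGroundTruth]:
    """Draw a labeled source dataset plus an unlabeled, shifted target.

    Returns ``(source, target_expression, target_truth)``. Target
    expression is an affine per-gene transform of draws from the same
    process as the source. Target responses use the source weights except
    for violated drugs (negated or freshly drawn weights) and are returned
    only inside the hidden evaluation truth, together with binary responder
    labels from a per-drug median split.
    """
    source, truth = generate_mtl(scenario.base)
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, scenario.base.seed, 7])
    )
    d = scenario.base.n_genes
    T = scenario.base.n_tasks
    X_raw = rng.standard_normal((scenario.n_target, d))
    X_target = X_raw * scenario.scale + scenario.shift

    W_target = truth.weights.copy()
    for t in sorted(scenario.violated_tasks):
        if scenario.violation == "negate":
            W_target[:, t] = -W_target[:, t]
        else:
            sc = scenario.base.weight_scale
            w_sd = sc * sc * np.sqrt(max(1.0 - scenario.base.sparsity, 1e-12))
            w_new = rng.normal(0.0, w_sd, size=d)
            if scenario.base.signal_sd is not None:
                w_new *= scenario.base.signal_sd / np.linalg.norm(w_new)
            W_target[:, t] = w_new
    # Conditional model acts on the underlying (unshifted) biology: the
    # affine transform is a measurement-scale shift, so Y|X is defined via
    # the raw draws for non-violated drugs (pure covariate shift) and via
    # the perturbed weights for violated ones.
    noise = rng.standard_normal((scenario.n_target, T)) * truth.noise_sd
    Y_target = X_raw @ W_target + noise
    responder = Y_target < np.median(Y_target, axis=0, keepdims=True)
    target_truth = DaGroundTruth(
        response=Y_target,
        responder=responder,
        weights=W_target,
        violated_tasks=scenario.violated_tasks,
    )
    return source, X_target, target_truth
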