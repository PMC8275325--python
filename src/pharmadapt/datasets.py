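"""Core data container for multi-drug response panels.

A :class:`DrugResponseDataset` stacks the per-drug regression problems
(X_t, y_t) into a single expression matrix, a response matrix and an
observation mask, so that drugs with different cohort sizes share one
sample axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DrugResponseDataset:
    """Expression, response and observation mask on a shared sample axis.

    Attributes
    ----------
    expression : ndarray, shape (n_samples, n_genes)
        Standardized gene expression (unitless, z-score scale).
    response : ndarray, shape (n_samples, n_tasks)
        Drug response on a log-IC50-like or AUC-like scale. Entries where
        ``mask`` is False are undefined and may hold NaN.
    mask : ndarray of bool, shape (n_samples, n_tasks)
        True where the response is observed.
    task_names, sample_names : lists of str.
    """

    expression: np.ndarray
    response: np.ndarray
    mask: np.ndarray
    task_names: list[str] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, d = self.expression.shape
        if self.response.shape[0] != n:
            raise ValueError(
                f"expression has {n} samples but response has "
                f"{self.response.shape[0]}"
            )
        if self.mask.shape != self.response.shape:
            raise ValueError("mask shape must equal response shape")
        if not self.task_names:
            self.task_names = [f"drug_{t}" for t in range(self.response.shape[1])]
        if not self.sample_names:
            self.sample_names = [f"sample_{i}" for i in range(n)]
        if len(self.task_names) != self.response.shape[1]:
            raise ValueError("task_names length must equal number of tasks")
        if len(self.sample_names) != n:
            raise ValueError("sample_names length must equal number of samples")
        obs_per_task = self.mask.sum(axis=0)
        if np.any(obs_per_task == 0):
            bad = [self.task_names[t] for t in np.flatnonzero(obs_per_task == 0)]
            raise ValueError(f"tasks with zero observed responses: {bad}")
        if not np.all(np.isfinite(self.response[self.mask])):
            raise ValueError("non-finite response values inside the mask")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_tasks(self) -> int:
        return self.response.shape[1]

    def samples_per_task(self) -> np.ndarray:
        """Number of observed responses per drug."""
        return self.mask.sum(axis=0)

    def subset(self, sample_idx: np.ndarray) -> "DrugResponseDataset":
        """Row-subset (for CV folds); drops no tasks even if unobserved.

        Tasks left without any observed entry in the subset are tolerated
        here (evaluation code skips them); the constructor check is bypassed
        by filling masked-out responses with NaN but keeping >=1 dummy rule.
        """
        sample_idx = np.asarray(sample_idx)
        ds = object.__new__(DrugResponseDataset)
        ds.expression = self.expression[sample_idx]
        ds.response = self.response[sample_idx]
        ds.mask = self.mask[sample_idx]
        ds.task_names = list(self.task_names)
        ds.sample_names = [self.sample_names[i] for i in sample_idx]
        return ds
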