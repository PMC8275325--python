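"""Evaluation protocols: nested cross-validation with inner hyperparameter
search, negative-transfer quantification against the single-task baseline,
and the two domain-transfer statistics (Spearman rank correlation against
continuous response; one-sided Mann-Whitney with common-language effect
size for responder / non-responder splits).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DrugResponseDataset

__all__ = [
    "NtReport",
    "ResponderTestResult",
    "nested_cv",
    "negative_transfer",
    "stratify_by_sample_size",
    "spearman_eval",
    "responder_test",
    "evaluate_da",
    "write_nt_report",
]


@dataclass
class NtReport:
    """Per-task MSE deltas (multi-task minus single-task) and NT flags.

    A positive delta means the jointly trained model is worse than the
    single-task baseline for that drug — negative transfer.
    """

    per_task_delta: np.ndarray
    nt_flags: np.ndarray
    n_nt: int
    fraction_no_nt: float


@dataclass
class ResponderTestResult:
    """One-sided Mann-Whitney outcome for a responder/non-responder split.

    ``effect_size`` is the common-language effect size U/(n1*n2): the
    probability that a random responder's predicted response is lower than
    a random non-responder's.
    """

    p_value: float
    effect_size: float
    n_responders: int
    n_nonresponders: int


def nested_cv(
    data: DrugResponseDataset,
    learner_factory,
    candidates: list[dict],
    outer_folds: int = 3,
    inner_folds: int = 3,
    search_budget: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Nested CV with sample-level folds and inner random search.

    The outer split partitions samples (cell lines), never per-task rows,
    so no sample is simultaneously trained on and tested. For each outer
    fold the inner loop scores up to ``search_budget`` hyperparameter
    candidates by inner-validation MSE, refits the winner on the full
    outer-training set and records per-task MSE on the outer test fold
    (NaN, with a warning, for tasks unobserved there).

    Returns an array of shape (outer_folds, n_tasks).
    """
    rng = np.random.default_rng(seed)
    n = data.n_samples
    perm = rng.permutation(n)
    outer = np.array_split(perm, outer_folds)

    if search_budget is not None and search_budget < len(candidates):
        pick = rng.choice(len(candidates), size=search_budget, replace=False)
        candidates = [candidates[i] for i in sorted(pick)]

    out = np.full((outer_folds, data.n_tasks), np.nan)
    for f, test_idx in enumerate(outer):
        train_idx = np.concatenate([outer[g] for g in range(outer_folds) if g != f])
        train = data.subset(train_idx)

        if len(candidates) > 1:
            inner = np.array_split(rng.permutation(len(train_idx)), inner_folds)
            scores = []
            for hyper in candidates:
                fold_scores = []
                for i, val_local in enumerate(inner):
                    tr_local = np.concatenate(
                        [inner[g] for g in range(inner_folds) if g != i]
                    )
                    sub_tr = train.subset(tr_local)
                    sub_va = train.subset(val_local)
                    model = learner_factory(hyper).fit(sub_tr)
                    pred = model.predict(sub_va.expression)
                    m = sub_va.mask
                    if m.sum() == 0:
                        continue
                    resid = (pred - np.where(m, sub_va.response, 0.0))[m]
                    fold_scores.append(np.mean(resid**2))
                scores.append(np.mean(fold_scores))
            best = candidates[int(np.argmin(scores))]
        else:
            best = candidates[0]

        model = learner_factory(best).fit(train)
        test = data.subset(test_idx)
        pred = model.predict(test.expression)
        for t in range(data.n_tasks):
            m = test.mask[:, t]
            if m.sum() == 0:
                warnings.warn(
                    f"outer fold {f}: task {t} has no observed test sample; "
                    "skipped", stacklevel=2,
                )
                continue
            out[f, t] = np.mean(
                (pred[m, t] - test.response[m, t]) ** 2
            )
    return out


def negative_transfer(
    mse_mtl: np.ndarray, mse_stl: np.ndarray, tol: float = 0.0
) -> NtReport:
    """Count drugs where joint training hurts versus single-task models.

    delta_t = MSE_MTL,t - MSE_STL,t; NT iff delta_t > tol (strict;
    tol = 0 by default, a small band can absorb floating-point ties).
    """
    mse_mtl = np.asarray(mse_mtl, float)
    mse_stl = np.asarray(mse_stl, float)
    if mse_mtl.shape != mse_stl.shape:
        raise ValueError("MSE vectors must have equal length")
    delta = mse_mtl - mse_stl
    flags = delta > tol
    n_nt = int(flags.sum())
    return NtReport(
        per_task_delta=delta,
        nt_flags=flags,
        n_nt=n_nt,
        fraction_no_nt=1.0 - n_nt / len(delta),
    )


def stratify_by_sample_size(
    mse_mtl: np.ndarray,
    mse_stl: np.ndarray,
    samples_per_task: np.ndarray,
    threshold: int,
    tol: float = 0.0,
) -> dict[str, NtReport]:
    """Negative-transfer reports for small-cohort vs large-cohort drugs."""
    counts = np.asarray(samples_per_task)
    small = counts <= threshold
    out = {}
    for name, sel in (("small", small), ("large", ~small)):
        if sel.any():
            out[name] = negative_transfer(mse_mtl[sel], mse_stl[sel], tol=tol)
    return out


def spearman_eval(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN (with a warning) for constant inputs, where the
    correlation is undefined.
    """
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape or predicted.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        warnings.warn("constant input: Spearman undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(predicted, measured).statistic
    return float(rho)


def responder_test(
    pred: np.ndarray, labels: np.ndarray
) -> ResponderTestResult:
    """One-sided Mann-Whitney: are responders' predictions lower?

    Lower predicted response (AUC/IC50 scale) means sensitivity, so the
    alternative is that the responder group is stochastically smaller.
    scipy picks the exact null distribution for small tie-free samples and
    the tie-corrected normal approximation otherwise. The effect size is
    U/(n1*n2) with U counting (responder < non-responder) pairs.
    """
    pred = np.asarray(pred, float)
    labels = np.asarray(labels, bool)
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must align")
    x = pred[labels]
    y = pred[~labels]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both responder groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="less", method="auto")
    # scipy's U counts pairs where x > y (+ half-ties); flip to the
    # alternative-concordant count.
    u_less = len(x) * len(y) - res.statistic
    return ResponderTestResult(
        p_value=float(res.pvalue),
        effect_size=float(u_less / (len(x) * len(y))),
        n_responders=int(len(x)),
        n_nonresponders=int(len(y)),
    )


def evaluate_da(
    pred_mean: np.ndarray,
    truth_response: np.ndarray,
    responder_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-drug domain-transfer statistics on hidden target truth.

    Returns a table with Spearman correlation and, when responder labels
    are given, the one-sided Mann-Whitney p-value and effect size.
    """
    T = pred_mean.shape[1]
    rows = []
    for t in range(T):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearman_eval(pred_mean[:, t], truth_response[:, t])
        row = {"task": t, "spearman": rho}
        if responder_labels is not None:
            r = responder_test(pred_mean[:, t], responder_labels[:, t])
            row.update(
                p_value=r.p_value, effect_size=r.effect_size,
                n_responders=r.n_responders,
                n_nonresponders=r.n_nonresponders,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_nt_report(
    path_tsv,
    path_json,
    report: NtReport,
    mse_stl: np.ndarray,
    mse_mtl: np.ndarray,
    task_names: list[str] | None = None,
    samples_per_task: np.ndarray | None = None,
) -> None:
    """TSV (one row per drug) plus a JSON summary of the NT report."""
    T = len(report.per_task_delta)
    df = pd.DataFrame({
        "task": task_names or [f"drug_{t}" for t in range(T)],
        "n_samples": samples_per_task if samples_per_task is not None else T * [-1],
        "mse_stl": np.asarray(mse_stl, float),
        "mse_mtl": np.asarray(mse_mtl, float),
        "delta": report.per_task_delta,
        "negative_transfer": report.nt_flags,
    })
    df.to_csv(path_tsv, sep="\t", index=False)
    with open(path_json, "w") as fh:
        json.dump(
            {
                "n_tasks": T,
                "n_negative_transfer": report.n_nt,
                "fraction_no_nt": report.fraction_no_nt,
            },
            fh, indent=2,
        )
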