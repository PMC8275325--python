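"""Reading and writing expression / response tables and run configs.

Canonical on-disk form: TSV with a header row and first-column sample
identifiers; response tables may have empty or "NA" cells for unobserved
entries. Comma-separated files are accepted by sniffing the header line.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import DrugResponseDataset

logger = logging.getLogger("pharmadapt")

__all__ = ["read_dataset", "write_dataset", "read_matrix", "load_run_config"]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_matrix(path) -> pd.DataFrame:
    """One identifier-indexed numeric table; hard errors name coordinates."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     na_values=["", "NA"], keep_default_na=True,
                     float_precision="round_trip")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated sample identifiers {dup}")
    dupc = df.columns[df.columns.duplicated()].unique().tolist()
    if dupc:
        raise ValueError(f"{path}: duplicated column identifiers {dupc}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_dataset(expression_path, response_path) -> DrugResponseDataset:
    """Load and align an expression table and a response table.

    Sample identifiers are intersected, in expression-file order; empty or
    NA response cells become unobserved mask entries.
    """
    expr = read_matrix(expression_path)
    resp = read_matrix(response_path)
    if expr.isna().any().any():
        raise ValueError(f"{expression_path}: missing expression values")
    shared = [s for s in expr.index if s in set(resp.index)]
    if not shared:
        raise ValueError(
            f"no overlapping samples between {expression_path} and "
            f"{response_path}"
        )
    expr = expr.loc[shared]
    resp = resp.loc[shared]
    mask = resp.notna().to_numpy()
    data = DrugResponseDataset(
        expression=expr.to_numpy(float),
        response=resp.to_numpy(float),
        mask=mask,
        task_names=[str(c) for c in resp.columns],
        sample_names=[str(s) for s in shared],
    )
    logger.info(
        "loaded %d samples x %d genes, %d drugs, %.1f%% missing responses",
        data.n_samples, data.n_genes, data.n_tasks,
        100.0 * (1.0 - mask.mean()),
    )
    return data


def write_dataset(
    data: DrugResponseDataset,
    expression_path,
    response_path,
    sidecar_path=None,
    sidecar: dict | None = None,
    gene_names: list[str] | None = None,
) -> None:
    """Write the two canonical TSVs (+ optional JSON sidecar).

    Unobserved responses are written as empty cells. Floats are written
    with full round-trip precision so read_dataset reproduces the arrays
    exactly.
    """
    genes = gene_names or [f"gene_{i}" for i in range(data.n_genes)]
    expr = pd.DataFrame(data.expression, index=data.sample_names, columns=genes)
    resp = pd.DataFrame(
        np.where(data.mask, data.response, np.nan),
        index=data.sample_names, columns=data.task_names,
    )
    expr.to_csv(expression_path, sep="\t", index_label="sample",
                float_format=lambda v: repr(float(v)))
    resp.to_csv(response_path, sep="\t", index_label="sample", na_rep="",
                float_format=lambda v: repr(float(v)))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar or {}, fh, indent=2, default=str)


def load_run_config(path) -> dict:
    """YAML key/value tree for a run; returns an empty dict for no file."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg
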