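"""Dataset ingestion and result reporting."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset
from .test_stats import BootstrapTestResult

__all__ = ["load_dataset", "run_report"]

_FAMILIES = ("negative.binomial", "bernoulli", "gaussian")


def load_dataset(
    responses_path,
    design_path,
    family: str = "negative.binomial",
    categorical: tuple[str, ...] | None = None,
    note: str = "",
) -> Dataset:
    """Read response and design CSV files into a validated Dataset.

    Both files need a header row; the design's categorical columns are
    auto-detected (object dtype) unless declared.  Errors name the
    offending rows/columns.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {_FAMILIES}")
    responses = pd.read_csv(responses_path)
    design = pd.read_csv(design_path)
    if len(responses) != len(design):
        raise ValueError(
            f"row mismatch: {len(responses)} response rows vs {len(design)} design rows"
        )
    if len(responses) < 2:
        raise ValueError("need at least two observations")
    Y = responses.to_numpy()
    if not np.issubdtype(Y.dtype, np.number):
        bad = [c for c in responses.columns if not np.issubdtype(responses[c].dtype, np.number)]
        raise ValueError(f"non-numeric response column(s): {bad}")
    if family in ("negative.binomial", "bernoulli"):
        neg = np.argwhere(Y < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative value at row {i}, column {responses.columns[j]!r}"
            )
        nonint = np.argwhere(Y != np.round(Y))
        if nonint.size:
            i, j = nonint[0]
            raise ValueError(
                f"non-integer value at row {i}, column {responses.columns[j]!r}"
            )
    if family == "bernoulli" and np.any(Y > 1):
        raise ValueError("bernoulli responses must be 0/1")
    if categorical:
        missing = set(categorical) - set(design.columns)
        if missing:
            raise ValueError(f"declared categorical column(s) not in design: {missing}")
        design = design.astype({c: "object" for c in categorical})
    return Dataset(responses=responses, design_table=design, family=family, note=note)


def run_report(
    result: BootstrapTestResult,
    out_prefix,
    dataset: Dataset | None = None,
    extra: dict | None = None,
) -> dict:
    """Write machine (JSON) and human (text) reports of a bootstrap test.

    Returns the report dictionary.  Output is deterministic given the
    result, so re-runs with the same seed are byte-identical.
    """
    out_prefix = Path(out_prefix)
    report = {
        "statistic": result.statistic,
        "p_value": result.p_value,
        "B": result.B,
        "n_valid": result.n_valid,
        "n_failed": result.n_failed,
        "scheme": result.scheme.name,
        "rejitter": result.scheme.rejitter,
        "rescale": result.scheme.rescale,
        "corr_model": result.scheme.corr_model,
        "seed": result.seed,
        "shrinkage_lambda": result.lam,
        "resample_flags": result.flags,
    }
    if dataset is not None:
        report["n"] = dataset.n
        report["p"] = dataset.p
        report["family"] = dataset.family
    if extra:
        report.update(extra)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [
        "Bootstrap test report",
        "---------------------",
        f"scheme        : {result.scheme.name} (B = {result.B}, seed = {result.seed})",
        f"statistic T   : {result.statistic:.4f}",
        f"p-value       : {result.p_value:.4f}",
        f"valid draws   : {result.n_valid} (failed: {result.n_failed})",
    ]
    if result.lam is not None:
        lines.append(f"shrinkage lam : {result.lam:.3f}")
    if result.flags:
        lines.append(f"draw flags    : {result.flags}")
    out_prefix.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return report
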