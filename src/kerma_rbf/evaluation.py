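"""Error criteria and regression diagnostics for the surrogate.

Two headline metrics: mean relative error in percent,
MRE% = 100/N * sum |X_exp - X_pred| / |X_pred| (note the *predicted*
value in the denominator — kept exactly in that form; a conventional
variant with the experimental value in the denominator is available via
``denominator="exp"``), and RMSE = sqrt(mean (X_exp - X_pred)^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import KermaDataset
from .rbf import RBFModel, predict


def _check_pair(y_exp, y_pred):
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1:
        raise ValueError("y_exp and y_pred must be 1-D arrays of equal length")
    if y_exp.size == 0:
        raise ValueError("empty input")
    return y_exp, y_pred


def mre(y_exp, y_pred, denominator: str = "pred") -> float:
    """Mean relative error in percent.

    The denominator defaults to the predicted value; ``denominator="exp"``
    switches to the conventional form.
    """
    y_exp, y_pred = _check_pair(y_exp, y_pred)
    den = y_pred if denominator == "pred" else y_exp
    if denominator not in ("pred", "exp"):
        raise ValueError("denominator must be 'pred' or 'exp'")
    if np.any(den == 0):
        raise ZeroDivisionError("zero value in the MRE denominator")
    return float(100.0 * np.mean(np.abs((y_exp - y_pred) / den)))


def rmse(y_exp, y_pred) -> float:
    """Root mean square error, in the units of the targets."""
    y_exp, y_pred = _check_pair(y_exp, y_pred)
    return float(np.sqrt(np.mean((y_exp - y_pred) ** 2)))


@dataclass
class EvaluationReport:
    """Per-split accuracy summary plus the residual series."""

    split_tag: str
    n: int
    mre_percent: float
    rmse: float
    residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "split": self.split_tag,
            "n": self.n,
            "mre_percent": self.mre_percent,
            "rmse": self.rmse,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_split(model: RBFModel, dataset: KermaDataset, tag: str) -> EvaluationReport:
    if len(dataset) == 0:
        raise ValueError("empty split")
    y_pred = predict(model, dataset.X)
    y_exp = dataset.y
    return EvaluationReport(
        split_tag=tag,
        n=len(dataset),
        mre_percent=mre(y_exp, y_pred),
        rmse=rmse(y_exp, y_pred),
        residuals=y_exp - y_pred,
    )


def evaluate(
    model: RBFModel,
    train: KermaDataset,
    test: KermaDataset,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Reports for both splits of a fitted model."""
    return evaluate_split(model, train, "train"), evaluate_split(model, test, "test")


def diagnostics_frame(model: RBFModel, dataset: KermaDataset) -> pd.DataFrame:
    """Target vs predicted pairs and residuals, for regression/error plots."""
    y_pred = predict(model, dataset.X)
    return pd.DataFrame({
        "target": dataset.y,
        "predicted": y_pred,
        "residual": dataset.y - y_pred,
    })


__all__ = [
    "EvaluationReport",
    "diagnostics_frame",
    "evaluate",
    "evaluate_split",
    "mre",
    "rmse",
]
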