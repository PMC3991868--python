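"""Model-comparison metrics and reports.

RMSE, Pearson correlation and mean absolute percent error computed per
(model, dataset) cell, plus the percent deviation between a predicted and a
verified optimum.  A "model" may be a fitted surrogate (anything callable on
an (n, s) array) or a precomputed prediction vector, so reference columns
can be compared on equal footing with live fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "rmse",
    "pearson_r",
    "mape",
    "prediction_deviation",
    "compare",
    "ComparisonReport",
]


def _pair(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty vectors")
    if p.shape != a.shape:
        raise ValueError("length mismatch")
    return p, a


def rmse(predicted, actual) -> float:
    """Root-mean-square error with denominator n."""
    p, a = _pair(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def pearson_r(a, b) -> float:
    """Product-moment correlation; raises on zero variance."""
    x, y = _pair(a, b)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    return float(xc @ yc / (sx * sy))


def mape(predicted, actual) -> float:
    """Mean absolute percent error (actual in the denominator)."""
    p, a = _pair(predicted, actual)
    if np.any(a == 0):
        raise ValueError("actual values must be nonzero")
    return float(np.mean(np.abs(a - p) / np.abs(a)) * 100.0)


def prediction_deviation(predicted_optimum: float, verified_mean: float) -> float:
    """|predicted - verified| / verified, as a percent."""
    if verified_mean == 0:
        raise ValueError("verified mean must be nonzero")
    return abs(predicted_optimum - verified_mean) / abs(verified_mean) * 100.0


@dataclass
class ComparisonReport:
    """Per-model, per-dataset metric cells plus parity-plot data."""

    cells: pd.DataFrame   # columns: model, dataset, n, rmse, pearson_r_pct, error_pct
    parity: pd.DataFrame  # columns: model, dataset, run, actual, predicted

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    def cell(self, model: str, dataset: str) -> pd.Series:
        sel = self.cells[(self.cells["model"] == model) & (self.cells["dataset"] == dataset)]
        if len(sel) != 1:
            raise KeyError(f"no unique cell for ({model}, {dataset})")
        return sel.iloc[0]


def _predictions(model, dataset: Dataset) -> np.ndarray:
    if callable(model):
        return np.asarray(model(dataset.X), dtype=float).ravel()
    arr = np.asarray(model, dtype=float).ravel()
    if arr.shape != dataset.y.shape:
        raise ValueError("prediction vector length does not match dataset")
    return arr


def compare(models: Mapping[str, object], train: Dataset, test: Dataset) -> ComparisonReport:
    """Fill every (model, dataset, metric) cell; correlations reported in percent."""
    rows, parity_rows = [], []
    for name, model in models.items():
        for ds_name, ds in (("train", train), ("test", test)):
            try:
                pred = _predictions(model, ds)
            except Exception as exc:
                raise type(exc)(f"model {name!r} on {ds_name} set: {exc}") from exc
            rows.append({
                "model": name, "dataset": ds_name, "n": len(ds),
                "rmse": rmse(pred, ds.y),
                "pearson_r_pct": pearson_r(pred, ds.y) * 100.0,
                "error_pct": mape(pred, ds.y),
            })
            for rec, p in zip(ds.records, pred):
                parity_rows.append({"model": name, "dataset": ds_name,
                                    "run": rec.run_id, "actual": rec.y_mean,
                                    "predicted": float(p)})
    return ComparisonReport(cells=pd.DataFrame(rows), parity=pd.DataFrame(parity_rows))
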