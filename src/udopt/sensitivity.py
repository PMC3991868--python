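"""Input-sensitivity analyses for fitted response surrogates.

Two complementary views are implemented.  The mean-value perturbation
statistic S_i randomly perturbs one input within +/- one training-data
standard deviation around the input means (others held at their means) and
summarizes the spread of the model outputs by their standard deviation —
large S_i means the response reacts strongly to that input near the center
of the data.  The coded-range sweep ("perturb method") instead walks each
factor across its whole range on a coded -2..2 grid and reports least-squares
slopes near the center ([-1, 1]) and at the edges ([-2, -1] and [1, 2]),
exposing curvature that the local statistic cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .data import CodedValueMap, Dataset

__all__ = [
    "PerturbationResult",
    "CodedCurve",
    "input_sd",
    "mean_perturbation",
    "coded_perturb",
]


def input_sd(dataset: Dataset, ddof: int = 1) -> np.ndarray:
    """Per-factor amplitude of perturbation: SD of each input column.

    Defaults to the sample convention (n-1).  A constant column is degenerate
    under ddof=1 (the perturbation would have zero amplitude) and raises;
    pass ddof=0 to get a plain 0 instead.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 records to compute input SDs")
    sds = dataset.X.std(axis=0, ddof=ddof)
    if ddof > 0 and np.any(sds == 0):
        bad = [dataset.space.names[i] for i in np.nonzero(sds == 0)[0]]
        raise ValueError(f"degenerate constant input column(s): {bad}")
    return sds


@dataclass
class PerturbationResult:
    factor_names: list[str]
    amplitudes: np.ndarray       # sigma_i per factor
    s_values: np.ndarray         # sensitivity statistic per factor
    outputs: np.ndarray          # (n_factors, n) perturbed model outputs
    perturbed_inputs: np.ndarray  # (n_factors, n) the perturbed coordinate values
    n: int
    seed: int
    statistic: str

    def ranking(self) -> list[str]:
        """Factor names ordered from most to least sensitive."""
        return [self.factor_names[i] for i in np.argsort(self.s_values)[::-1]]


def mean_perturbation(
    model: Callable[[np.ndarray], np.ndarray],
    dataset: Dataset,
    n: int = 30,
    seed: int = 0,
    statistic: Literal["sd", "rms"] = "sd",
) -> PerturbationResult:
    """Mean-value perturbation sensitivity.

    For each factor i, draws ``n`` offsets uniformly on [-sigma_i, sigma_i]
    (sigma_i = training-input SD), evaluates the model with the other factors
    fixed at their training means, and reports S_i.  The default statistic is
    the sample standard deviation of the n outputs; ``statistic="rms"`` gives
    the literal root-mean-square of the raw outputs instead (a location-
    dependent quantity, kept only for completeness).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    sigmas = input_sd(dataset)
    means = dataset.X.mean(axis=0)
    rng = np.random.default_rng(seed)
    m = dataset.space.n_factors
    outputs = np.empty((m, n))
    inputs = np.empty((m, n))
    for i in range(m):
        eps = rng.uniform(-sigmas[i], sigmas[i], size=n)
        pts = np.tile(means, (n, 1))
        pts[:, i] = means[i] + eps
        vals = np.asarray(model(pts), dtype=float).ravel()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"model undefined at a perturbed point of factor {dataset.space.names[i]!r}")
        outputs[i] = vals
        inputs[i] = pts[:, i]
    if statistic == "sd":
        s = outputs.std(axis=1, ddof=1)
    elif statistic == "rms":
        s = np.sqrt((outputs**2).sum(axis=1) / n)
    else:
        raise ValueError("statistic must be 'sd' or 'rms'")
    return PerturbationResult(
        factor_names=dataset.space.names, amplitudes=sigmas, s_values=s,
        outputs=outputs, perturbed_inputs=inputs, n=n, seed=seed, statistic=statistic,
    )


@dataclass
class CodedCurve:
    factor: str
    coded_grid: np.ndarray
    response: np.ndarray
    center_slope: float   # LS slope on coded [-1, 1], response units per coded unit
    edge_slope_low: float   # on [-2, -1]
    edge_slope_high: float  # on [1, 2]

    @property
    def edge_slope(self) -> float:
        """Mean magnitude of the two edge slopes."""
        return float((abs(self.edge_slope_low) + abs(self.edge_slope_high)) / 2.0)


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def coded_perturb(
    model: Callable[[np.ndarray], np.ndarray],
    coded_map: CodedValueMap,
    grid_step: float = 0.1,
) -> dict[str, CodedCurve]:
    """Full-range sweep of each factor on a coded grid, others at coded 0."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    names = coded_map.factor_names
    n_steps = int(round(4.0 / grid_step))
    grid = np.linspace(-2.0, 2.0, n_steps + 1)
    centers = np.array([coded_map.centers[f] for f in names])
    curves: dict[str, CodedCurve] = {}
    for i, name in enumerate(names):
        pts = np.tile(centers, (len(grid), 1))
        pts[:, i] = coded_map.to_real(name, grid)
        y = np.asarray(model(pts), dtype=float).ravel()
        center = (grid >= -1.0 - 1e-12) & (grid <= 1.0 + 1e-12)
        low = grid <= -1.0 + 1e-12
        high = grid >= 1.0 - 1e-12
        curves[name] = CodedCurve(
            factor=name, coded_grid=grid, response=y,
            center_slope=_ls_slope(grid[center], y[center]),
            edge_slope_low=_ls_slope(grid[low], y[low]),
            edge_slope_high=_ls_slope(grid[high], y[high]),
        )
    return curves
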