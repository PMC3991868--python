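"""Bundled experiment tables and a synthetic response-surface generator.

The package ships the run sheets of a published-style iturin A fed-batch
fermentation experiment: a 10-run uniform-design training table and a 15-run
unseen test table, each with replicate-mean titers (U/mL) and replicate
standard deviations, plus the reference predictions printed alongside them.
The synthetic generator emulates the same kind of 3-factor response surface
with additive Gaussian replicate noise so every downstream stage can be
tested against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .design import FactorSpace, UniformDesign, reference_space

__all__ = [
    "ResponseRecord",
    "Dataset",
    "CodedValueMap",
    "SyntheticSurfaceSpec",
    "load_training_table",
    "load_test_table",
    "load_coded_values",
    "generate_synthetic",
    "read_response_table",
    "write_response_table",
    "DEFAULT_NOISE_SD",
]

#: Default replicate noise, matching the replicate SDs of the bundled tables
#: (they span roughly 268.6-289.6 U/mL).
DEFAULT_NOISE_SD = 280.0


@dataclass(frozen=True)
class ResponseRecord:
    run_id: int
    x: tuple[float, ...]
    y_mean: float
    y_sd: float
    n_reps: int

    def __post_init__(self) -> None:
        if self.y_sd < 0:
            raise ValueError("y_sd must be nonnegative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")


@dataclass
class Dataset:
    """A response table: factor settings with replicate-mean titers."""

    records: list[ResponseRecord]
    role: Literal["train", "test"]
    space: FactorSpace
    ann_reference: np.ndarray | None = None
    ud_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        for r in self.records:
            if len(r.x) != self.space.n_factors:
                raise ValueError(f"record {r.run_id}: x dimension != factor count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def X(self) -> np.ndarray:
        return np.array([r.x for r in self.records], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([r.y_mean for r in self.records], dtype=float)

    @property
    def y_sd(self) -> np.ndarray:
        return np.array([r.y_sd for r in self.records], dtype=float)


def _fixture(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("udopt.fixtures").joinpath(name)) as p:
        return pd.read_csv(p)


def _table_to_dataset(table: str, predictions: str, role: Literal["train", "test"]) -> Dataset:
    space = reference_space()
    df = _fixture(table)
    preds = _fixture(predictions)
    records = [
        ResponseRecord(
            run_id=int(row["run"]),
            x=(row["asn_mg_l"], row["glu_mg_l"], row["pro_mg_l"]),
            y_mean=float(row["titer_mean"]),
            y_sd=float(row["titer_sd"]),
            n_reps=int(row["n_reps"]),
        )
        for _, row in df.iterrows()
    ]
    return Dataset(
        records=records,
        role=role,
        space=space,
        ann_reference=preds["ann_prediction"].to_numpy(dtype=float),
        ud_reference=preds["ud_prediction"].to_numpy(dtype=float),
    )


def load_training_table() -> Dataset:
    """The 10-run uniform-design training table with reference predictions."""
    return _table_to_dataset("train_table.csv", "train_predictions.csv", "train")


def load_test_table() -> Dataset:
    """The 15-run unseen test table with reference predictions."""
    return _table_to_dataset("test_table.csv", "test_predictions.csv", "test")


@dataclass(frozen=True)
class CodedValueMap:
    """Affine per-factor map between coded values (-2..2) and real units."""

    centers: dict[str, float]
    half_steps: dict[str, float]  # real change per +1 coded unit

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "CodedValueMap":
        centers, steps = {}, {}
        for _, row in df.iterrows():
            name = row["factor"]
            centers[name] = float(row["c_0"])
            steps[name] = float(row["c_plus1"]) - float(row["c_0"])
        return cls(centers, steps)

    @property
    def factor_names(self) -> list[str]:
        return list(self.centers)

    def to_real(self, factor: str, coded: float | np.ndarray) -> np.ndarray:
        return self.centers[factor] + np.asarray(coded, dtype=float) * self.half_steps[factor]

    def to_coded(self, factor: str, real: float | np.ndarray) -> np.ndarray:
        return (np.asarray(real, dtype=float) - self.centers[factor]) / self.half_steps[factor]


def load_coded_values() -> CodedValueMap:
    """Coded-value map (-2, -1, 0, 1, 2) for the bundled factors."""
    return CodedValueMap.from_table(_fixture("coded_values.csv"))


@dataclass
class SyntheticSurfaceSpec:
    """Ground-truth surface for synthetic response generation.

    Either ``surface`` (vectorized callable on an (n, s) array) or
    ``coefficients`` + ``terms`` (a quadratic term set from :mod:`udopt.rsm`)
    must be given.  ``optimum`` stores the known argmax for recovery tests.
    """

    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    surface: Callable[[np.ndarray], np.ndarray] | None = None
    coefficients: np.ndarray | None = None
    terms: object | None = None
    optimum: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.surface is None and (self.coefficients is None or self.terms is None):
            raise ValueError("provide surface or (coefficients, terms)")

    def true_surface(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.surface is not None:
            return np.asarray(self.surface(X), dtype=float)
        from .rsm import build_design_matrix

        return build_design_matrix(X, self.terms) @ np.asarray(self.coefficients, dtype=float)


def generate_synthetic(spec: SyntheticSurfaceSpec, design: UniformDesign, n_reps: int = 3) -> Dataset:
    """Draw replicate responses at each design point and return their means.

    Replicates are true_surface(x) + N(0, noise_sd) i.i.d.; the dataset stores
    the replicate mean and sample SD exactly as a wet-lab table would.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if design.realized_matrix is None or design.space is None:
        raise ValueError("design must be realized over a factor space")
    rng = np.random.default_rng(spec.seed)
    X = design.realized_matrix
    truth = spec.true_surface(X)
    draws = truth[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(X), n_reps))
    y_mean = draws.mean(axis=1)
    y_sd = draws.std(axis=1, ddof=1) if n_reps > 1 else np.zeros(len(X))
    records = [
        ResponseRecord(i + 1, tuple(X[i]), float(y_mean[i]), float(y_sd[i]), n_reps)
        for i in range(len(X))
    ]
    return Dataset(records=records, role="train", space=design.space)


def write_response_table(dataset: Dataset, path) -> None:
    df = pd.DataFrame(dataset.X, columns=dataset.space.names)
    df.insert(0, "run", [r.run_id for r in dataset.records])
    df["titer_mean"] = dataset.y
    df["titer_sd"] = dataset.y_sd
    df["n_reps"] = [r.n_reps for r in dataset.records]
    df.to_csv(path, index=False)


def read_response_table(path, role: Literal["train", "test"] = "train",
                        space: FactorSpace | None = None) -> Dataset:
    space = space or reference_space()
    df = pd.read_csv(path)
    records = [
        ResponseRecord(
            run_id=int(row["run"]),
            x=tuple(float(row[n]) for n in space.names),
            y_mean=float(row["titer_mean"]),
            y_sd=float(row.get("titer_sd", 0.0)),
            n_reps=int(row.get("n_reps", 1)),
        )
        for _, row in df.iterrows()
    ]
    return Dataset(records=records, role=role, space=space)
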