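"""Uniform-design construction by the good-lattice-point method.

A uniform design (UD) spreads *n* runs as evenly as possible over the
factor space, allowing each factor to take the largest possible number
of levels — for the U*_n(n^s) family, every factor has *n* levels and
every design column is a permutation of 1..n.  Columns are generated
from integer multipliers coprime to n+1 and a subset of them is chosen
to minimize the centered L2 discrepancy, the standard scalar measure of
non-uniformity on the unit cube.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorSpace",
    "UniformDesign",
    "glp_design",
    "glp_columns",
    "centered_l2_discrepancy",
    "realize_design",
    "reference_design",
    "reference_space",
    "write_design",
    "read_design",
]


@dataclass(frozen=True)
class Factor:
    """A named experimental factor with a discrete level grid and box bounds."""

    name: str
    unit: str
    levels: tuple[float, ...]
    lower: float = math.nan
    upper: float = math.nan

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError(f"factor {self.name!r}: levels must be nonempty")
        lv = np.asarray(self.levels, dtype=float)
        if not np.all(np.diff(lv) > 0):
            raise ValueError(f"factor {self.name!r}: levels must be strictly increasing")
        object.__setattr__(self, "levels", tuple(float(v) for v in lv))
        if math.isnan(self.lower):
            object.__setattr__(self, "lower", float(lv[0]))
        if math.isnan(self.upper):
            object.__setattr__(self, "upper", float(lv[-1]))
        if self.lower > lv[0] or self.upper < lv[-1]:
            raise ValueError(f"factor {self.name!r}: box bounds must contain all levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class FactorSpace:
    """An ordered collection of factors sharing one level count."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        counts = {f.n_levels for f in self.factors}
        if len(counts) > 1:
            raise ValueError("all factors in one design must share the same number of levels")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_levels(self) -> int:
        return self.factors[0].n_levels

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bound vectors for constrained optimization."""
        lo = np.array([f.lower for f in self.factors])
        hi = np.array([f.upper for f in self.factors])
        return lo, hi


@dataclass
class UniformDesign:
    """An n-run design as 1-based level indices plus (optionally) realized values."""

    level_matrix: np.ndarray
    realized_matrix: np.ndarray | None = None
    label: str = ""
    space: FactorSpace | None = None

    def __post_init__(self) -> None:
        self.level_matrix = np.asarray(self.level_matrix, dtype=int)
        if self.level_matrix.ndim != 2 or self.level_matrix.size == 0:
            raise ValueError("level_matrix must be a nonempty 2-D array")
        if self.realized_matrix is not None:
            self.realized_matrix = np.asarray(self.realized_matrix, dtype=float)

    @property
    def n_runs(self) -> int:
        return self.level_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.level_matrix.shape[1]


def glp_columns(n_runs: int) -> dict[int, np.ndarray]:
    """Candidate good-lattice-point columns for the U* variant.

    Column for multiplier g (coprime to n_runs+1) is h_i = (i*g) mod (n_runs+1)
    for i = 1..n_runs; each such column is a permutation of 1..n_runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    m = n_runs + 1
    i = np.arange(1, n_runs + 1)
    return {g: (i * g) % m for g in range(1, m) if math.gcd(g, m) == 1}


def centered_l2_discrepancy(design: UniformDesign | np.ndarray, n_levels: int | None = None) -> float:
    """Centered L2 discrepancy of a level design mapped to the unit cube.

    Levels 1..L are placed at cell centers x = (level - 0.5)/L.  Lower values
    indicate a more uniform point set.
    """
    if isinstance(design, UniformDesign):
        levels = design.level_matrix
        L = n_levels if n_levels is not None else design.n_runs
    else:
        levels = np.asarray(design, dtype=float)
        if levels.size == 0:
            raise ValueError("empty design")
        L = n_levels if n_levels is not None else levels.shape[0]
    n, s = levels.shape
    x = (levels - 0.5) / L
    d = np.abs(x - 0.5)
    term1 = (13.0 / 12.0) ** s
    term2 = (2.0 / n) * np.prod(1.0 + 0.5 * d - 0.5 * d**2, axis=1).sum()
    # pairwise product over factors: 1 + |xi-.5|/2 + |xj-.5|/2 - |xi-xj|/2
    diff = np.abs(x[:, None, :] - x[None, :, :])
    pair = 1.0 + 0.5 * d[:, None, :] + 0.5 * d[None, :, :] - 0.5 * diff
    term3 = pair.prod(axis=2).sum() / n**2
    return float(math.sqrt(max(term1 - term2 + term3, 0.0)))


def glp_design(n_runs: int, n_factors: int) -> UniformDesign:
    """Construct a U*-type uniform design by good-lattice-point search.

    All admissible column subsets of size ``n_factors`` are scored by centered
    L2 discrepancy and the best is returned; ties break toward the
    lexicographically smallest multiplier set, so the result is deterministic.
    """
    cols = glp_columns(n_runs)
    if n_factors < 1:
        raise ValueError("n_factors must be positive")
    if n_factors > len(cols):
        raise ValueError(
            f"design not constructible: {n_runs} runs admit at most "
            f"{len(cols)} columns, requested {n_factors}"
        )
    best_g: tuple[int, ...] | None = None
    best_cd = math.inf
    for gs in itertools.combinations(sorted(cols), n_factors):
        mat = np.column_stack([cols[g] for g in gs])
        cd = centered_l2_discrepancy(mat, n_levels=n_runs)
        if cd < best_cd - 1e-15:
            best_cd, best_g = cd, gs
    assert best_g is not None
    matrix = np.column_stack([cols[g] for g in best_g])
    label = f"U{n_runs}*({n_runs}^{len(cols)}) multipliers {set(best_g)}"
    return UniformDesign(level_matrix=matrix, label=label)


def realize_design(level_matrix: np.ndarray, space: FactorSpace) -> UniformDesign:
    """Map 1-based level indices to real factor values from each factor's grid."""
    levels = np.asarray(level_matrix, dtype=int)
    if levels.ndim != 2 or levels.shape[1] != space.n_factors:
        raise ValueError("level matrix width must equal the number of factors")
    realized = np.empty(levels.shape, dtype=float)
    for j, factor in enumerate(space.factors):
        col = levels[:, j]
        bad = (col < 1) | (col > factor.n_levels)
        if bad.any():
            run = int(np.argmax(bad)) + 1
            raise ValueError(
                f"level index out of range at run {run}, factor {factor.name!r} "
                f"(got {int(col[run - 1])}, valid 1..{factor.n_levels})"
            )
        realized[:, j] = np.asarray(factor.levels)[col - 1]
    return UniformDesign(level_matrix=levels, realized_matrix=realized, space=space)


# The bundled iturin A study: three amino-acid feeds, ten levels each.
_REFERENCE_LEVELS = np.array(
    [
        [1, 5, 7],
        [2, 10, 3],
        [3, 4, 10],
        [4, 9, 6],
        [5, 3, 2],
        [6, 8, 9],
        [7, 2, 5],
        [8, 7, 1],
        [9, 1, 8],
        [10, 6, 4],
    ]
)


def reference_space() -> FactorSpace:
    """Factor grids of the bundled fed-batch experiment (10 levels per factor)."""
    return FactorSpace(
        (
            Factor("asn_mg_l", "mg/L", tuple(np.linspace(50, 185, 10))),
            Factor("glu_mg_l", "mg/L", tuple(np.linspace(200, 380, 10))),
            Factor("pro_mg_l", "mg/L", tuple(np.linspace(50, 185, 10))),
        )
    )


def reference_design() -> UniformDesign:
    """The exact 10-run, 3-factor uniform design of the bundled experiment.

    Its columns coincide with good-lattice-point multipliers {1, 5, 7} mod 11.
    """
    d = realize_design(_REFERENCE_LEVELS, reference_space())
    d.label = "U10*(10^8) multipliers {1, 5, 7}"
    return d


def write_design(design: UniformDesign, path: str | Path) -> None:
    """Write realized values to CSV and level indices to a ``.levels.csv`` sidecar."""
    path = Path(path)
    if design.realized_matrix is None or design.space is None:
        raise ValueError("design must be realized before writing")
    names = design.space.names
    runs = np.arange(1, design.n_runs + 1)
    pd.DataFrame(design.realized_matrix, columns=names).assign(run=runs).set_index("run").to_csv(path)
    pd.DataFrame(design.level_matrix, columns=names).assign(run=runs).set_index("run").to_csv(
        path.with_suffix(".levels.csv")
    )


def read_design(path: str | Path, space: FactorSpace) -> UniformDesign:
    """Read a run sheet written by :func:`write_design` and re-derive level indices."""
    realized = pd.read_csv(path, index_col="run")[space.names].to_numpy(dtype=float)
    levels = np.empty(realized.shape, dtype=int)
    for j, factor in enumerate(space.factors):
        grid = np.asarray(factor.levels)
        idx = np.abs(realized[:, [j]] - grid[None, :]).argmin(axis=1)
        if not np.allclose(grid[idx], realized[:, j]):
            raise ValueError(f"values in column {factor.name!r} are not on the level grid")
        levels[:, j] = idx + 1
    return UniformDesign(level_matrix=levels, realized_matrix=realized, space=space)
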