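"""Quadratic response-surface modelling and analytic optimization.

Fits the second-order polynomial

    Y = b0 + sum_i bi Xi + sum_i bii Xi^2 + sum_{i<j} bij Xi Xj

(or any configured subset of its terms) to replicate-mean responses by
ordinary least squares, produces an ANOVA table, and locates the
constrained stationary-point optimum by solving the gradient system
analytically, with a grid-plus-polish fallback for saddles or optima
outside the factor box.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy import stats
from scipy.linalg import solve_triangular

from .data import Dataset

__all__ = [
    "Term",
    "TermSet",
    "QuadraticModel",
    "AnovaTable",
    "StationaryPointResult",
    "build_design_matrix",
    "fit_quadratic",
    "fit_quadratic_xy",
    "anova",
    "predict",
    "stationary_point",
    "reference_equation",
    "default_terms",
]

# A term is ("intercept",), ("linear", i), ("square", i) or ("cross", i, j) with i<j.
Term = tuple


def _term_name(term: Term) -> str:
    kind = term[0]
    if kind == "intercept":
        return "1"
    if kind == "linear":
        return f"X{term[1] + 1}"
    if kind == "square":
        return f"X{term[1] + 1}^2"
    if kind == "cross":
        return f"X{term[1] + 1}*X{term[2] + 1}"
    raise ValueError(f"unknown term kind {kind!r}")


@dataclass(frozen=True)
class TermSet:
    """An ordered, duplicate-free collection of polynomial terms."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        for t in self.terms:
            if t[0] == "cross" and not t[1] < t[2]:
                raise ValueError(f"cross term must have i < j, got {t}")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def names(self) -> list[str]:
        return [_term_name(t) for t in self.terms]

    def max_factor_index(self) -> int:
        return max((t[-1] for t in self.terms if t[0] != "intercept"), default=-1)

    @classmethod
    def full_quadratic(cls, n_factors: int) -> "TermSet":
        terms: list[Term] = [("intercept",)]
        terms += [("linear", i) for i in range(n_factors)]
        terms += [("square", i) for i in range(n_factors)]
        terms += [("cross", i, j) for i in range(n_factors) for j in range(i + 1, n_factors)]
        return cls(tuple(terms))

    def drop(self, *dropped: Term) -> "TermSet":
        dropped_set = {tuple(t) for t in dropped}
        missing = dropped_set - set(self.terms)
        if missing:
            raise ValueError(f"cannot drop absent terms {missing}")
        return TermSet(tuple(t for t in self.terms if t not in dropped_set))


def default_terms() -> TermSet:
    """The reduced 8-term set used for the bundled data.

    The X1*X2 and X2*X3 interactions are dropped (they are highly correlated
    with the main effects on this design), leaving intercept, three linear,
    three square terms and the X1*X3 interaction.
    """
    return TermSet.full_quadratic(3).drop(("cross", 0, 1), ("cross", 1, 2))


def build_design_matrix(points: np.ndarray, term_set: TermSet) -> np.ndarray:
    """One column per term, in term order; intercept is a column of ones."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if term_set.max_factor_index() >= X.shape[1]:
        raise ValueError(
            f"term set references factor index {term_set.max_factor_index()} "
            f"but points have only {X.shape[1]} columns"
        )
    cols = []
    for t in term_set.terms:
        if t[0] == "intercept":
            cols.append(np.ones(len(X)))
        elif t[0] == "linear":
            cols.append(X[:, t[1]])
        elif t[0] == "square":
            cols.append(X[:, t[1]] ** 2)
        else:
            cols.append(X[:, t[1]] * X[:, t[2]])
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """A fitted (or externally supplied) polynomial response surface."""

    term_set: TermSet
    coefficients: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.term_set):
            raise ValueError("coefficient count must equal term count")

    def predict(self, points: np.ndarray) -> np.ndarray:
        return build_design_matrix(points, self.term_set) @ self.coefficients

    __call__ = predict

    def to_json(self, path) -> None:
        payload = {
            "terms": [list(t) for t in self.term_set.terms],
            "term_names": self.term_set.names,
            "coefficients": self.coefficients.tolist(),
            "fitted_on": self.fitted_on,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            term_set=TermSet(tuple(tuple(t) for t in payload["terms"])),
            coefficients=np.array(payload["coefficients"]),
            fitted_on=payload.get("fitted_on", ""),
        )


def reference_equation() -> QuadraticModel:
    """The rounded regression equation reported for the bundled training table.

    Y = -4864 + 60.0 X1 + 87.6 X2 + 21.8 X3
        - 0.226 X1^2 - 0.150 X2^2 - 0.0752 X3^2 + 0.0011 X1 X3
    """
    return QuadraticModel(
        term_set=default_terms(),
        coefficients=np.array([-4864.0, 60.0, 87.6, 21.8, -0.226, -0.150, -0.0752, 0.0011]),
        fitted_on="reference (rounded printed coefficients)",
    )


def fit_quadratic_xy(X: np.ndarray, y: np.ndarray, term_set: TermSet,
                     label: str = "") -> QuadraticModel:
    """OLS fit via QR; raises on rank deficiency naming the collinear terms."""
    A = build_design_matrix(X, term_set)
    y = np.asarray(y, dtype=float)
    if len(y) < len(term_set):
        raise ValueError(
            f"need at least {len(term_set)} records to fit {len(term_set)} terms, got {len(y)}"
        )
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        bad = [term_set.names[i] for i in np.nonzero(diag <= tol)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    coef = solve_triangular(R, Q.T @ y)
    return QuadraticModel(term_set=term_set, coefficients=coef, fitted_on=label)


def fit_quadratic(dataset: Dataset, term_set: TermSet | None = None) -> QuadraticModel:
    """Fit the polynomial to a dataset's replicate-mean responses."""
    term_set = term_set or default_terms()
    return fit_quadratic_xy(dataset.X, dataset.y, term_set, label=dataset.role)


def predict(model: QuadraticModel, points: np.ndarray) -> np.ndarray:
    return model.predict(points)


@dataclass
class AnovaTable:
    """Per-term and model-level OLS diagnostics.

    Computed on the replicate-mean fit: df_model = p - 1, df_resid = n - p.
    Per-term sum of squares is the partial SS (t^2 * MSE_resid); standard
    errors come from the unscaled covariance (X'X)^-1 * MSE_resid.
    """

    table: pd.DataFrame  # columns: term, coefficient, std_error, sum_sq, df, t, p
    f_value: float
    p_value: float
    r_squared: float
    s: float  # residual standard error sqrt(SSE / df_resid)
    df_model: int
    df_resid: int

    def to_csv(self, path) -> None:
        df = self.table.copy()
        footer = pd.DataFrame(
            [{"term": f"Model (df={self.df_model}, resid df={self.df_resid})",
              "coefficient": np.nan, "std_error": np.nan,
              "sum_sq": np.nan, "df": self.df_model,
              "t": self.f_value, "p": self.p_value}]
        )
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)


def anova(model: QuadraticModel, dataset: Dataset) -> AnovaTable:
    A = build_design_matrix(dataset.X, model.term_set)
    y = dataset.y
    n, p = A.shape
    resid = y - A @ model.coefficients
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = sst - sse
    df_model, df_resid = p - 1, n - p
    if df_resid <= 0:
        mse = math.nan
        f_value = p_value = s = math.nan
    else:
        mse = sse / df_resid
        f_value = (ssr / df_model) / mse if df_model > 0 else math.nan
        p_value = float(stats.f.sf(f_value, df_model, df_resid)) if df_model > 0 else math.nan
        s = math.sqrt(mse)
    xtx_inv = np.linalg.inv(A.T @ A)
    if df_resid > 0:
        se = np.sqrt(np.diag(xtx_inv) * mse)
        t = model.coefficients / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
        partial_ss = t**2 * mse
    else:
        se = t = pvals = partial_ss = np.full(p, math.nan)
    table = pd.DataFrame(
        {
            "term": model.term_set.names,
            "coefficient": model.coefficients,
            "std_error": se,
            "sum_sq": partial_ss,
            "df": 1,
            "t": t,
            "p": pvals,
        }
    )
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    return AnovaTable(table=table, f_value=f_value, p_value=p_value, r_squared=r2,
                      s=s, df_model=df_model, df_resid=df_resid)


@dataclass
class StationaryPointResult:
    x_star: np.ndarray
    y_star: float
    hessian_classification: Literal["maximum", "minimum", "saddle"]
    clipped: bool
    method: Literal["analytic", "fallback"]


def _gradient_system(model: QuadraticModel):
    """Linear coefficients b and Hessian H such that grad Y = b + H x."""
    m = model.term_set.max_factor_index() + 1
    b = np.zeros(m)
    H = np.zeros((m, m))
    for t, c in zip(model.term_set.terms, model.coefficients):
        if t[0] == "linear":
            b[t[1]] += c
        elif t[0] == "square":
            H[t[1], t[1]] += 2.0 * c
        elif t[0] == "cross":
            H[t[1], t[2]] += c
            H[t[2], t[1]] += c
    return b, H


def stationary_point(model: QuadraticModel, box: tuple[np.ndarray, np.ndarray],
                     grid_points: int = 101) -> StationaryPointResult:
    """Solve grad Y = 0 analytically; fall back to constrained maximization.

    The stationary point is classified by the Hessian's eigenvalues.  If it is
    not an interior maximum of the box, the box maximum is located instead by
    a dense grid scan polished with L-BFGS-B, and flagged method="fallback".
    """
    lo, hi = (np.asarray(v, dtype=float) for v in box)
    b, H = _gradient_system(model)
    m = len(b)
    squares = {t[1] for t in model.term_set.terms if t[0] == "square"}
    if squares != set(range(m)):
        raise ValueError("model must contain every square term for a stationary point")
    if abs(np.linalg.det(H)) < 1e-12 * max(1.0, np.abs(H).max()) ** m:
        raise ValueError("degenerate surface: singular Hessian, no unique stationary point")
    x_star = np.linalg.solve(H, -b)
    eig = np.linalg.eigvalsh(H)
    if np.all(eig < 0):
        classification = "maximum"
    elif np.all(eig > 0):
        classification = "minimum"
    else:
        classification = "saddle"
    interior = bool(np.all(x_star >= lo) and np.all(x_star <= hi))
    if classification == "maximum" and interior:
        return StationaryPointResult(
            x_star=x_star, y_star=float(model.predict(x_star[None, :])[0]),
            hessian_classification=classification, clipped=False, method="analytic",
        )
    # constrained fallback: dense grid scan then local polish
    axes = [np.linspace(lo[i], hi[i], grid_points) for i in range(m)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, m)
    vals = model.predict(mesh)
    x0 = mesh[int(np.argmax(vals))]
    res = sciopt.minimize(
        lambda x: -model.predict(x[None, :])[0], x0,
        jac=lambda x: -(b + H @ x), bounds=list(zip(lo, hi)), method="L-BFGS-B",
    )
    x_best = np.clip(res.x, lo, hi)
    return StationaryPointResult(
        x_star=x_best, y_star=float(model.predict(x_best[None, :])[0]),
        hessian_classification=classification, clipped=True, method="fallback",
    )
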