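"""Bilinear-quadratic predictive surfaces in the lattice indices (m, n).

A descriptor y(m, n) of either lattice family is modelled as a product
quadratic — degree two in m and in n separately:

    y(m, n) = c1 m^2 n^2 + c2 m n^2 + c3 n^2 + c4 m^2 n + c5 m n + c6 n
            + c7 m^2 + c8 m + c9

The nine coefficients are estimated by ordinary least squares on a grid
of exactly computed descriptor values; the fitted surface then predicts
the descriptor for unit-cell counts too large to diagonalise comfortably.
Fixing m collapses the surface to a quadratic in n,

    y(n) = a2 n^2 + a1 n + a0,   a2 = c1 m^2 + c2 m + c3, etc.

The module follows the statsmodels shape: a :class:`BilinearSurfaceModel`
built from data whose :meth:`fit` returns a :class:`SurfaceFitResults`
carrying estimates, uncertainties and diagnostics.  Four coefficient sets
for the BiI3 and BRE families (energy and Estrada index) ship as builtin
models under the names E_BII3, EE_BII3, E_BRE and EE_BRE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BASIS_TERMS",
    "SurfaceModel",
    "QuadraticInN",
    "BilinearSurfaceModel",
    "SurfaceFitResults",
    "IdentifiabilityError",
    "basis_row",
    "fit_surface",
    "evaluate_surface",
    "reduce_at_m",
    "builtin_surface",
    "BUILTIN_SURFACES",
    "round_half_away",
    "truncate_decimals",
]

#: Ordered basis of the product-quadratic surface (descending mixed degree).
BASIS_TERMS = ("m2n2", "mn2", "n2", "m2n", "mn", "n", "m2", "m", "1")


class IdentifiabilityError(ValueError):
    """Design matrix cannot identify all nine surface coefficients."""


def basis_row(m: int, n: int) -> np.ndarray:
    """[m2n2, mn2, n2, m2n, mn, n, m2, m, 1] for one grid point."""
    if m < 1 or n < 1:
        raise ValueError(f"lattice indices must be >= 1, got ({m}, {n})")
    return np.array([m * m * n * n, m * n * n, n * n, m * m * n,
                     m * n, n, m * m, m, 1], dtype=float)


@dataclass(frozen=True)
class QuadraticInN:
    """a2 n^2 + a1 n + a0 — a surface restricted to fixed m."""

    a2: float
    a1: float
    a0: float

    def __post_init__(self):
        if not all(math.isfinite(c) for c in (self.a2, self.a1, self.a0)):
            raise ValueError("quadratic coefficients must be finite")

    def __call__(self, n: float) -> float:
        return self.a2 * n * n + self.a1 * n + self.a0


@dataclass(frozen=True)
class SurfaceModel:
    """Nine coefficients over :data:`BASIS_TERMS` plus identifying tags."""

    coefficients: tuple[float, ...]
    property_tag: str = "energy"
    structure_tag: str = ""

    def __post_init__(self):
        if len(self.coefficients) != 9:
            raise ValueError(
                f"surface model needs exactly 9 coefficients, got {len(self.coefficients)}")
        if not all(math.isfinite(c) for c in self.coefficients):
            raise ValueError("surface coefficients must be finite")

    def evaluate(self, m: int, n: int) -> float:
        return float(np.dot(self.coefficients, basis_row(m, n)))

    def reduce_at_m(self, m: int) -> QuadraticInN:
        """Collapse the surface to a quadratic in n at fixed m >= 1."""
        if m < 1:
            raise ValueError(f"m must be >= 1, got {m}")
        c = self.coefficients
        return QuadraticInN(
            a2=c[0] * m * m + c[1] * m + c[2],
            a1=c[3] * m * m + c[4] * m + c[5],
            a0=c[6] * m * m + c[7] * m + c[8],
        )

    def to_file(self, path: str | Path) -> None:
        payload = {
            "property_tag": self.property_tag,
            "structure_tag": self.structure_tag,
            "basis": list(BASIS_TERMS),
            "coefficients": [float(c) for c in self.coefficients],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SurfaceModel":
        payload = yaml.safe_load(Path(path).read_text())
        basis = tuple(payload.get("basis", BASIS_TERMS))
        if basis != BASIS_TERMS:
            raise ValueError(f"unsupported basis order {basis}")
        return cls(coefficients=tuple(float(c) for c in payload["coefficients"]),
                   property_tag=payload.get("property_tag", ""),
                   structure_tag=payload.get("structure_tag", ""))


def evaluate_surface(model: SurfaceModel, m: int, n: int) -> float:
    return model.evaluate(m, n)


def reduce_at_m(model: SurfaceModel, m: int) -> QuadraticInN:
    return model.reduce_at_m(m)


class BilinearSurfaceModel:
    """Product-quadratic surface model, statsmodels style.

    Parameters
    ----------
    values : array-like
        Exact descriptor values, one per grid point.
    mn : array-like of shape (k, 2)
        Integer lattice indices (m, n) of each observation.

    The product-quadratic basis is identifiable only if the grid spans at
    least three distinct m and three distinct n values (a quadratic needs
    three abscissae in each direction) and at least nine points in total;
    violations raise :class:`IdentifiabilityError` naming the deficient
    direction rather than silently returning a minimum-norm solution.
    """

    def __init__(self, values, mn, property_tag: str = "energy",
                 structure_tag: str = ""):
        self.endog = np.asarray(values, dtype=float)
        self.mn = np.asarray(mn, dtype=int)
        if self.mn.ndim != 2 or self.mn.shape[1] != 2:
            raise ValueError("mn must have shape (k, 2)")
        if len(self.endog) != len(self.mn):
            raise ValueError("values and mn must have equal length")
        self.property_tag = property_tag
        self.structure_tag = structure_tag
        self._check_identifiable()
        self.exog = np.vstack([basis_row(m, n) for m, n in self.mn])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str,
                       structure_tag: str = "") -> "BilinearSurfaceModel":
        """Build from a descriptor table with columns m, n and ``value_col``."""
        for col in ("m", "n", value_col):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        return cls(df[value_col].to_numpy(), df[["m", "n"]].to_numpy(),
                   property_tag=value_col, structure_tag=structure_tag)

    def _check_identifiable(self) -> None:
        n_points = len(self.mn)
        distinct_m = len(set(self.mn[:, 0]))
        distinct_n = len(set(self.mn[:, 1]))
        problems = []
        if distinct_m < 3:
            problems.append(f"only {distinct_m} distinct m value(s), need 3")
        if distinct_n < 3:
            problems.append(f"only {distinct_n} distinct n value(s), need 3")
        if n_points < 9:
            problems.append(f"only {n_points} point(s), need 9")
        if problems:
            raise IdentifiabilityError("; ".join(problems))

    def fit(self) -> "SurfaceFitResults":
        """Least-squares estimate of the nine coefficients."""
        x, y = self.exog, self.endog
        if np.linalg.matrix_rank(x) < 9:
            raise IdentifiabilityError(
                "design matrix is rank deficient despite the grid spanning "
                "3 distinct values in each direction")
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ coef
        resid = y - fitted
        sse = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if tss == 0 else 1.0 - sse / tss
        dof = len(y) - 9
        sigma2 = sse / dof if dof > 0 else float("nan")
        xtx_inv = np.linalg.inv(x.T @ x)
        bse = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
        model = SurfaceModel(coefficients=tuple(float(c) for c in coef),
                             property_tag=self.property_tag,
                             structure_tag=self.structure_tag)
        return SurfaceFitResults(model=self, surface=model, params=coef,
                                 bse=bse, resid=resid, fittedvalues=fitted,
                                 sse=sse, rsquared=r2, df_resid=dof)


@dataclass
class SurfaceFitResults:
    """Estimates, uncertainties and diagnostics of a surface fit."""

    model: BilinearSurfaceModel
    surface: SurfaceModel
    params: np.ndarray
    bse: np.ndarray
    resid: np.ndarray
    fittedvalues: np.ndarray
    sse: float
    rsquared: float
    df_resid: int

    def predict(self, m: int, n: int) -> float:
        return self.surface.evaluate(m, n)

    def reduce_at_m(self, m: int) -> QuadraticInN:
        return self.surface.reduce_at_m(m)

    def summary(self) -> str:
        lines = [
            "Bilinear-quadratic surface fit",
            "==============================",
            f"property:  {self.model.property_tag or '-'}",
            f"structure: {self.model.structure_tag or '-'}",
            f"points:    {len(self.model.endog)}   df resid: {self.df_resid}",
            f"SSE:       {self.sse:.6e}",
            f"R^2:       {self.rsquared:.8f}",
            "",
            f"{'term':>6} {'coef':>16} {'std err':>12}",
        ]
        for term, c, se in zip(BASIS_TERMS, self.params, self.bse):
            lines.append(f"{term:>6} {c:>16.8g} {se:>12.4g}")
        return "\n".join(lines)


def fit_surface(records: Sequence[tuple[int, int, float]] | pd.DataFrame,
                value_col: str = "energy",
                structure_tag: str = "") -> SurfaceFitResults:
    """Convenience wrapper: fit from (m, n, value) triples or a DataFrame."""
    if isinstance(records, pd.DataFrame):
        model = BilinearSurfaceModel.from_dataframe(records, value_col,
                                                    structure_tag=structure_tag)
    else:
        arr = np.asarray(list(records), dtype=float)
        model = BilinearSurfaceModel(arr[:, 2], arr[:, :2].astype(int),
                                     property_tag=value_col,
                                     structure_tag=structure_tag)
    return model.fit()


#: Builtin coefficient sets for the two lattice families.
BUILTIN_SURFACES: dict[str, SurfaceModel] = {
    "E_BII3": SurfaceModel(
        (7e-9, -9e-5, 0.0003, -0.0003, 13.794, 9.5506, -0.0014, 5.1553, -0.3239),
        property_tag="energy", structure_tag="bii3"),
    "EE_BII3": SurfaceModel(
        (3.167, -15.839, 19.009, -12.67, 110.86, -44.392, 9.49, -32.462, 57.857),
        property_tag="estrada", structure_tag="bii3"),
    "E_BRE": SurfaceModel(
        (2e-7, -2e-5, 2e-5, -0.01, 35.2, 0.98, -0.0085, 0.9773, -0.1176),
        property_tag="energy", structure_tag="bre"),
    "EE_BRE": SurfaceModel(
        (0.0542, -0.1387, -0.0665, -0.0145, 70.062, 2.193, -0.1985, 2.3475, -1.994),
        property_tag="estrada", structure_tag="bre"),
}


def builtin_surface(name: str) -> SurfaceModel:
    """Builtin surface by name (E_BII3, EE_BII3, E_BRE, EE_BRE)."""
    try:
        return BUILTIN_SURFACES[name]
    except KeyError:
        raise ValueError(
            f"unknown builtin surface {name!r}; available: "
            f"{', '.join(sorted(BUILTIN_SURFACES))}") from None


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def truncate_decimals(x: float, ndigits: int = 3) -> float:
    """Truncate toward zero at ``ndigits`` decimals.

    This is the display convention of the shipped reference comparison
    tables: their estimated columns are surface evaluations cut, not
    rounded, at the third decimal (e.g. 269.77965 -> 269.779).
    """
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor), x) / factor
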