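"""Exact-vs-estimated error analysis.

Compares descriptor values computed from the spectrum ("exact") with
values predicted by a fitted surface ("estimated"), row by row, and
aggregates:

* error            = estimated - exact
* absolute error   = |error|
* APE              = 100 * |error| / denominator
* MAPE             = mean of the APEs
* mean absolute error, standard deviation of the absolute errors

Two conventions are explicit parameters rather than hidden defaults:
the APE denominator (``estimated`` or ``exact`` — both appear in the
reference comparison tables shipped with the package) and the standard
deviation mode (``sample`` n-1 or ``population`` n).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ErrorRow",
    "ErrorReport",
    "compare",
    "mape",
    "mean_abs_error",
    "stdev",
    "normal_curve",
    "load_reference_table",
    "REFERENCE_TABLES",
]

#: Reference comparison tables shipped as package data, keyed by
#: (structure, property).  Columns: m, n, exact, estimated, error,
#: abs_error, ape — as printed in the source tabulation, including its
#: internal inconsistencies (documented in docs/methods.md).
REFERENCE_TABLES = {
    ("bii3", "energy"): "energy_bii3.csv",
    ("bii3", "estrada"): "estrada_bii3.csv",
    ("bre", "energy"): "energy_bre.csv",
    ("bre", "estrada"): "estrada_bre.csv",
}


@dataclass(frozen=True)
class ErrorRow:
    label: str
    exact: float
    estimated: float
    error: float
    abs_error: float
    ape: float
    rel_error_pct: float


@dataclass(frozen=True)
class ErrorReport:
    rows: tuple[ErrorRow, ...]
    denominator_mode: str
    mape: float
    mean_abs_error: float
    stdev: float
    stdev_mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.exact, r.estimated, r.error, r.abs_error, r.ape,
              r.rel_error_pct) for r in self.rows],
            columns=["label", "exact", "estimated", "error", "abs_error",
                     "ape", "rel_error_pct"],
        )


def compare(labels: Sequence[str], exact: Sequence[float],
            estimated: Sequence[float], denominator_mode: str = "estimated",
            stdev_mode: str = "sample") -> ErrorReport:
    """Row-wise error report with aggregate statistics.

    ``error = estimated - exact`` (so an overestimate is positive);
    ``denominator_mode`` selects what the APE divides by.
    """
    if denominator_mode not in ("exact", "estimated"):
        raise ValueError(
            f"denominator_mode must be 'exact' or 'estimated', got {denominator_mode!r}")
    if not (len(labels) == len(exact) == len(estimated)):
        raise ValueError(
            f"length mismatch: {len(labels)} labels, {len(exact)} exact, "
            f"{len(estimated)} estimated")
    if len(exact) == 0:
        raise ValueError("empty comparison")
    rows = []
    for label, ex, est in zip(labels, exact, estimated):
        denom = est if denominator_mode == "estimated" else ex
        if denom == 0:
            raise ValueError(f"zero APE denominator in row {label!r}")
        err = est - ex
        ape = 100.0 * abs(err) / abs(denom)
        # signed relative error in percent, against the same denominator
        rel = 100.0 * err / denom
        rows.append(ErrorRow(label=str(label), exact=float(ex),
                             estimated=float(est), error=float(err),
                             abs_error=abs(float(err)), ape=float(ape),
                             rel_error_pct=float(rel)))
    abs_errors = [r.abs_error for r in rows]
    return ErrorReport(
        rows=tuple(rows),
        denominator_mode=denominator_mode,
        mape=mape([r.ape for r in rows]),
        mean_abs_error=mean_abs_error(abs_errors),
        stdev=stdev(abs_errors, stdev_mode) if len(abs_errors) >= 2 else 0.0,
        stdev_mode=stdev_mode,
    )


def mape(apes: Sequence[float]) -> float:
    """Mean absolute percentage error: arithmetic mean of per-row APEs."""
    if len(apes) == 0:
        raise ValueError("mape of an empty list")
    return float(np.mean(apes))


def mean_abs_error(values: Sequence[float]) -> float:
    """Mean of absolute values."""
    if len(values) == 0:
        raise ValueError("mean_abs_error of an empty list")
    return float(np.mean(np.abs(values)))


def stdev(values: Sequence[float], mode: str) -> float:
    """Standard deviation; ``sample`` uses n-1, ``population`` uses n."""
    if mode not in ("sample", "population"):
        raise ValueError(f"mode must be 'sample' or 'population', got {mode!r}")
    if len(values) < 2:
        raise ValueError("stdev needs at least 2 values")
    return float(np.std(values, ddof=1 if mode == "sample" else 0))


def normal_curve(mu: float, sigma: float, xs: Sequence[float]) -> np.ndarray:
    """Gaussian density at each x (the normal-curve error summary)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return scipy.stats.norm.pdf(np.asarray(xs, dtype=float), loc=mu, scale=sigma)


def load_reference_table(structure: str, prop: str) -> pd.DataFrame:
    """Load one of the shipped exact/estimated comparison tables."""
    try:
        fname = REFERENCE_TABLES[(structure, prop)]
    except KeyError:
        keys = ", ".join(f"{s}/{p}" for s, p in REFERENCE_TABLES)
        raise ValueError(
            f"no reference table for {structure!r}/{prop!r}; available: {keys}"
        ) from None
    with resources.files("latspec.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)
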