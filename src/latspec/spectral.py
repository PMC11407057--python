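"""Adjacency-spectrum descriptors.

Everything here is a function of the eigenvalues l1 >= ... >= lq of the
0/1 adjacency matrix A of a molecular graph:

* energy           E(G)  = sum |l_i|         (total pi-electron energy proxy)
* Estrada index    EE(G) = sum exp(l_i)      (folding-degree measure)
* inertia          p / eta / n-  = counts of positive / zero / negative l_i
* signature        s = p - n-
* rank             p + n-  (rank of A)

Zero eigenvalues are classified with an explicit tolerance because the
nullity is a count, not a limit: the default is 1e-8 * max(1, l1), which
cleanly separates the genuinely-zero eigenvalues of these lattice
spectra from small nonzero ones at double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import AdjacencyMatrix, MolecularGraph, GraphError, adjacency_of
from .lattices import (LatticeIndex, bii3_sheet, benzene_ptype,
                       reference_graph, STRUCTURES, REFERENCE_FAMILIES)

__all__ = [
    "Spectrum",
    "DescriptorRecord",
    "DEFAULT_ZERO_TOL_SCALE",
    "spectrum_of",
    "graph_energy",
    "estrada_index",
    "inertia_of",
    "signature_rank",
    "descriptors_of",
    "descriptor_sweep",
    "sweep_to_frame",
]

DEFAULT_ZERO_TOL_SCALE = 1e-8

DESCRIPTOR_COLUMNS = ("m", "n", "energy", "estrada", "p", "n_minus",
                      "eta", "signature", "rank")


@dataclass(frozen=True)
class Spectrum:
    """Adjacency eigenvalues sorted descending, with a zero tolerance."""

    values: np.ndarray
    zero_tol: float
    source_order: int

    def __post_init__(self):
        if len(self.values) != self.source_order:
            raise GraphError("spectrum length must equal the matrix order")
        if self.zero_tol < 0:
            raise GraphError("zero tolerance must be non-negative")


@dataclass(frozen=True)
class DescriptorRecord:
    """One row of a descriptor table for lattice index (m, n)."""

    m: int
    n: int
    energy: float
    estrada: float
    p_plus: int
    n_minus: int
    eta: int
    signature: int
    rank: int

    def __post_init__(self):
        if self.signature != self.p_plus - self.n_minus:
            raise GraphError("signature must equal p - n-")
        if self.rank != self.p_plus + self.n_minus:
            raise GraphError("rank must equal p + n-")


def spectrum_of(a: AdjacencyMatrix | MolecularGraph | np.ndarray,
                zero_tol: float | None = None) -> Spectrum:
    """Eigenvalues of a symmetric 0/1 matrix, sorted descending.

    Accepts an :class:`AdjacencyMatrix`, a :class:`MolecularGraph` or a
    raw symmetric ndarray.  ``zero_tol`` defaults to
    ``1e-8 * max(1, spectral radius)`` and is recorded for downstream
    zero-classification.
    """
    if isinstance(a, MolecularGraph):
        a = adjacency_of(a)
    if isinstance(a, AdjacencyMatrix):
        entries = a.entries
    else:
        entries = np.asarray(a, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise GraphError(f"matrix must be square, got shape {entries.shape}")
        if entries.size and not np.allclose(entries, entries.T):
            raise GraphError("matrix must be symmetric")
    order = entries.shape[0]
    if order == 0:
        values = np.empty(0)
    else:
        values = np.linalg.eigvalsh(entries.astype(float))[::-1]
    if zero_tol is None:
        radius = float(np.abs(values).max()) if order else 0.0
        zero_tol = DEFAULT_ZERO_TOL_SCALE * max(1.0, radius)
    return Spectrum(values=values, zero_tol=float(zero_tol), source_order=order)


def graph_energy(s: Spectrum) -> float:
    """E(G) = sum of |eigenvalues|; zero iff the graph is edgeless."""
    return float(np.abs(s.values).sum())


def estrada_index(s: Spectrum) -> float:
    """EE(G) = sum of exp(eigenvalue); equals the order for edgeless graphs."""
    return float(np.exp(s.values).sum())


def inertia_of(s: Spectrum) -> tuple[int, int, int]:
    """(p, eta, n-): positive / zero / negative eigenvalue counts.

    An eigenvalue counts as zero when |l| <= zero_tol.
    """
    v, tol = s.values, s.zero_tol
    p = int((v > tol).sum())
    eta = int((np.abs(v) <= tol).sum())
    n_minus = int((v < -tol).sum())
    return p, eta, n_minus


def signature_rank(s: Spectrum) -> tuple[int, int]:
    """(signature, rank) = (p - n-, p + n-)."""
    p, _, n_minus = inertia_of(s)
    return p - n_minus, p + n_minus


def descriptors_of(g: MolecularGraph, m: int, n: int,
                   zero_tol: float | None = None) -> DescriptorRecord:
    """All spectral descriptors of one graph, tagged with (m, n)."""
    s = spectrum_of(g, zero_tol=zero_tol)
    p, eta, n_minus = inertia_of(s)
    return DescriptorRecord(
        m=m, n=n,
        energy=graph_energy(s),
        estrada=estrada_index(s),
        p_plus=p, n_minus=n_minus, eta=eta,
        signature=p - n_minus, rank=p + n_minus,
    )


def _build(structure: str, m: int, n: int) -> MolecularGraph:
    if structure == "bii3":
        return bii3_sheet(LatticeIndex(m, n))
    if structure == "bre":
        return benzene_ptype(LatticeIndex(m, n))
    if structure in REFERENCE_FAMILIES:
        return reference_graph(structure, n)
    raise GraphError(
        f"unknown structure {structure!r}; expected one of "
        f"{STRUCTURES + REFERENCE_FAMILIES}")


def descriptor_sweep(structure: str, m: int, n_range: Iterable[int],
                     zero_tol: float | None = None) -> list[DescriptorRecord]:
    """Generate -> adjacency -> spectrum -> descriptors for each n.

    ``structure`` is one of the lattice families ("bii3", "bre"), for
    which (m, n) are unit-cell counts, or a reference family ("path",
    "cycle", ...) for which n plays the role of the vertex count k.
    """
    ns = list(n_range)
    if not ns:
        raise GraphError("empty n range")
    return [descriptors_of(_build(structure, m, n), m, n, zero_tol=zero_tol)
            for n in ns]


def sweep_to_frame(records: Sequence[DescriptorRecord]) -> pd.DataFrame:
    """Descriptor records as a DataFrame with the standard column layout."""
    return pd.DataFrame(
        [(r.m, r.n, r.energy, r.estrada, r.p_plus, r.n_minus, r.eta,
          r.signature, r.rank) for r in records],
        columns=list(DESCRIPTOR_COLUMNS),
    )
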