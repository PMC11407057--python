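"""Independent oracles used only by the test suite.

The spectral pipeline under test goes through a dense symmetric
eigensolver; the oracle here instead expands the characteristic
polynomial det(xI - A) exactly over the integers with sympy and extracts
its roots at high precision.  The two routes share no code.
"""

import numpy as np
import sympy


def charpoly_eigenvalues(a: np.ndarray) -> list[float]:
    """Real roots (with multiplicity) of det(xI - A), descending."""
    m = sympy.Matrix(np.asarray(a, dtype=int).tolist())
    poly = sympy.Poly(m.charpoly().as_expr())
    # exact isolation of the real roots, with multiplicity
    vals = sorted((float(r.evalf(30)) for r in poly.real_roots()), reverse=True)
    return vals


def energy_from_charpoly(a: np.ndarray) -> float:
    return float(sum(abs(v) for v in charpoly_eigenvalues(a)))


def estrada_from_charpoly(a: np.ndarray) -> float:
    return float(sum(np.exp(v) for v in charpoly_eigenvalues(a)))
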