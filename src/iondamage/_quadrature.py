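"""Shared fixed-order Gauss-Legendre helpers.

The integrands in this package are smooth once split at their known
features (a Drude resonance, a Bragg maximum, a Heaviside edge), so
fixed-order panels beat generic adaptive routines by a wide margin and
keep every result bit-reproducible.  Orders are chosen so that doubling
them moves results by far less than the documented tolerances; the
convergence tests exercise exactly that.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=32)
def leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def lin_nodes(a, b, n: int):
    """Nodes/weights for int_a^b f dx on a linear scale; a, b may be arrays."""
    x, w = leggauss(n)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    half = 0.5 * (b - a)
    t = half[..., None] * (x + 1.0) + a[..., None]
    return t, half[..., None] * w


def log_nodes(a, b, n: int):
    """Nodes/weights for int_a^b f dx using a log substitution (a, b > 0)."""
    x, w = leggauss(n)
    la = np.log(np.asarray(a, dtype=float))
    lb = np.log(np.asarray(b, dtype=float))
    half = 0.5 * (lb - la)
    t = np.exp(half[..., None] * (x + 1.0) + la[..., None])
    return t, half[..., None] * w * t
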