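"""Analytic benchmark functions for validating sensitivity estimators.

Both functions are defined on the unit hypercube so they can be driven by the
same designs as the PBPK model adapter.  Their Sobol indices are available in
closed form, which makes them the standard ground truth for variance-based
estimators.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ishigami",
    "ishigami_indices",
    "sobol_g",
    "sobol_g_indices",
]


def ishigami(u: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Ishigami function with inputs mapped from [0,1]^3 to (-pi, pi)^3."""
    u = np.atleast_2d(u)
    x = -np.pi + 2.0 * np.pi * u
    return (
        np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2 + b * x[:, 2] ** 4 * np.sin(x[:, 0])
    )


def ishigami_indices(a: float = 7.0, b: float = 0.1):
    """Closed-form main and total Sobol indices of the Ishigami function."""
    pi4 = np.pi ** 4
    v1 = 0.5 * (1.0 + b * pi4 / 5.0) ** 2
    v2 = a ** 2 / 8.0
    v13 = b ** 2 * pi4 ** 2 * (1.0 / 18.0 - 1.0 / 50.0)
    v = v1 + v2 + v13
    S = np.array([v1 / v, v2 / v, 0.0])
    ST = np.array([(v1 + v13) / v, v2 / v, v13 / v])
    return S, ST


def sobol_g(u: np.ndarray, a=(0.0, 9.0)) -> np.ndarray:
    """Sobol g-function: prod_i (|4 u_i - 2| + a_i) / (1 + a_i)."""
    u = np.atleast_2d(u)
    a = np.asarray(a, dtype=float)
    return np.prod((np.abs(4.0 * u - 2.0) + a) / (1.0 + a), axis=1)


def sobol_g_indices(a=(0.0, 9.0)):
    """Closed-form indices: V_i = (1/3)/(1+a_i)^2, V = prod(1+V_i) - 1."""
    a = np.asarray(a, dtype=float)
    vi = (1.0 / 3.0) / (1.0 + a) ** 2
    v = np.prod(1.0 + vi) - 1.0
    S = vi / v
    ST = np.empty_like(vi)
    for i in range(len(a)):
        others = np.prod(1.0 + np.delete(vi, i))
        ST[i] = vi[i] * others / v
    return S, ST
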