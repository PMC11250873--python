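"""Finite-difference helpers shared by the likelihood modules."""

from __future__ import annotations

from typing import Callable

import numpy as np


def hessian_from_score(
    score: Callable[[np.ndarray], np.ndarray],
    params: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Symmetric Hessian by central differences of an analytic gradient.

    Needs 2p gradient evaluations for p parameters, which is far cheaper and
    more accurate than differencing the objective twice.
    """
    params = np.asarray(params, float)
    p = params.shape[0]
    h = rel_step * np.maximum(1.0, np.abs(params))
    H = np.empty((p, p))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h[j]
        H[:, j] = (score(params + e) - score(params - e)) / (2.0 * h[j])
    return 0.5 * (H + H.T)


def gradient_fd(
    fun: Callable[[np.ndarray], float],
    params: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central-difference gradient of a scalar function."""
    params = np.asarray(params, float)
    p = params.shape[0]
    h = rel_step * np.maximum(1.0, np.abs(params))
    g = np.empty(p)
    for j in range(p):
        e = np.zeros(p)
        e[j] = h[j]
        g[j] = (fun(params + e) - fun(params - e)) / (2.0 * h[j])
    return g
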