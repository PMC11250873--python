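"""Halton-sequence standard-normal draws for simulated maximum likelihood.

Random-coefficient likelihoods integrate over the mixing distribution; that
integral is approximated by averaging over D draws per observation.  Halton
sequences — radical inverses of the integers in a prime base — cover (0,1)
far more evenly than pseudo-random numbers, so far fewer draws are needed
for a stable simulated likelihood.  Everything here is deterministic: no
random state exists in this module.

Dimension d uses the d-th smallest prime (2, 3, 5, 7, 11, ...); the first
``discard`` sequence elements are skipped to avoid the degenerate leading
points, and each observation receives a consecutive block of D elements,
transformed by the standard-normal quantile function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

__all__ = ["DrawMatrix", "radical_inverse", "halton_sequence", "halton_normal_draws", "PRIMES"]

#: default prime bases, one per random-coefficient dimension
PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)


def radical_inverse(index, base: int):
    """Digit-reversal radical inverse of ``index`` in ``base``, in (0, 1).

    Writing ``index`` in base b as d_m ... d_1 d_0, the radical inverse is
    0.d_0 d_1 ... d_m in base b.  Index 0 maps to 0, whose normal quantile
    is infinite, so it is rejected.
    """
    idx = np.asarray(index)
    if np.any(idx < 1):
        raise ValueError("index must be >= 1 (0 maps to 0, outside (0,1))")
    if base < 2:
        raise ValueError("base must be >= 2")
    i = idx.astype(np.int64)
    result = np.zeros(i.shape, dtype=float)
    f = 1.0
    while np.any(i > 0):
        f /= base
        result = result + f * (i % base)
        i = i // base
    return float(result) if np.isscalar(index) else result


def halton_sequence(n: int, base: int, start: int = 1) -> np.ndarray:
    """First ``n`` Halton points in ``base`` beginning at sequence index ``start``."""
    return radical_inverse(np.arange(start, start + n), base)


@dataclass(frozen=True)
class DrawMatrix:
    """Per-observation, per-draw standard-normal values.

    ``values`` has shape (n_obs, D, n_dims); element [i, d, r] is the r-th
    mixing dimension of draw d for observation i.
    """

    values: np.ndarray
    primes: tuple[int, ...]
    discard: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("values must be n_obs x D x n_dims")
        if len(set(self.primes)) != len(self.primes):
            raise ValueError("dimension primes must be distinct")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("draws must be finite")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]

    @property
    def n_dims(self) -> int:
        return self.values.shape[2]


def halton_normal_draws(
    n_obs: int,
    n_dims: int,
    D: int,
    discard: int = 10,
    primes: tuple[int, ...] | None = None,
) -> DrawMatrix:
    """Build the standard-normal draw matrix for simulated likelihood.

    Per dimension, sequence elements ``discard + 1 ... discard + n_obs * D``
    are generated, observation i taking the i-th consecutive block of D, and
    each point is mapped through the standard-normal quantile.  The
    construction is bit-reproducible: identical arguments give identical
    matrices.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if primes is None:
        primes = PRIMES[:n_dims]
    primes = tuple(int(p) for p in primes)
    if len(primes) != n_dims:
        raise ValueError(f"need {n_dims} primes, got {len(primes)}")
    if len(set(primes)) != n_dims:
        raise ValueError("duplicate primes")

    total = n_obs * D
    values = np.empty((n_obs, D, n_dims))
    for r, p in enumerate(primes):
        u = halton_sequence(total, p, start=discard + 1)
        values[:, :, r] = ndtri(u).reshape(n_obs, D)
    return DrawMatrix(values=values, primes=primes, discard=discard)


def star_discrepancy_1d(points: np.ndarray) -> float:
    """Exact star discrepancy of a 1-D point set in [0, 1)."""
    x = np.sort(np.asarray(points, float))
    n = x.shape[0]
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - x, x - (i - 1) / n)))
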