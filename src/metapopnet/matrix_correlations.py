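"""Mantel matrix-correlation tests and the attractiveness/repulsiveness analysis.

The Mantel statistic Z used here is the normalized one: the Pearson
correlation of the off-diagonal entries of two symmetric population-by-
population matrices, so |Z| <= 1 and Z is invariant to positive affine
rescaling of either matrix. Significance comes from jointly permuting the
rows and columns of the second matrix; p-values use the add-one convention
(see :mod:`metapopnet.permutation_tests`).

The attractiveness/repulsiveness analysis correlates three population-by-
temporal-class count matrices: events within each population (internal
activity) against events arriving in it (attractiveness) and events leaving
it (repulsiveness). These matrices are rectangular, so the classical Mantel
row/column scheme does not apply; the null instead permutes the population
rows of the second matrix, which preserves each temporal class's profile
while breaking the population pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import nan
from typing import Optional

import numpy as np

__all__ = ["MantelResult", "mantel_test", "attract_repulse_test"]

_TAILS = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class MantelResult:
    """Normalized Mantel correlation with its permutation p-value."""

    z: float
    p_value: float
    n_permutations: int
    tail: str
    seed: Optional[int] = None
    scheme: str = "joint row/column permutation"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def _tail_p(perm: np.ndarray, obs: float, tail: str) -> float:
    eps = 1e-12
    if tail == "greater":
        extreme = perm >= obs - eps
    elif tail == "less":
        extreme = perm <= obs + eps
    else:
        extreme = np.abs(perm) >= abs(obs) - eps
    return float((1 + np.count_nonzero(extreme)) / (1 + len(perm)))


def mantel_test(
    M1,
    M2,
    n_perm: int = 10_000,
    tail: str = "two-sided",
    seed: Optional[int] = None,
) -> MantelResult:
    """Mantel Z-test between two symmetric matrices over the same populations.

    Z is the Pearson correlation of the lower-triangle off-diagonal entries;
    the null distribution comes from applying the same random relabeling to
    the rows and columns of ``M2``. Matrices must be square, symmetric, of
    equal shape, with n >= 3. A zero-variance triangle leaves Z undefined:
    the result then carries NaN fields and a warning is raised.
    """
    A = np.asarray(M1, dtype=float)
    B = np.asarray(M2, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 populations")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("matrices must be symmetric")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    il = np.tril_indices(n, -1)
    x = A[il]
    y = B[il]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Mantel statistic undefined: zero variance in a triangle", stacklevel=2)
        return MantelResult(nan, nan, 0, tail, seed, "degenerate: zero variance")
    obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for t in range(n_perm):
        order = rng.permutation(n)
        perm[t] = _pearson(x, B[np.ix_(order, order)][il])
    return MantelResult(obs, _tail_p(perm, obs, tail), n_perm, tail, seed)


def attract_repulse_test(
    internal,
    arrivals,
    departures,
    n_perm: int = 10_000,
    tail: str = "two-sided",
    seed: Optional[int] = None,
) -> tuple[MantelResult, MantelResult]:
    """Correlate internal dispersal activity with arrivals and with departures.

    All three matrices are populations x temporal classes and must share a
    shape. Returns ``(attractiveness, repulsiveness)`` results: internal vs
    arrivals and internal vs departures, each a Pearson correlation of the
    flattened matrices with a population-row permutation null.
    """
    I = np.asarray(internal, dtype=float)
    A = np.asarray(arrivals, dtype=float)
    D = np.asarray(departures, dtype=float)
    if not (I.shape == A.shape == D.shape) or I.ndim != 2:
        raise ValueError("matrices must share the same populations x classes shape")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    rng = np.random.default_rng(seed)
    results = []
    for other in (A, D):
        x = I.ravel()
        y = other.ravel()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("correlation undefined: zero variance", stacklevel=2)
            results.append(MantelResult(nan, nan, 0, tail, seed, "degenerate: zero variance"))
            continue
        obs = _pearson(x, y)
        perm = np.empty(n_perm)
        for t in range(n_perm):
            perm[t] = _pearson(x, other[rng.permutation(I.shape[0]), :].ravel())
        results.append(
            MantelResult(obs, _tail_p(perm, obs, tail), n_perm, tail, seed, "population-row permutation")
        )
    return results[0], results[1]
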