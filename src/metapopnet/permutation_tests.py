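"""Permutation chi-squared tests for flow asymmetry and the node-strength trend F-test.

All tests share the Monte-Carlo p-value convention

    p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations)

(the add-one rule), which is never exactly zero and is unbiased as a
Monte-Carlo estimate of the exact conditional p-value. Every test takes a
seed and is exactly reproducible.

The asymmetry statistics are ordinary chi-squares - ``(a - b)^2 / (a + b)``
for a directed edge against the 50:50 expectation, and the Pearson
independence chi-square for an In/Out table - so their values do not depend
on the permutation scheme; only the p-values do. The schemes used are the
minimal exchangeable nulls for "no asymmetry": each event's direction is a
fair coin flip (edge test), and each row's split is binomial with the pooled
column fraction, conditional on row totals (table test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "edge_asymmetry_test",
    "table_asymmetry_test",
    "strength_trend_test",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its permutation p-value and provenance."""

    test: str
    statistic: float
    p_value: float
    n_permutations: int
    scheme: str
    seed: Optional[int] = None
    details: dict = field(default_factory=dict)


def _perm_p(perm_stats: np.ndarray, observed: float) -> float:
    # small epsilon so exact ties on a discrete statistic count as >=
    return float((1 + np.count_nonzero(perm_stats >= observed - 1e-12)) / (1 + len(perm_stats)))


def edge_asymmetry_test(
    a: int, b: int, n_perm: int = 10_000, seed: Optional[int] = None
) -> TestResult:
    """Test whether a directed edge's two flow counts are compatible with symmetry.

    ``a`` and ``b`` are the event counts i->j and j->i. The statistic is the
    goodness-of-fit chi-square against equal expected counts,
    ``(a - b)^2 / (a + b)``; under the null each of the a+b events takes
    either direction with probability 1/2.
    """
    a, b = int(a), int(b)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n = a + b
    if n == 0:
        warnings.warn("edge asymmetry test on zero events is degenerate", stacklevel=2)
        return TestResult("edge_asymmetry", 0.0, 1.0, 0, "degenerate: no events", seed)
    observed = (a - b) ** 2 / n
    rng = np.random.default_rng(seed)
    k = rng.binomial(n, 0.5, size=n_perm)
    perm = (2 * k - n) ** 2 / n
    return TestResult(
        "edge_asymmetry",
        float(observed),
        _perm_p(perm, observed),
        n_perm,
        "direction of each event flipped with probability 1/2",
        seed,
        {"a": a, "b": b},
    )


def table_asymmetry_test(
    table, n_perm: int = 10_000, seed: Optional[int] = None
) -> TestResult:
    """Test whether the In/Out split differs across the rows of an r x 2 count table.

    The statistic is the Pearson chi-square of independence. Under the null
    each row's first-column count is redrawn Binomial(row total, pooled
    first-column fraction), conditional on the row totals.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[1] != 2:
        raise ValueError("table must be r x 2")
    if np.any(T < 0):
        raise ValueError("counts must be non-negative")
    row_tot = T.sum(axis=1)
    if np.any(row_tot < 1):
        raise ValueError("all row sums must be >= 1")
    col_tot = T.sum(axis=0)
    if np.any(col_tot == 0):
        raise ValueError("zero column margin: statistic undefined")
    observed = float(stats.chi2_contingency(T, correction=False).statistic)

    rng = np.random.default_rng(seed)
    N = T.sum()
    p1 = col_tot[0] / N
    k = rng.binomial(row_tot.astype(int), p1, size=(n_perm, len(row_tot)))
    c1 = k.sum(axis=1)  # column-1 margin of each permuted table
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = row_tot[None, :] * (c1[:, None] / N)
        e2 = row_tot[None, :] - e1
        chi2 = ((k - e1) ** 2 / e1 + ((row_tot[None, :] - k) - e2) ** 2 / e2).sum(axis=1)
    # permuted tables with an empty column have no defined statistic; score 0
    chi2 = np.where((c1 == 0) | (c1 == N), 0.0, chi2)
    return TestResult(
        "table_asymmetry",
        observed,
        _perm_p(chi2, observed),
        n_perm,
        "row-conditional binomial redraw of the In/Out split",
        seed,
        {"rows": int(T.shape[0]), "n_events": int(N)},
    )


def strength_trend_test(
    strengths: "pd.DataFrame | Mapping[tuple[str, int], float]",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Permutation F-test of a linear trend of node strength over temporal classes.

    ``strengths`` maps (population, temporal class index) to a strength, or
    is a DataFrame with columns ``population``, ``class_index``, ``strength``.
    Strength is regressed on class index (OLS pooled over populations); the
    null permutes each population's strengths across its class indices, so
    population identity is preserved and only the time ordering is broken.
    Requires at least 3 temporal classes. The result carries ``r_squared``
    in ``details``.
    """
    if isinstance(strengths, Mapping):
        rows = [(pop, idx, val) for (pop, idx), val in strengths.items()]
        df = pd.DataFrame(rows, columns=["population", "class_index", "strength"])
    else:
        df = strengths[["population", "class_index", "strength"]].copy()
    if df["class_index"].nunique() < 3:
        raise ValueError("need at least 3 temporal classes")
    x = df["class_index"].to_numpy(dtype=float)
    y = df["strength"].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")

    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("class index has zero variance")

    def f_and_r2(yv: np.ndarray) -> tuple[float, float]:
        yc = yv - yv.mean()
        syy = float(yc @ yc)
        if syy == 0:
            return math.nan, 0.0
        r2 = (float(xc @ yc)) ** 2 / (sxx * syy)
        if r2 >= 1.0:
            return math.inf, 1.0
        return r2 / (1 - r2) * (n - 2), r2

    observed_f, r2 = f_and_r2(y)
    if math.isnan(observed_f):
        warnings.warn("strength trend F undefined: constant strengths", stacklevel=2)
        return TestResult(
            "strength_trend",
            math.nan,
            1.0,
            0,
            "degenerate: constant strengths",
            seed,
            {"r_squared": 0.0},
        )

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(df["population"].to_numpy() == pop) for pop in df["population"].unique()]
    perm = np.empty(n_perm)
    yp = y.copy()
    for t in range(n_perm):
        for g in groups:
            yp[g] = y[g][rng.permutation(len(g))]
        perm[t], _ = f_and_r2(yp)
    return TestResult(
        "strength_trend",
        float(observed_f),
        _perm_p(perm, observed_f),
        n_perm,
        "strengths permuted across temporal classes within population",
        seed,
        {"r_squared": float(r2), "n": n},
    )
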