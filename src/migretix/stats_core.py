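"""Shared statistical kernels.

Multiple-testing procedures (Benjamini-Hochberg step-up, Bonferroni
threshold), the contingency and rank tests used for cohort demographics
tables, and normal-tail p-value utilities used throughout the docking and
drug-target normalisation steps.

All functions are pure and operate on plain arrays / scalars.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "bonferroni_threshold",
    "chi2_yates",
    "mann_whitney_u",
    "upper_tail_p_from_z",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array-like of float
        Raw p-values, each in [0, 1]. Order is preserved: the i-th
        q-value corresponds to the i-th input p-value.

    Returns
    -------
    numpy.ndarray
        q-values in [0, 1], ``q_(i) = min_{j >= i} p_(j) * m / j`` on the
        sorted scale, capped at 1.

    Raises
    ------
    ValueError
        If the input is empty or any value lies outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(q, 1.0)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance cutoff ``alpha / m`` for ``m`` tests."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / int(m)


def chi2_yates(table, correction: bool = True) -> tuple[float, float]:
    """Chi-squared test on a 2x2 contingency table.

    By default applies the Yates continuity correction,
    ``sum(max(|O - E| - 0.5, 0)^2 / E)`` on 1 degree of freedom, which is
    the convention that reproduces published cohort sex-distribution
    statistics; pass ``correction=False`` for the uncorrected statistic.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Non-negative integer counts (rows = groups, columns = categories).
    correction : bool
        Apply the continuity correction (default True).

    Returns
    -------
    (statistic, pvalue)

    Raises
    ------
    ValueError
        For a non-2x2 table, negative counts, or a zero row/column margin.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("counts must be finite and non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(
    x,
    y,
    convention: Literal["min", "x"] = "min",
    method: Literal["auto", "exact", "asymptotic"] = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The reported U statistic follows the min-U convention by default
    (``min(U_x, U_y)``, the value most published demographics tables
    print); ``convention="x"`` reports U for the first sample. The p-value
    is exact for combined sample size <= 20 without ties, and uses the
    normal approximation with tie correction otherwise (``method="auto"``).

    Returns
    -------
    (U, pvalue)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "asymptotic" if (x.size + y.size > 20 or has_ties) else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x) if convention == "min" else u_x
    return u, float(res.pvalue)


def upper_tail_p_from_z(z) -> float | np.ndarray:
    """Upper-tail standard-normal probability ``1 - Phi(z)``.

    Strictly decreasing in z; ``upper_tail_p_from_z(z) +
    upper_tail_p_from_z(-z) == 1``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    p = stats.norm.sf(z)
    return float(p) if p.ndim == 0 else p
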