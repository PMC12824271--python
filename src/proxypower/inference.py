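"""Two-sided independent Welch's t-test — the sole hypothesis test used.

The public :func:`welch_test` wraps :func:`scipy.stats.ttest_ind` with
``equal_var=False``.  A vectorized variant evaluates one test per row of a
replicate matrix; it implements the same Welch-Satterthwaite formulas and is
cross-checked against scipy in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestResult", "welch_test", "welch_test_matrix"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one Welch t-test.

    ``t_stat`` is oriented as (mean_b - mean_a); ``reject`` uses strict
    inequality ``p_value < alpha`` (boundary cases have measure zero).
    """

    t_stat: float
    df: float
    p_value: float
    reject: bool


def _validate(sample, name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} must be 1-D with at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_test(sample_a, sample_b, alpha: float = 0.05) -> TestResult:
    """Two-sided Welch t-test of sample_b vs sample_a.

    Parameters
    ----------
    sample_a, sample_b : array-like
        Each with >= 2 finite values; at least one must have nonzero
        variance.
    alpha : float
        Two-sided level used for the ``reject`` flag.

    Returns
    -------
    TestResult
        t statistic (b minus a), Welch-Satterthwaite degrees of freedom,
        two-sided p-value, and the rejection decision at ``alpha``.
    """
    a = _validate(sample_a, "sample_a")
    b = _validate(sample_b, "sample_b")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError(
            "both samples have zero variance; the Welch t statistic is undefined"
        )
    res = stats.ttest_ind(b, a, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return TestResult(t_stat=t, df=df, p_value=p, reject=bool(p < alpha))


def welch_test_matrix(a: np.ndarray, b: np.ndarray, alpha: float):
    """Row-wise Welch tests on replicate matrices of shape (reps, n).

    Returns
    -------
    t : ndarray
        Welch t statistics (b minus a), one per replicate.
    p : ndarray
        Two-sided p-values.
    reject : ndarray of bool
        ``p < alpha`` per replicate.
    """
    n_a = a.shape[1]
    n_b = b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / n_a + vb / n_b
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, p < alpha
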