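"""Shared scalar/vector statistics used across modules."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats


@lru_cache(maxsize=2_000_000)
def cached_fisher_two_sided(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table, memoised on the counts.

    Degenerate margins (an all-zero row or column) carry no information
    about dependence and return 1.0.
    """
    if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
        return 1.0
    return float(stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")[1])


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch (unequal-variance) two-sided t-test; returns (t, p).

    Requires >=2 observations per side; otherwise returns (nan, 1.0), the
    caller's "untestable" convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return float("nan"), 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    if not np.isfinite(p):  # zero variance on both sides with equal means
        return float(t) if np.isfinite(t) else float("nan"), 1.0
    return float(t), float(p)


def fisher_p_array(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for an (m, 4) array of tables (n11, n10, n01, n00).

    Computes each distinct table once; cross-tabulations from cohort scans
    repeat heavily, so this is the fast path behind the pairwise scans.
    """
    tables = np.asarray(tables, dtype=np.int64).reshape(-1, 4)
    if tables.size == 0:
        return np.empty(0)
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    p_uniq = np.array([cached_fisher_two_sided(*map(int, t)) for t in uniq])
    return p_uniq[inverse.ravel()]
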