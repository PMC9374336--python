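"""Exact rank-based two-sample and paired tests.

Both tests condition on the observed (mid)ranks, so ties are handled
exactly in the enumeration paths instead of by an approximation: the exact
null is the permutation distribution of the rank statistic over sign flips
(signed rank) or group splits (Mann-Whitney) of the actual tied ranks.
Two-sided p-values count outcomes at least as far from the null mean as the
observed statistic; both null distributions are symmetric about their mean,
so this coincides with the usual doubled one-tail definition in the
continuous case.

Large samples fall back to the normal approximation with the standard tie
correction of the variance (no continuity correction).
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple

import numpy as np
from scipy.stats import norm, rankdata

from .types import DegenerateInputError

__all__ = ["RankTestResult", "wilcoxon_signed_rank", "mann_whitney_u"]

_EPS = 1e-12


class RankTestResult(NamedTuple):
    statistic: float  # W+ (signed rank) or U of the first sample (MWU)
    p_value: float
    exact: bool


def wilcoxon_signed_rank(diffs, max_exact: int = 15) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention); ties in |d| get
    midranks.  Exact enumeration over all 2^n sign assignments is used for
    n <= ``max_exact``, the tie-corrected normal approximation otherwise.
    Raises ``DegenerateInputError`` if every difference is zero.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = float(ranks.sum()) / 2.0

    if n <= max_exact:
        # all sign assignments: rows of the n-bit counter
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        stats = signs @ ranks
        p = float(np.mean(np.abs(stats - mu) >= np.abs(w_plus - mu) - _EPS))
        return RankTestResult(w_plus, p, True)

    # normal approximation; tie correction subtracts sum(t^3 - t) / 48
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts ** 3 - counts)) / 48.0
    if var <= 0:
        return RankTestResult(w_plus, 1.0, False)
    z = (w_plus - mu) / np.sqrt(var)
    return RankTestResult(w_plus, float(2.0 * norm.sf(abs(z))), False)


def mann_whitney_u(x, y, max_exact_total: int = 20) -> RankTestResult:
    """Two-sided Mann-Whitney U test; U is reported for sample ``x``.

    Exact enumeration over all C(n_x + n_y, n_x) rank splits of the pooled
    midranks for combined n <= ``max_exact_total``; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise DegenerateInputError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = float(ranks[:nx].sum())
    u_x = r_x - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    n = nx + ny

    if n <= max_exact_total:
        obs_dev = abs(u_x - mu)
        shift = nx * (nx + 1) / 2.0
        hits = total = 0
        for comb in combinations(range(n), nx):
            rs = ranks[list(comb)].sum()
            total += 1
            if abs((rs - shift) - mu) >= obs_dev - _EPS:
                hits += 1
        return RankTestResult(u_x, hits / total, True)

    # tie-corrected variance of U
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(u_x, 1.0, False)
    z = (u_x - mu) / np.sqrt(var)
    return RankTestResult(u_x, float(2.0 * norm.sf(abs(z))), False)
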