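"""Exact tests used throughout the pipeline.

Two primitives carry the pipeline's inference and are implemented here
rather than delegated, so their small-sample behaviour is fully specified
and oracle-testable:

* one-/two-sided Fisher exact tests on 2x2 tables, computed by explicit
  enumeration of the hypergeometric support in log space;
* the Wilcoxon rank-sum test with midrank ties, using exact enumeration
  of rank allocations for small groups and the tie-corrected normal
  approximation otherwise.

Both are deterministic, dependency-light, and agree with independent
enumeration oracles to machine precision (see the test suite).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, rankdata

__all__ = [
    "fisher_exact_greater",
    "fisher_exact_twosided",
    "odds_ratio_ci",
    "rank_sum_test",
    "rank_sum_matrix",
    "OddsRatioResult",
]

# maximum per-group size for which the Wilcoxon p is computed by exact
# enumeration of rank allocations; beyond this the normal approximation
# with tie correction is used
EXACT_RANKSUM_MAX_N = 10

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _check_table(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("2x2 table entries must be non-negative integers")


def _hypergeom_log_pmf_support(a: int, b: int, c: int, d: int):
    """Log pmf of A over its support, margins fixed at (a+b, c+d, a+c)."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    log_pmf = (
        _log_binom(row1, ks)
        + _log_binom(n_total - row1, col1 - ks)
        - _log_binom(n_total, col1)
    )
    return ks, log_pmf


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p-value for association (odds ratio > 1).

    P(A >= a) under the central hypergeometric null with all margins
    fixed, evaluated by enumeration in log space. A table with any zero
    margin carries no information and returns 1.0 by convention.
    """
    _check_table(a, b, c, d)
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0
    ks, log_pmf = _hypergeom_log_pmf_support(a, b, c, d)
    tail = log_pmf[ks >= a]
    if tail.size == 0:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(tail))))


def fisher_exact_twosided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: total probability of tables no more
    likely than the observed one (the standard convention)."""
    _check_table(a, b, c, d)
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0
    ks, log_pmf = _hypergeom_log_pmf_support(a, b, c, d)
    log_obs = log_pmf[ks == a][0]
    # relative tolerance guards against ties broken by rounding
    keep = log_pmf <= log_obs + 1e-7
    return float(min(1.0, math.exp(logsumexp(log_pmf[keep]))))


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied for the CI


def odds_ratio_ci(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Sample odds ratio a*d/(b*c) with a 95% Woolf (log) CI.

    Whenever any cell is zero the CI (and the OR it is centred on) uses
    the Haldane-Anscombe +0.5 correction on all four cells; the reported
    point estimate stays uncorrected (+inf / 0 / nan for degenerate
    numerators and denominators).
    """
    _check_table(a, b, c, d)
    if a * d == 0 and b * c == 0:
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), True)
    if b * c == 0:
        or_point = float("inf")
    elif a * d == 0:
        or_point = 0.0
    else:
        or_point = (a * d) / (b * c)
    corrected = min(a, b, c, d) == 0
    if corrected:
        ah, bh, ch, dh = (x + 0.5 for x in (a, b, c, d))
    else:
        ah, bh, ch, dh = float(a), float(b), float(c), float(d)
    log_or = math.log(ah * dh / (bh * ch))
    se = math.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    return OddsRatioResult(
        odds_ratio=or_point,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_ranksum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all C(N, n1) rank allocations.

    Ties are carried through midranks; the two-sided p doubles the
    smaller tail probability (capped at 1).
    """
    n_total = ranks.size
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n_total), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    ws = ranks[idx].sum(axis=1)
    n_alloc = ws.size
    eps = 1e-9
    p_low = np.count_nonzero(ws <= w_obs + eps) / n_alloc
    p_high = np.count_nonzero(ws >= w_obs - eps) / n_alloc
    return min(1.0, 2.0 * min(p_low, p_high))


def rank_sum_test(x, y, exact_max_n: int = EXACT_RANKSUM_MAX_N) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Returns (W, p) where W is the midrank sum of x in the pooled sample.
    Exact enumeration when both groups have at most ``exact_max_n``
    observations; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    if n1 <= exact_max_n and n2 <= exact_max_n:
        return w, _exact_ranksum_p(ranks, n1, w)
    return w, _normal_p_single(ranks, n1)


def _normal_p_single(ranks: np.ndarray, n1: int) -> float:
    n_total = ranks.size
    n2 = n_total - n1
    w = ranks[:n1].sum()
    mu = n1 * (n_total + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def rank_sum_matrix(X: np.ndarray, mask1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided rank-sum test per column of X.

    ``mask1`` selects group-1 rows. Uses midranks and the tie-corrected
    normal approximation (intended for the group sizes where the exact
    path does not apply); columns are genes.
    """
    X = np.asarray(X, dtype=float)
    mask1 = np.asarray(mask1, dtype=bool)
    n_total, n_genes = X.shape
    n1 = int(mask1.sum())
    n2 = n_total - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(X, axis=0)
    w = ranks[mask1].sum(axis=0)
    mu = n1 * (n_total + 1) / 2.0
    # tie correction per gene: sum over tied groups of (t^3 - t)
    sorted_cols = np.sort(X, axis=0)
    tie_term = np.empty(n_genes)
    for j in range(n_genes):
        _, counts = np.unique(sorted_cols[:, j], return_counts=True)
        tie_term[j] = ((counts**3 - counts)).sum()
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    z = np.zeros(n_genes)
    ok = var > 0
    z[ok] = (w[ok] - mu) / np.sqrt(var[ok])
    p = np.minimum(1.0, 2.0 * norm.sf(np.abs(z)))
    p[~ok] = 1.0
    return w, p
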