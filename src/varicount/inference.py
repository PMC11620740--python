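"""Permutation inference for small cohorts of precursor estimates.

Precursor-number estimates arrive a handful per condition (one per
biological replicate), with no credible distributional model, so group
comparisons use permutation tests: the paired test enumerates all
``2^k`` sign flips of the per-replicate differences, the unpaired test
all ``C(n1+n2, n1)`` relabelings of the pooled estimates.  Exhaustive
enumeration is used whenever the arrangement count is modest (default
cap one million), otherwise seeded Monte Carlo sampling with the
identity arrangement always counted — so p can never be 0 and the
smallest attainable p is 1/#arrangements (e.g. 1/8 at three pairs,
1/32 at five).  The default direction is one-sided in the observed
direction, which is what makes those attainable minima achievable.

Also here: the analysis-of-covariance F-tests used to compare two
log-linear calibration fits (equal slopes via the interaction term,
equal intercepts on the common-slope model).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "PermutationResult",
    "paired_permutation",
    "unpaired_permutation",
    "compare_regressions",
]

_REL_TIE_TOL = 1e-12  # relative tolerance when counting tied statistics


@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float
    p_value: float
    mode: str  # "exact" | "monte_carlo"
    n_arrangements: int
    min_attainable_p: float
    paired: bool
    direction: str  # "observed" | "two-sided"


def _count_extreme(perm: np.ndarray, obs: float, direction: str) -> int:
    tol = _REL_TIE_TOL * max(1.0, abs(obs))
    if direction == "two-sided":
        return int(np.sum(np.abs(perm) >= abs(obs) - tol))
    # one-sided in the observed direction
    if obs >= 0:
        return int(np.sum(perm >= obs - tol))
    return int(np.sum(perm <= obs + tol))


def paired_permutation(
    a,
    b,
    direction: str = "observed",
    max_exact: int = 1_000_000,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Sign-flip permutation test on paired estimates.

    Statistic: mean of the paired differences ``a - b``.  Enumerates all
    ``2^k`` sign assignments exactly while that count does not exceed
    ``max_exact``; otherwise samples ``n_mc`` random sign vectors with
    the identity arrangement always included.  ``direction="observed"``
    counts arrangements at least as extreme in the observed direction
    (attainable minimum ``1/2^k``); ``"two-sided"`` compares absolute
    statistics.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and of equal length (paired)")
    k = a.size
    if k < 2:
        raise ValueError("need at least 2 pairs")
    if direction not in ("observed", "two-sided"):
        raise ValueError("direction must be 'observed' or 'two-sided'")
    d = a - b
    obs = float(d.mean())
    n_arr = 2**k

    if np.all(d == 0):
        return PermutationResult(0.0, 1.0, "exact", n_arr, 1.0 / n_arr,
                                 True, direction)

    if n_arr <= max_exact:
        count = 0
        bits = np.arange(k)
        for start in range(0, n_arr, 1 << 16):
            idx = np.arange(start, min(start + (1 << 16), n_arr))
            signs = ((idx[:, None] >> bits) & 1) * 2 - 1
            perm = (signs * d).mean(axis=1)
            count += _count_extreme(perm, obs, direction)
        return PermutationResult(obs, count / n_arr, "exact", n_arr,
                                 1.0 / n_arr, True, direction)

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_mc, k))
    perm = (signs * d).mean(axis=1)
    count = 1 + _count_extreme(perm, obs, direction)  # identity included
    return PermutationResult(obs, count / (n_mc + 1), "monte_carlo", n_arr,
                             1.0 / (n_mc + 1), True, direction)


def unpaired_permutation(
    a,
    b,
    direction: str = "observed",
    max_exact: int = 1_000_000,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Relabeling permutation test on two independent groups.

    Statistic: ``mean(a) - mean(b)``.  Enumerates all
    ``C(n1+n2, n1)`` reassignments of the pooled values to group A while
    that count does not exceed ``max_exact``; otherwise seeded Monte
    Carlo.  Attainable minimum p under exact enumeration is
    ``1/C(n1+n2, n1)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("both groups must be 1-D with at least 2 values")
    if direction not in ("observed", "two-sided"):
        raise ValueError("direction must be 'observed' or 'two-sided'")
    n1, n2 = a.size, b.size
    pool = np.concatenate([a, b])
    total = float(pool.sum())
    obs = float(a.mean() - b.mean())
    n_arr = comb(n1 + n2, n1)

    def stat_from_sum_a(sum_a):
        return sum_a / n1 - (total - sum_a) / n2

    if n_arr <= max_exact:
        idx = np.fromiter(
            (i for c in combinations(range(n1 + n2), n1) for i in c),
            dtype=np.intp, count=n_arr * n1,
        ).reshape(n_arr, n1)
        perm = stat_from_sum_a(pool[idx].sum(axis=1))
        count = _count_extreme(perm, obs, direction)
        return PermutationResult(obs, count / n_arr, "exact", n_arr,
                                 1.0 / n_arr, False, direction)

    rng = np.random.default_rng(seed)
    perm = np.empty(n_mc)
    for i in range(n_mc):
        sel = rng.choice(n1 + n2, size=n1, replace=False)
        perm[i] = stat_from_sum_a(pool[sel].sum())
    count = 1 + _count_extreme(perm, obs, direction)
    return PermutationResult(obs, count / (n_mc + 1), "monte_carlo", n_arr,
                             1.0 / (n_mc + 1), False, direction)


def compare_regressions(x1, y1, x2, y2) -> tuple[float, float]:
    """ANCOVA comparison of two straight-line fits.

    Returns ``(p_equal_slopes, p_equal_intercepts)``: the equal-slopes
    p-value comes from the group-by-predictor interaction term of the
    full model; the equal-intercepts p-value from the group term of the
    common-slope model.  Used to check, e.g., that calibration lines for
    different marker channels share the theoretical slope while their
    intercepts differ with the channel's mean labeling fraction.
    """
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    for x, y in ((x1, y1), (x2, y2)):
        if x.shape != y.shape or x.ndim != 1 or x.size < 3:
            raise ValueError("each line needs >= 3 paired points")
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: predictor has no variation")
    df = pd.DataFrame({
        "x": np.concatenate([x1, x2]),
        "y": np.concatenate([y1, y2]),
        "g": [0] * x1.size + [1] * x2.size,
    })
    full = smf.ols("y ~ x * C(g)", data=df).fit()
    p_slopes = float(full.pvalues["x:C(g)[T.1]"])
    common = smf.ols("y ~ x + C(g)", data=df).fit()
    p_intercepts = float(common.pvalues["C(g)[T.1]"])
    return p_slopes, p_intercepts
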