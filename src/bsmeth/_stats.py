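"""Exact-test primitives shared by the DMR caller and the enrichment module."""

from __future__ import annotations

import math

from scipy.stats import fisher_exact as _scipy_fisher

# Above this grand total the exact big-integer path becomes slow and the
# knife-edge tie risk it guards against is gone; hand off to scipy.
_EXACT_MAX_TOTAL = 200


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Sums the probabilities of all tables with the observed margins that are
    no more likely than the observed table (the standard exact convention).
    For small tables the sum is carried out in integer arithmetic — the
    hypergeometric probabilities share the denominator C(M, N), so tables
    are compared by their integer numerators and no floating-point tie
    tolerance is needed. Large tables delegate to ``scipy.stats.fisher_exact``.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    m = a + b + c + d
    if m == 0:
        return 1.0
    if m > _EXACT_MAX_TOTAL:
        return float(_scipy_fisher([[a, b], [c, d]]).pvalue)
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    # numerator of P(k) is C(row1, k) * C(row2, col1 - k)
    row2 = c + d
    obs = math.comb(row1, a) * math.comb(row2, col1 - a)
    num = 0
    for k in range(lo, hi + 1):
        w = math.comb(row1, k) * math.comb(row2, col1 - k)
        if w <= obs:
            num += w
    return min(1.0, num / math.comb(m, col1))


def benjamini_hochberg(pvals):
    """Thin wrapper kept here so multiple-testing policy lives in one place."""
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]
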