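"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the Wilson interval is
the textbook closed form, the paired-score reference is an exact trinomial
enumeration at the restricted null, and McNemar's reference is the exact
binomial test on the discordant pairs.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import binomtest, norm


def wilson_interval_textbook(k: int, n: int, conf: float = 0.95):
    """Wilson score interval straight from the closed-form expression."""
    z = norm.ppf(1 - (1 - conf) / 2)
    phat = k / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return max(center - half, 0.0), min(center + half, 1.0)


def trinomial_pmf(n10: int, n01: int, n: int, p1: float, p2: float) -> float:
    m = n - n10 - n01
    p3 = 1.0 - p1 - p2
    for p in (p1, p2, p3):
        if p < -1e-9:
            return 0.0
    p1, p2, p3 = max(p1, 0.0), max(p2, 0.0), max(p3, 0.0)
    coeff = (math.factorial(n)
             // (math.factorial(n10) * math.factorial(n01) * math.factorial(m)))

    def power(p, k):
        return 1.0 if k == 0 else p ** k

    return coeff * power(p1, n10) * power(p2, n01) * power(p3, m)


def exact_score_p(n10: int, n01: int, n: int, delta: float, statistic) -> float:
    """Exact one-sided p by brute-force enumeration of all paired outcomes.

    ``statistic(n10, n01, n, delta0)`` must return the signed score statistic;
    the null distribution is the trinomial at the restricted MLE implied by
    the observed table (delta0 = -delta), and p = P(Z >= Z_obs).
    """
    from lvhscreen.paired import restricted_p01  # nuisance estimate only

    d0 = -delta
    eta = float(restricted_p01(n10, n01, n, d0))
    p1, p2 = eta + d0, eta
    z_obs = statistic(n10, n01, n, d0)
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            if statistic(a, b, n, d0) >= z_obs - 1e-12:
                total += trinomial_pmf(a, b, n, p1, p2)
    return total


def exact_binomial_p(n10: int, n01: int) -> float:
    """Exact two-sided binomial test on the discordant pairs (p = 1/2)."""
    return binomtest(n10, n10 + n01, 0.5).pvalue


def kappa_closed_form(table) -> float:
    """kappa = (po - pe)/(1 - pe) computed directly from the table."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) / n) @ (t.sum(axis=0) / n))
    return (po - pe) / (1 - pe)


def exact_predictive_values(tp: int, fp: int, fn: int, tn: int):
    """PPV/NPV as exact rationals straight from the 2x2 definition."""
    return Fraction(tp, tp + fp), Fraction(tn, tn + fn)
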