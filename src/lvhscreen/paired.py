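"""Paired comparisons of two binary tests on the same subjects.

Three tools:

* :func:`paired_noninferiority` — score-based non-inferiority test for the
  difference of paired proportions (Tango-type). With both tests applied to
  every subject, the data form a paired 2x2 table with discordant counts
  ``n10`` (A positive only) and ``n01`` (B positive only). The hypothesis
  H0: pA - pB <= -delta is tested against H1: pA - pB > -delta with the score
  statistic evaluated at the restricted maximum-likelihood estimate of the
  nuisance discordance probability under pA - pB = -delta. The restricted
  MLE solves a quadratic in closed form; the resulting statistic reduces to
  the (signed) McNemar score statistic when delta = 0.

* :func:`mcnemar_test` — the classical chi-square test on discordant pairs,
  used here as the delta = 0 reference.

* :func:`cohen_kappa` — chance-corrected inter-rater agreement with the
  large-sample (Fleiss-type) confidence interval, clipped to [-1, 1]; a
  pair-resampling bootstrap interval is available for small re-read samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

__all__ = [
    "PairedBinaryTable",
    "NoninferiorityResult",
    "McNemarResult",
    "KappaResult",
    "tango_z",
    "paired_noninferiority",
    "mcnemar_test",
    "cohen_kappa",
    "agreement_table_from_reads",
]


@dataclass(frozen=True)
class PairedBinaryTable:
    """Counts of subjects by (test A outcome, test B outcome) on one endpoint."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.n <= 0:
            raise ValueError("paired table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def p_a(self) -> float:
        return (self.n11 + self.n10) / self.n

    @property
    def p_b(self) -> float:
        return (self.n11 + self.n01) / self.n

    @property
    def difference(self) -> float:
        """pA - pB = (n10 - n01) / n."""
        return (self.n10 - self.n01) / self.n

    @classmethod
    def from_labels(cls, a, b) -> "PairedBinaryTable":
        a = np.asarray(a).astype(int)
        b = np.asarray(b).astype(int)
        if a.shape != b.shape:
            raise ValueError("paired outcome vectors must have equal length")
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("outcomes must be binary 0/1")
        return cls(
            n11=int(((a == 1) & (b == 1)).sum()),
            n10=int(((a == 1) & (b == 0)).sum()),
            n01=int(((a == 0) & (b == 1)).sum()),
            n00=int(((a == 0) & (b == 0)).sum()),
        )


@dataclass(frozen=True)
class NoninferiorityResult:
    delta: float
    alpha: float
    difference: float  # pA - pB
    statistic: float
    p_value: float
    non_inferior: bool
    n: int
    n10: int
    n01: int
    endpoint: Optional[str] = None


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    correction: bool
    defined: bool = True


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    lo: float
    hi: float
    se: float
    po: float
    pe: float
    n: int
    method: str = "large-sample"
    defined: bool = True


def restricted_p01(n10, n01, n, delta0):
    """Restricted MLE of the (A-, B+) discordance probability under
    pA - pB = delta0.

    The profile-likelihood stationarity condition is a quadratic in
    p01; both roots are clipped to the feasible interval
    [max(0, -delta0), (1 - delta0)/2] and the one with the higher
    log-likelihood is returned. Vectorised over table counts.
    """
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n = np.asarray(n, dtype=float)
    d0 = float(delta0)
    m = n - n10 - n01
    a = -2.0 * n
    b = (n10 + n01) - d0 * (n10 + 3.0 * n01 + 2.0 * m)
    c = n01 * d0 * (1.0 - d0)
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    sq = np.sqrt(disc)
    lo, hi = max(0.0, -d0), (1.0 - d0) / 2.0
    roots = np.stack([(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)])
    roots = np.clip(roots, lo, hi)

    def loglik(eta):
        p1 = eta + d0
        p2 = eta
        p3 = 1.0 - 2.0 * eta - d0
        out = np.zeros_like(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            for cnt, p in ((n10, p1), (n01, p2), (m, p3)):
                term = np.where(cnt > 0, cnt * np.log(np.maximum(p, 0.0)), 0.0)
                out = out + np.where((cnt > 0) & (p <= 0), -np.inf, term)
        return out

    lls = loglik(roots)
    pick = np.argmax(lls, axis=0)
    eta = np.take_along_axis(roots, pick[None, ...], axis=0)[0]
    return eta


def tango_z(n10, n01, n, delta0):
    """Signed score statistic for H0: pA - pB = delta0 (vectorised).

    Z = (n10 - n01 - n*delta0) / sqrt(n * (2*eta + delta0 - delta0^2)) with
    eta the restricted MLE from :func:`restricted_p01`. Large positive Z is
    evidence that pA - pB exceeds delta0. Degenerate tables (zero variance,
    only possible when both discordant probabilities vanish under the null)
    return Z = 0.
    """
    n10a = np.asarray(n10, dtype=float)
    n01a = np.asarray(n01, dtype=float)
    na = np.asarray(n, dtype=float)
    d0 = float(delta0)
    eta = restricted_p01(n10a, n01a, na, d0)
    var = na * (2.0 * eta + d0 - d0 * d0)
    num = n10a - n01a - na * d0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, num / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    if np.isscalar(n10) or z.ndim == 0:
        return float(z)
    return z


def paired_noninferiority(
    table: PairedBinaryTable,
    delta: float = 0.05,
    alpha: float = 0.05,
    endpoint: Optional[str] = None,
) -> NoninferiorityResult:
    """Non-inferiority of test A relative to test B on paired data.

    Tests H0: pA - pB <= -delta against H1: pA - pB > -delta with the
    restricted-MLE score statistic; one-sided p = 1 - Phi(Z). Non-inferiority
    is declared when p < alpha. ``delta`` is the margin (largest tolerated
    deficit of A); ``delta = 0`` reduces to a one-sided McNemar-type score
    test, for which the all-concordant table is defined as Z = 0, p = 0.5.
    """
    if not (0 <= delta < 1):
        raise ValueError("delta must lie in [0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    z = tango_z(table.n10, table.n01, table.n, -delta)
    p = float(norm.sf(z))
    return NoninferiorityResult(
        delta=delta,
        alpha=alpha,
        difference=table.difference,
        statistic=float(z),
        p_value=p,
        non_inferior=bool(p < alpha),
        n=table.n,
        n10=table.n10,
        n01=table.n01,
        endpoint=endpoint,
    )


def mcnemar_test(table: PairedBinaryTable, correction: bool = False) -> McNemarResult:
    """McNemar chi-square test on the discordant pairs.

    chi2 = (|n10 - n01| - 1)^2 / (n10 + n01) with continuity correction,
    or (n10 - n01)^2 / (n10 + n01) without; two-sided p from chi2(1). A table
    with no discordant pairs is undefined-flagged.
    """
    if table.n10 + table.n01 == 0:
        return McNemarResult(statistic=float("nan"), p_value=float("nan"),
                             correction=correction, defined=False)
    sm_table = [[table.n11, table.n10], [table.n01, table.n00]]
    res = _sm_mcnemar(sm_table, exact=False, correction=correction)
    return McNemarResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                         correction=correction, defined=True)


def agreement_table_from_reads(read1, read2, categories=(0, 1)) -> np.ndarray:
    """Square rater-by-rater contingency table over the given categories."""
    r1 = np.asarray(read1)
    r2 = np.asarray(read2)
    if r1.shape != r2.shape:
        raise ValueError("read vectors must have equal length")
    k = len(categories)
    table = np.zeros((k, k), dtype=int)
    index = {c: i for i, c in enumerate(categories)}
    for a, b in zip(r1.tolist(), r2.tolist()):
        if a not in index or b not in index:
            raise ValueError(f"read value outside categories {categories}: {(a, b)}")
        table[index[a], index[b]] += 1
    return table


def cohen_kappa(
    table,
    conf: float = 0.95,
    method: str = "large-sample",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> KappaResult:
    """Cohen's kappa with a confidence interval, clipped to [-1, 1].

    kappa = (po - pe) / (1 - pe), po the observed agreement proportion and pe
    the chance agreement implied by the margins. ``method='large-sample'``
    uses the Fleiss-type asymptotic standard error; ``'bootstrap'`` resamples
    subject pairs. Both raters constant in the same category make pe = 1 and
    kappa undefined (flagged, not raised).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if (t < 0).any():
        raise ValueError("agreement table counts must be nonnegative")
    n = t.sum()
    if n <= 0:
        raise ValueError("agreement table must contain at least one subject")
    po = float(np.trace(t) / n)
    marg1 = t.sum(axis=1) / n
    marg2 = t.sum(axis=0) / n
    pe = float((marg1 * marg2).sum())
    if pe >= 1.0 - 1e-12:
        return KappaResult(kappa=float("nan"), lo=float("nan"), hi=float("nan"),
                           se=float("nan"), po=po, pe=pe, n=int(n),
                           method=method, defined=False)
    if method == "large-sample":
        res = _sm_cohens_kappa(t, return_results=True)
        kappa = float(res.kappa)
        se = float(np.sqrt(res.var_kappa))
        z = norm.ppf(1 - (1 - conf) / 2)
        lo, hi = kappa - z * se, kappa + z * se
    elif method == "bootstrap":
        kappa = (po - pe) / (1 - pe)
        rng = np.random.default_rng(seed)
        k = t.shape[0]
        cells = [(i, j) for i in range(k) for j in range(k)]
        probs = (t / n).ravel()
        stats = []
        for _ in range(n_boot):
            counts = rng.multinomial(int(n), probs).reshape(k, k)
            bn = counts.sum()
            bpo = np.trace(counts) / bn
            bpe = float((counts.sum(axis=1) / bn * (counts.sum(axis=0) / bn)).sum())
            if bpe < 1.0 - 1e-12:
                stats.append((bpo - bpe) / (1 - bpe))
        lo, hi = np.quantile(stats, [(1 - conf) / 2, 1 - (1 - conf) / 2])
        se = float(np.std(stats, ddof=1))
    else:
        raise ValueError("method must be 'large-sample' or 'bootstrap'")
    return KappaResult(
        kappa=kappa,
        lo=float(np.clip(lo, -1.0, 1.0)),
        hi=float(np.clip(hi, -1.0, 1.0)),
        se=se,
        po=po,
        pe=pe,
        n=int(n),
        method=method,
        defined=True,
    )
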