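"""Diagnostic test characteristics against a gold standard.

Sensitivity, specificity, PPV and NPV from 2x2 counts with binomial
confidence intervals (Wilson score by default, Clopper-Pearson exact on
request), the Bayes conversion from (prevalence, sensitivity, specificity)
to predictive values, and the normal-approximation sample size for
estimating a proportion to a prescribed margin of error.

Degenerate denominators are reported as explicitly undefined quantities
(``defined=False``), never silently as zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "ProportionEstimate",
    "TestCharacteristics",
    "test_characteristics",
    "ppv_npv_from_prevalence",
    "wilson_ci",
    "binomial_ci",
    "sample_size_proportion",
]

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta", "exact": "beta"}


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts of a binary criterion against the gold-standard label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.n <= 0:
            raise ValueError("total count must be positive")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Gold-standard positives."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n

    @classmethod
    def from_labels(cls, gold, predicted) -> "ConfusionCounts":
        g = np.asarray(gold).astype(int)
        p = np.asarray(predicted).astype(int)
        if g.shape != p.shape:
            raise ValueError("gold and predicted must have equal length")
        if not (np.isin(g, (0, 1)).all() and np.isin(p, (0, 1)).all()):
            raise ValueError("labels must be binary 0/1")
        return cls(
            tp=int(((g == 1) & (p == 1)).sum()),
            fp=int(((g == 0) & (p == 1)).sum()),
            fn=int(((g == 1) & (p == 0)).sum()),
            tn=int(((g == 0) & (p == 0)).sum()),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its confidence interval.

    ``defined=False`` flags a zero denominator; the numeric fields are then
    NaN and must not be interpreted.
    """

    value: float
    lo: float
    hi: float
    k: int = 0
    n: int = 0
    defined: bool = True

    @classmethod
    def undefined(cls) -> "ProportionEstimate":
        return cls(value=math.nan, lo=math.nan, hi=math.nan, k=0, n=0,
                   defined=False)


@dataclass(frozen=True)
class TestCharacteristics:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    ci_method: str = "wilson"
    conf: float = 0.95


def binomial_ci(k: int, n: int, conf: float = 0.95,
                method: str = "wilson") -> Tuple[float, float]:
    """Confidence interval for a binomial proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    key = method.strip().lower()
    if key not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from "
                         f"{sorted(_CI_METHODS)}")
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method=_CI_METHODS[key])
    # the analytical bounds at k=0 and k=n are exactly 0 and 1; snap away
    # floating-point residue from the library computation
    lo = 0.0 if k == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if k == n else float(np.clip(hi, 0.0, 1.0))
    return (lo, hi)


def wilson_ci(k: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for ``k`` successes in ``n`` trials."""
    return binomial_ci(k, n, conf=conf, method="wilson")


def _estimate(k: int, n: int, conf: float, method: str) -> ProportionEstimate:
    if n == 0:
        return ProportionEstimate.undefined()
    lo, hi = binomial_ci(k, n, conf=conf, method=method)
    return ProportionEstimate(value=k / n, lo=lo, hi=hi, k=k, n=n, defined=True)


def test_characteristics(
    counts: ConfusionCounts, ci_method: str = "wilson", conf: float = 0.95
) -> TestCharacteristics:
    """Sensitivity, specificity, PPV, NPV with confidence intervals.

    sens = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn); any quantity with a zero denominator is returned
    undefined-flagged.
    """
    return TestCharacteristics(
        sensitivity=_estimate(counts.tp, counts.tp + counts.fn, conf, ci_method),
        specificity=_estimate(counts.tn, counts.tn + counts.fp, conf, ci_method),
        ppv=_estimate(counts.tp, counts.tp + counts.fp, conf, ci_method),
        npv=_estimate(counts.tn, counts.tn + counts.fn, conf, ci_method),
        ci_method=ci_method,
        conf=conf,
    )


def ppv_npv_from_prevalence(prevalence, sensitivity, specificity):
    """Predictive values from prevalence and operating characteristics (Bayes).

    ppv = p*se / (p*se + (1-p)(1-sp));  npv = (1-p)*sp / ((1-p)*sp + p(1-se)).

    Works with floats or exact :class:`fractions.Fraction` inputs (no float
    coercion). A zero denominator yields ``None`` for that value.
    """
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    p, se, sp = prevalence, sensitivity, specificity
    ppv_den = p * se + (1 - p) * (1 - sp)
    npv_den = (1 - p) * sp + p * (1 - se)
    ppv = (p * se / ppv_den) if ppv_den != 0 else None
    npv = ((1 - p) * sp / npv_den) if npv_den != 0 else None
    return ppv, npv


def sample_size_proportion(
    p: float, margin: float, conf: float = 0.95, rounding: str = "floor"
) -> int:
    """Subjects needed to estimate a proportion ``p`` to +/- ``margin``.

    n = z^2 p (1-p) / E^2 with z the two-sided normal quantile for ``conf``.
    Default integerisation is ``floor``; ``ceil`` (the usual conservative
    convention) is available.
    """
    if not (0 < p < 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not (0 < margin < 1):
        raise ValueError("margin of error must lie in (0, 1)")
    if rounding not in ("floor", "ceil"):
        raise ValueError("rounding must be 'floor' or 'ceil'")
    z = norm.ppf(1 - (1 - conf) / 2)
    n_raw = z * z * p * (1 - p) / (margin * margin)
    return int(math.floor(n_raw) if rounding == "floor" else math.ceil(n_raw))
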