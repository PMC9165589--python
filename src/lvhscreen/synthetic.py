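"""Synthetic cohorts, re-read samples and 12-lead waveforms.

The evaluation pipeline needs three kinds of input that real studies draw
from an EHR: a cohort table (gold-standard LVH label plus the binary outcome
of each ECG criterion per subject), a re-read table for inter-rater
agreement, and 12-lead waveforms that do or do not exhibit the screening
signs. This module generates all three with controlled statistical structure
and mandatory seeds.

Cohort model
------------
Each subject carries a latent severity ``S = shift*gold + L`` with
``L ~ N(0,1)`` — higher on average in gold-positive subjects, mimicking left
ventricular mass. Criterion ``i`` is positive when its latent liability
``X_i = sqrt(rho)*S + sqrt(1-rho)*eps_i`` exceeds a per-criterion,
per-stratum threshold. Because ``X_i`` given the gold label is Gaussian with
known mean, the threshold that yields a prescribed sensitivity or specificity
is the analytic probit quantile — the calibration equation is solved exactly,
so the achieved marginal operating characteristics equal the requested ones.
The shared ``S`` makes criterion errors positively correlated (``rho`` is the
dependence knob), which materially affects paired discordant counts and
hence non-inferiority p-values.

Default operating characteristics are the package's reference description of
a low-sensitivity / high-specificity screening setting (sensitivities
0.05-0.18, specificities 0.89-0.98, prevalence 756/2184), with the Cornell
criterion sex-specific.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .waveform import EcgWaveform, PRECORDIAL_LEADS

__all__ = [
    "CriterionOperatingPoint",
    "CohortSpec",
    "WaveformSpec",
    "CalibrationError",
    "DEFAULT_OPERATING_POINTS",
    "simulate_cohort",
    "simulate_reread",
    "simulate_waveform",
    "expected_flip_kappa",
]


class CalibrationError(ValueError):
    """The requested (sensitivity, specificity, dependence) cannot be realised."""


@dataclass(frozen=True)
class CriterionOperatingPoint:
    """Marginal sensitivity/specificity for one criterion; optionally by sex."""

    sensitivity: float
    specificity: float
    by_sex: Optional[Dict[str, Tuple[float, float]]] = None  # sex -> (sens, spec)

    def params_for(self, sex: str) -> Tuple[float, float]:
        if self.by_sex and sex in self.by_sex:
            return self.by_sex[sex]
        return self.sensitivity, self.specificity


#: Reference operating points of the four criteria (Cornell sex-specific;
#: its overall sensitivity/specificity arise as the sex mixture).
DEFAULT_OPERATING_POINTS: Dict[str, CriterionOperatingPoint] = {
    "seamens": CriterionOperatingPoint(0.11, 0.92),
    "sl1": CriterionOperatingPoint(0.05, 0.98),
    "sl2": CriterionOperatingPoint(0.08, 0.94),
    "cornell": CriterionOperatingPoint(
        0.13, 0.92, by_sex={"M": (0.09, 0.94), "F": (0.18, 0.89)}
    ),
}

DEFAULT_PREVALENCE = 756 / 2184


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic screening cohort.

    ``dependence`` is the shared-latent loading rho in [0, 1): the
    within-stratum tetrachoric-style correlation between criterion
    liabilities. ``seed`` is mandatory; identical specs give byte-identical
    cohorts.
    """

    n: int = 2184
    prevalence: float = DEFAULT_PREVALENCE
    criteria: Mapping[str, CriterionOperatingPoint] = field(
        default_factory=lambda: dict(DEFAULT_OPERATING_POINTS)
    )
    dependence: float = 0.5
    sex_ratio: float = 1135 / 2184  # P(male)
    severity_shift: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 <= self.prevalence <= 1):
            raise ValueError("prevalence must lie in [0, 1]")
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not (0 <= self.dependence < 1):
            raise CalibrationError(
                "dependence (shared-latent loading) must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for name, op in self.criteria.items():
            points = [(op.sensitivity, op.specificity)]
            if op.by_sex:
                points.extend(op.by_sex.values())
            for se, sp in points:
                if not (0 <= se <= 1 and 0 <= sp <= 1):
                    raise CalibrationError(
                        f"criterion {name!r}: sensitivity/specificity must lie "
                        f"in [0, 1], got ({se}, {sp})")


def _threshold(p_positive: float, mean: float) -> float:
    """Liability threshold giving P(X > t) = p_positive for X ~ N(mean, 1)."""
    if p_positive <= 0:
        return np.inf
    if p_positive >= 1:
        return -np.inf
    return mean + norm.ppf(1.0 - p_positive)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: subject_id, sex, age, ecg_to_tte_days, gold and
    one binary column per criterion.

    Age (median ~63, IQR ~51-73) and the ECG-to-TTE interval (median ~1 day,
    upper quartile ~3 weeks) are generated for descriptive-table realism only;
    no statistic consumes them.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    gold = (rng.random(n) < spec.prevalence).astype(int)
    sex = np.where(rng.random(n) < spec.sex_ratio, "M", "F")
    age = np.clip(np.round(rng.normal(63.0, 16.3, n)), 18, 105).astype(int)
    ecg_to_tte = np.minimum(
        np.round(np.exp(rng.normal(np.log(2.0), 3.55 / 2, n))).astype(int) - 1, 90)
    ecg_to_tte = np.maximum(ecg_to_tte, 0)

    rho = spec.dependence
    latent = spec.severity_shift * gold + rng.standard_normal(n)
    shared = np.sqrt(rho) * latent
    # conditional mean of sqrt(rho)*S given gold enters the threshold so the
    # requested per-stratum positivity probabilities hold exactly
    cond_mean = np.sqrt(rho) * spec.severity_shift * gold

    df = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "sex": sex,
        "age": age,
        "ecg_to_tte_days": ecg_to_tte,
        "gold": gold,
    })
    mean_pos = np.sqrt(rho) * spec.severity_shift  # cond_mean within gold==1
    for name, op in spec.criteria.items():
        liability = shared + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        thresholds = np.empty(n)
        for s in ("M", "F"):
            se, sp = op.params_for(s)
            sel = sex == s
            # within each (sex, gold) stratum the threshold is a single
            # probit quantile, so only two values are needed per sex
            thresholds[sel] = np.where(
                gold[sel] == 1,
                _threshold(se, mean_pos),
                _threshold(1.0 - sp, 0.0),
            )
        df[name] = (liability > thresholds).astype(int)
    return df


def simulate_reread(
    cohort: pd.DataFrame,
    criterion: str,
    flip_prob: float,
    seed: int,
    n_reread: int = 250,
) -> pd.DataFrame:
    """Emulate an independent second read of a random subsample.

    The second read equals the first with each call independently flipped
    with probability ``flip_prob``; a small flip probability yields the high
    agreement expected of an easy-to-apply sign. Returns the re-read schema
    ``subject_id, criterion, read1, read2``.
    """
    if not (0 <= flip_prob <= 1):
        raise ValueError("flip_prob must lie in [0, 1]")
    if criterion not in cohort.columns:
        raise KeyError(f"criterion column {criterion!r} not in cohort table")
    rng = np.random.default_rng(seed)
    k = min(n_reread, len(cohort))
    idx = rng.choice(len(cohort), size=k, replace=False)
    sub = cohort.iloc[np.sort(idx)]
    read1 = sub[criterion].to_numpy(dtype=int)
    flips = rng.random(k) < flip_prob
    read2 = np.where(flips, 1 - read1, read1)
    return pd.DataFrame({
        "subject_id": sub["subject_id"].to_numpy(),
        "criterion": criterion,
        "read1": read1,
        "read2": read2,
    })


def expected_flip_kappa(p_positive: float, flip_prob: float) -> float:
    """Population kappa of the flip model: read1 ~ Bern(q), read2 = read1
    xored with an independent Bern(f) flip. po = 1 - f; pe from the margins."""
    q, f = p_positive, flip_prob
    po = 1.0 - f
    p2 = q * (1 - f) + (1 - q) * f
    pe = q * p2 + (1 - q) * (1 - p2)
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

#: per-lead QRS template: (r_mv, s_mv, dominant) where ``dominant`` is the
#: lobe rendered mid-QRS ("R" or "S"); the minor lobe sits 45 ms away. The
#: values are typical adult resting amplitudes: deep S right-precordially
#: (V1-V2), tall R laterally (V4-V6).
DEFAULT_TEMPLATE: Dict[str, Tuple[float, float, str]] = {
    "I": (0.6, 0.10, "R"),
    "II": (1.0, 0.15, "R"),
    "III": (0.5, 0.20, "R"),
    "aVR": (0.10, 0.8, "S"),
    "aVL": (0.4, 0.10, "R"),
    "aVF": (0.7, 0.15, "R"),
    "V1": (0.3, 1.0, "S"),
    "V2": (0.6, 1.5, "S"),
    "V3": (0.9, 0.9, "R"),
    "V4": (1.5, 0.5, "R"),
    "V5": (1.4, 0.3, "R"),
    "V6": (1.2, 0.15, "R"),
}


@dataclass(frozen=True)
class WaveformSpec:
    """Specification of a stylised synthetic 12-lead record.

    Hypertrophy enters as a scalar ``severity >= 0`` that multiplies the
    precordial R/S amplitudes by ``1 + amplitude_gain * severity`` — the
    larger electrical vector of a hypertrophied ventricle translated into
    increased precordial voltage. Severity 0 with zero noise reproduces the
    template exactly (up to sampling quantisation).
    """

    heart_rate: float = 75.0
    template: Mapping[str, Tuple[float, float, str]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE)
    )
    severity: float = 0.0
    amplitude_gain: float = 0.6
    noise_sd: float = 0.01
    sampling_rate: float = 500.0
    n_beats: int = 6
    include_p_t: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ValueError("sampling rate below 100 Hz cannot resolve QRS "
                             "complexes")
        if self.severity < 0:
            raise ValueError("severity must be >= 0")
        if not (20 <= self.heart_rate <= 250):
            raise ValueError("heart_rate must be physiological (20-250 bpm)")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lead, (r, s, dom) in self.template.items():
            if not (np.isfinite(r) and np.isfinite(s) and r >= 0 and s >= 0):
                raise ValueError(f"template amplitudes for {lead} must be "
                                 f"finite and >= 0")
            if dom not in ("R", "S"):
                raise ValueError("dominant lobe must be 'R' or 'S'")

    @classmethod
    def zero_severity(cls, seed: int = 0, **kw) -> "WaveformSpec":
        """Documented all-negative record: template amplitudes, no scaling."""
        return cls(severity=0.0, noise_sd=0.0, seed=seed, **kw)

    @classmethod
    def high_severity(cls, seed: int = 0, **kw) -> "WaveformSpec":
        """Documented record positive for Seamens' Sign (pointwise) and SL-1
        at the default geometry: precordial amplitudes scaled by 1.6."""
        return cls(severity=1.0, amplitude_gain=0.6, noise_sd=0.0, seed=seed, **kw)


_QRS_SIGMA_S = 0.010       # Gaussian lobe width
_LOBE_OFFSET_S = 0.045     # dominant (mid-QRS) to minor lobe separation
_P_AMP, _P_CENTER, _P_SIGMA = 0.08, -0.16, 0.018
_T_AMP, _T_CENTER, _T_SIGMA = 0.15, 0.28, 0.032


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_waveform(spec: WaveformSpec) -> EcgWaveform:
    """Render the spec as an :class:`EcgWaveform` with QRS annotations.

    Each beat is an asymmetric biphasic QRS (two Gaussian lobes, the
    dominant one mid-QRS at the annotated fiducial, the minor one 45 ms
    earlier for an early r / late elsewhere), plus optional low-amplitude P
    and T bumps and additive white noise. All leads share beat timing, so the
    S nadir of an S-dominant lead is simultaneous with the R peak of an
    R-dominant lead — the geometry in which touching complexes occur.
    """
    fs = spec.sampling_rate
    period = 60.0 / spec.heart_rate
    duration = (spec.n_beats + 0.5) * period
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    beat_centers = (np.arange(spec.n_beats) + 0.75) * period
    scale = 1.0 + spec.amplitude_gain * spec.severity
    rng = np.random.default_rng(spec.seed)

    leads: Dict[str, np.ndarray] = {}
    for lead, (r_mv, s_mv, dominant) in spec.template.items():
        amp_scale = scale if lead in PRECORDIAL_LEADS else 1.0
        r_amp = r_mv * amp_scale
        s_amp = s_mv * amp_scale
        sig = np.zeros(n)
        for c in beat_centers:
            if dominant == "S":
                # rS morphology: early small r, deep S at the fiducial
                sig += r_amp * _gauss(t, c - _LOBE_OFFSET_S, _QRS_SIGMA_S)
                sig -= s_amp * _gauss(t, c, _QRS_SIGMA_S)
            else:
                # qRs-like morphology: tall R at the fiducial, late small s
                sig += r_amp * _gauss(t, c, _QRS_SIGMA_S)
                sig -= s_amp * _gauss(t, c + _LOBE_OFFSET_S, _QRS_SIGMA_S)
            if spec.include_p_t:
                sig += _P_AMP * _gauss(t, c + _P_CENTER, _P_SIGMA)
                sig += _T_AMP * _gauss(t, c + _T_CENTER, _T_SIGMA)
        if spec.noise_sd > 0:
            sig += rng.normal(0.0, spec.noise_sd, n)
        leads[lead] = sig

    annotations = [int(round(c * fs)) for c in beat_centers]
    return EcgWaveform(lead_signals=leads, sampling_rate=fs,
                       annotations=annotations)
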