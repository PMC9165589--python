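"""ECG voltage criteria for left ventricular hypertrophy.

Four criteria, all stated in rendered millimetres at the configured gain:

* Sokolow-Lyon 1 (SL-1): S in V1 plus the larger R of V5/V6, positive at
  >= 35 mm (inclusive).
* Sokolow-Lyon 2 (SL-2): R in aVL, positive at >= 11 mm (inclusive).
* Cornell: S in V3 plus R in aVL, positive at > 28 mm in males and > 20 mm
  in females (strict).
* Seamens' Sign: QRS complexes of two contiguous rendered precordial leads
  touching or overlapping — pairs (V1,V2), (V2,V3), (V4,V5), (V5,V6) in the
  standard 3x4 layout. Equality (exact touch) counts as positive.

Seamens' Sign comes in two flavours. :func:`seamens_sign_pointwise` is the
definition: render each column with baselines ``baseline_separation`` mm
apart and ask whether, at some shared instant inside a QRS complex, the upper
lead's downward excursion plus the lower lead's upward excursion reaches the
separation. :func:`seamens_sign_amplitude` is a fast surrogate using summary
amplitudes; because the S nadir and R peak may occur at different instants it
can only over-call relative to the pointwise test (pointwise positive implies
amplitude positive, never the reverse).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .waveform import (
    EcgWaveform,
    LayoutGeometry,
    LeadAmplitudes,
    MissingLeadError,
    QrsWindow,
    detect_qrs,
    estimate_baseline,
    normalize_lead_name,
)

__all__ = [
    "CriteriaThresholds",
    "CriterionResult",
    "sokolow_lyon_1",
    "sokolow_lyon_2",
    "cornell",
    "seamens_sign_amplitude",
    "seamens_sign_pointwise",
    "evaluate_voltage_criteria",
    "read_amplitude_table",
    "amplitudes_from_row",
    "apply_criteria_table",
    "write_criteria_csv",
]


@dataclass(frozen=True)
class CriteriaThresholds:
    """Millimetre thresholds of the voltage criteria (at the rendering gain)."""

    sl1_mm: float = 35.0
    sl2_mm: float = 11.0
    cornell_male_mm: float = 28.0
    cornell_female_mm: float = 20.0

    def __post_init__(self) -> None:
        for name in ("sl1_mm", "sl2_mm", "cornell_male_mm", "cornell_female_mm"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "sl1_mm": self.sl1_mm,
            "sl2_mm": self.sl2_mm,
            "cornell_male_mm": self.cornell_male_mm,
            "cornell_female_mm": self.cornell_female_mm,
        }


DEFAULT_THRESHOLDS = CriteriaThresholds()


@dataclass(frozen=True)
class CriterionResult:
    """Binary criterion outcome plus the measured evidence that produced it."""

    criterion: str
    positive: bool
    evidence: Dict[str, object] = field(default_factory=dict)

    def evidence_json(self) -> str:
        return json.dumps(self.evidence, sort_keys=True, default=float)


def sokolow_lyon_1(
    amp: LeadAmplitudes, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> CriterionResult:
    """SL-1: S(V1) + max(R(V5), R(V6)) >= 35 mm, boundary inclusive."""
    s_v1 = amp.s("V1", "Sokolow-Lyon 1")
    candidates = {}
    for lead in ("V5", "V6"):
        if lead in amp.r_mm:
            candidates[lead] = amp.r_mm[lead]
    if not candidates:
        raise MissingLeadError("V5", "Sokolow-Lyon 1 needs R in V5 or V6")
    used = max(candidates, key=lambda l: (candidates[l], l == "V5"))
    total = s_v1 + candidates[used]
    return CriterionResult(
        criterion="sl1",
        positive=bool(total >= thresholds.sl1_mm),
        evidence={"sum_mm": total, "s_v1_mm": s_v1, "r_lead_used": used,
                  "r_mm": candidates[used], "threshold_mm": thresholds.sl1_mm},
    )


def sokolow_lyon_2(
    amp: LeadAmplitudes, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> CriterionResult:
    """SL-2: R(aVL) >= 11 mm, boundary inclusive."""
    r_avl = amp.r("aVL", "Sokolow-Lyon 2")
    return CriterionResult(
        criterion="sl2",
        positive=bool(r_avl >= thresholds.sl2_mm),
        evidence={"r_avl_mm": r_avl, "threshold_mm": thresholds.sl2_mm},
    )


def cornell(
    amp: LeadAmplitudes,
    sex: Optional[str] = None,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> CriterionResult:
    """Cornell: S(V3) + R(aVL) > 28 mm (male) / > 20 mm (female), strict."""
    sex = (sex or amp.sex or "").strip().upper()[:1]
    if sex not in ("M", "F"):
        raise ValueError("Cornell criterion is sex-specific: sex must be 'M' or 'F'")
    s_v3 = amp.s("V3", "Cornell")
    r_avl = amp.r("aVL", "Cornell")
    threshold = thresholds.cornell_male_mm if sex == "M" else thresholds.cornell_female_mm
    total = s_v3 + r_avl
    return CriterionResult(
        criterion="cornell",
        positive=bool(total > threshold),
        evidence={"sum_mm": total, "s_v3_mm": s_v3, "r_avl_mm": r_avl,
                  "sex": sex, "threshold_mm": threshold},
    )


def seamens_sign_amplitude(
    amp: LeadAmplitudes, geometry: Optional[LayoutGeometry] = None
) -> CriterionResult:
    """Amplitude surrogate for Seamens' Sign.

    Positive iff for any rendered pair (upper, lower) among the contiguous
    precordial pairs, ``s_upper + r_lower >= baseline_separation``. Equality
    is a touch and counts as positive. Over-calls relative to the pointwise
    test when the S nadir and R peak are not simultaneous.
    """
    geom = geometry or LayoutGeometry()
    best: Optional[Tuple[str, str, float]] = None
    for upper, lower in geom.precordial_pairs():
        if not (upper in amp.s_mm and lower in amp.r_mm):
            continue
        total = amp.s_mm[upper] + amp.r_mm[lower]
        if best is None or total > best[2]:
            best = (upper, lower, total)
    if best is None:
        raise MissingLeadError("V1", "Seamens' Sign needs at least one contiguous "
                                     "precordial pair (S of upper, R of lower)")
    upper, lower, total = best
    sep = geom.baseline_separation
    return CriterionResult(
        criterion="seamens_amplitude",
        positive=bool(total >= sep),
        evidence={"pair": f"{upper}/{lower}", "sum_mm": total,
                  "clearance_mm": sep - total, "baseline_separation_mm": sep},
    )


def seamens_sign_pointwise(
    waveform: EcgWaveform,
    windows: Optional[Sequence[QrsWindow]] = None,
    geometry: Optional[LayoutGeometry] = None,
    decision: str = "any",
) -> CriterionResult:
    """Seamens' Sign on the rendered traces, sample by sample.

    For each contiguous precordial pair the upper trace occupies
    ``[-s(t), r(t)]`` mm around its baseline and the lower trace likewise one
    ``baseline_separation`` below; the complexes touch or overlap at instant
    ``t`` iff the upper's excursion below its baseline plus the lower's
    excursion above its own reaches the separation. Only instants inside a
    QRS window are considered. ``decision='any'`` calls the record positive
    if any beat of any pair fires (a human calls the sign if any complexes
    touch); ``'majority'`` requires more than half of the beats of some pair.
    """
    if decision not in ("any", "majority"):
        raise ValueError("decision must be 'any' or 'majority'")
    if windows is None:
        windows = detect_qrs(waveform)
    geom = geometry or LayoutGeometry()
    sep = geom.baseline_separation
    pairs = [
        (u, l) for (u, l) in geom.precordial_pairs()
        if u in waveform.lead_signals and l in waveform.lead_signals
    ]
    if not pairs:
        raise MissingLeadError("V1", "Seamens' Sign needs at least one contiguous "
                                     "precordial pair of leads")
    best: Optional[Tuple[str, str, float]] = None
    fired_beats: Dict[str, List[int]] = {}
    n_beats = len(windows)
    for upper, lower in pairs:
        xu = waveform.lead_signals[upper]
        xl = waveform.lead_signals[lower]
        bu = estimate_baseline(xu, windows)
        bl = estimate_baseline(xl, windows)
        below_u = np.clip(bu - xu, 0.0, None) * geom.gain
        above_l = np.clip(xl - bl, 0.0, None) * geom.gain
        total = below_u + above_l
        pair_max = -np.inf
        for w in windows:
            seg_max = float(total[w.slice()].max()) if w.offset > w.onset else -np.inf
            pair_max = max(pair_max, seg_max)
            if seg_max >= sep:
                fired_beats.setdefault(f"{upper}/{lower}", []).append(w.beat_index)
        if n_beats and (best is None or pair_max > best[2]):
            best = (upper, lower, pair_max)
    if best is None:  # no QRS windows: flat record, nothing can touch
        return CriterionResult(
            criterion="seamens",
            positive=False,
            evidence={"pair": None, "max_sum_mm": 0.0,
                      "baseline_separation_mm": sep, "decision": decision,
                      "n_beats": 0},
        )
    if decision == "any":
        positive = any(fired_beats.values())
    else:
        positive = any(len(set(b)) * 2 > n_beats for b in fired_beats.values())
    upper, lower, max_sum = best
    return CriterionResult(
        criterion="seamens",
        positive=bool(positive),
        evidence={"pair": f"{upper}/{lower}", "max_sum_mm": max_sum,
                  "clearance_mm": sep - max_sum, "baseline_separation_mm": sep,
                  "decision": decision, "n_beats": n_beats,
                  "fired_pairs": sorted(fired_beats)},
    )


def evaluate_voltage_criteria(
    amp: LeadAmplitudes,
    sex: Optional[str] = None,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    geometry: Optional[LayoutGeometry] = None,
) -> Dict[str, CriterionResult]:
    """Apply SL-1, SL-2, Cornell and the Seamens' amplitude surrogate."""
    return {
        "sl1": sokolow_lyon_1(amp, thresholds),
        "sl2": sokolow_lyon_2(amp, thresholds),
        "cornell": cornell(amp, sex=sex, thresholds=thresholds),
        "seamens": seamens_sign_amplitude(amp, geometry),
    }


# ---------------------------------------------------------------------------
# Amplitude-table I/O
# ---------------------------------------------------------------------------

_AMP_COL = re.compile(r"^([rs])_([a-z0-9]+)_mm$")


def amplitudes_from_row(row: pd.Series) -> LeadAmplitudes:
    """Build :class:`LeadAmplitudes` from one amplitude-table row.

    Recognised columns match ``r_<lead>_mm`` / ``s_<lead>_mm`` (lead names
    case-insensitive, e.g. ``s_v1_mm``, ``r_avl_mm``); other columns are
    ignored. An optional ``sex`` column is carried along for Cornell.
    """
    r_mm: Dict[str, float] = {}
    s_mm: Dict[str, float] = {}
    for col, value in row.items():
        m = _AMP_COL.match(str(col).strip().lower())
        if not m or pd.isna(value):
            continue
        kind, lead_raw = m.groups()
        try:
            lead = normalize_lead_name(lead_raw)
        except ValueError:
            continue
        (r_mm if kind == "r" else s_mm)[lead] = float(value)
    sex = row.get("sex")
    return LeadAmplitudes(r_mm=r_mm, s_mm=s_mm,
                          sex=None if pd.isna(sex) else str(sex))


def read_amplitude_table(path) -> pd.DataFrame:
    """Read a pre-measured per-lead amplitude CSV (one row per subject)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: amplitude table must contain 'subject_id'")
    return df


def apply_criteria_table(
    table: pd.DataFrame,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    geometry: Optional[LayoutGeometry] = None,
) -> pd.DataFrame:
    """Evaluate all four criteria for every row of an amplitude table.

    Returns the long-format criterion CSV schema:
    ``subject_id, criterion, positive, evidence`` (evidence as JSON).
    """
    records = []
    for _, row in table.iterrows():
        amp = amplitudes_from_row(row)
        results = evaluate_voltage_criteria(amp, thresholds=thresholds,
                                            geometry=geometry)
        for res in results.values():
            records.append({
                "subject_id": row["subject_id"],
                "criterion": res.criterion,
                "positive": int(res.positive),
                "evidence": res.evidence_json(),
            })
    return pd.DataFrame(records, columns=["subject_id", "criterion",
                                          "positive", "evidence"])


def write_criteria_csv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False)
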