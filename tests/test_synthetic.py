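"""Synthetic cohort, re-read and waveform generators: calibration and realism."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lvhscreen import (
    CohortSpec,
    ConfusionCounts,
    CriterionOperatingPoint,
    LayoutGeometry,
    WaveformSpec,
    agreement_table_from_reads,
    cohen_kappa,
    evaluate_voltage_criteria,
    expected_flip_kappa,
    measure_amplitudes,
    simulate_cohort,
    simulate_reread,
    simulate_waveform,
    wilson_ci,
)
from lvhscreen.criteria import seamens_sign_pointwise
from lvhscreen.synthetic import DEFAULT_OPERATING_POINTS, CalibrationError

CRITERIA = ("seamens", "sl1", "sl2", "cornell")


def _sens_spec(df: pd.DataFrame, criterion: str, sex: str | None = None):
    sub = df if sex is None else df[df["sex"] == sex]
    c = ConfusionCounts.from_labels(sub["gold"], sub[criterion])
    return c.tp / (c.tp + c.fn), c.tn / (c.tn + c.fp)


class TestCohortGenerator:
    def test_deterministic_under_seed(self):
        spec = CohortSpec(n=500, seed=314)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_cohort(CohortSpec(n=500, seed=315))
        assert not a.equals(c)

    def test_schema(self):
        df = simulate_cohort(CohortSpec(n=50, seed=1))
        for col in ("subject_id", "sex", "age", "ecg_to_tte_days",
                    "gold") + CRITERIA:
            assert col in df.columns
        assert set(df["gold"].unique()) <= {0, 1}
        assert set(df["sex"].unique()) <= {"M", "F"}
        assert (df["age"] >= 18).all()
        assert (df["ecg_to_tte_days"] >= 0).all()

    def test_perfect_criterion_equals_gold(self):
        spec = CohortSpec(
            n=5000, seed=8,
            criteria={"perfect": CriterionOperatingPoint(1.0, 1.0)},
        )
        df = simulate_cohort(spec)
        assert (df["perfect"] == df["gold"]).all()

    def test_prevalence_recovered(self):
        df = simulate_cohort(CohortSpec(n=200_000, seed=21))
        assert df["gold"].mean() == pytest.approx(756 / 2184, abs=0.005)
        assert (df["sex"] == "M").mean() == pytest.approx(1135 / 2184, abs=0.005)

    def test_single_cohort_within_sampling_error(self):
        # one n=2184 draw: the Seamens' Sign specificity estimate must sit
        # inside its own Wilson interval around the generating value
        df = simulate_cohort(CohortSpec(seed=77))
        _, spec_hat = _sens_spec(df, "seamens")
        neg = int((df["gold"] == 0).sum())
        lo, hi = wilson_ci(round(0.92 * neg), neg)
        assert lo <= spec_hat <= hi

    def test_exact_calibration_large_n(self):
        """n = 10^6: every marginal sensitivity/specificity (including the
        sex-specific Cornell pair) lands within 0.002 of its target."""
        df = simulate_cohort(CohortSpec(n=1_000_000, seed=99))
        for name, op in DEFAULT_OPERATING_POINTS.items():
            if op.by_sex:
                for sex, (se, sp) in op.by_sex.items():
                    se_hat, sp_hat = _sens_spec(df, name, sex)
                    assert se_hat == pytest.approx(se, abs=0.002), (name, sex)
                    assert sp_hat == pytest.approx(sp, abs=0.002), (name, sex)
            se_hat, sp_hat = _sens_spec(df, name)
            assert se_hat == pytest.approx(op.sensitivity, abs=0.004), name
            assert sp_hat == pytest.approx(op.specificity, abs=0.004), name

    def test_dependence_increases_criterion_correlation(self):
        lo = simulate_cohort(CohortSpec(n=100_000, seed=3, dependence=0.0))
        hi = simulate_cohort(CohortSpec(n=100_000, seed=3, dependence=0.9))

        def cond_corr(df):
            neg = df[df["gold"] == 0]
            return np.corrcoef(neg["seamens"], neg["sl2"])[0, 1]

        assert cond_corr(hi) > cond_corr(lo) + 0.1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n=0)
        with pytest.raises(CalibrationError):
            CohortSpec(dependence=1.0)
        with pytest.raises(CalibrationError):
            CohortSpec(criteria={"bad": CriterionOperatingPoint(1.2, 0.5)})

    def test_operating_point_recovery_across_replicates(self):
        """100 independent n=2184 cohorts: for each criterion the replicate's
        sensitivity and specificity, rounded to two decimals, falls in the
        reference interval in at least 90 of 100 replicates — except SL-1
        specificity, whose generating value (0.98) sits at the edge of its
        two-sided interval (0.97, 0.98); its expected per-replicate hit rate
        is ~91%, so the bound there is 85/100 (chosen by power analysis
        before running, not tuned afterwards)."""
        intervals = {
            ("seamens", "sens"): (0.09, 0.13), ("seamens", "spec"): (0.91, 0.94),
            ("sl1", "sens"): (0.03, 0.07), ("sl1", "spec"): (0.97, 0.98),
            ("sl2", "sens"): (0.06, 0.10), ("sl2", "spec"): (0.93, 0.95),
            ("cornell", "sens"): (0.11, 0.15), ("cornell", "spec"): (0.90, 0.93),
        }
        hits = {k: 0 for k in intervals}
        master = np.random.default_rng(1234)
        seeds = master.integers(0, 2**31 - 1, size=100)
        for seed in seeds:
            df = simulate_cohort(CohortSpec(seed=int(seed)))
            for crit in CRITERIA:
                se, sp = _sens_spec(df, crit)
                for kind, val in (("sens", se), ("spec", sp)):
                    lo, hi = intervals[(crit, kind)]
                    if lo <= round(val, 2) <= hi:
                        hits[(crit, kind)] += 1
        for key, count in hits.items():
            bound = 85 if key == ("sl1", "spec") else 90
            assert count >= bound, (key, count)


class TestReread:
    def test_zero_flip_perfect_agreement(self):
        df = simulate_cohort(CohortSpec(n=2000, seed=5))
        rr = simulate_reread(df, "seamens", flip_prob=0.0, seed=6)
        assert (rr["read1"] == rr["read2"]).all()
        res = cohen_kappa(agreement_table_from_reads(rr["read1"], rr["read2"]))
        assert res.kappa == pytest.approx(1.0)

    def test_half_flip_destroys_agreement(self):
        df = simulate_cohort(CohortSpec(n=20_000, seed=5))
        rr = simulate_reread(df, "seamens", flip_prob=0.5, seed=6,
                             n_reread=20_000)
        res = cohen_kappa(agreement_table_from_reads(rr["read1"], rr["read2"]))
        assert abs(res.kappa) < 0.05

    def test_kappa_matches_closed_form_expectation(self):
        q, f = 0.30, 0.02
        df = simulate_cohort(
            CohortSpec(n=100_000, seed=12, prevalence=q,
                       criteria={"c": CriterionOperatingPoint(1.0, 1.0)}))
        rr = simulate_reread(df, "c", flip_prob=f, seed=13, n_reread=100_000)
        res = cohen_kappa(agreement_table_from_reads(rr["read1"], rr["read2"]))
        assert res.kappa == pytest.approx(expected_flip_kappa(q, f), abs=0.02)

    def test_schema_and_subsample(self):
        df = simulate_cohort(CohortSpec(n=2184, seed=4))
        rr = simulate_reread(df, "seamens", flip_prob=0.02, seed=9)
        assert list(rr.columns) == ["subject_id", "criterion", "read1", "read2"]
        assert len(rr) == 250
        assert rr["subject_id"].is_unique
        assert (rr["criterion"] == "seamens").all()

    def test_invalid_inputs(self):
        df = simulate_cohort(CohortSpec(n=100, seed=4))
        with pytest.raises(ValueError):
            simulate_reread(df, "seamens", flip_prob=1.5, seed=1)
        with pytest.raises(KeyError):
            simulate_reread(df, "nonexistent", flip_prob=0.1, seed=1)


class TestWaveformGenerator:
    def test_deterministic_under_seed(self):
        a = simulate_waveform(WaveformSpec(seed=7))
        b = simulate_waveform(WaveformSpec(seed=7))
        np.testing.assert_array_equal(a.lead_signals["V2"],
                                      b.lead_signals["V2"])

    def test_severity_scales_precordial_not_limb(self):
        geom = LayoutGeometry()
        low = measure_amplitudes(
            simulate_waveform(WaveformSpec.zero_severity(seed=2)),
            geometry=geom).amplitudes
        high = measure_amplitudes(
            simulate_waveform(WaveformSpec.high_severity(seed=2)),
            geometry=geom).amplitudes
        for lead in ("V1", "V2", "V5"):
            assert high.s_mm[lead] > 1.4 * low.s_mm[lead] or low.s_mm[lead] < 1
            assert high.r_mm[lead] > 1.4 * low.r_mm[lead] or low.r_mm[lead] < 1
        for lead in ("I", "II", "aVL"):
            assert high.r_mm[lead] == pytest.approx(low.r_mm[lead], abs=0.2)

    def test_amplitude_monotone_in_severity(self):
        geom = LayoutGeometry()
        s_v1 = []
        for sev in (0.0, 0.5, 1.0, 2.0):
            wf = simulate_waveform(WaveformSpec(severity=sev, noise_sd=0.0,
                                                seed=1))
            amp = measure_amplitudes(wf, geometry=geom).amplitudes
            s_v1.append(amp.s_mm["V1"])
        assert all(b > a for a, b in zip(s_v1, s_v1[1:]))

    def test_zero_severity_negative_for_all_criteria(self):
        wf = simulate_waveform(WaveformSpec.zero_severity(seed=11))
        geom = LayoutGeometry()
        amp = measure_amplitudes(wf, geometry=geom).amplitudes
        results = evaluate_voltage_criteria(amp, sex="M", geometry=geom)
        assert not any(r.positive for r in results.values())
        assert not seamens_sign_pointwise(wf, geometry=geom).positive

    def test_high_severity_positive_for_target_criteria(self):
        wf = simulate_waveform(WaveformSpec.high_severity(seed=11))
        geom = LayoutGeometry()
        amp = measure_amplitudes(wf, geometry=geom).amplitudes
        results = evaluate_voltage_criteria(amp, sex="M", geometry=geom)
        assert results["sl1"].positive
        assert seamens_sign_pointwise(wf, geometry=geom).positive

    def test_invalid_specs_rejected(self):
        for kw in ({"sampling_rate": 50}, {"severity": -1},
                   {"heart_rate": 300}, {"n_beats": 0}, {"noise_sd": -0.1}):
            with pytest.raises(ValueError):
                WaveformSpec(**kw)


class TestExpectedFlipKappa:
    def test_zero_flip_is_one(self):
        assert expected_flip_kappa(0.3, 0.0) == pytest.approx(1.0)

    def test_half_flip_is_zero(self):
        assert expected_flip_kappa(0.3, 0.5) == pytest.approx(0.0)

    def test_degenerate_margin_is_nan(self):
        assert np.isnan(expected_flip_kappa(0.0, 0.0))
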