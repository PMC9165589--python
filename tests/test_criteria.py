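"""Criterion semantics: thresholds, boundary behaviour and the two Seamens' tests."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvhscreen import (
    EcgWaveform,
    LayoutGeometry,
    LeadAmplitudes,
    MissingLeadError,
    cornell,
    detect_qrs,
    measure_amplitudes,
    seamens_sign_amplitude,
    seamens_sign_pointwise,
    sokolow_lyon_1,
    sokolow_lyon_2,
)
from lvhscreen.criteria import amplitudes_from_row, apply_criteria_table
from lvhscreen.synthetic import WaveformSpec, simulate_waveform

FS = 500.0


def amps(r=None, s=None, sex=None):
    return LeadAmplitudes(r_mm=r or {}, s_mm=s or {}, sex=sex)


def _gauss(t, c, sigma):
    return np.exp(-0.5 * ((t - c) / sigma) ** 2)


class TestSokolowLyon1:
    @pytest.mark.parametrize("s_v1,r_v5,r_v6,positive,used", [
        (20.0, 15.0, 0.0, True, "V5"),    # boundary: sum exactly 35 is positive
        (20.0, 14.9, 10.0, False, "V5"),  # just below threshold
        (10.0, 5.0, 26.0, True, "V6"),    # larger R of V5/V6 is used
    ])
    def test_rule(self, s_v1, r_v5, r_v6, positive, used):
        a = amps(r={"V5": r_v5, "V6": r_v6}, s={"V1": s_v1})
        res = sokolow_lyon_1(a)
        assert res.positive is positive
        assert res.evidence["r_lead_used"] == used

    def test_works_with_single_lateral_lead(self):
        res = sokolow_lyon_1(amps(r={"V6": 20.0}, s={"V1": 15.0}))
        assert res.positive and res.evidence["r_lead_used"] == "V6"

    def test_missing_lead_named(self):
        with pytest.raises(MissingLeadError, match="V1"):
            sokolow_lyon_1(amps(r={"V5": 30.0}, s={}))
        with pytest.raises(MissingLeadError, match="V5"):
            sokolow_lyon_1(amps(r={}, s={"V1": 30.0}))


class TestSokolowLyon2:
    @pytest.mark.parametrize("r_avl,positive", [
        (11.0, True),   # boundary inclusive
        (10.9, False),
        (0.0, False),
    ])
    def test_rule(self, r_avl, positive):
        assert sokolow_lyon_2(amps(r={"aVL": r_avl})).positive is positive

    def test_missing_lead(self):
        with pytest.raises(MissingLeadError, match="aVL"):
            sokolow_lyon_2(amps())


class TestCornell:
    @pytest.mark.parametrize("sex,s_v3,r_avl,positive", [
        ("M", 20.0, 8.0, False),   # sum exactly 28: strict, negative
        ("M", 20.0, 8.1, True),
        ("F", 12.0, 8.1, True),    # 20.1 > 20
        ("F", 12.0, 8.0, False),   # sum exactly 20: strict, negative
    ])
    def test_rule(self, sex, s_v3, r_avl, positive):
        a = amps(r={"aVL": r_avl}, s={"V3": s_v3})
        assert cornell(a, sex=sex).positive is positive

    def test_sex_required(self):
        with pytest.raises(ValueError, match="sex"):
            cornell(amps(r={"aVL": 10.0}, s={"V3": 20.0}))

    def test_sex_taken_from_amplitudes(self):
        a = amps(r={"aVL": 10.0}, s={"V3": 11.0}, sex="F")
        assert cornell(a).positive  # 21 > 20 for a female subject

    def test_missing_lead(self):
        with pytest.raises(MissingLeadError, match="V3"):
            cornell(amps(r={"aVL": 10.0}), sex="M")


class TestSeamensAmplitude:
    def test_exact_touch_is_positive(self, geometry):
        a = amps(r={"V2": 1.0, "V3": 12.0, "V5": 1.0, "V6": 1.0},
                 s={"V1": 1.0, "V2": 18.0, "V4": 1.0, "V5": 1.0})
        res = seamens_sign_amplitude(a, geometry)
        assert res.positive
        assert res.evidence["pair"] == "V2/V3"
        assert res.evidence["clearance_mm"] == pytest.approx(0.0)

    def test_all_pairs_small_is_negative(self, geometry):
        a = amps(r={l: 12.0 for l in ("V2", "V3", "V5", "V6")},
                 s={l: 12.0 for l in ("V1", "V2", "V4", "V5")})
        assert not seamens_sign_amplitude(a, geometry).positive

    def test_v3_v4_not_a_rendered_pair(self, geometry):
        # huge S in V3 and R in V4, but V3/V4 sit in different columns
        a = amps(r={"V2": 1.0, "V3": 1.0, "V4": 40.0, "V5": 1.0, "V6": 1.0},
                 s={"V1": 1.0, "V2": 1.0, "V3": 40.0, "V4": 1.0, "V5": 1.0})
        assert not seamens_sign_amplitude(a, geometry).positive

    def test_no_evaluable_pair_raises(self, geometry):
        with pytest.raises(MissingLeadError):
            seamens_sign_amplitude(amps(r={"aVL": 5.0}, s={"V3": 5.0}), geometry)

    def test_separation_knob(self):
        a = amps(r={"V3": 12.0}, s={"V2": 12.0})
        assert seamens_sign_amplitude(a, LayoutGeometry(baseline_separation=24)).positive
        assert not seamens_sign_amplitude(a, LayoutGeometry(baseline_separation=25)).positive


class TestSeamensPointwise:
    def _waveform(self, s_depth_mm, r_height_mm, offset_s, gain=10.0):
        t = np.arange(int(1.2 * FS)) / FS
        v2 = -(s_depth_mm / gain) * _gauss(t, 0.5, 0.010)
        v3 = (r_height_mm / gain) * _gauss(t, 0.5 + offset_s, 0.010)
        wf = EcgWaveform({"V2": v2, "V3": v3}, FS,
                         annotations=[int(0.5 * FS + 0.5 * offset_s * FS)])
        windows = detect_qrs(wf, window_halfwidth_s=0.1)
        return wf, windows

    def test_aligned_case_reduces_to_amplitude_rule(self, geometry):
        wf, windows = self._waveform(18.0, 12.0, 0.0)
        assert seamens_sign_pointwise(wf, windows, geometry).positive

    def test_offset_peaks_pointwise_negative_amplitude_positive(self, geometry):
        """Narrow complexes 80 ms apart: max S-depth plus max R-height reaches
        the separation but never simultaneously, so the pointwise test stays
        negative while the amplitude surrogate over-calls."""
        wf, windows = self._waveform(18.0, 12.0, 0.080)
        pw = seamens_sign_pointwise(wf, windows, geometry)
        # brute-force the pointwise maximum over every sample
        v2, v3 = wf.lead_signals["V2"], wf.lead_signals["V3"]
        brute = float((np.clip(-v2, 0, None) + np.clip(v3, 0, None)).max() * 10)
        assert brute < 30.0
        assert not pw.positive
        assert pw.evidence["max_sum_mm"] == pytest.approx(brute, abs=1e-9)
        res = measure_amplitudes(wf, windows, geometry)
        assert seamens_sign_amplitude(res.amplitudes, geometry).positive

    def test_flat_waveform_negative(self, geometry):
        wf = EcgWaveform({"V2": np.zeros(600), "V3": np.zeros(600)}, FS)
        assert not seamens_sign_pointwise(wf, detect_qrs(wf), geometry).positive

    def test_majority_decision(self, geometry):
        # one touching beat out of three: 'any' fires, 'majority' does not
        t = np.arange(int(3.0 * FS)) / FS
        v2 = -(1.2 * _gauss(t, 0.5, 0.01) + 1.2 * _gauss(t, 1.5, 0.01)
               + 2.0 * _gauss(t, 2.5, 0.01))
        v3 = (1.2 * _gauss(t, 0.5, 0.01) + 1.2 * _gauss(t, 1.5, 0.01)
              + 2.0 * _gauss(t, 2.5, 0.01))
        ann = [int(0.5 * FS), int(1.5 * FS), int(2.5 * FS)]
        wf = EcgWaveform({"V2": v2, "V3": v3}, FS, annotations=ann)
        windows = detect_qrs(wf)
        assert seamens_sign_pointwise(wf, windows, geometry, decision="any").positive
        assert not seamens_sign_pointwise(wf, windows, geometry,
                                          decision="majority").positive


class TestInvariants:
    @given(severity=st.floats(0.0, 3.0), seed=st.integers(0, 10 ** 6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_pointwise_implies_amplitude(self, severity, seed):
        """The amplitude surrogate dominates the pointwise definition on any
        randomised synthetic waveform and geometry."""
        spec = WaveformSpec(severity=severity, noise_sd=0.02, n_beats=3,
                            seed=seed)
        wf = simulate_waveform(spec)
        windows = detect_qrs(wf)
        geom = LayoutGeometry(baseline_separation=10 + (seed % 30))
        pw = seamens_sign_pointwise(wf, windows, geom)
        res = measure_amplitudes(wf, windows, geom, summary="max")
        amp = seamens_sign_amplitude(res.amplitudes, geom)
        if pw.positive:
            assert amp.positive

    @given(k=st.floats(1.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scaling_up_never_turns_seamens_negative(self, k):
        geometry = LayoutGeometry()
        base = amps(r={"V2": 9.0, "V3": 16.0, "V5": 2.0, "V6": 2.0},
                    s={"V1": 4.0, "V2": 15.0, "V4": 2.0, "V5": 2.0})
        scaled = amps(r={l: k * v for l, v in base.r_mm.items()},
                      s={l: k * v for l, v in base.s_mm.items()})
        if seamens_sign_amplitude(base, geometry).positive:
            assert seamens_sign_amplitude(scaled, geometry).positive
        # lowering the separation likewise cannot flip positive to negative
        tight = LayoutGeometry(baseline_separation=geometry.baseline_separation / k)
        if seamens_sign_amplitude(base, geometry).positive:
            assert seamens_sign_amplitude(base, tight).positive

    @given(bump=st.floats(0.0, 30.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_raising_an_amplitude_never_flips_voltage_criteria_negative(self, bump):
        base = amps(r={"V5": 12.0, "V6": 10.0, "aVL": 9.0},
                    s={"V1": 20.0, "V3": 15.0}, sex="M")
        raised = amps(r={**base.r_mm, "aVL": base.r_mm["aVL"] + bump},
                      s=base.s_mm, sex="M")
        for crit in (sokolow_lyon_1, sokolow_lyon_2,
                     lambda a: cornell(a, sex="M")):
            if crit(base).positive:
                assert crit(raised).positive

    def test_criteria_are_pure(self):
        a = amps(r={"V5": 20.0, "V6": 10.0, "aVL": 12.0},
                 s={"V1": 16.0, "V3": 15.0})
        assert sokolow_lyon_1(a) == sokolow_lyon_1(a)
        assert sokolow_lyon_2(a) == sokolow_lyon_2(a)


class TestAmplitudeTable:
    def test_row_parsing_and_application(self):
        import pandas as pd
        table = pd.DataFrame([
            {"subject_id": "a", "sex": "M", "s_v1_mm": 20.0, "r_v5_mm": 15.0,
             "r_v6_mm": 1.0, "r_avl_mm": 2.0, "s_v3_mm": 2.0,
             "s_v2_mm": 1.0, "r_v3_mm": 1.0, "s_v4_mm": 1.0, "r_v2_mm": 1.0,
             "s_v5_mm": 1.0, "r_v4_mm": 1.0, "s_v6_mm": 1.0, "r_v1_mm": 1.0,
             "ignored": 99},
        ])
        amp = amplitudes_from_row(table.iloc[0])
        assert amp.s_mm["V1"] == 20.0 and amp.sex == "M"
        out = apply_criteria_table(table)
        by_crit = out.set_index("criterion")["positive"]
        assert by_crit["sl1"] == 1       # 20 + 15 = 35
        assert by_crit["sl2"] == 0
        assert by_crit["cornell"] == 0
        assert by_crit["seamens_amplitude"] == 0
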