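"""Synthetic-cohort generator: curve models, artefact injection, bookkeeping."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfml.cohort import (
    AcquisitionDesign,
    AifShapeParams,
    ArtefactParams,
    KineticTruth,
    SignalModelParams,
    concentration_to_signal,
    generate_aif_concentration,
    generate_cohort,
    generate_tissue_concentration,
    inject_dark_rim,
)
from perfml.curves import ConcentrationCurve, SignalIntensityCurve
from perfml.errors import GridError, ParameterError, WindowError


class TestGammaVariateAif:
    def test_peak_at_closed_form_location(self):
        # maximum of A*(t-t0)^a*exp(-(t-t0)/b) sits at t0 + a*b with value A*(ab)^a*e^-a
        p = AifShapeParams(amplitude=1, alpha=3, beta=2, t0=10, recirculation_fraction=0)
        t = np.arange(0, 60, 0.5)
        curve = generate_aif_concentration(p, t)
        assert t[np.argmax(curve.values)] == pytest.approx(16.0)
        assert curve.values.max() == pytest.approx(6**3 * np.exp(-3), rel=1e-6)

    def test_zero_before_onset_and_nonnegative(self, times60):
        p = AifShapeParams(t0=10.0)
        curve = generate_aif_concentration(p, times60)
        assert np.all(curve.values[times60 <= 10.0] == 0)
        assert np.all(curve.values >= 0)

    def test_area_scales_linearly_with_amplitude(self, times60):
        p1 = AifShapeParams(amplitude=0.3)
        p2 = dataclasses.replace(p1, amplitude=0.6)
        a1 = np.trapezoid(generate_aif_concentration(p1, times60).values, times60)
        a2 = np.trapezoid(generate_aif_concentration(p2, times60).values, times60)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(alpha=-1.0), dict(beta=0.0), dict(amplitude=0.0)])
    def test_invalid_shape_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            AifShapeParams(**bad)

    def test_times_must_start_at_zero(self):
        with pytest.raises(GridError):
            generate_aif_concentration(AifShapeParams(), np.arange(1.0, 30.0))


class TestTissueConcentration:
    def test_hand_convolution(self):
        # C_b=[1,2,1] against h=[3,1,0] at dt=1 gives [3,7,5]
        aif = ConcentrationCurve([0, 1, 2], [1, 2, 1], role="arterial")

        class FixedTruth(KineticTruth):
            def residue_function(self, times):
                return np.array([3.0, 1.0, 0.0])

        ct = generate_tissue_concentration(aif, FixedTruth(mbf_true=1.0))
        assert np.allclose(ct.values, [3.0, 7.0, 5.0])

    def test_unit_impulse_aif_returns_residue_function(self, times60):
        vals = np.zeros_like(times60)
        vals[0] = 1.0  # 1/dt with dt=1
        aif = ConcentrationCurve(times60, vals, role="arterial")
        truth = KineticTruth(mbf_true=2.0)
        ct = generate_tissue_concentration(aif, truth)
        assert np.allclose(ct.values, truth.residue_function(times60))

    def test_zero_flow_rejected(self):
        with pytest.raises(ParameterError):
            KineticTruth(mbf_true=0.0)

    def test_residue_function_initial_value_is_flow(self, times60):
        truth = KineticTruth(mbf_true=3.0)
        h = truth.residue_function(times60)
        assert h[0] == pytest.approx(3.0 / 60.0)
        assert np.all(np.diff(h) <= 0)


class TestSignalModel:
    def test_closed_form_at_zero_concentration(self, times60):
        sig = SignalModelParams(S0=1000, TS=0.15, R10=1, r1=4, noise_sd=0)
        curve = ConcentrationCurve(times60, np.zeros_like(times60))
        si = concentration_to_signal(curve, sig, 0)
        assert np.allclose(si.values, 1000 * (1 - np.exp(-0.15)))
        assert si.values[0] == pytest.approx(139.29, abs=0.01)

    def test_saturation_ceiling(self, times60):
        sig = SignalModelParams(noise_sd=0)
        huge = ConcentrationCurve(times60, np.full_like(times60, 1e6))
        si = concentration_to_signal(huge, sig, 0)
        assert np.allclose(si.values, sig.S0, rtol=1e-6)

    def test_strictly_increasing_in_concentration(self):
        sig = SignalModelParams(noise_sd=0)
        grid = np.linspace(0, 10, 200)
        si = sig.signal(grid)
        assert np.all(np.diff(si) > 0)
        # concave: increments shrink
        assert np.all(np.diff(si, 2) < 0)

    def test_noise_is_seed_deterministic(self, times60):
        sig = SignalModelParams(noise_sd=3.0)
        curve = ConcentrationCurve(times60, np.ones_like(times60))
        a = concentration_to_signal(curve, sig, 42)
        b = concentration_to_signal(curve, sig, 42)
        c = concentration_to_signal(curve, sig, 43)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-6, max_value=0.05))
    def test_linear_regime_proportionality(self, c):
        # baseline-subtracted SI tracks C within 2% where TS*r1*C << 1
        sig = SignalModelParams(noise_sd=0)
        enh = sig.signal(c) - sig.baseline_signal
        assert enh == pytest.approx(sig.linear_gain * c, rel=0.02)


class TestDarkRimInjection:
    def _flat_curve(self, n=60, level=100.0, enhance_at=20):
        vals = np.full(n, level)
        vals[enhance_at:] = np.linspace(level + 5, level + 300, n - enhance_at)
        return SignalIntensityCurve(np.arange(float(n)), vals)

    def test_dip_crosses_baseline_and_recovers(self):
        curve = self._flat_curve()
        art = ArtefactParams(dip_amplitude=60, dip_duration=4)
        out = inject_dark_rim(curve, 20, art)
        base = curve.values[:20].mean()
        assert out.values[20:24].min() < base
        assert out.values[24:].max() > base
        assert np.array_equal(out.values[:20], curve.values[:20])

    def test_insufficient_dip_rejected(self):
        curve = self._flat_curve()
        art = ArtefactParams(dip_amplitude=1.0, dip_duration=2)
        with pytest.raises(WindowError):
            inject_dark_rim(curve, 25, art)  # enhancement already ~50 a.u. there

    def test_dip_covering_rest_of_series_rejected(self):
        curve = self._flat_curve(n=30, enhance_at=20)
        art = ArtefactParams(dip_amplitude=60, dip_duration=10)
        with pytest.raises(WindowError):
            inject_dark_rim(curve, 20, art)


class TestCohortBookkeeping:
    def test_default_design_record_count(self, default_cohort):
        # 5 subjects x 24 ROIs x 2 states minus one excluded 24-ROI session
        assert len(default_cohort.records) == 216

    def test_single_subject_rest_only(self):
        design = AcquisitionDesign(n_subjects=1, states=("rest",), excluded_sessions=())
        cohort = generate_cohort(design, seed=0)
        assert len(cohort.records) == 24

    @pytest.mark.parametrize(
        "n_subjects,states,excluded,expected",
        [
            (5, ("rest", "stress"), ((3, "stress"),), 216),
            (5, ("rest", "stress"), (), 240),
            (3, ("rest",), (), 72),
            (4, ("rest", "stress"), ((1, "rest"), (2, "stress")), 144),
        ],
    )
    def test_record_count_arithmetic(self, n_subjects, states, excluded, expected):
        design = AcquisitionDesign(
            n_subjects=n_subjects, states=states, excluded_sessions=excluded
        )
        assert design.n_records == expected
        assert len(generate_cohort(design, seed=1).records) == expected

    def test_artefact_count_matches_prevalence(self, default_cohort):
        flags = sum(r.artefact_flag for r in default_cohort.records)
        assert flags == round(default_cohort.design.artefact_prevalence * 216) == 103

    def test_seeded_reproducibility(self, small_design):
        a = generate_cohort(small_design, seed=5)
        b = generate_cohort(small_design, seed=5)
        c = generate_cohort(small_design, seed=6)
        assert a.records_frame().equals(b.records_frame())
        assert a.aif_frame().equals(b.aif_frame())
        assert not a.records_frame().equals(c.records_frame())

    def test_artefact_flag_matches_baseline_crossing_noise_free(self, noise_free_sig):
        design = AcquisitionDesign(
            n_subjects=2, states=("rest",), excluded_sessions=(), artefact_prevalence=0.5
        )
        cohort = generate_cohort(design, seed=3, signal_params=noise_free_sig)
        for rec in cohort.records:
            arrival = cohort.aifs[(rec.subject_id, rec.state)].arrival_frame
            base = rec.si.values[:arrival].mean()
            crosses = bool(np.any(rec.si.values[arrival:] < base))
            assert crosses == rec.artefact_flag

    def test_roundtrip_serialization(self, small_design, tmp_path):
        cohort = generate_cohort(small_design, seed=7)
        cohort.save(tmp_path)
        loaded = type(cohort).load(tmp_path)
        assert loaded.design == cohort.design
        assert len(loaded.records) == len(cohort.records)
        assert np.allclose(
            loaded.records[0].si.values, cohort.records[0].si.values
        )
        assert loaded.records[5].key == cohort.records[5].key

    def test_invalid_designs_rejected(self):
        with pytest.raises(ParameterError):
            AcquisitionDesign(apical_segments=10)  # 10 + 16 != 24
        with pytest.raises(ParameterError):
            AcquisitionDesign(n_frames=5)
        with pytest.raises(ParameterError):
            AcquisitionDesign(dilution_factor=1.0)
        with pytest.raises(ParameterError):
            AcquisitionDesign(artefact_prevalence=1.5)
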