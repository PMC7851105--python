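"""Signal/concentration conversion, arrival detection, dual-bolus correction."""
import dataclasses

import numpy as np
import pytest

from perfml.aif import (
    bolus_arrival,
    correct_aif_dual_bolus,
    detect_arrival,
    signal_to_concentration,
)
from perfml.cohort import (
    AifShapeParams,
    SignalModelParams,
    concentration_to_signal,
    generate_aif_concentration,
)
from perfml.curves import BaselineWindow, ConcentrationCurve, SignalIntensityCurve
from perfml.errors import ArrivalNotFoundError, CorrectionError, SaturationError

BASE = BaselineWindow(0, 4)


def _si(values):
    values = np.asarray(values, dtype=float)
    return SignalIntensityCurve(np.arange(float(len(values))), values)


class TestSignalToConcentration:
    def test_exact_inverse_roundtrips_forward_map(self, times60, plain_aif_params):
        sig = SignalModelParams(noise_sd=0)
        conc = generate_aif_concentration(plain_aif_params, times60)
        si = concentration_to_signal(conc, sig, 0)
        back = signal_to_concentration(si, sig, BASE, mode="exact_inverse")
        assert np.allclose(back.values, conc.values, rtol=1e-6, atol=1e-9)

    def test_constant_baseline_maps_to_zero(self):
        sig = SignalModelParams(noise_sd=0)
        si = _si(np.full(30, sig.baseline_signal))
        for mode in ("exact_inverse", "linear"):
            conc = signal_to_concentration(si, sig, BASE, mode=mode)
            assert np.allclose(conc.values, 0.0, atol=1e-9)

    def test_linear_mode_underestimates_saturated_peak(self, times60, plain_aif_params):
        # concavity of the saturation-recovery map blunts the measured peak
        sig = SignalModelParams(noise_sd=0)
        conc = generate_aif_concentration(plain_aif_params, times60)
        si = concentration_to_signal(conc, sig, 0)
        lin = signal_to_concentration(si, sig, BASE, mode="linear")
        assert lin.values.max() < 0.85 * conc.values.max()

    def test_signal_at_ceiling_raises(self):
        sig = SignalModelParams(noise_sd=0)
        si = _si(np.concatenate([np.full(10, sig.baseline_signal), [sig.S0 + 1.0] * 5]))
        with pytest.raises(SaturationError):
            signal_to_concentration(si, sig, BASE, mode="exact_inverse")

    def test_negative_concentrations_clipped(self, caplog):
        sig = SignalModelParams(noise_sd=0)
        vals = np.full(30, sig.baseline_signal)
        vals[10] -= 50.0  # dips below baseline
        with caplog.at_level("WARNING", logger="perfml.aif"):
            conc = signal_to_concentration(_si(vals), sig, BASE)
        assert np.all(conc.values >= 0)
        assert any("clipping" in rec.message for rec in caplog.records)


class TestDetectArrival:
    def test_noise_free_step(self):
        vals = np.concatenate([np.full(20, 100.0), np.full(20, 200.0)])
        assert detect_arrival(_si(vals), BASE) == 20

    def test_flat_curve_raises(self):
        with pytest.raises(ArrivalNotFoundError):
            detect_arrival(_si(np.full(30, 100.0)), BASE)

    def test_gamma_variate_matches_exhaustive_scan(self, times60):
        params = AifShapeParams(t0=15.0, recirculation_fraction=0.0)
        conc = generate_aif_concentration(params, times60)
        vals = conc.values + 100.0
        si = _si(vals)
        k_sd = 3.0
        mean, sd = BASE.stats(vals)
        thr = mean + k_sd * sd
        brute = next(
            i
            for i in range(BASE.last_frame + 1, len(vals) - 1)
            if vals[i] > thr and vals[i + 1] > thr
        )
        assert detect_arrival(si, BASE, k_sd) == brute
        assert detect_arrival(si, BASE, k_sd) >= 15

    def test_single_frame_spike_ignored(self):
        vals = np.full(40, 100.0)
        vals[10] = 500.0  # isolated spike, no sustained rise
        vals[25:] = 300.0
        assert detect_arrival(_si(vals), BASE) == 25


class TestDualBolusCorrection:
    def _session(self, offset_frames=0, noise=0.0, sig=None, times=None):
        sig = sig or SignalModelParams(noise_sd=noise, aif_noise_sd=noise)
        times = np.arange(60.0) if times is None else times
        full_p = AifShapeParams(t0=10.0)
        pre_p = dataclasses.replace(full_p, t0=10.0 + offset_frames)
        full = generate_aif_concentration(full_p, times)
        pre = generate_aif_concentration(pre_p, times)
        pre_d = pre.with_values(pre.values / 21.0)
        sig_bp = sig.blood_pool()
        return (
            concentration_to_signal(pre_d, sig_bp, 1),
            concentration_to_signal(full, sig_bp, 2),
            full,
            sig,
        )

    def test_corrected_peak_recovers_truth_naive_does_not(self):
        pre_si, full_si, truth, sig = self._session()
        corrected = correct_aif_dual_bolus(pre_si, full_si, sig, BASE, 21.0)
        naive = signal_to_concentration(full_si, sig, BASE, mode="linear")
        true_peak = truth.values.max()
        assert abs(corrected.values.max() - true_peak) / true_peak < 0.05
        assert (true_peak - naive.values.max()) / true_peak > 0.15

    def test_dilution_factor_one_identity(self):
        pre_si, _, _, sig = self._session()
        corrected = correct_aif_dual_bolus(pre_si, pre_si, sig, BASE, 1.0)
        lin = signal_to_concentration(pre_si, sig, BASE, mode="linear")
        arrival = bolus_arrival(lin, BASE)
        assert np.allclose(
            corrected.values[arrival:], lin.values[arrival:], rtol=1e-9
        )

    @pytest.mark.parametrize("offset", [-3, -1, 0, 2])
    def test_alignment_moves_prebolus_arrival_to_fulldose_arrival(self, offset):
        pre_si, full_si, _, sig = self._session(offset_frames=offset)
        corrected = correct_aif_dual_bolus(pre_si, full_si, sig, BASE, 21.0)
        full_conc = signal_to_concentration(full_si, sig, BASE, mode="exact_inverse")
        assert bolus_arrival(corrected, BASE) == bolus_arrival(full_conc, BASE)

    def test_framewise_scaling_linearity(self):
        # corrected AIF == dilution_factor * aligned pre-bolus concentration
        pre_si, full_si, _, sig = self._session(offset_frames=0)
        c21 = correct_aif_dual_bolus(pre_si, full_si, sig, BASE, 21.0)
        c42 = correct_aif_dual_bolus(pre_si, full_si, sig, BASE, 42.0)
        assert np.allclose(c42.values, 2.0 * c21.values, rtol=1e-12)
        lin = signal_to_concentration(pre_si, sig, BASE, mode="linear")
        # offset 0 means no shift: frame-wise 21x wherever not floored to zero
        nz = c21.values > 0
        assert np.allclose(c21.values[nz], 21.0 * lin.values[nz], rtol=1e-12)

    def test_peak_recovery_over_seeded_shapes(self):
        # median corrected-peak error < 5%, naive underestimation > 15%
        rng = np.random.default_rng(0)
        corr_errs, naive_errs = [], []
        times = np.arange(60.0)
        for _ in range(20):
            sig = SignalModelParams()
            full_p = AifShapeParams(
                amplitude=0.28 * rng.uniform(0.9, 1.1),
                alpha=3.0 * rng.uniform(0.9, 1.1),
                beta=2.0 * rng.uniform(0.9, 1.1),
                t0=rng.uniform(8, 12),
            )
            pre_p = dataclasses.replace(
                full_p, t0=full_p.t0 + rng.integers(-2, 3) * 1.0
            )
            full = generate_aif_concentration(full_p, times)
            pre = generate_aif_concentration(pre_p, times)
            sig_bp = sig.blood_pool()
            pre_si = concentration_to_signal(
                pre.with_values(pre.values / 21), sig_bp, int(rng.integers(1 << 30))
            )
            full_si = concentration_to_signal(full, sig_bp, int(rng.integers(1 << 30)))
            corrected = correct_aif_dual_bolus(pre_si, full_si, sig, BASE, 21.0)
            naive = signal_to_concentration(full_si, sig, BASE, mode="linear")
            tp = full.values.max()
            corr_errs.append(abs(corrected.values.max() - tp) / tp)
            naive_errs.append((tp - naive.values.max()) / tp)
        assert np.median(corr_errs) < 0.05
        assert np.median(naive_errs) > 0.15

    def test_undetectable_arrival_raises_correction_error(self):
        sig = SignalModelParams(noise_sd=0)
        flat = _si(np.full(60, sig.baseline_signal))
        with pytest.raises(CorrectionError):
            correct_aif_dual_bolus(flat, flat, sig, BASE, 21.0)

    def test_mismatched_grids_rejected(self):
        pre_si, full_si, _, sig = self._session()
        short = SignalIntensityCurve(pre_si.times[:30], pre_si.values[:30])
        with pytest.raises(CorrectionError):
            correct_aif_dual_bolus(short, full_si, sig, BASE, 21.0)
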