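"""Spectral core: DFT conventions, peak measurement, phasing, file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrsmm as M
from mrsmm.models import GaussianComponent, gaussian_component_fid


def _acq(n=2048, bw=6000.0, f0=297.2):
    return M.AcquisitionParams(dwell_time=1.0 / bw, n_points=n, transmitter_frequency=f0)


class TestFidSpectrum:
    def test_zero_fid_gives_zero_spectrum(self):
        acq = _acq(64)
        spec = M.fid_to_spectrum(M.FIDSignal(np.zeros(64, complex), acq))
        assert np.all(spec.values == 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_identity(self, seed):
        acq = _acq(256)
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        fid = M.FIDSignal(x, acq)
        back = M.spectrum_to_fid(M.fid_to_spectrum(fid))
        assert np.max(np.abs(back.samples - x)) < 1e-10 * np.max(np.abs(x))

    def test_round_trip_with_first_point_halving(self):
        acq = _acq(128)
        rng = np.random.default_rng(7)
        x = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        fid = M.FIDSignal(x, acq)
        spec = M.fid_to_spectrum(fid, halve_first_point=True)
        back = M.spectrum_to_fid(spec, halve_first_point=True)
        assert np.max(np.abs(back.samples - x)) < 1e-10

    def test_known_frequency_lands_at_predicted_ppm(self):
        # f = +600 Hz, 298.06 MHz, ref 4.7 ppm -> 4.7 + 600/298.06 = 6.713 ppm
        acq = M.AcquisitionParams(1 / 6000, 2048, 298.06, reference_ppm=4.7)
        t = acq.time_axis
        spec = M.fid_to_spectrum(M.FIDSignal(np.exp(2j * np.pi * 600.0 * t), acq))
        k = np.argmax(np.abs(spec.values))
        expected = 4.7 + 600.0 / 298.06
        assert abs(spec.ppm_axis[k] - expected) <= acq.hz_per_bin / acq.transmitter_frequency

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-2900, 2900), st.integers(0, 2**31 - 1))
    def test_ppm_axis_property_random_frequency(self, f, seed):
        acq = _acq(1024)
        t = acq.time_axis
        spec = M.fid_to_spectrum(M.FIDSignal(np.exp(2j * np.pi * f * t), acq))
        k = np.argmax(np.abs(spec.values))
        predicted = acq.hz_to_ppm(f)
        assert abs(spec.ppm_axis[k] - predicted) <= 1.01 * acq.hz_per_bin / acq.transmitter_frequency

    def test_parseval(self):
        acq = _acq(512)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(512) + 1j * rng.standard_normal(512)
        spec = M.fid_to_spectrum(M.FIDSignal(x, acq))
        lhs = np.sum(np.abs(x) ** 2)
        rhs = np.sum(np.abs(spec.values) ** 2) / 512
        assert abs(lhs - rhs) < 1e-9 * lhs

    def test_nonfinite_samples_rejected(self):
        acq = _acq(16)
        bad = np.zeros(16, complex)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            M.FIDSignal(bad, acq)


class TestMeasurePeak:
    def test_gaussian_fwhm_round_trip(self, acq):
        comp = GaussianComponent("x", 2.0, 12.0, 1.0)
        spec = M.fid_to_spectrum(gaussian_component_fid(comp, acq))
        pm = M.measure_peak(spec, (1.8, 2.2), (-3.0, -1.0))
        assert pm.fwhm_hz == pytest.approx(12.0, abs=0.2)
        assert pm.center_ppm == pytest.approx(2.0, abs=0.005)

    def test_lorentzian_fwhm_closed_form(self):
        # FWHM of exp(-t/T2*) is 1/(pi T2*) = 6.366 Hz for T2* = 50 ms
        acq = _acq(n=16384, bw=6000.0)  # dense grid: 0.37 Hz/bin
        t = acq.time_axis
        f = acq.ppm_to_hz(2.0)
        fid = M.FIDSignal(np.exp((2j * np.pi * f - 1 / 0.05) * t), acq)
        pm = M.measure_peak(M.fid_to_spectrum(fid), (1.9, 2.1), (-3.0, -1.0))
        assert pm.fwhm_hz == pytest.approx(1 / (np.pi * 0.05), rel=0.02)

    def test_snr_scale_equivariance(self, acq):
        rng = np.random.default_rng(11)
        comp = GaussianComponent("x", 2.0, 15.0, 1.0)
        noise = 0.01 * (rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points))
        base = gaussian_component_fid(comp, acq).samples + noise
        m1 = M.measure_peak(M.fid_to_spectrum(M.FIDSignal(base, acq)), (1.8, 2.2), (-3, -1))
        m2 = M.measure_peak(M.fid_to_spectrum(M.FIDSignal(2 * base, acq)), (1.8, 2.2), (-3, -1))
        assert m2.snr == pytest.approx(m1.snr, rel=1e-9)
        assert m2.fwhm_hz == pytest.approx(m1.fwhm_hz, rel=1e-9)

    @pytest.mark.parametrize("fwhm_hz", [25.0, 40.0, 80.0])
    def test_fwhm_error_below_2pct_when_resolved(self, acq, fwhm_hz):
        # >= 8 bins above half height needs FWHM >= 8 * 2.93 Hz
        comp = GaussianComponent("x", 2.5, fwhm_hz, 1.0)
        spec = M.fid_to_spectrum(gaussian_component_fid(comp, acq))
        pm = M.measure_peak(spec, (2.0, 3.0), (-3.0, -1.0))
        assert pm.fwhm_hz == pytest.approx(fwhm_hz, rel=0.02)

    def test_unresolved_peak_raises(self, acq):
        flat = M.fid_to_spectrum(M.FIDSignal(np.ones(acq.n_points, complex), acq))
        with pytest.raises(ValueError, match="unresolved|window"):
            M.measure_peak(flat, (1.99, 2.01), (-3.0, -1.0))


class TestPhaseCorrect:
    def test_zero_phase_is_identity(self, acq):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        spec = M.fid_to_spectrum(M.FIDSignal(x, acq))
        out = M.phase_correct(spec, 0.0, 0.0)
        assert np.allclose(out.values, spec.values)

    def test_360_degrees_is_identity(self, acq):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        spec = M.fid_to_spectrum(M.FIDSignal(x, acq))
        out = M.phase_correct(spec, 360.0, 0.0)
        assert np.allclose(out.values, spec.values, atol=1e-12 * np.max(np.abs(spec.values)))

    def test_inverse_by_negated_arguments(self, acq):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        spec = M.fid_to_spectrum(M.FIDSignal(x, acq))
        out = M.phase_correct(M.phase_correct(spec, 30.0, 8.0, 4.7), -30.0, -8.0, 4.7)
        assert np.allclose(out.values, spec.values, atol=1e-10 * np.max(np.abs(spec.values)))

    def test_truncation_ramp_restored_to_absorptive(self, acq):
        """Dropping the first k points imposes a linear phase ramp that
        phi1 = 360 * k * dwell * f0 deg/ppm removes (time-shift theorem)."""
        k = 39
        comp = GaussianComponent("x", 2.0, 20.0, 1.0)
        full = gaussian_component_fid(
            comp, M.AcquisitionParams(acq.dwell_time, acq.n_points + k, acq.transmitter_frequency)
        ).samples
        delayed = M.FIDSignal(full[k:], acq)
        spec = M.fid_to_spectrum(delayed)
        phi1 = 360.0 * k * acq.dwell_time * acq.transmitter_frequency
        fixed = M.phase_correct(spec, 0.0, phi1, pivot_ppm=acq.reference_ppm)
        w = spec.window(1.9, 2.1)
        # before: the peak carries phase 2 pi f tau; after: ~0 at its center
        k_peak = np.flatnonzero(w)[np.argmax(np.abs(spec.values[w]))]
        before = np.angle(spec.values[k_peak], deg=True) % 360
        after = np.angle(fixed.values[k_peak], deg=True)
        assert min(before, 360 - before) > 30
        assert abs((after + 180) % 360 - 180) < 5
        # absorptive: dispersive (imag) part ~antisymmetric about the peak
        imag = fixed.values.imag[w]
        assert abs(np.sum(imag)) < 0.1 * np.sum(np.abs(imag))
        assert np.max(fixed.values.real[w]) > np.max(np.abs(spec.values.real[w])) * 1.05


class TestProtocolAndIO:
    def test_nominal_voxel_sizes(self):
        assert M.nominal_voxel_size_mm(220, 64) == pytest.approx(3.4, abs=0.05)
        assert M.nominal_voxel_size_mm(180, 32) == pytest.approx(5.6, abs=0.05)

    def test_jmrui_text_round_trip(self, tmp_path, acq):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        small = M.AcquisitionParams(acq.dwell_time, 64, acq.transmitter_frequency,
                                    reference_ppm=4.7, te_star=1.3e-3)
        path = tmp_path / "fid.txt"
        M.write_jmrui_txt(path, M.FIDSignal(x, small))
        back = M.read_jmrui_txt(path)
        assert np.allclose(back.samples, x, atol=1e-10)
        assert back.acq.n_points == 64
        assert back.acq.dwell_time == pytest.approx(small.dwell_time)
        assert back.acq.transmitter_frequency == pytest.approx(small.transmitter_frequency)
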