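"""Hankel-SVD decomposition: exactness on its model class, filtering,
and MM parameterization behavior."""

import numpy as np
import pytest

import mrsmm as M
from mrsmm.hlsvd import filter_components, hlsvd_decompose, parameterize_mm_hlsvd, reconstruct
from mrsmm.models import DampedSinusoid, damped_sinusoid_fid


def _acq(n=512, bw=6000.0):
    return M.AcquisitionParams(1.0 / bw, n, 297.2)


def _signal(acq, params):
    t = acq.time_axis
    total = np.zeros(acq.n_points, dtype=complex)
    for f, d, a, ph in params:
        total += a * np.exp(1j * ph) * np.exp((-d + 2j * np.pi * f) * t)
    return M.FIDSignal(total, acq)


class TestDecompose:
    def test_single_damped_exponential_exact(self):
        acq = _acq()
        fid = _signal(acq, [(150.0, 20.0, 1.0, 0.5)])
        (c,) = hlsvd_decompose(fid, 1)
        assert c.frequency_hz == pytest.approx(150.0, rel=1e-6)
        assert c.damping == pytest.approx(20.0, rel=1e-6)
        assert c.amplitude == pytest.approx(1.0, rel=1e-6)
        assert c.phase_rad == pytest.approx(0.5, rel=1e-6)

    def test_three_components_recovered(self):
        acq = _acq()
        params = [(-400.0, 35.0, 0.5, -1.2), (150.0, 20.0, 1.0, 0.5), (900.0, 10.0, 2.0, 2.0)]
        comps = hlsvd_decompose(_signal(acq, params), 3)
        for (f, d, a, ph), c in zip(sorted(params), comps):
            assert c.frequency_hz == pytest.approx(f, rel=1e-5, abs=1e-5)
            assert c.damping == pytest.approx(d, rel=1e-5)
            assert c.amplitude == pytest.approx(a, rel=1e-5)
            assert c.phase_rad == pytest.approx(ph, rel=1e-5)

    @pytest.mark.parametrize("k", [2, 5, 13])
    def test_exact_on_model_class_up_to_13(self, k):
        acq = _acq(1024)
        rng = np.random.default_rng(k)
        params = [
            (float(f), float(d), float(a), float(ph))
            for f, d, a, ph in zip(
                rng.uniform(-2500, 2500, k), rng.uniform(5, 60, k),
                rng.uniform(0.3, 2.0, k), rng.uniform(-3, 3, k),
            )
        ]
        comps = hlsvd_decompose(_signal(acq, params), k)
        got = sorted((c.frequency_hz, c.damping, c.amplitude) for c in comps)
        want = sorted((f, d, a) for f, d, a, _ in params)
        for (gf, gd, ga), (wf, wd, wa) in zip(got, want):
            assert gf == pytest.approx(wf, abs=1e-4)
            assert gd == pytest.approx(wd, rel=1e-5)
            assert ga == pytest.approx(wa, rel=1e-5)

    def test_amplitudes_match_dense_oracle_on_true_poles(self):
        """Short-signal oracle: amplitudes re-estimated by dense least
        squares on the true poles agree with the pipeline."""
        acq = _acq(64)
        params = [(200.0, 30.0, 1.0, 0.3), (-500.0, 15.0, 0.7, -0.8)]
        fid = _signal(acq, params)
        comps = hlsvd_decompose(fid, 2, hankel_rows=30)
        t = acq.time_axis
        V = np.stack([np.exp((-d + 2j * np.pi * f) * t) for f, d, _, _ in sorted(params)]).T
        oracle, *_ = np.linalg.lstsq(V, fid.samples, rcond=None)
        for c, o in zip(comps, oracle):
            assert c.amplitude == pytest.approx(abs(o), rel=1e-8)
            assert c.phase_rad == pytest.approx(np.angle(o), abs=1e-8)

    def test_residual_power_monotone_in_component_count(self):
        """More components never fit a noisy multi-exponential worse
        (up to a small tolerance: the state-space estimator is not an
        exact projection)."""
        acq = _acq(128)
        rng = np.random.default_rng(0)
        for trial in range(20):
            n_true = rng.integers(2, 6)
            params = [
                (float(f), float(d), float(a), float(ph))
                for f, d, a, ph in zip(
                    rng.uniform(-2500, 2500, n_true), rng.uniform(10, 80, n_true),
                    rng.uniform(0.5, 2.0, n_true), rng.uniform(-3, 3, n_true),
                )
            ]
            x = _signal(acq, params).samples
            x = x + 0.05 * (rng.standard_normal(128) + 1j * rng.standard_normal(128))
            fid = M.FIDSignal(x, acq)
            prev = np.inf
            for k in (1, 2, 4, 6):
                comps = hlsvd_decompose(fid, k, hankel_rows=40)
                resid = np.sum(np.abs(reconstruct(comps, acq).samples - x) ** 2)
                assert resid <= prev * (1 + 1e-2)
                prev = resid

    def test_sorted_by_frequency(self):
        acq = _acq()
        comps = hlsvd_decompose(
            _signal(acq, [(900.0, 10.0, 1.0, 0.0), (-100.0, 10.0, 1.0, 0.0)]), 2
        )
        assert comps[0].frequency_hz < comps[1].frequency_hz

    def test_rank_deficiency_warns_and_returns_fewer(self):
        acq = _acq(128)
        fid = _signal(acq, [(100.0, 10.0, 1.0, 0.0)])
        with pytest.warns(UserWarning, match="rank"):
            comps = hlsvd_decompose(fid, 4, hankel_rows=40)
        assert len(comps) < 4

    def test_growing_pole_kept_and_flagged(self):
        acq = _acq(128)
        fid = _signal(acq, [(100.0, -5.0, 1.0, 0.0)])  # growing
        (c,) = hlsvd_decompose(fid, 1, hankel_rows=40)
        assert c.growing
        assert c.damping == pytest.approx(-5.0, rel=1e-6)


class TestReconstructAndFilter:
    def test_empty_reconstruction_is_zero(self):
        acq = _acq(64)
        assert np.all(reconstruct([], acq).samples == 0)

    def test_single_component_closed_form(self):
        acq = _acq(64)
        c = DampedSinusoid(100.0, 12.0, 1.5, 0.7)
        t = acq.time_axis
        want = 1.5 * np.exp(1j * 0.7) * np.exp((-12.0 + 2j * np.pi * 100.0) * t)
        assert np.allclose(reconstruct([c], acq).samples, want, atol=1e-12)

    def test_round_trip_two_components(self):
        acq = _acq()
        fid = _signal(acq, [(200.0, 30.0, 1.0, 0.3), (-500.0, 15.0, 0.7, -0.8)])
        comps = hlsvd_decompose(fid, 2)
        back = reconstruct(comps, acq)
        assert np.max(np.abs(back.samples - fid.samples)) < 1e-8 * np.max(np.abs(fid.samples))

    def test_filter_identity_when_all_inside(self, acq):
        comps = [DampedSinusoid(acq.ppm_to_hz(p), 30.0, 1.0, 0.0) for p in (1.0, 2.0, 3.0)]
        assert filter_components(comps, (0.5, 4.0), 100.0, acq) == comps

    def test_out_of_window_component_dropped(self, acq):
        comps = [DampedSinusoid(acq.ppm_to_hz(5.1), 30.0, 1.0, 0.0)]
        assert filter_components(comps, (0.5, 4.0), 100.0, acq) == []

    def test_thirteen_with_four_bad_leaves_nine(self, acq):
        """Constructed fixture: 13 poles of which 2 out-of-window and 2
        over-broad -> exactly the 9 MM-like poles survive."""
        good = [DampedSinusoid(acq.ppm_to_hz(p), 60.0, 1.0, 0.0)
                for p in M.MM_CENTERS_PPM.values()]
        bad = [
            DampedSinusoid(acq.ppm_to_hz(4.7), 30.0, 5.0, 0.0),   # water region
            DampedSinusoid(acq.ppm_to_hz(0.2), 30.0, 1.0, 0.0),   # upfield of window
            DampedSinusoid(acq.ppm_to_hz(2.5), 700.0, 2.0, 0.0),  # over-broad
            DampedSinusoid(acq.ppm_to_hz(3.0), 400.0, 2.0, 0.0),  # over-broad
        ]
        kept = filter_components(good + bad, (0.5, 4.0), 100.0, acq)
        assert len(kept) == 9
        assert kept == good


class TestParameterizeMM:
    def test_recovers_nine_centers_at_snr_100(self, acq):
        truth = M.MMTruth.default(acq, seed=2)
        sd = M.mm_noise_sd_for_snr(truth, acq, 100.0)
        fid = M.generate_mm_fid(truth, acq, noise_sd=sd, seed=2)
        model = parameterize_mm_hlsvd(fid)
        assert model.variant == "ind_MM_HL"
        assert len(model.components) == 9
        for name, center in M.MM_CENTERS_PPM.items():
            assert abs(model.params[name].center_ppm(acq) - center) < 0.03

    def test_deterministic_for_fixed_seed(self, acq):
        truth = M.MMTruth.default(acq, seed=5)
        sd = M.mm_noise_sd_for_snr(truth, acq, 100.0)
        fid = M.generate_mm_fid(truth, acq, noise_sd=sd, seed=5)
        a = parameterize_mm_hlsvd(fid)
        b = parameterize_mm_hlsvd(fid)
        for name in M.MM_NAMES:
            assert np.array_equal(a.components[name].samples, b.components[name].samples)

    def test_lorentzian_tails_exceed_gaussian_tails(self, acq, mm_truth, mm_model_amares):
        """The lineshape-mismatch property behind the elevated baseline:
        HLSVD's Lorentzian-mixture components put a larger fraction of
        their spectral energy outside the line core than the Gaussian
        components of the prior-knowledge fit."""
        fid = M.generate_mm_fid(mm_truth, acq, 0.0)
        hl = parameterize_mm_hlsvd(fid)

        def tail_fraction(fid_c, center, fwhm_hz):
            spec = M.fid_to_spectrum(fid_c)
            v = np.abs(spec.values.real)
            w_ppm = fwhm_hz / acq.transmitter_frequency
            core = spec.window(center - w_ppm, center + w_ppm)
            return 1.0 - np.sum(v[core]) / np.sum(v)

        am_tail = np.mean([
            tail_fraction(mm_model_amares.components[n],
                          mm_model_amares.params[n].center_ppm,
                          mm_model_amares.params[n].fwhm_hz)
            for n in M.MM_NAMES
        ])
        hl_tail = np.mean([
            tail_fraction(hl.components[n], hl.params[n].center_ppm(acq),
                          hl.params[n].lorentzian_fwhm_hz)
            for n in M.MM_NAMES
        ])
        assert hl_tail > am_tail

    def test_failure_when_no_mm_content(self, acq):
        # a single water-region line leaves nothing in the MM window
        t = acq.time_axis
        fid = M.FIDSignal(np.exp((-30 + 2j * np.pi * acq.ppm_to_hz(4.7)) * t), acq)
        with pytest.raises(ValueError, match="MM parameterization failed"):
            parameterize_mm_hlsvd(fid, n_components=3)
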