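"""Frequency-domain linear-combination model fitting (LCModel-analog).

A measured spectrum is modeled over the fit range (default 4.2–0.2 ppm)
as a non-negative combination of basis spectra — each allowed a small
frequency shift and a shared Gaussian line broadening — under a
zero-order (optionally first-order) phase, plus a cubic B-spline
baseline.  For the con_* MM variants a soft penalty pulls the fitted
MM(XX)/MM1 amplitude ratios toward their priors.

Numerics: the real part of the phased data is fitted.  Amplitudes and
spline coefficients are solved exactly at every step of the outer
nonlinear search (variable projection): the spline subspace is projected
out with a precomputed orthonormal basis, the amplitudes are found by
non-negative least squares on the projected problem (with the ratio-
penalty rows appended, iteratively re-linearized in the MM1 amplitude),
and the spline coefficients are recovered afterwards.  Data residuals
are whitened by the spectral noise SD estimated in a peak-free window so
the fit — and the dimensionless ratio penalty — are invariant to overall
signal scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import least_squares, nnls

from .basis import BasisSet
from .core import Spectrum, fid_to_spectrum, measure_peak
from .models import gaussian_beta

__all__ = ["LCFitOptions", "LCFitResult", "lc_fit", "compute_crlb"]

CRLB_UNFITTABLE = 999.0


@dataclass(frozen=True)
class LCFitOptions:
    """Control parameters of the linear-combination fit."""

    fit_range_ppm: tuple[float, float] = (0.2, 4.2)
    baseline_knot_spacing_ppm: float = 0.4
    max_global_shift_ppm: float = 0.05
    per_component_shift_ppm: float = 0.01
    lipid_shift_ppm: float = 0.05
    phi0_bounds_deg: tuple[float, float] = (-180.0, 180.0)
    fit_phi1: bool = False
    phi1_bounds_deg_per_ppm: tuple[float, float] = (-50.0, 50.0)
    max_broadening_hz: float = 20.0
    use_ratio_priors: bool = True
    ratio_prior_weight: float = 1.0
    noise_window_ppm: tuple[float, float] = (-3.0, -1.0)
    naa_window_ppm: tuple[float, float] = (1.85, 2.15)
    max_iter: int = 60
    tol: float = 1e-8

    def __post_init__(self) -> None:
        lo, hi = self.fit_range_ppm
        if not lo < hi:
            raise ValueError("fit_range_ppm must be an increasing interval")
        if self.baseline_knot_spacing_ppm <= 0:
            raise ValueError("baseline_knot_spacing_ppm must be positive")


@dataclass
class LCFitResult:
    """Per-spectrum fit output: amplitudes, CRLBs, phases, baseline, QA stats."""

    amplitudes: dict[str, float]
    crlb_percent: dict[str, float]
    phi0_deg: float
    phi1_deg_per_ppm: float
    global_shift_ppm: float
    broadening_hz: float
    baseline: np.ndarray
    residual: np.ndarray
    fit_ppm: np.ndarray
    fwhm_naa_hz: float
    snr_naa: float
    converged: bool
    cost: float = 0.0

    def amplitude(self, name: str) -> float:
        return self.amplitudes[name]


def _spline_design(ppm: np.ndarray, lo: float, hi: float, spacing: float) -> np.ndarray:
    n_seg = max(1, int(round((hi - lo) / spacing)))
    interior = np.linspace(lo, hi, n_seg + 1)[1:-1]
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    x = np.clip(ppm, lo, hi)
    return BSpline.design_matrix(x, knots, 3).toarray()


def _shift_broaden_fft(units: np.ndarray, shifts_hz: np.ndarray, gamma_hz: float,
                       t: np.ndarray) -> np.ndarray:
    """FFT of basis FIDs after per-entry frequency shift and shared
    Gaussian broadening; returns display-order spectra (rows)."""
    beta = gaussian_beta(gamma_hz) if gamma_hz > 0 else 0.0
    if np.ptp(shifts_hz) == 0.0:
        # common case (per-component shifts frozen): one shared envelope
        env1 = np.exp(2j * np.pi * shifts_hz[0] * t - beta * t**2)
        mod = units * env1[None, :]
    else:
        env = np.exp(2j * np.pi * np.outer(shifts_hz, t) - beta * t[None, :] ** 2)
        mod = units * env
    spec = np.fft.fftshift(np.fft.fft(mod, axis=1), axes=1)
    return spec[:, ::-1]


def lc_fit(spec: Spectrum, basis: BasisSet, opts: LCFitOptions | None = None) -> LCFitResult:
    """Fit one spectrum with a basis set.

    See the module docstring for the model.  Per-component shifts are
    parameterized as one bounded offset per basis entry (lipids get the
    wider ``lipid_shift_ppm`` bound); setting
    ``per_component_shift_ppm=0`` freezes them onto the global shift,
    which is much faster and appropriate when the data are known to share
    a single frequency offset per voxel.
    """
    if opts is None:
        opts = LCFitOptions()
    acq = spec.acq
    if basis.acq != acq:
        raise ValueError("basis and spectrum acquisition parameters differ")
    if opts.baseline_knot_spacing_ppm <= 2.0 * acq.hz_per_bin / acq.transmitter_frequency:
        raise ValueError("baseline knot spacing must exceed 2x the ppm per bin")

    names = list(basis.entries)
    units = basis.matrix()
    if len(set(names)) != len(names):
        raise ValueError("duplicate basis entries")
    J = len(names)
    t = acq.time_axis
    lo, hi = opts.fit_range_ppm
    win = spec.window(lo, hi)
    if not np.any(win):
        raise ValueError("fit range outside the spectral axis")
    ppm_win = spec.ppm_axis[win]
    y_win = spec.values[win]

    S = _spline_design(ppm_win, lo, hi, opts.baseline_knot_spacing_ppm)
    Qs, _ = np.linalg.qr(S)

    # noise SD of the real part in a peak-free window; whitens the data rows
    nmask = spec.window(*sorted(opts.noise_window_ppm))
    sigma = float(np.std(spec.values.real[nmask])) if np.any(nmask) else 0.0
    sigma = max(sigma, 1e-9 * float(np.max(np.abs(y_win))) + 1e-300)

    # ratio priors
    priors = ()
    if opts.use_ratio_priors and basis.mm_variant.startswith("con_"):
        priors = basis.ratio_priors
    prior_idx = [(names.index(rp.numerator), names.index(rp.denominator), rp) for rp in priors]

    # per-component shift bounds
    per_shift = np.array([
        opts.lipid_shift_ppm if n in basis.lipid_names else opts.per_component_shift_ppm
        for n in names
    ])
    free_shift = per_shift > 0

    # nonlinear parameter vector: [phi0_deg, (phi1), gamma_hz, global_shift_ppm,
    #                              per-component shifts for entries with freedom]
    x0, lb, ub = [0.0], [opts.phi0_bounds_deg[0]], [opts.phi0_bounds_deg[1]]
    if opts.fit_phi1:
        x0 += [0.0]; lb += [opts.phi1_bounds_deg_per_ppm[0]]; ub += [opts.phi1_bounds_deg_per_ppm[1]]
    x0 += [0.5, 0.0]
    lb += [0.0, -opts.max_global_shift_ppm]
    ub += [opts.max_broadening_hz, opts.max_global_shift_ppm]
    n_free = int(np.sum(free_shift))
    x0 += [0.0] * n_free
    lb += list(-per_shift[free_shift])
    ub += list(per_shift[free_shift])

    f0 = acq.transmitter_frequency

    def unpack(x):
        i = 0
        phi0 = x[i]; i += 1
        phi1 = 0.0
        if opts.fit_phi1:
            phi1 = x[i]; i += 1
        gamma = x[i]; i += 1
        gshift = x[i]; i += 1
        shifts = np.zeros(J)
        shifts[free_shift] = x[i:]
        return phi0, phi1, gamma, gshift + shifts

    state: dict = {"a_prev": None, "key": None, "M": None}

    def _prior_rows(a_lin):
        rows = np.zeros((len(prior_idx), J))
        w0 = math.sqrt(opts.ratio_prior_weight)
        a_mm1 = max(a_lin[prior_idx[0][1]], 1e-12)
        for r, (ix, iden, rp) in enumerate(prior_idx):
            w = w0 / (rp.sd * a_mm1)
            rows[r, ix] = w
            rows[r, iden] = -w * rp.expected_ratio
        return rows

    def solve_linear(M, y_re, irls: int = 1):
        """NNLS amplitudes + free spline via the spline annihilator.

        The ratio penalty is linearized at the previous amplitude
        solution (``irls`` re-linearization passes; one suffices inside
        the outer search, the final solve uses three).
        """
        Py = y_re - Qs @ (Qs.T @ y_re)
        PM = M - Qs @ (Qs.T @ M)
        A = PM / sigma
        b = Py / sigma
        if prior_idx:
            # linearization point: fixed during the outer search so the
            # residual stays a deterministic function of x
            a_prev = state["a_prev"]
            if a_prev is None:
                a_prev, _ = nnls(A, b)
                state["a_prev"] = a_prev
            for _ in range(irls):
                rows = _prior_rows(a_prev)
                amps, _ = nnls(np.vstack([A, rows]),
                               np.concatenate([b, np.zeros(len(prior_idx))]))
                a_prev = amps
            pen = rows @ amps
        else:
            amps, _ = nnls(A, b)
            pen = np.zeros(0)
        coef = Qs.T @ (y_re - M @ amps)
        baseline = Qs @ coef
        return amps, baseline, pen

    def model_matrix(gamma, shifts_ppm):
        key = (gamma, shifts_ppm.tobytes())
        if state["key"] != key:
            B = _shift_broaden_fft(units, shifts_ppm * f0, gamma, t)
            state["M"] = B[:, win].real.T  # (n_bins, J)
            state["key"] = key
        return state["M"]

    def phased_real(phi0, phi1):
        ph = np.deg2rad(phi0 + phi1 * (ppm_win - acq.reference_ppm))
        return (y_win * np.exp(-1j * ph)).real

    def residual(x):
        phi0, phi1, gamma, shifts = unpack(x)
        M = model_matrix(gamma, shifts)
        y_re = phased_real(phi0, phi1)
        amps, baseline, pen = solve_linear(M, y_re)
        r = (y_re - M @ amps - baseline) / sigma
        return np.concatenate([r, pen])

    x0 = np.clip(np.array(x0), np.array(lb), np.array(ub))
    res = least_squares(
        residual, x0, bounds=(np.array(lb), np.array(ub)),
        method="trf", ftol=opts.tol, xtol=opts.tol, gtol=opts.tol,
        max_nfev=opts.max_iter * (len(x0) + 1),
    )
    phi0, phi1, gamma, shifts = unpack(res.x)
    M = model_matrix(gamma, shifts)
    y_re = phased_real(phi0, phi1)
    amps, baseline, pen = solve_linear(M, y_re, irls=3)
    fit_resid = y_re - M @ amps - baseline

    crlb = compute_crlb(M, Qs, amps, fit_resid, names)

    # QA stats on the phased full spectrum
    ph = np.deg2rad(phi0 + phi1 * (spec.ppm_axis - acq.reference_ppm))
    phased = Spectrum(spec.values * np.exp(-1j * ph), spec.ppm_axis, acq)
    try:
        naa = measure_peak(phased, opts.naa_window_ppm, opts.noise_window_ppm)
        fwhm_naa, snr_naa = naa.fwhm_hz, naa.snr
    except ValueError:
        fwhm_naa, snr_naa = np.inf, 0.0

    gidx = (1 if opts.fit_phi1 else 0) + 2
    return LCFitResult(
        amplitudes=dict(zip(names, map(float, amps))),
        crlb_percent=crlb,
        phi0_deg=float(phi0),
        phi1_deg_per_ppm=float(phi1),
        global_shift_ppm=float(res.x[gidx]),
        broadening_hz=float(gamma),
        baseline=baseline,
        residual=fit_resid,
        fit_ppm=ppm_win,
        fwhm_naa_hz=float(fwhm_naa),
        snr_naa=float(snr_naa),
        converged=bool(res.success),
        cost=float(res.cost),
    )


def compute_crlb(M: np.ndarray, Qs: np.ndarray, amps: np.ndarray,
                 fit_resid: np.ndarray, names: list[str]) -> dict[str, float]:
    """Amplitude CRLBs in percent from the Fisher information.

    The spline baseline is a nuisance: the amplitude block of the inverse
    Fisher information equals ``(M^T P M)^-1 sigma^2`` with ``P`` the
    projector onto the spline's orthogonal complement.  The noise SD is
    estimated robustly (MAD) from the fit residual, which is signal-free
    by construction.  Entries fitted at zero report the sentinel 999%.
    """
    sigma = 1.4826 * float(np.median(np.abs(fit_resid - np.median(fit_resid))))
    sigma = max(sigma, 1e-300)
    PM = M - Qs @ (Qs.T @ M)
    F = PM.T @ PM / sigma**2
    out: dict[str, float] = {}
    try:
        cov = np.linalg.inv(F)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular Fisher information in CRLB computation", stacklevel=2)
        return {n: np.inf for n in names}
    for j, n in enumerate(names):
        if amps[j] <= 0:
            out[n] = CRLB_UNFITTABLE
        else:
            out[n] = 100.0 * sds[j] / amps[j]
    return out
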