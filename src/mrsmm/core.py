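"""Core signal model for MR spectroscopy: FIDs, spectra, ppm axes.

Everything downstream (parameterization, basis building, linear-combination
fitting) passes time-domain free-induction-decay signals (:class:`FIDSignal`)
and frequency-domain spectra (:class:`Spectrum`) built on a shared
acquisition description (:class:`AcquisitionParams`).

Conventions
-----------
* FID sample ``k`` sits at time ``t_k = k * dwell_time`` (no implicit delay;
  an acquisition delay TE* manifests as a first-order phase ramp that
  :func:`phase_correct` can remove).
* The chemical-shift axis is ``ppm[k] = reference_ppm + f_hz[k] /
  transmitter_frequency`` with offsets spanning ``[-BW/2, +BW/2)``.  The
  water reference defaults to 4.7 ppm.
* Spectra are stored in display order: ppm strictly decreasing left to
  right, the universal plotting convention in MRS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionParams",
    "FIDSignal",
    "Spectrum",
    "PeakMeasurement",
    "fid_to_spectrum",
    "spectrum_to_fid",
    "measure_peak",
    "phase_correct",
    "nominal_voxel_size_mm",
    "read_jmrui_txt",
    "write_jmrui_txt",
]

DEFAULT_REFERENCE_PPM = 4.7


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata shared by a signal and its basis set.

    Parameters
    ----------
    dwell_time:
        Seconds per complex point; the acquisition bandwidth is
        ``1/dwell_time``.
    n_points:
        Number of complex points.
    transmitter_frequency:
        Larmor frequency in MHz (~297.2 MHz for protons at 7 T).
    reference_ppm:
        Chemical shift assigned to zero frequency offset (water).
    te_star:
        Acquisition delay in seconds (time from excitation to the first
        acquired point).  Metadata; not applied implicitly.
    tr, ti1, ti2:
        Repetition time and the two inversion times of a double-inversion
        metabolite-nulling protocol.  Metadata only.
    """

    dwell_time: float
    n_points: int
    transmitter_frequency: float
    reference_ppm: float = DEFAULT_REFERENCE_PPM
    te_star: float = 0.0
    tr: float | None = None
    ti1: float | None = None
    ti2: float | None = None

    def __post_init__(self) -> None:
        if not self.dwell_time > 0:
            raise ValueError("dwell_time must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.transmitter_frequency > 0:
            raise ValueError("transmitter_frequency must be positive (MHz)")

    @property
    def bandwidth(self) -> float:
        """Acquisition bandwidth in Hz."""
        return 1.0 / self.dwell_time

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_points) * self.dwell_time

    def hz_to_ppm(self, f_hz) -> np.ndarray | float:
        return self.reference_ppm + np.asarray(f_hz, dtype=float) / self.transmitter_frequency

    def ppm_to_hz(self, ppm) -> np.ndarray | float:
        return (np.asarray(ppm, dtype=float) - self.reference_ppm) * self.transmitter_frequency

    @property
    def hz_per_bin(self) -> float:
        return self.bandwidth / self.n_points


@dataclass(frozen=True)
class FIDSignal:
    """Complex time-domain signal plus its acquisition description."""

    samples: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=complex)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or len(samples) != self.acq.n_points:
            raise ValueError(
                f"FID length {samples.shape} does not match acq.n_points={self.acq.n_points}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("FID contains non-finite samples")

    def __add__(self, other: "FIDSignal") -> "FIDSignal":
        if other.acq != self.acq:
            raise ValueError("cannot add FIDs with different acquisition parameters")
        return FIDSignal(self.samples + other.samples, self.acq)

    def scaled(self, factor: complex) -> "FIDSignal":
        return FIDSignal(self.samples * factor, self.acq)


@dataclass(frozen=True)
class Spectrum:
    """Complex spectrum in display order (ppm decreasing left to right)."""

    values: np.ndarray
    ppm_axis: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=complex)
        ppm = np.asarray(self.ppm_axis, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ppm_axis", ppm)
        if len(values) != len(ppm):
            raise ValueError("values and ppm_axis length mismatch")
        d = np.diff(ppm)
        if not np.all(d < 0):
            raise ValueError("ppm_axis must be strictly decreasing (display order)")
        if np.ptp(d) > 1e-9:
            raise ValueError("ppm_axis spacing must be uniform")

    def window(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Boolean mask of bins with lo_ppm <= ppm <= hi_ppm."""
        return (self.ppm_axis >= lo_ppm) & (self.ppm_axis <= hi_ppm)


@dataclass(frozen=True)
class PeakMeasurement:
    """Summary of one resolved spectral peak."""

    center_ppm: float
    fwhm_hz: float
    height: float
    snr: float


def fid_to_spectrum(fid: FIDSignal, halve_first_point: bool = False) -> Spectrum:
    """Discrete Fourier transform of an FID, zero frequency centered.

    Parameters
    ----------
    halve_first_point:
        Halve the first FID point before transforming.  This removes the
        constant baseline offset a finite sum over a one-sided decay
        introduces; off by default so that the plain DFT identities
        (Parseval, exact round trip via :func:`spectrum_to_fid` with the
        same flag) hold.
    """
    samples = fid.samples.copy()
    if halve_first_point:
        samples[0] *= 0.5
    n = fid.acq.n_points
    values = np.fft.fftshift(np.fft.fft(samples))
    f_hz = np.fft.fftshift(np.fft.fftfreq(n, d=fid.acq.dwell_time))
    ppm = fid.acq.hz_to_ppm(f_hz)
    # store in display order (ppm decreasing)
    return Spectrum(values[::-1], ppm[::-1], fid.acq)


def spectrum_to_fid(spec: Spectrum, halve_first_point: bool = False) -> FIDSignal:
    """Inverse of :func:`fid_to_spectrum` (pass the same flag)."""
    values = spec.values[::-1]  # back to increasing-frequency order
    samples = np.fft.ifft(np.fft.ifftshift(values))
    if halve_first_point:
        samples[0] *= 2.0
    return FIDSignal(samples, spec.acq)


def phase_correct(spec: Spectrum, phi0: float, phi1: float, pivot_ppm: float | None = None) -> Spectrum:
    """Zero/first-order phase correction.

    ``values[k] *= exp(-1j * (phi0 + phi1*(ppm[k]-pivot)) * pi/180)`` with
    ``phi0`` in degrees and ``phi1`` in degrees per ppm.  Invertible by
    negating both arguments.  An FID acquired with delay TE* needs
    ``phi1 = 360 * TE* * transmitter_frequency`` (deg/ppm) about
    ``pivot_ppm = reference_ppm`` to restore absorptive lineshapes.
    """
    if pivot_ppm is None:
        pivot_ppm = spec.acq.reference_ppm
    phase = np.deg2rad(phi0 + phi1 * (spec.ppm_axis - pivot_ppm))
    return Spectrum(spec.values * np.exp(-1j * phase), spec.ppm_axis, spec.acq)


def _parabolic_vertex(y_m1: float, y_0: float, y_p1: float) -> float:
    """Sub-bin offset of the vertex of a parabola through three points."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom == 0:
        return 0.0
    delta = 0.5 * (y_m1 - y_p1) / denom
    return float(np.clip(delta, -0.5, 0.5))


def measure_peak(
    spec: Spectrum,
    window_ppm: tuple[float, float],
    noise_window_ppm: tuple[float, float],
) -> PeakMeasurement:
    """Locate the tallest real-part peak in a window and measure it.

    Center: real-part maximum refined by a 3-point parabola (the raw grid
    is ~2.9 Hz/bin for a 6 kHz / 2048-point acquisition, too coarse for
    line-width maps).  FWHM: linear interpolation of the half-height
    crossings, converted to Hz.  SNR: peak height over twice the standard
    deviation of the real part in a peak-free noise window.

    Raises
    ------
    ValueError
        If no half-height crossing exists on either side inside the window
        ("peak unresolved").
    """
    lo, hi = sorted(window_ppm)
    mask = spec.window(lo, hi)
    if not np.any(mask):
        raise ValueError("peak window outside the ppm axis")
    idx = np.flatnonzero(mask)
    real = spec.values.real
    k = idx[np.argmax(real[idx])]
    height = float(real[k])

    delta = 0.0
    if 0 < k < len(real) - 1:
        delta = _parabolic_vertex(real[k - 1], real[k], real[k + 1])
        height = float(real[k] - 0.25 * (real[k - 1] - real[k + 1]) * delta)
    step_ppm = float(spec.ppm_axis[1] - spec.ppm_axis[0])  # negative
    center_ppm = float(spec.ppm_axis[k] + delta * step_ppm)

    half = height / 2.0

    def _crossing(direction: int) -> float:
        j = k
        while 0 < j < len(real) - 1 and idx[0] <= j <= idx[-1]:
            j2 = j + direction
            if real[j2] < half <= real[j]:
                frac = (real[j] - half) / (real[j] - real[j2])
                return float(spec.ppm_axis[j] + frac * (spec.ppm_axis[j2] - spec.ppm_axis[j]))
            j = j2
        raise ValueError("peak unresolved: no half-height crossing inside window")

    left = _crossing(-1)
    right = _crossing(+1)
    fwhm_ppm = abs(left - right)
    fwhm_hz = fwhm_ppm * spec.acq.transmitter_frequency

    nlo, nhi = sorted(noise_window_ppm)
    nmask = spec.window(nlo, nhi)
    if not np.any(nmask):
        raise ValueError("noise window outside the ppm axis")
    noise_sd = float(np.std(real[nmask]))
    snr = height / (2.0 * noise_sd) if noise_sd > 0 else np.inf
    return PeakMeasurement(center_ppm=center_ppm, fwhm_hz=fwhm_hz, height=height, snr=snr)


def nominal_voxel_size_mm(fov_mm: float, matrix: int) -> float:
    """Nominal in-plane voxel size FoV/matrix, as quoted in MRSI protocols."""
    if matrix <= 0:
        raise ValueError("matrix must be positive")
    return fov_mm / matrix


# ---------------------------------------------------------------------------
# jMRUI-style ASCII FID I/O
# ---------------------------------------------------------------------------

def write_jmrui_txt(path: str | Path, fid: FIDSignal) -> None:
    """Write an FID as jMRUI-style ASCII text.

    Header keys mirror the jMRUI text export: PointsInDataset,
    SamplingInterval (ms), TransmitterFrequency (Hz); the body holds two
    whitespace-separated columns (real, imaginary).
    """
    acq = fid.acq
    lines = [
        "jMRUI-style ASCII FID",
        "",
        f"PointsInDataset: {acq.n_points}",
        f"SamplingInterval: {acq.dwell_time * 1e3:.9g}",
        f"TransmitterFrequency: {acq.transmitter_frequency * 1e6:.9g}",
        f"ReferencePpm: {acq.reference_ppm:.9g}",
        f"TEstar: {acq.te_star:.9g}",
        "",
        "Signal (real imag)",
    ]
    body = "\n".join(f"{s.real:.12e} {s.imag:.12e}" for s in fid.samples)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_jmrui_txt(path: str | Path) -> FIDSignal:
    """Read an FID written by :func:`write_jmrui_txt`."""
    header: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if ":" in line and not _is_number_pair(line):
            key, _, val = line.partition(":")
            try:
                header[key.strip()] = float(val)
            except ValueError:
                pass
            continue
        if _is_number_pair(line):
            a, b = line.split()[:2]
            rows.append((float(a), float(b)))
    required = ("PointsInDataset", "SamplingInterval", "TransmitterFrequency")
    missing = [k for k in required if k not in header]
    if missing:
        raise ValueError(f"jMRUI header missing keys: {missing}")
    acq = AcquisitionParams(
        dwell_time=header["SamplingInterval"] * 1e-3,
        n_points=int(header["PointsInDataset"]),
        transmitter_frequency=header["TransmitterFrequency"] * 1e-6,
        reference_ppm=header.get("ReferencePpm", DEFAULT_REFERENCE_PPM),
        te_star=header.get("TEstar", 0.0),
    )
    samples = np.array([complex(r, i) for r, i in rows])
    return FIDSignal(samples, acq)


def _is_number_pair(line: str) -> bool:
    parts = line.split()
    if len(parts) < 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True
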