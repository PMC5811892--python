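"""Synthetic data: metabolite basis FIDs, metabolite-nulled MM spectra,
and 2D FID-MRSI phantoms with ground truth.

All generators are pure functions of their parameters and a seed.  The
default acquisition mirrors a 7 T FID-MRSI protocol: 2,048 complex points,
6,000 Hz bandwidth, TE* 1.3 ms, 64x64 matrix.

The metabolite simulation uses weak-coupling line lists (chemical shift +
relative amplitude per proton group) rather than density-matrix evolution:
at a 1.3 ms acquisition delay J-coupling evolution is negligible, so each
resonance reduces to a phase-coherent exponentially damped line.  The line
lists below are standard literature shifts entered as synthetic package
fixtures (proton-count amplitude weights, normalized to unit sum per
compound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import AcquisitionParams, FIDSignal, fid_to_spectrum
from .grid import MRSIGrid
from .models import MM_CENTERS_PPM, MM_NAMES, GaussianComponent, gaussian_beta, gaussian_component_fid

__all__ = [
    "LineGroup",
    "MMTruth",
    "PhantomTruth",
    "default_acquisition",
    "default_metabolite_groups",
    "METABOLITE_NAMES",
    "RESIDUAL_POSITIONS_PPM",
    "simulate_metabolite_fid",
    "generate_mm_fid",
    "generate_metabolite_nulled_spectrum",
    "generate_mrsi_phantom",
    "default_contrast_rules",
    "mm_noise_sd_for_snr",
    "phantom_noise_sd_for_snr",
]

#: Chemical shifts (ppm) of the five metabolite residuals that survive
#: metabolite nulling: NAA, myo-inositol, Glu, Gln, tCr(CH2).
RESIDUAL_POSITIONS_PPM: tuple[float, ...] = (2.01, 3.52, 2.30, 2.45, 3.98)

DEFAULT_TRANSMITTER_MHZ = 297.2  # 1H at 7 T
DEFAULT_N_TRUNCATE = 39
DEFAULT_OVERSAMPLING = 5  # 6 kHz * 5 = 30 kHz internal grid; 39 pts = 1.3 ms


def default_acquisition(
    n_points: int = 2048,
    bandwidth_hz: float = 6000.0,
    transmitter_frequency: float = DEFAULT_TRANSMITTER_MHZ,
    reference_ppm: float = 4.7,
) -> AcquisitionParams:
    """The 7 T FID-MRSI acquisition used throughout: 2,048 pts, 6 kHz, TE* 1.3 ms."""
    return AcquisitionParams(
        dwell_time=1.0 / bandwidth_hz,
        n_points=n_points,
        transmitter_frequency=transmitter_frequency,
        reference_ppm=reference_ppm,
        te_star=1.3e-3,
        tr=0.6,
        ti1=0.570,
        ti2=0.021,
    )


@dataclass(frozen=True)
class LineGroup:
    """Weak-coupling line list for one compound: (shift ppm, relative amp)."""

    metabolite_name: str
    lines: tuple[tuple[float, float], ...]
    t2_star: float = 0.06

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError(f"{self.metabolite_name}: at least one line required")
        if not sum(a for _, a in self.lines) > 0:
            raise ValueError(f"{self.metabolite_name}: relative amplitudes must sum > 0")


# 17 simulated compounds; tCho = GPC + PCho and tCr = Cr + PCr are reported
# as sums downstream.  Synthetic line lists (literature shifts, proton-count
# weights), not a quantum simulation.
_RAW_LINES: dict[str, list[tuple[float, float]]] = {
    "Glc": [(3.43, 1), (3.47, 1), (3.53, 1), (3.70, 1), (3.82, 1)],
    "Asp": [(2.68, 1), (2.80, 1), (3.89, 1)],
    "GPC": [(3.21, 9), (3.68, 2), (3.90, 2)],
    "PCho": [(3.22, 9), (3.58, 2), (4.16, 2)],
    "Cr": [(3.03, 3), (3.91, 2)],
    "PCr": [(3.03, 3), (3.93, 2)],
    "GABA": [(1.89, 2), (2.28, 2), (3.01, 2)],
    "Glu": [(2.08, 2), (2.35, 2), (3.75, 1)],
    "Gln": [(2.13, 2), (2.45, 2), (3.77, 1)],
    "GSH": [(2.15, 2), (2.55, 2), (2.95, 2), (3.77, 1)],
    "Gly": [(3.55, 2)],
    "Lac": [(1.31, 3), (4.10, 1)],
    "Ins": [(3.27, 1), (3.52, 2), (3.61, 2), (4.05, 1)],
    "NAA": [(2.01, 3), (2.49, 1), (2.67, 1)],
    "NAAG": [(2.04, 3), (2.19, 2), (2.52, 2), (3.78, 1)],
    "sIns": [(3.34, 6)],
    "Tau": [(3.25, 2), (3.42, 2)],
}

METABOLITE_NAMES: tuple[str, ...] = tuple(_RAW_LINES)

#: Compound groups reported as sums (LCModel convention).
REPORTING_SUMS: dict[str, tuple[str, ...]] = {
    "tCho": ("GPC", "PCho"),
    "tCr": ("Cr", "PCr"),
}


def default_metabolite_groups() -> list[LineGroup]:
    """The 17 simulated metabolite line groups, unit-normalized amplitudes."""
    groups = []
    for name, lines in _RAW_LINES.items():
        total = sum(a for _, a in lines)
        groups.append(
            LineGroup(name, tuple((ppm, a / total) for ppm, a in lines))
        )
    return groups


# ---------------------------------------------------------------------------
# MM ground truth
# ---------------------------------------------------------------------------

# Default truth amplitudes / widths.  The printed record fixes only the nine
# positions; amplitudes follow the visual prominence order MM1 >= MM9 >=
# MM5 > others and FWHMs span 0.04-0.12 ppm.  Fixture choices, labeled such.
_MM_DEFAULT_AMPLITUDE = {
    "MM1": 1.00, "MM2": 0.45, "MM3": 0.40, "MM4": 0.35, "MM5": 0.70,
    "MM6": 0.40, "MM7": 0.45, "MM8": 0.40, "MM9": 0.75,
}
_MM_DEFAULT_FWHM_PPM = {
    "MM1": 0.050, "MM2": 0.060, "MM3": 0.070, "MM4": 0.090, "MM5": 0.070,
    "MM6": 0.100, "MM7": 0.070, "MM8": 0.060, "MM9": 0.100,
}


@dataclass(frozen=True)
class MMTruth:
    """Ground truth for a synthetic metabolite-nulled MM spectrum.

    Nine Gaussian components pinned to the canonical MM1..MM9 chemical
    shifts (0.90, 1.21, 1.43, 1.67, 2.04, 2.26, 2.99, 3.21, 3.77 ppm).
    """

    components: tuple[GaussianComponent, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) != 9:
            raise ValueError("MMTruth requires exactly 9 components")
        for comp in self.components:
            want = MM_CENTERS_PPM.get(comp.name)
            if want is None:
                raise ValueError(f"unknown MM component {comp.name!r}")
            if abs(comp.center_ppm - want) > 1e-12:
                raise ValueError(
                    f"{comp.name} center must be {want} ppm, got {comp.center_ppm}"
                )
            if not comp.amplitude > 0:
                raise ValueError(f"{comp.name}: truth amplitude must be > 0")

    @classmethod
    def default(cls, acq: AcquisitionParams, seed: int = 0) -> "MMTruth":
        comps = tuple(
            GaussianComponent(
                name=name,
                center_ppm=MM_CENTERS_PPM[name],
                fwhm_hz=_MM_DEFAULT_FWHM_PPM[name] * acq.transmitter_frequency,
                amplitude=_MM_DEFAULT_AMPLITUDE[name],
            )
            for name in MM_NAMES
        )
        return cls(components=comps, seed=seed)

    def amplitude(self, name: str) -> float:
        for comp in self.components:
            if comp.name == name:
                return comp.amplitude
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_metabolite_fid(
    group: LineGroup,
    acq: AcquisitionParams,
    n_truncate: int = DEFAULT_N_TRUNCATE,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> FIDSignal:
    """Hard-pulse FID simulation of one compound with initial-point removal.

    The signal is simulated on an internal grid oversampled by
    ``oversampling`` (default 5, i.e. 30 kHz for a 6 kHz acquisition), its
    first ``n_truncate`` internal points are dropped (39 points at 30 kHz
    = 1.3 ms, emulating the acquisition delay), and the remainder is
    decimated back to the acquisition grid.  Deterministic and exactly
    linear in the line amplitudes.
    """
    if n_truncate < 0 or n_truncate >= acq.n_points * oversampling:
        raise ValueError("n_truncate out of range")
    half_bw = acq.bandwidth / 2.0
    dwell_int = acq.dwell_time / oversampling
    t = (n_truncate + oversampling * np.arange(acq.n_points)) * dwell_int
    samples = np.zeros(acq.n_points, dtype=complex)
    for ppm, amp in group.lines:
        f = acq.ppm_to_hz(ppm)
        if not (-half_bw <= f < half_bw):
            raise ValueError(
                f"{group.metabolite_name}: line at {ppm} ppm ({f:.1f} Hz) "
                f"outside +/-{half_bw:.0f} Hz"
            )
        samples += amp * np.exp((2j * np.pi * f - 1.0 / group.t2_star) * t)
    return FIDSignal(samples, acq)


def _mm_signal(truth: MMTruth, acq: AcquisitionParams) -> np.ndarray:
    total = np.zeros(acq.n_points, dtype=complex)
    for comp in truth.components:
        total += gaussian_component_fid(comp, acq).samples
    return total


def _complex_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    return sd * (rng.standard_normal(n) + 1j * rng.standard_normal(n))


def generate_mm_fid(
    truth: MMTruth,
    acq: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FIDSignal:
    """Nine-Gaussian MM FID plus complex white Gaussian noise.

    Component j contributes ``A_j exp(i phi_j) exp(2 pi i f_j t - beta_j t^2)``
    with ``beta_j = (pi FWHM_j)^2 / (4 ln 2)``.  ``noise_sd`` is the
    per-channel (real/imag) time-domain noise SD.  Bit-reproducible for a
    fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    samples = _mm_signal(truth, acq)
    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        samples = samples + _complex_noise(rng, acq.n_points, noise_sd)
    return FIDSignal(samples, acq)


def _residual_components(truth: MMTruth, acq: AcquisitionParams, residual_scale: float):
    a_mm1 = truth.amplitude("MM1")
    fwhm_hz = 0.02 * acq.transmitter_frequency  # narrow metabolite-like lines
    return [
        GaussianComponent(
            name=f"res{ppm:.2f}",
            center_ppm=ppm,
            fwhm_hz=fwhm_hz,
            amplitude=residual_scale * a_mm1,
        )
        for ppm in RESIDUAL_POSITIONS_PPM
    ]


def generate_metabolite_nulled_spectrum(
    truth: MMTruth,
    residual_scale: float,
    acq: AcquisitionParams,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> FIDSignal:
    """MM FID plus the five narrow metabolite residuals of nulling.

    Residual lines sit at 2.01, 3.52, 2.30, 2.45 and 3.98 ppm (NAA, Ins,
    Glu, Gln, tCr) with amplitude ``residual_scale`` relative to MM1.  With
    ``residual_scale = 0`` the output equals :func:`generate_mm_fid` for
    the same seed, bit for bit.
    """
    if not 0.0 <= residual_scale <= 0.5:
        raise ValueError("residual_scale must be in [0, 0.5]")
    samples = _mm_signal(truth, acq)
    if residual_scale > 0:
        for comp in _residual_components(truth, acq, residual_scale):
            samples = samples + gaussian_component_fid(comp, acq).samples
    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        samples = samples + _complex_noise(rng, acq.n_points, noise_sd)
    return FIDSignal(samples, acq)


def mm_noise_sd_for_snr(truth: MMTruth, acq: AcquisitionParams, snr: float) -> float:
    """Time-domain noise SD giving the requested spectral SNR for MM1.

    SNR follows the measurement convention height / (2 * spectral noise
    SD); unnormalized-DFT noise has real-part SD ``sigma_t * sqrt(n)``.
    """
    spec = fid_to_spectrum(generate_mm_fid(truth, acq, 0.0))
    height = float(np.max(spec.values.real[spec.window(0.2, 4.2)]))
    return height / (2.0 * snr * math.sqrt(acq.n_points))


# ---------------------------------------------------------------------------
# MRSI phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Everything the phantom generator decided: per-voxel amplitudes,
    tissue fractions, mask, frequency offsets, and the noise level."""

    amplitudes: dict[str, np.ndarray]
    f_gm: np.ndarray
    f_wm: np.ndarray
    f_csf: np.ndarray
    mask: np.ndarray
    gm_share: np.ndarray
    freq_offset_hz: np.ndarray
    contrast_rules: dict[str, tuple[float, float]]
    noise_sd: float
    seed: int


def default_contrast_rules(truth: MMTruth) -> dict[str, tuple[float, float]]:
    """Default (intercept, GM-slope) amplitude rules per basis component.

    Amplitude of component c in a voxel is ``intercept_c + slope_c * g``
    with ``g = f_GM/(f_GM+f_WM)`` the CSF-free GM fraction.  Metabolite
    numbers give a brain-like spectrum (NAA dominant, GM/WM contrast for
    Glu and tCr); MM components ride mostly on GM except MM8 (higher in
    WM).  Fixture choices.
    """
    rules: dict[str, tuple[float, float]] = {
        "NAA": (1.00, 0.10),
        "NAAG": (0.20, -0.10),
        "Cr": (0.30, 0.25),
        "PCr": (0.28, 0.20),
        "GPC": (0.16, -0.04),
        "PCho": (0.14, -0.04),
        "Glu": (0.55, 0.45),
        "Gln": (0.18, 0.10),
        "Ins": (0.45, 0.15),
        "GSH": (0.12, 0.05),
        "GABA": (0.10, 0.08),
        "Glc": (0.10, 0.00),
        "Asp": (0.15, 0.05),
        "Gly": (0.06, 0.02),
        "Lac": (0.06, 0.00),
        "sIns": (0.05, 0.00),
        "Tau": (0.12, 0.10),
    }
    for comp in truth.components:
        if comp.name == "MM8":
            rules[comp.name] = (1.1 * comp.amplitude, -0.4 * comp.amplitude)
        else:
            rules[comp.name] = (0.7 * comp.amplitude, 0.6 * comp.amplitude)
    return rules


def _brain_tissue_pattern(matrix: int):
    """Elliptical 'brain': WM core, GM cortex band, small central CSF blob."""
    coord = (np.arange(matrix) - (matrix - 1) / 2.0) / (matrix / 2.0)
    x, y = np.meshgrid(coord, coord, indexing="ij")
    r = np.sqrt(x**2 + y**2)
    mask = r <= 0.9
    f_csf = 0.8 * np.exp(-((r / 0.12) ** 2))
    g = 0.15 + 0.75 / (1.0 + np.exp(-(r - 0.60) / 0.08))
    f_gm = (1.0 - f_csf) * g
    f_wm = (1.0 - f_csf) * (1.0 - g)
    for arr in (f_csf, f_gm, f_wm):
        arr[~mask] = 0.0
    return mask, f_gm, f_wm, f_csf


def _uniform_tissue_pattern(matrix: int):
    """Constant 60/40 GM/WM everywhere inside the elliptical mask."""
    coord = (np.arange(matrix) - (matrix - 1) / 2.0) / (matrix / 2.0)
    x, y = np.meshgrid(coord, coord, indexing="ij")
    mask = np.sqrt(x**2 + y**2) <= 0.9
    f_gm = np.where(mask, 0.6, 0.0)
    f_wm = np.where(mask, 0.4, 0.0)
    f_csf = np.zeros_like(f_gm)
    return mask, f_gm, f_wm, f_csf


_TISSUE_PATTERNS = {"brain": _brain_tissue_pattern, "uniform": _uniform_tissue_pattern}

LIPID_LINES = (("Lip09", 0.9, 0.15), ("Lip13", 1.3, 0.15))  # name, ppm, FWHM ppm


def _lipid_fid(ppm: float, fwhm_ppm: float, acq: AcquisitionParams) -> np.ndarray:
    f = acq.ppm_to_hz(ppm)
    d = math.pi * fwhm_ppm * acq.transmitter_frequency  # Lorentzian damping
    t = acq.time_axis
    return np.exp((2j * np.pi * f - d) * t)


def generate_mrsi_phantom(
    matrix: int = 64,
    acq: AcquisitionParams | None = None,
    tissue_pattern: str = "brain",
    contrast_rules: dict[str, tuple[float, float]] | None = None,
    lipid_ring: bool = True,
    noise_sd: float = 0.0,
    seed: int = 0,
    mm_truth: MMTruth | None = None,
    freq_offset_max_hz: float = 2.0,
    n_truncate: int = DEFAULT_N_TRUNCATE,
) -> tuple[MRSIGrid, PhantomTruth]:
    """Simulate a 2D FID-MRSI slice with known per-voxel amplitudes.

    Each in-mask voxel is a linear combination of the 17 simulated
    metabolite FIDs and the nine MM Gaussians, with amplitudes set by the
    contrast rules on the CSF-free GM fraction, an optional broad lipid
    pair (0.9/1.3 ppm, 10x MM1) in the outermost 2-voxel rim, a small
    per-voxel frequency offset, and complex white noise.

    Returns the grid and a :class:`PhantomTruth` recording every decision.
    """
    if matrix < 8 or (matrix & (matrix - 1)) != 0:
        raise ValueError("matrix must be a square power of two >= 8")
    if acq is None:
        acq = default_acquisition()
    if mm_truth is None:
        mm_truth = MMTruth.default(acq, seed=seed)
    if contrast_rules is None:
        contrast_rules = default_contrast_rules(mm_truth)
    try:
        pattern = _TISSUE_PATTERNS[tissue_pattern]
    except KeyError:
        raise ValueError(f"unknown tissue_pattern {tissue_pattern!r}") from None
    mask, f_gm, f_wm, f_csf = pattern(matrix)

    tissue = f_gm + f_wm
    g = np.where(tissue > 0, f_gm / np.where(tissue > 0, tissue, 1.0), 0.0)

    # unit component shapes
    unit_fids: dict[str, np.ndarray] = {}
    for group in default_metabolite_groups():
        if group.metabolite_name in contrast_rules:
            unit_fids[group.metabolite_name] = simulate_metabolite_fid(
                group, acq, n_truncate=n_truncate
            ).samples
    mm_unit = {
        comp.name: gaussian_component_fid(
            GaussianComponent(comp.name, comp.center_ppm, comp.fwhm_hz, 1.0, comp.phase_deg),
            acq,
        ).samples
        for comp in mm_truth.components
    }
    unit_fids.update({k: v for k, v in mm_unit.items() if k in contrast_rules})

    names = [n for n in contrast_rules if n in unit_fids]
    units = np.stack([unit_fids[n] for n in names])  # (C, n)

    amplitudes: dict[str, np.ndarray] = {}
    amp_matrix = np.zeros((matrix, matrix, len(names)))
    for c, name in enumerate(names):
        intercept, slope = contrast_rules[name]
        amp = np.clip(intercept + slope * g, 0.0, None) * mask
        amplitudes[name] = amp
        amp_matrix[:, :, c] = amp

    fids = amp_matrix.reshape(-1, len(names)) @ units
    fids = fids.reshape(matrix, matrix, acq.n_points)

    if lipid_ring:
        eroded = ndimage.binary_erosion(mask, iterations=2)
        rim = mask & ~eroded
        lipid_amp = 10.0 * mm_truth.amplitude("MM1")
        for name, ppm, fwhm_ppm in LIPID_LINES:
            amp = np.where(rim, lipid_amp, 0.0)
            amplitudes[name] = amp
            fids += amp[:, :, None] * _lipid_fid(ppm, fwhm_ppm, acq)[None, None, :]

    rng = np.random.default_rng(seed)
    offsets = np.where(mask, rng.uniform(-freq_offset_max_hz, freq_offset_max_hz, mask.shape), 0.0)
    if freq_offset_max_hz > 0:
        ramp = np.exp(2j * np.pi * offsets[:, :, None] * acq.time_axis[None, None, :])
        fids = fids * ramp
    if noise_sd > 0:
        fids = fids + noise_sd * (
            rng.standard_normal(fids.shape) + 1j * rng.standard_normal(fids.shape)
        )

    grid = MRSIGrid(
        fids=fids, mask=mask, f_gm=f_gm, f_wm=f_wm, f_csf=f_csf, acq=acq,
        freq_offset_hz=offsets,
    )
    truth = PhantomTruth(
        amplitudes=amplitudes,
        f_gm=f_gm, f_wm=f_wm, f_csf=f_csf, mask=mask,
        gm_share=g,
        freq_offset_hz=offsets,
        contrast_rules=dict(contrast_rules),
        noise_sd=noise_sd,
        seed=seed,
    )
    return grid, truth


def phantom_noise_sd_for_snr(
    snr: float,
    acq: AcquisitionParams | None = None,
    mm_truth: MMTruth | None = None,
    n_truncate: int = DEFAULT_N_TRUNCATE,
) -> float:
    """Time-domain noise SD giving a target NAA spectral SNR in a typical voxel.

    Uses the default contrast rules at GM share 0.5 and the NAA peak height
    of the corresponding noiseless voxel spectrum.
    """
    if acq is None:
        acq = default_acquisition()
    if mm_truth is None:
        mm_truth = MMTruth.default(acq)
    rules = default_contrast_rules(mm_truth)
    groups = {grp.metabolite_name: grp for grp in default_metabolite_groups()}
    intercept, slope = rules["NAA"]
    amp = intercept + 0.5 * slope
    fid = simulate_metabolite_fid(groups["NAA"], acq, n_truncate=n_truncate)
    spec = fid_to_spectrum(FIDSignal(amp * fid.samples, acq))
    # truncation phase-twists the lineshape; magnitude height is robust
    height = float(np.max(np.abs(spec.values[spec.window(1.9, 2.1)])))
    return height / (2.0 * snr * math.sqrt(acq.n_points))
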