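"""Voxel-wise quantification of an MRSI grid, QA filtering, component
maps, tissue-fraction downsampling, and GM-fraction regression.

QA follows the conjunctive rule: a voxel is auto-excluded only when
*both* the NAA Cramér–Rao bound exceeds 30% *and* the NAA line width
exceeds 20 Hz (strict inequalities).  Voxels failing a single criterion
are flagged for visual inspection, never auto-excluded — flagging keeps
the pipeline deterministic.

Tissue fractions at MRSI resolution come from k-space truncation of the
high-resolution segmentation: Fourier transform, central crop to the
MRSI matrix (optionally with an elliptical k-space mask mirroring
elliptical sampling), inverse transform, clip to [0, 1].  This matches
the MRSI point-spread function instead of simple block averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .basis import BasisSet
from .core import fid_to_spectrum
from .grid import MRSIGrid
from .lcfit import LCFitOptions, LCFitResult, lc_fit

__all__ = [
    "GridFitResults",
    "QAResult",
    "ComponentMap",
    "quantify_grid",
    "qa_filter",
    "make_map",
    "downsample_tissue_maps",
    "gm_fraction_regression",
    "write_component_map_nifti",
    "results_long_table",
]

FWHM_LIMIT_HZ = 20.0
CRLB_LIMIT_PERCENT = 30.0
CSF_LIMIT_FRACTION = 0.20


@dataclass
class GridFitResults:
    """Per-voxel LC fit results over a grid; ``results[i][j]`` is None
    outside the mask or where the fit failed (failures are recorded,
    never abort the grid)."""

    results: list[list[LCFitResult | None]]
    grid: MRSIGrid
    basis: BasisSet
    failures: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def matrix(self) -> int:
        return self.grid.matrix

    def voxel(self, i: int, j: int) -> LCFitResult | None:
        return self.results[i][j]

    def fitted_indices(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i in range(self.matrix)
            for j in range(self.matrix)
            if self.results[i][j] is not None
        ]


@dataclass
class QAResult:
    """Per-voxel QA decisions plus the stats they were based on."""

    excluded: np.ndarray
    reason: np.ndarray  # "none" | "auto" | "flagged_single_criterion"
    crlb_naa: np.ndarray
    fwhm_naa: np.ndarray
    fwhm_limit_hz: float
    crlb_limit_percent: float


@dataclass
class ComponentMap:
    component: str
    values: np.ndarray  # NaN where masked / excluded / above CRLB threshold

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def quantify_grid(
    grid: MRSIGrid,
    basis: BasisSet,
    opts: LCFitOptions | None = None,
) -> GridFitResults:
    """LC-fit every masked voxel independently (order-invariant)."""
    if not np.any(grid.mask):
        raise ValueError("grid mask is empty")
    m = grid.matrix
    results: list[list[LCFitResult | None]] = [[None] * m for _ in range(m)]
    failures: dict[tuple[int, int], str] = {}
    for i, j in grid.masked_indices():
        try:
            spec = fid_to_spectrum(grid.voxel_fid(i, j))
            results[i][j] = lc_fit(spec, basis, opts)
        except Exception as exc:  # record, never abort the grid
            failures[(i, j)] = str(exc)
    return GridFitResults(results=results, grid=grid, basis=basis, failures=failures)


def _naa_crlb(result: LCFitResult) -> float:
    """NAA CRLB in percent; falls back to the first NAA-like entry name."""
    if "NAA" in result.crlb_percent:
        return result.crlb_percent["NAA"]
    raise KeyError("results contain no NAA entry")


def qa_filter(
    fits: GridFitResults,
    fwhm_limit_hz: float = FWHM_LIMIT_HZ,
    crlb_limit_percent: float = CRLB_LIMIT_PERCENT,
) -> QAResult:
    """Conjunctive auto-exclusion; single-criterion voxels only flagged.

    Auto-excluded iff ``CRLB_NAA > crlb_limit`` AND ``FWHM_NAA >
    fwhm_limit`` (both strict).  A voxel at exactly the limits is
    retained unflagged.
    """
    m = fits.matrix
    excluded = np.zeros((m, m), dtype=bool)
    reason = np.full((m, m), "none", dtype=object)
    crlb_naa = np.full((m, m), np.nan)
    fwhm_naa = np.full((m, m), np.nan)
    for i, j in fits.fitted_indices():
        r = fits.voxel(i, j)
        c = _naa_crlb(r)
        w = r.fwhm_naa_hz
        crlb_naa[i, j] = c
        fwhm_naa[i, j] = w
        bad_c = c > crlb_limit_percent
        bad_w = w > fwhm_limit_hz
        if bad_c and bad_w:
            excluded[i, j] = True
            reason[i, j] = "auto"
        elif bad_c or bad_w:
            reason[i, j] = "flagged_single_criterion"
    return QAResult(
        excluded=excluded,
        reason=reason,
        crlb_naa=crlb_naa,
        fwhm_naa=fwhm_naa,
        fwhm_limit_hz=fwhm_limit_hz,
        crlb_limit_percent=crlb_limit_percent,
    )


def make_map(
    fits: GridFitResults,
    qa: QAResult,
    component: str,
    crlb_threshold_percent: float = CRLB_LIMIT_PERCENT,
) -> ComponentMap:
    """Amplitude map of one component; undefined (NaN) where the voxel is
    unmasked/unfitted, auto-excluded, or the component CRLB exceeds the
    display threshold."""
    if component not in fits.basis.entries:
        raise ValueError(f"unknown component {component!r}")
    m = fits.matrix
    values = np.full((m, m), np.nan)
    for i, j in fits.fitted_indices():
        if qa.excluded[i, j]:
            continue
        r = fits.voxel(i, j)
        if r.crlb_percent.get(component, np.inf) > crlb_threshold_percent:
            continue
        values[i, j] = r.amplitudes[component]
    return ComponentMap(component=component, values=values)


def downsample_tissue_maps(
    highres_maps,
    target_matrix: int,
    elliptical_k: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Downsample GM/WM/CSF probability maps to MRSI resolution via
    k-space truncation.

    Each high-resolution map (square, side >= target and an integer
    multiple of it) is 2D-DFTed, centrally cropped to
    ``target_matrix x target_matrix`` (k-space center at index n/2,
    0-based row-major), optionally masked with an inscribed ellipse, and
    inverse-transformed; the real part is clipped to [0, 1] and the three
    fractions are renormalized per voxel only where they sum above 1.
    The DC term — the image mean — is preserved exactly before clipping.
    """
    maps = [np.asarray(m, dtype=float) for m in highres_maps]
    if len(maps) != 3:
        raise ValueError("expected three probability maps (GM, WM, CSF)")
    H = maps[0].shape[0]
    for m in maps:
        if m.shape != (H, H):
            raise ValueError("tissue maps must be square and share a shape")
        if m.min() < 0 or m.max() > 1.001:
            raise ValueError("tissue maps must contain probabilities in [0, 1]")
    if H < target_matrix or H % target_matrix:
        raise ValueError("high-res matrix must be a multiple of the target matrix")

    lo = H // 2 - target_matrix // 2
    hi = lo + target_matrix
    if elliptical_k:
        c = (np.arange(target_matrix) - target_matrix // 2) / (target_matrix / 2.0)
        kx, ky = np.meshgrid(c, c, indexing="ij")
        kmask = kx**2 + ky**2 <= 1.0
    out = []
    scale = (target_matrix / H) ** 2
    for m in maps:
        K = np.fft.fftshift(np.fft.fft2(m))
        Kc = K[lo:hi, lo:hi]
        if elliptical_k:
            Kc = Kc * kmask
        img = np.fft.ifft2(np.fft.ifftshift(Kc)).real * scale
        out.append(img)
    gm, wm, csf = (np.clip(m, 0.0, 1.0) for m in out)
    total = gm + wm + csf
    over = total > 1.0
    for m in (gm, wm, csf):
        m[over] /= total[over]
    return gm, wm, csf


def gm_fraction_regression(
    cmap: ComponentMap,
    grid: MRSIGrid,
    csf_limit: float = CSF_LIMIT_FRACTION,
    min_voxels: int = 10,
):
    """OLS regression of a component amplitude on the GM fraction.

    The GM fraction is CSF-free, f_GM/(f_GM+f_WM).  Voxels with CSF
    fraction above ``csf_limit`` are excluded (the map already encodes
    the CRLB display threshold).  Returns (slope, intercept, r).
    """
    g = grid.gm_share
    eligible = cmap.defined & (grid.f_csf <= csf_limit) & np.isfinite(g)
    n = int(np.sum(eligible))
    if n < min_voxels:
        raise ValueError(f"insufficient data: {n} eligible voxels < {min_voxels}")
    x = g[eligible]
    y = cmap.values[eligible]
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate GM fraction: no variation across eligible voxels")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_component_map_nifti(path: str | Path, cmap: ComponentMap,
                              voxel_size_mm: float = 3.4) -> None:
    """Write a component map as a single-volume NIfTI image."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm, voxel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(cmap.values.astype(np.float32)[..., None], affine)
    nib.save(img, str(path))


def results_long_table(fits: GridFitResults, qa: QAResult):
    """Long-format DataFrame: one row per fitted voxel and component."""
    import pandas as pd

    rows = []
    for i, j in fits.fitted_indices():
        r = fits.voxel(i, j)
        for name, amp in r.amplitudes.items():
            rows.append({
                "row": i, "col": j, "component": name,
                "amplitude": amp,
                "crlb_percent": r.crlb_percent[name],
                "fwhm_naa_hz": r.fwhm_naa_hz,
                "snr_naa": r.snr_naa,
                "excluded": bool(qa.excluded[i, j]),
                "qa_reason": str(qa.reason[i, j]),
                "f_gm": fits.grid.f_gm[i, j],
                "f_wm": fits.grid.f_wm[i, j],
                "f_csf": fits.grid.f_csf[i, j],
            })
    return pd.DataFrame(rows)
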