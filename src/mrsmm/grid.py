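"""2D MRSI grid container: a matrix of FIDs plus mask and tissue fractions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AcquisitionParams, FIDSignal

__all__ = ["MRSIGrid"]


@dataclass
class MRSIGrid:
    """A square grid of FIDs with per-voxel mask and GM/WM/CSF fractions.

    ``fids`` has shape (matrix, matrix, n_points); voxel indices are
    0-based and row-major.  Tissue fractions are probabilities in [0, 1]
    summing to at most 1 per voxel (the remainder is non-brain).
    """

    fids: np.ndarray
    mask: np.ndarray
    f_gm: np.ndarray
    f_wm: np.ndarray
    f_csf: np.ndarray
    acq: AcquisitionParams
    freq_offset_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fids = np.asarray(self.fids, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("f_gm", "f_wm", "f_csf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        m1, m2, n = self.fids.shape
        if m1 != m2:
            raise ValueError("grid must be square")
        if n != self.acq.n_points:
            raise ValueError("FID length does not match acq.n_points")
        for name in ("mask", "f_gm", "f_wm", "f_csf"):
            if getattr(self, name).shape != (m1, m2):
                raise ValueError(f"{name} shape mismatch")
        frac = self.f_gm + self.f_wm + self.f_csf
        if np.any(self.f_gm < 0) or np.any(self.f_wm < 0) or np.any(self.f_csf < 0):
            raise ValueError("tissue fractions must be non-negative")
        if np.any(frac > 1.0001):
            raise ValueError("tissue fractions must sum to <= 1 per voxel")
        if not np.all(np.isfinite(self.fids[self.mask])):
            raise ValueError("masked voxels must contain finite FIDs")

    @property
    def matrix(self) -> int:
        return self.fids.shape[0]

    @property
    def gm_share(self) -> np.ndarray:
        """CSF-free gray-matter fraction f_GM / (f_GM + f_WM), NaN where no tissue."""
        tissue = self.f_gm + self.f_wm
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tissue > 0, self.f_gm / np.where(tissue > 0, tissue, 1.0), np.nan)
        return out

    def voxel_fid(self, i: int, j: int) -> FIDSignal:
        return FIDSignal(self.fids[i, j], self.acq)

    def masked_indices(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.mask)]

    # -- container I/O ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the grid to an HDF5 container (documented layout)."""
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("fids", data=self.fids)
            h5.create_dataset("mask", data=self.mask)
            h5.create_dataset("f_gm", data=self.f_gm)
            h5.create_dataset("f_wm", data=self.f_wm)
            h5.create_dataset("f_csf", data=self.f_csf)
            if self.freq_offset_hz is not None:
                h5.create_dataset("freq_offset_hz", data=self.freq_offset_hz)
            a = h5.attrs
            a["dwell_time"] = self.acq.dwell_time
            a["n_points"] = self.acq.n_points
            a["transmitter_frequency"] = self.acq.transmitter_frequency
            a["reference_ppm"] = self.acq.reference_ppm
            a["te_star"] = self.acq.te_star
            for key in ("tr", "ti1", "ti2"):
                val = getattr(self.acq, key)
                if val is not None:
                    a[key] = val

    @classmethod
    def load(cls, path: str | Path) -> "MRSIGrid":
        import h5py

        with h5py.File(path, "r") as h5:
            optional = {
                key: float(h5.attrs[key])
                for key in ("tr", "ti1", "ti2")
                if key in h5.attrs
            }
            acq = AcquisitionParams(
                dwell_time=float(h5.attrs["dwell_time"]),
                n_points=int(h5.attrs["n_points"]),
                transmitter_frequency=float(h5.attrs["transmitter_frequency"]),
                reference_ppm=float(h5.attrs["reference_ppm"]),
                te_star=float(h5.attrs["te_star"]),
                **optional,
            )
            kw = {}
            if "freq_offset_hz" in h5:
                kw["freq_offset_hz"] = h5["freq_offset_hz"][...]
            return cls(
                fids=h5["fids"][...],
                mask=h5["mask"][...],
                f_gm=h5["f_gm"][...],
                f_wm=h5["f_wm"][...],
                f_csf=h5["f_csf"][...],
                acq=acq,
                **kw,
            )
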