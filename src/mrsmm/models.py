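"""Shared parameter types for macromolecule (MM) models.

The MM background of short-TE* brain spectra at 7 T resolves into nine
distinct peaks between ~0.9 and ~3.8 ppm (MM1..MM9; the ~4.3 ppm MM10 sits
too close to water to parameterize).  Two parameterizations of a
metabolite-nulled spectrum are supported — Gaussian peaks fitted with
prior knowledge (AMARES-style, :mod:`mrsmm.amares`) and damped sinusoids
from a Hankel-SVD state-space decomposition (HLSVD-style,
:mod:`mrsmm.hlsvd`) — and both are carried around as :class:`MMModel`
instances that the basis builder turns into complete fitting basis sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import AcquisitionParams, FIDSignal

__all__ = [
    "MM_CENTERS_PPM",
    "MM_NAMES",
    "MM_GROUPS",
    "MM_VARIANTS",
    "GaussianComponent",
    "DampedSinusoid",
    "RatioPrior",
    "MMModel",
    "gaussian_beta",
    "gaussian_component_fid",
    "damped_sinusoid_fid",
]

#: Chemical shifts (ppm) of the nine parameterizable MM peaks.
MM_CENTERS_PPM: dict[str, float] = {
    "MM1": 0.90,
    "MM2": 1.21,
    "MM3": 1.43,
    "MM4": 1.67,
    "MM5": 2.04,
    "MM6": 2.26,
    "MM7": 2.99,
    "MM8": 3.21,
    "MM9": 3.77,
}

MM_NAMES: tuple[str, ...] = tuple(MM_CENTERS_PPM)

#: Grouping of the nine peaks into four groups (0.9-1.6, 2.04-2.26,
#: 2.99-3.21 ppm bands plus the lone 3.77 ppm peak).
MM_GROUPS: dict[str, tuple[str, ...]] = {
    "MM1-MM4": ("MM1", "MM2", "MM3", "MM4"),
    "MM5-MM6": ("MM5", "MM6"),
    "MM7-MM8": ("MM7", "MM8"),
    "MM9": ("MM9",),
}

#: The seven MM model variants: the full measured spectrum as one
#: component, individual components from either parameterization, grouped
#: components, and individual components with soft concentration-ratio
#: priors.
MM_VARIANTS: tuple[str, ...] = (
    "full_MM",
    "ind_MM_HL",
    "ind_MM_AM",
    "grp_MM_HL",
    "grp_MM_AM",
    "con_MM_HL",
    "con_MM_AM",
)

_VARIANT_CARDINALITY = {
    "full_MM": 1,
    "ind_MM_HL": 9,
    "ind_MM_AM": 9,
    "grp_MM_HL": 4,
    "grp_MM_AM": 4,
    "con_MM_HL": 9,
    "con_MM_AM": 9,
}


def gaussian_beta(fwhm_hz: float) -> float:
    """Gaussian time-domain decay rate beta (s^-2) for a given FWHM in Hz.

    A time-domain envelope exp(-beta t^2) Fourier-transforms to a Gaussian
    line of full width at half maximum ``fwhm = 2 sqrt(beta ln 2)/pi`` Hz,
    hence ``beta = (pi fwhm)^2 / (4 ln 2)``.
    """
    return (math.pi * fwhm_hz) ** 2 / (4.0 * math.log(2.0))


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian spectral component (the AMARES-style model atom)."""

    name: str
    center_ppm: float
    fwhm_hz: float
    amplitude: float
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.fwhm_hz > 0:
            raise ValueError(f"{self.name}: fwhm_hz must be positive")
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")


@dataclass(frozen=True)
class DampedSinusoid:
    """One damped complex sinusoid (the HLSVD-style model atom).

    ``s(t) = amplitude * exp(i phase) * exp((-damping + 2 pi i frequency) t)``
    with frequency in Hz (offset from the carrier) and damping in s^-1.
    A negative damping (growing signal) is physically suspect but is kept
    as estimated and merely flagged via :attr:`growing`.
    """

    frequency_hz: float
    damping: float
    amplitude: float
    phase_rad: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def growing(self) -> bool:
        return self.damping < 0

    @property
    def lorentzian_fwhm_hz(self) -> float:
        """FWHM of the equivalent Lorentzian line, damping/pi."""
        return abs(self.damping) / math.pi

    def center_ppm(self, acq: AcquisitionParams) -> float:
        return float(acq.hz_to_ppm(self.frequency_hz))


@dataclass(frozen=True)
class RatioPrior:
    """Soft prior on the amplitude ratio MM(XX)/MM1.

    MM1 (0.9 ppm) is the denominator throughout: it is easy to quantify
    and overlaps no metabolite resonance.  ``expected_ratio`` and ``sd``
    describe a Gaussian prior on the fitted amplitude ratio.
    """

    numerator: str
    expected_ratio: float
    sd: float
    denominator: str = "MM1"

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("ratio numerator must differ from the denominator (MM1)")
        if not self.expected_ratio > 0:
            raise ValueError("expected_ratio must be positive")
        if not self.sd > 0:
            raise ValueError("sd must be positive")


def gaussian_component_fid(comp: GaussianComponent, acq: AcquisitionParams) -> FIDSignal:
    """Time-domain signal of a single Gaussian component on the acq grid."""
    t = acq.time_axis
    f = acq.ppm_to_hz(comp.center_ppm)
    beta = gaussian_beta(comp.fwhm_hz)
    phase = np.deg2rad(comp.phase_deg)
    samples = comp.amplitude * np.exp(1j * phase) * np.exp(2j * np.pi * f * t - beta * t**2)
    return FIDSignal(samples, acq)


def damped_sinusoid_fid(atom: DampedSinusoid, acq: AcquisitionParams) -> FIDSignal:
    """Time-domain signal of a single damped sinusoid on the acq grid."""
    t = acq.time_axis
    samples = (
        atom.amplitude
        * np.exp(1j * atom.phase_rad)
        * np.exp((-atom.damping + 2j * np.pi * atom.frequency_hz) * t)
    )
    return FIDSignal(samples, acq)


@dataclass(frozen=True)
class MMModel:
    """A named MM model variant: component basis FIDs plus metadata.

    ``components`` maps component names to as-fitted FIDs (parameterized
    amplitudes embedded); ``params`` records the fitted parameter atoms
    (:class:`GaussianComponent` or :class:`DampedSinusoid`) keyed the same
    way.  ``ratio_priors`` is present only for the con_* variants.
    """

    variant: str
    components: dict[str, FIDSignal]
    acq: AcquisitionParams
    provenance: str = ""
    params: dict[str, object] = field(default_factory=dict)
    ratio_priors: tuple[RatioPrior, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in MM_VARIANTS:
            raise ValueError(f"unknown MM variant {self.variant!r}")
        want = _VARIANT_CARDINALITY[self.variant]
        if len(self.components) != want:
            raise ValueError(
                f"{self.variant} requires exactly {want} components, got {len(self.components)}"
            )
        if self.variant.startswith("con_"):
            if not self.ratio_priors:
                raise ValueError(f"{self.variant} requires ratio_priors")
        elif self.ratio_priors:
            raise ValueError(f"{self.variant} must not carry ratio_priors")

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(self.components)

    def component_amplitude(self, name: str) -> float:
        """Parameterized amplitude of a component (1.0 if unrecorded)."""
        p = self.params.get(name)
        if isinstance(p, GaussianComponent):
            return p.amplitude
        if isinstance(p, DampedSinusoid):
            return p.amplitude
        return 1.0

    def with_ratio_priors(self, priors) -> "MMModel":
        """Return the con_* variant of an ind_* model with priors attached."""
        if not self.variant.startswith("ind_"):
            raise ValueError("ratio priors apply to individual-component models")
        variant = self.variant.replace("ind_", "con_")
        return replace(self, variant=variant, ratio_priors=tuple(priors))
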