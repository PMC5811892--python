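"""Assembly of complete fitting basis sets: 17 simulated metabolites plus
one of seven macromolecule model variants, optional lipids, and soft
concentration-ratio priors.

The seven MM variants are: the full measured-analog MM spectrum as a
single component (``full_MM``); the nine individual components from
either parameterization (``ind_MM_HL`` / ``ind_MM_AM``); the four groups
MM1–MM4 / MM5–MM6 / MM7–MM8 / MM9 (``grp_MM_HL`` / ``grp_MM_AM``); and
the individual components with soft ratio priors MM(XX)/MM1
(``con_MM_HL`` / ``con_MM_AM``).

Basis normalization: individual MM entries are divided by their
parameterized amplitude before entering the basis, so a fitted linear-
combination amplitude is on the same scale as the parameterization (and
as the ratio priors, which are derived from amplitude ratios of nulled
spectra).  The parameterized amplitudes are kept in
:attr:`BasisSet.mm_scale` for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .amares import PeakPrior, amares_fit, default_mm_priors
from .core import AcquisitionParams, FIDSignal
from .models import MM_GROUPS, MM_NAMES, MMModel, RatioPrior
from .synth import DEFAULT_N_TRUNCATE, LineGroup, simulate_metabolite_fid

__all__ = [
    "BasisSet",
    "build_basis",
    "group_mm_components",
    "derive_ratio_priors",
    "add_simulated_lipids",
    "full_mm_model",
    "write_basis",
    "read_basis",
    "DEFAULT_LIPID_SPEC",
]

#: Default simulated lipid components: (name, center ppm, FWHM ppm).
#: Broad Lorentzians covering the 0.9 and 1.2-1.4 ppm contamination bands;
#: the linear-combination fit gives them a wider shift freedom (+-0.05 ppm).
DEFAULT_LIPID_SPEC: tuple[tuple[str, float, float], ...] = (
    ("Lip09", 0.9, 0.15),
    ("Lip13", 1.3, 0.15),
)

N_METABOLITES = 17


@dataclass(frozen=True)
class BasisSet:
    """Named basis FIDs sharing one acquisition grid."""

    entries: dict[str, FIDSignal]
    acq: AcquisitionParams
    metabolite_names: tuple[str, ...]
    mm_variant: str
    n_truncate: int = DEFAULT_N_TRUNCATE
    ratio_priors: tuple[RatioPrior, ...] = ()
    mm_scale: dict[str, float] = field(default_factory=dict)
    lipid_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.metabolite_names) != N_METABOLITES:
            raise ValueError(f"basis requires {N_METABOLITES} metabolite entries")
        for name, fid in self.entries.items():
            if fid.acq != self.acq:
                raise ValueError(f"entry {name}: acquisition mismatch")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def mm_names(self) -> tuple[str, ...]:
        skip = set(self.metabolite_names) | set(self.lipid_names)
        return tuple(n for n in self.entries if n not in skip)

    def matrix(self) -> np.ndarray:
        """Stack entries as an (n_entries, n_points) complex array."""
        return np.stack([fid.samples for fid in self.entries.values()])


def build_basis(
    metabolite_groups: list[LineGroup],
    mm_model: MMModel,
    acq: AcquisitionParams,
    with_lipids: bool = False,
    n_truncate: int = DEFAULT_N_TRUNCATE,
    lipid_spec=DEFAULT_LIPID_SPEC,
) -> BasisSet:
    """Simulate the metabolite basis and attach one MM model variant.

    Metabolite FIDs are hard-pulse simulations with the first 39
    oversampled points removed (the TE* = 1.3 ms convention).  Individual
    MM components are unit-amplitude normalized (see module docstring);
    grouped and full_MM entries enter as assembled.
    """
    if len(metabolite_groups) != N_METABOLITES:
        raise ValueError(f"expected {N_METABOLITES} metabolite groups, got {len(metabolite_groups)}")
    if mm_model.acq != acq:
        raise ValueError("MM model acquisition grid differs from basis grid")

    entries: dict[str, FIDSignal] = {}
    met_names = []
    for group in metabolite_groups:
        name = group.metabolite_name
        if name in entries:
            raise ValueError(f"duplicate basis entry {name!r}")
        entries[name] = simulate_metabolite_fid(group, acq, n_truncate=n_truncate)
        met_names.append(name)

    mm_scale: dict[str, float] = {}
    individual = mm_model.variant.startswith(("ind_", "con_"))
    for name, fid in mm_model.components.items():
        if name in entries:
            raise ValueError(f"duplicate basis entry {name!r}")
        if individual:
            amp = mm_model.component_amplitude(name)
            if amp <= 0:
                raise ValueError(f"MM component {name} has non-positive amplitude")
            entries[name] = fid.scaled(1.0 / amp)
            mm_scale[name] = amp
        else:
            entries[name] = fid
            mm_scale[name] = 1.0

    basis = BasisSet(
        entries=entries,
        acq=acq,
        metabolite_names=tuple(met_names),
        mm_variant=mm_model.variant,
        n_truncate=n_truncate,
        ratio_priors=tuple(mm_model.ratio_priors or ()),
        mm_scale=mm_scale,
    )
    if with_lipids:
        basis = add_simulated_lipids(basis, lipid_spec)
    return basis


def group_mm_components(mm_model: MMModel) -> MMModel:
    """Combine nine individual MM components into the four groups.

    Groups are complex sums of the as-fitted member FIDs, so the relative
    amplitudes (and phases) within a group stay frozen at their
    parameterization values, and the sum over grouped FIDs equals the sum
    over individual FIDs exactly.
    """
    if set(mm_model.components) != set(MM_NAMES):
        missing = sorted(set(MM_NAMES) - set(mm_model.components))
        raise ValueError(f"grouping requires MM1..MM9; missing {missing}")
    if not mm_model.variant.startswith("ind_"):
        raise ValueError("grouping applies to ind_* models")
    acq = mm_model.acq
    grouped: dict[str, FIDSignal] = {}
    for gname, members in MM_GROUPS.items():
        total = np.zeros(acq.n_points, dtype=complex)
        for m in members:
            total = total + mm_model.components[m].samples
        grouped[gname] = FIDSignal(total, acq)
    return MMModel(
        variant=mm_model.variant.replace("ind_", "grp_"),
        components=grouped,
        acq=acq,
        provenance=mm_model.provenance,
        params={g: tuple(mm_model.params.get(m) for m in members)
                for g, members in MM_GROUPS.items()},
    )


def derive_ratio_priors(
    nulled_fids: list[FIDSignal],
    priors: list[PeakPrior] | None = None,
    sd_floor_frac: float = 0.10,
) -> list[RatioPrior]:
    """Amplitude-ratio priors MM(XX)/MM1 from a set of nulled spectra.

    Each spectrum gets a nine-peak fit; for every MM peak other than MM1
    the expected ratio is the across-spectra mean of amplitude(XX)/
    amplitude(MM1) and the sd is the sample SD, floored at
    ``sd_floor_frac`` of the mean so noiseless fixtures cannot produce a
    degenerate hard constraint.
    """
    if len(nulled_fids) < 2:
        raise ValueError("at least 2 nulled spectra required")
    if priors is None:
        priors = default_mm_priors()
    ratios: dict[str, list[float]] = {name: [] for name in MM_NAMES if name != "MM1"}
    for i, fid in enumerate(nulled_fids):
        fit = amares_fit(fid, priors)
        by_center = sorted(fit.components, key=lambda c: c.center_ppm)
        amps = {name: comp.amplitude for name, comp in zip(MM_NAMES, by_center)}
        if amps["MM1"] <= 0:
            warnings.warn(f"spectrum {i}: MM1 amplitude <= 0, excluded from ratio priors",
                          stacklevel=2)
            continue
        for name in ratios:
            ratios[name].append(amps[name] / amps["MM1"])
    out = []
    for name, values in ratios.items():
        if len(values) < 2:
            raise ValueError("fewer than 2 usable spectra for ratio priors")
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        out.append(RatioPrior(numerator=name, expected_ratio=mean,
                              sd=max(sd, sd_floor_frac * mean)))
    return out


def add_simulated_lipids(basis: BasisSet, lipid_spec=DEFAULT_LIPID_SPEC) -> BasisSet:
    """Append broad mobile-lipid components to a basis set."""
    t = basis.acq.time_axis
    entries = dict(basis.entries)
    lipid_names = list(basis.lipid_names)
    for name, ppm, fwhm_ppm in lipid_spec:
        if name in entries:
            raise ValueError(f"lipid entry name collision: {name!r}")
        f = basis.acq.ppm_to_hz(ppm)
        d = np.pi * fwhm_ppm * basis.acq.transmitter_frequency
        entries[name] = FIDSignal(np.exp((2j * np.pi * f - d) * t), basis.acq)
        lipid_names.append(name)
    return replace(basis, entries=entries, lipid_names=tuple(lipid_names))


def full_mm_model(cleaned_nulled_fids: list[FIDSignal]) -> MMModel:
    """The conventional single-component MM model: the average
    residual-cleaned metabolite-nulled FID (measured-analog)."""
    if not cleaned_nulled_fids:
        raise ValueError("at least one nulled FID required")
    acq = cleaned_nulled_fids[0].acq
    avg = np.mean([f.samples for f in cleaned_nulled_fids], axis=0)
    return MMModel(
        variant="full_MM",
        components={"MM": FIDSignal(avg, acq)},
        acq=acq,
        provenance="measured-analog",
    )


# ---------------------------------------------------------------------------
# Plain-text basis file (layout modeled on LCModel basis conventions)
# ---------------------------------------------------------------------------

def write_basis(path: str | Path, basis: BasisSet, name: str = "mrsmm") -> None:
    """Write a basis set as deterministic plain text.

    Header records (one per line) carry the acquisition and MM metadata,
    ``ratio_prior`` records mirror the soft-constraint idea of LCModel's
    CHRATO parameter, and each ``entry`` block holds real/imag columns.
    """
    lines = [
        "# mrsmm basis v1",
        f"name {name}",
        f"dwell_time {basis.acq.dwell_time:.17e}",
        f"transmitter_frequency_mhz {basis.acq.transmitter_frequency:.17e}",
        f"n_points {basis.acq.n_points}",
        f"reference_ppm {basis.acq.reference_ppm:.17e}",
        f"te_star {basis.acq.te_star:.17e}",
        f"n_truncate {basis.n_truncate}",
        f"mm_variant {basis.mm_variant}",
        f"metabolites {' '.join(basis.metabolite_names)}",
    ]
    if basis.lipid_names:
        lines.append(f"lipids {' '.join(basis.lipid_names)}")
    for rp in basis.ratio_priors:
        lines.append(f"ratio_prior {rp.numerator} {rp.expected_ratio:.17e} {rp.sd:.17e}")
    for mm_name, scale in basis.mm_scale.items():
        lines.append(f"mm_scale {mm_name} {scale:.17e}")
    for entry_name, fid in basis.entries.items():
        lines.append(f"entry {entry_name}")
        for s in fid.samples:
            lines.append(f"{s.real:.17e} {s.imag:.17e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_basis(path: str | Path) -> BasisSet:
    """Read a basis set written by :func:`write_basis`."""
    header: dict[str, str] = {}
    ratio_priors: list[RatioPrior] = []
    mm_scale: dict[str, float] = {}
    blocks: dict[str, list[complex]] = {}
    current: list[complex] | None = None
    lipids: tuple[str, ...] = ()
    metabolites: tuple[str, ...] = ()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        key = parts[0]
        if key == "entry":
            current = blocks.setdefault(parts[1], [])
        elif key == "ratio_prior":
            ratio_priors.append(RatioPrior(parts[1], float(parts[2]), float(parts[3])))
        elif key == "mm_scale":
            mm_scale[parts[1]] = float(parts[2])
        elif key == "metabolites":
            metabolites = tuple(parts[1:])
        elif key == "lipids":
            lipids = tuple(parts[1:])
        elif current is not None and len(parts) == 2:
            current.append(complex(float(parts[0]), float(parts[1])))
        else:
            header[key] = " ".join(parts[1:])
    acq = AcquisitionParams(
        dwell_time=float(header["dwell_time"]),
        n_points=int(header["n_points"]),
        transmitter_frequency=float(header["transmitter_frequency_mhz"]),
        reference_ppm=float(header["reference_ppm"]),
        te_star=float(header.get("te_star", 0.0)),
    )
    entries = {name: FIDSignal(np.array(vals), acq) for name, vals in blocks.items()}
    return BasisSet(
        entries=entries,
        acq=acq,
        metabolite_names=metabolites,
        mm_variant=header["mm_variant"],
        n_truncate=int(header["n_truncate"]),
        ratio_priors=tuple(ratio_priors),
        mm_scale=mm_scale,
        lipid_names=lipids,
    )
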