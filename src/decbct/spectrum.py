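"""Polychromatic X-ray tube spectra.

The default generator is the Kramers thin-target bremsstrahlung model,
N(E) proportional to (kVp - E)/E on a 1 keV grid, hardened by the tube's
inherent aluminum filtration via Beer-Lambert.  Characteristic tungsten lines
are omitted: the projection-domain look-up table absorbs residual spectrum
model error by construction, so the decomposition is self-consistent for any
fixed spectrum.  Measured spectra exported from other tools can be loaded
verbatim from two-column text files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .materials import ENERGY_MIN_KEV, Material, get_material, linear_attenuation

__all__ = [
    "Spectrum",
    "generate_spectrum",
    "filter_spectrum",
    "mean_energy",
    "delta_spectrum",
    "load_spectrum_file",
]


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Normalized relative fluence per energy bin.

    ``weights`` sum to 1 and vanish above the peak tube potential ``kvp``.
    """

    energies: np.ndarray  # keV, ascending bin centers
    weights: np.ndarray  # relative fluence, >= 0, sums to 1
    kvp: float
    description: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape:
            raise SpectrumError("energies and weights must be 1-D and equal length")
        if not np.all(np.diff(e) > 0):
            raise SpectrumError("energy grid must be strictly ascending")
        if np.any(w < 0):
            raise SpectrumError("negative fluence weight")
        if np.any(w[e > self.kvp] > 0):
            raise SpectrumError("nonzero fluence above the peak tube potential")
        total = w.sum()
        if total <= 0:
            raise SpectrumError("spectrum has no fluence")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / total)


def generate_spectrum(
    kvp: float,
    inherent_filtration_mm_al: float = 2.5,
    energy_step_keV: float = 1.0,
    energy_min_keV: float = ENERGY_MIN_KEV,
) -> Spectrum:
    """Kramers-law bremsstrahlung spectrum at ``kvp``, filtered by aluminum.

    Parameters
    ----------
    kvp
        Peak tube potential in kV (40-150 supported).
    inherent_filtration_mm_al
        Equivalent aluminum thickness of the inherent tube filtration (mm).
    """
    if not 40.0 <= kvp <= 150.0:
        raise SpectrumError(f"kvp {kvp} outside supported range [40, 150]")
    if inherent_filtration_mm_al < 0:
        raise ValueError("filtration thickness must be >= 0")
    e = np.arange(energy_min_keV, kvp + 0.5 * energy_step_keV, energy_step_keV)
    w = np.clip(kvp - e, 0.0, None) / e
    s = Spectrum(e, w, kvp, description=f"kramers:{kvp:g}kVp")
    if inherent_filtration_mm_al > 0:
        s = filter_spectrum(s, get_material("aluminum"), inherent_filtration_mm_al)
        s = replace(s, description=f"kramers:{kvp:g}kVp+{inherent_filtration_mm_al:g}mmAl")
    return s


def filter_spectrum(s: Spectrum, material: Material, thickness_mm: float) -> Spectrum:
    """Harden a spectrum through ``thickness_mm`` of ``material`` (Beer-Lambert)."""
    if thickness_mm < 0:
        raise ValueError("filter thickness must be >= 0")
    mu = linear_attenuation(material, s.energies)  # 1/mm
    w = s.weights * np.exp(-mu * thickness_mm)
    return Spectrum(s.energies, w, s.kvp,
                    description=f"{s.description}|{material.name}:{thickness_mm:g}mm")


def mean_energy(s: Spectrum) -> float:
    """Fluence-weighted mean photon energy (keV)."""
    total = s.weights.sum()
    if total <= 0:
        raise SpectrumError("degenerate spectrum: all weights zero")
    return float(np.sum(s.weights * s.energies) / total)


def delta_spectrum(energy_keV: float) -> Spectrum:
    """Monochromatic test spectrum: all fluence in a single bin."""
    return Spectrum(np.array([float(energy_keV)]), np.array([1.0]),
                    kvp=float(energy_keV), description=f"delta:{energy_keV:g}keV")


def load_spectrum_file(path, kvp: float | None = None) -> Spectrum:
    """Load a two-column (energy_keV, relative_fluence) whitespace/CSV file."""
    arr = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    arr = np.atleast_2d(arr)
    e, w = arr[:, 0], arr[:, 1]
    nz = e[w > 0]
    peak = kvp if kvp is not None else float(nz.max())
    return Spectrum(e, w, peak, description=f"file:{path}")


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True
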