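"""Materials, mass-attenuation tables and electron densities.

X-ray attenuation in the 10-150 keV range is described per element by tabulated
mass attenuation coefficients mu/rho(E) (cm^2/g).  A compound or mixture obeys
the mixture rule

    (mu/rho)(E) = sum_i w_i (mu/rho)_i(E)

with w_i the elemental mass fractions.  Tables are interpolated log-log, the
standard scheme for attenuation data (smooth power-law behaviour, no K-edges
among H, C, N, O, Al, Si above 10 keV).

Electron densities are reported in the convention used throughout this
package: electrons per cm^3 in units of N_A/2, i.e.

    rho_e = 2 * rho * sum_i w_i * Z_i / A_i

so that liquid water is 1.1102.  Multiply by N_A/2 (:data:`NA_HALF`) to obtain
absolute electrons per cm^3.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ElementTable",
    "Material",
    "BasisPair",
    "ATOMIC_DATA",
    "NA_HALF",
    "element_table",
    "get_material",
    "load_materials_yaml",
    "material_from_formula",
    "mass_attenuation",
    "linear_attenuation",
    "electron_density",
    "electron_density_per_cm3",
    "make_basis_pair",
]

NA_HALF = 6.02214076e23 / 2.0
"""Half the Avogadro constant; converts package electron-density units to e/cm^3."""

#: symbol -> (atomic number Z, standard atomic mass A in g/mol)
ATOMIC_DATA: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
}

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 150.0


class AttenuationRangeError(ValueError):
    """Requested energy lies outside the tabulated 10-150 keV range."""


class UnknownElementError(KeyError):
    """Element symbol has no packaged attenuation table."""


@dataclass(frozen=True)
class ElementTable:
    """Tabulated mass attenuation coefficient for one element."""

    symbol: str
    Z: int
    A: float
    energies: np.ndarray  # keV, strictly ascending
    mu_over_rho: np.ndarray  # cm^2/g

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("energies and mu_over_rho must be 1-D and equal length")
        if not np.all(np.diff(e) > 0) or not np.all(e > 0):
            raise ValueError(f"{self.symbol}: energy grid must be positive, strictly ascending")
        if not np.all(m > 0):
            raise ValueError(f"{self.symbol}: mu/rho values must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", m)

    def __call__(self, energy_keV: float | np.ndarray) -> np.ndarray:
        """Log-log interpolated mu/rho (cm^2/g) at ``energy_keV``."""
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise AttenuationRangeError(
                f"{self.symbol}: energy outside tabulated range "
                f"[{self.energies[0]:g}, {self.energies[-1]:g}] keV"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(self.mu_over_rho))
        )
        return out if out.ndim else float(out)


_element_cache: dict[str, ElementTable] = {}


def element_table(symbol: str) -> ElementTable:
    """Load the packaged attenuation table for an element (cached)."""
    if symbol in _element_cache:
        return _element_cache[symbol]
    if symbol not in ATOMIC_DATA:
        raise UnknownElementError(f"no attenuation table for element {symbol!r}")
    Z, A = ATOMIC_DATA[symbol]
    ref = resources.files("decbct.data.elements").joinpath(f"{symbol}.csv")
    with ref.open("r") as fh:
        rows = list(csv.DictReader(fh))
    e = np.array([float(r["energy_keV"]) for r in rows])
    m = np.array([float(r["mu_over_rho_cm2_g"]) for r in rows])
    tab = ElementTable(symbol, Z, A, e, m)
    _element_cache[symbol] = tab
    return tab


@dataclass(frozen=True, eq=False)
class Material:
    """A material: elemental mass fractions plus a mass density (g/cm^3).

    ``composition`` may be empty only for the vacuum sentinel (density 0).
    Equality and hashing are by value (name, density, composition), so
    materials can key path-length maps.
    """

    name: str
    composition: Mapping[str, float] = field(default_factory=dict)
    density: float = 0.0

    def _key(self) -> tuple:
        return (self.name, self.density, tuple(sorted(self.composition.items())))

    def __eq__(self, other) -> bool:
        return isinstance(other, Material) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if self.density < 0:
            raise ValueError(f"{self.name}: density must be >= 0")
        if not comp:
            if self.density != 0:
                raise ValueError(f"{self.name}: empty composition requires density 0")
        else:
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.name}: mass fractions sum to {total:.8f}, expected 1"
                )
            for sym in comp:
                if sym not in ATOMIC_DATA:
                    raise UnknownElementError(f"{self.name}: unknown element {sym!r}")
        object.__setattr__(self, "composition", comp)

    def with_density(self, density: float) -> "Material":
        return Material(self.name, self.composition, density)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def material_from_formula(name: str, formula: str, density: float) -> Material:
    """Build a material from a chemical formula such as ``H2O`` or ``C5H8O2``."""
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        sym, n = m.group(1), m.group(2)
        if sym not in ATOMIC_DATA:
            raise UnknownElementError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0.0) + (int(n) if n else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    masses = {sym: n * ATOMIC_DATA[sym][1] for sym, n in counts.items()}
    total = sum(masses.values())
    return Material(name, {sym: m / total for sym, m in masses.items()}, density)


def load_materials_yaml(source) -> dict[str, Material]:
    """Parse a materials YAML mapping (name -> {formula|composition, density})."""
    data = yaml.safe_load(source)
    out: dict[str, Material] = {}
    for name, entry in data.items():
        density = float(entry.get("density", 0.0))
        if "formula" in entry:
            out[name] = material_from_formula(name, entry["formula"], density)
        else:
            out[name] = Material(name, entry.get("composition", {}), density)
    return out


_builtin_materials: dict[str, Material] | None = None


def get_material(name: str, density: float | None = None) -> Material:
    """Fetch a built-in material, optionally overriding its density."""
    global _builtin_materials
    if _builtin_materials is None:
        ref = resources.files("decbct.data").joinpath("materials.yaml")
        with ref.open("r") as fh:
            _builtin_materials = load_materials_yaml(fh)
    try:
        mat = _builtin_materials[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(_builtin_materials)}"
        ) from None
    return mat.with_density(density) if density is not None else mat


def mass_attenuation(material: Material, energy_keV: float | np.ndarray) -> np.ndarray:
    """Mixture-rule mass attenuation coefficient (cm^2/g) at ``energy_keV``."""
    e = np.asarray(energy_keV, dtype=float)
    out = np.zeros_like(e)
    for sym, w in material.composition.items():
        out = out + w * element_table(sym)(e)
    return out if out.ndim else float(out)


def linear_attenuation(material: Material, energy_keV: float | np.ndarray) -> np.ndarray:
    """Linear attenuation coefficient in 1/mm: (mu/rho) * rho / 10."""
    if material.density == 0.0:
        e = np.asarray(energy_keV, dtype=float)
        return np.zeros_like(e) if e.ndim else 0.0
    return mass_attenuation(material, energy_keV) * material.density / 10.0


def electron_density(material: Material) -> float:
    """Electron density in package units (N_A/2 electrons per cm^3).

    Computed as ``2 * rho * sum_i w_i * Z_i / A_i``; water at 1.000 g/cm^3
    gives 1.1102.
    """
    s = sum(w * ATOMIC_DATA[sym][0] / ATOMIC_DATA[sym][1]
            for sym, w in material.composition.items())
    return 2.0 * material.density * s


def electron_density_per_cm3(material: Material) -> float:
    """Absolute electron density in electrons per cm^3."""
    return electron_density(material) * NA_HALF


@dataclass(frozen=True)
class BasisPair:
    """The two basis materials of the decomposition (graphite and aluminum).

    ``rho_e1``/``rho_e2`` are their electron densities in package units; the
    electron-density image is the voxel-wise combination
    ``b1 * rho_e1 + b2 * rho_e2``.
    """

    material1: Material
    material2: Material
    rho_e1: float
    rho_e2: float

    def __post_init__(self) -> None:
        if not (0 < self.rho_e1 < self.rho_e2):
            raise ValueError("expected 0 < rho_e1 < rho_e2 (tissue-like vs bone-like basis)")


def make_basis_pair(
    material1: Material | None = None, material2: Material | None = None
) -> BasisPair:
    """Default graphite/aluminum basis pair."""
    m1 = material1 if material1 is not None else get_material("graphite")
    m2 = material2 if material2 is not None else get_material("aluminum")
    return BasisPair(m1, m2, electron_density(m1), electron_density(m2))
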