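"""Polychromatic forward projection.

Each detector reading is the fluence-weighted Beer-Lambert transmission

    g = -ln  sum_E S(E) * exp( - sum_m mu_m(E) * d_m )

with S the normalized spectrum, mu_m the linear attenuation of material m
(1/mm) and d_m the exact analytic path length of the ray through material m.
The sign convention g = -ln(I/I0) >= 0 is fixed and recorded on every
projection set.  The energy integral is a discrete sum on the spectrum's own
grid.  No scatter, detector blur or lag is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import PhantomSpec, ScanGeometry, detector_pixel_positions, path_lengths_batch, source_position
from .materials import linear_attenuation
from .spectrum import Spectrum

__all__ = ["ProjectionSet", "polychromatic_projection", "add_poisson_noise", "SIGN_CONVENTION"]

SIGN_CONVENTION = "g = -ln(I/I0)"


@dataclass(frozen=True)
class ProjectionSet:
    """Log-attenuation projections: values shape (n_projections, det_rows, det_cols)."""

    values: np.ndarray
    geometry: ScanGeometry
    spectrum_id: str
    convention: str = SIGN_CONVENTION

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_projections, self.geometry.det_rows, self.geometry.det_cols)
        if v.shape != expected:
            raise ValueError(f"projection array shape {v.shape} != geometry shape {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("projection values must be finite")
        object.__setattr__(self, "values", v)

    def same_geometry(self, other: "ProjectionSet") -> bool:
        return self.geometry == other.geometry


def polychromatic_projection(
    phantom: PhantomSpec, geom: ScanGeometry, s: Spectrum
) -> ProjectionSet:
    """Noiseless polychromatic projections of an analytic phantom.

    Deterministic; rays that miss the phantom give exactly g = 0.
    """
    materials = phantom.materials
    # (n_mat, n_E) linear attenuation in 1/mm on the spectrum grid
    mu = np.stack([linear_attenuation(m, s.energies) for m in materials])
    w = s.weights
    out = np.empty((geom.n_projections, geom.det_rows, geom.det_cols))
    for k, ang in enumerate(geom.angles_deg):
        src = source_position(geom, ang)
        pix = detector_pixel_positions(geom, ang)
        paths = path_lengths_batch(phantom, src, pix)
        # (rows, cols, n_mat) path lengths in mm
        d = np.stack([paths.get(m, np.zeros(pix.shape[:2])) for m in materials], axis=-1)
        # transmission summed over the spectrum
        intensity = np.exp(-d @ mu) @ w
        out[k] = -np.log(intensity)
    # rays that miss everything accumulate only rounding error; snap to 0
    out[np.abs(out) < 1e-14] = 0.0
    return ProjectionSet(out, geom, spectrum_id=s.description)


def add_poisson_noise(
    p: ProjectionSet, photons_per_ray: float, seed: int | np.random.Generator
) -> ProjectionSet:
    """Resample each ray's intensity as Poisson counts and re-log.

    ``photons_per_ray`` is the unattenuated count I0.  Zero counts are clamped
    to 1 before the log.  Reproducible given the same seed.
    """
    if photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intensity = photons_per_ray * np.exp(-p.values)
    counts = rng.poisson(intensity).astype(float)
    counts = np.maximum(counts, 1.0)
    noisy = -np.log(counts / photons_per_ray)
    return replace(p, values=noisy, spectrum_id=f"{p.spectrum_id}|poisson:{photons_per_ray:g}")
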