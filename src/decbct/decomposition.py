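"""Projection-domain basis-material decomposition via a look-up table.

The forward model maps a pair of basis-material path lengths (d1 graphite,
d2 aluminum, mm) to the pair of dual-energy log-attenuations

    gH(d1, d2) = -ln sum_E S_H(E) exp(-d1 mu1(E) - d2 mu2(E))
    gL(d1, d2) = -ln sum_E S_L(E) exp(-d1 mu1(E) - d2 mu2(E))

evaluated with the same polychromatic spectra used for scanning, so beam
hardening is built into the table.  Decomposition inverts this map: each
measured (gH, gL) pixel becomes an equivalent path-length pair (B1, B2),
which are the line integrals of the basis-material coefficient images.

Inversion uses a piecewise-linear look-up on the tabulated grid for the
initial guess, refined by a damped 2-D Newton iteration on the smooth forward
model with its analytic Jacobian.  Negative path lengths are legitimate (the
basis expansion is algebraic, not a physical mixture: materials less
attenuating than graphite need d2 < 0), so the grid extends below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .geometry import ScanGeometry
from .materials import BasisPair, linear_attenuation
from .projector import ProjectionSet
from .spectrum import Spectrum

__all__ = [
    "DecompositionLUT",
    "BasisProjections",
    "build_lut",
    "default_d1_grid",
    "default_d2_grid",
    "invert_pair",
    "decompose",
    "LUTBuildError",
]

NEWTON_TOL_G = 1e-6
NEWTON_MAX_ITER = 50


class LUTBuildError(RuntimeError):
    """The computed forward table violates its monotonicity contract."""


@dataclass(frozen=True)
class BasisProjections:
    """Decomposed sinograms: equivalent basis path lengths B1, B2 in mm."""

    B1: np.ndarray
    B2: np.ndarray
    geometry: ScanGeometry
    provenance: str = ""
    n_nonconverged: int = 0


def grid_about_zero(lo: float, hi: float, step: float) -> np.ndarray:
    """Uniform grid anchored at exactly 0, spanning [lo, hi] (lo <= 0 <= hi)."""
    if not (lo <= 0.0 <= hi) or step <= 0:
        raise ValueError("grid must span 0 with a positive step")
    neg = -np.arange(step, -lo + 0.5 * step, step)[::-1]
    pos = np.arange(0.0, hi + 0.5 * step, step)
    return np.concatenate([neg, pos])


def default_d1_grid(step: float = 2.0) -> np.ndarray:
    """Graphite thickness samples, mm (extends negative; see module docstring)."""
    return grid_about_zero(-50.0, 400.0, step)


def default_d2_grid(step: float = 0.5) -> np.ndarray:
    """Aluminum thickness samples, mm."""
    return grid_about_zero(-20.0, 60.0, step)


def step_wedge_d1_grid() -> np.ndarray:
    """Physical calibration fidelity: 10 mm graphite slabs, 0..160 mm."""
    return np.arange(0.0, 160.0 + 5.0, 10.0)


def step_wedge_d2_grid() -> np.ndarray:
    """Physical calibration fidelity: aluminum step wedge, 0..20 mm in 1 mm steps."""
    return np.arange(0.0, 20.0 + 0.5, 1.0)


class _ForwardModel:
    """Vectorized polychromatic two-slab forward model and its Jacobian."""

    def __init__(self, basis: BasisPair, s: Spectrum):
        self.mu1 = linear_attenuation(basis.material1, s.energies)  # 1/mm
        self.mu2 = linear_attenuation(basis.material2, s.energies)
        self.w = s.weights

    def g(self, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
        t = np.exp(-np.multiply.outer(d1, self.mu1) - np.multiply.outer(d2, self.mu2))
        return -np.log(t @ self.w)

    def g_and_jac(self, d1, d2):
        t = np.exp(-np.multiply.outer(d1, self.mu1) - np.multiply.outer(d2, self.mu2))
        intensity = t @ self.w
        g = -np.log(intensity)
        dg_dd1 = (t @ (self.w * self.mu1)) / intensity
        dg_dd2 = (t @ (self.w * self.mu2)) / intensity
        return g, dg_dd1, dg_dd2


@dataclass
class DecompositionLUT:
    """Forward table (d1, d2) -> (gH, gL) on a rectangular grid, with inversion."""

    d1_grid: np.ndarray
    d2_grid: np.ndarray
    gH_table: np.ndarray  # shape (len(d1_grid), len(d2_grid))
    gL_table: np.ndarray
    basis: BasisPair
    spectra: tuple[Spectrum, Spectrum]
    _fwdH: _ForwardModel = field(init=False, repr=False)
    _fwdL: _ForwardModel = field(init=False, repr=False)
    _inverse: object = field(init=False, repr=False, default=None)
    _inverse_nn: object = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self._fwdH = _ForwardModel(self.basis, self.spectra[0])
        self._fwdL = _ForwardModel(self.basis, self.spectra[1])

    def forward(self, d1, d2) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the smooth forward model (not the tabulated grid)."""
        d1 = np.asarray(d1, dtype=float)
        d2 = np.asarray(d2, dtype=float)
        return self._fwdH.g(d1, d2), self._fwdL.g(d1, d2)

    def _initial_guess(self, gH: np.ndarray, gL: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear look-up of the inverse map on the tabulated grid."""
        if self._inverse is None:
            # subsample the grid: the guess only needs to land in Newton's basin
            i = np.unique(np.r_[np.arange(0, len(self.d1_grid), 4), len(self.d1_grid) - 1])
            j = np.unique(np.r_[np.arange(0, len(self.d2_grid), 4), len(self.d2_grid) - 1])
            D1, D2 = np.meshgrid(self.d1_grid[i], self.d2_grid[j], indexing="ij")
            pts = np.column_stack([
                self.gH_table[np.ix_(i, j)].ravel(),
                self.gL_table[np.ix_(i, j)].ravel(),
            ])
            vals = np.column_stack([D1.ravel(), D2.ravel()])
            self._inverse = LinearNDInterpolator(pts, vals)
            self._inverse_nn = NearestNDInterpolator(pts, vals)
        q = np.column_stack([gH.ravel(), gL.ravel()])
        d = self._inverse(q)
        bad = ~np.isfinite(d[:, 0])
        if np.any(bad):
            d[bad] = self._inverse_nn(q[bad])
        return d[:, 0], d[:, 1]


def build_lut(
    basis: BasisPair,
    sH: Spectrum,
    sL: Spectrum,
    d1_grid: np.ndarray | None = None,
    d2_grid: np.ndarray | None = None,
) -> DecompositionLUT:
    """Tabulate the dual-energy forward model on a (d1, d2) grid.

    Raises :class:`LUTBuildError` if the table is not strictly increasing
    along both axes (a pathological spectrum/basis combination).
    """
    d1_grid = default_d1_grid() if d1_grid is None else np.asarray(d1_grid, float)
    d2_grid = default_d2_grid() if d2_grid is None else np.asarray(d2_grid, float)
    for name, g in (("d1", d1_grid), ("d2", d2_grid)):
        if g.ndim != 1 or not np.all(np.diff(g) > 0):
            raise ValueError(f"{name} grid must be 1-D strictly ascending")
        if not np.any(g == 0.0):
            raise ValueError(f"{name} grid must contain 0")
    fwdH = _ForwardModel(basis, sH)
    fwdL = _ForwardModel(basis, sL)
    D1, D2 = np.meshgrid(d1_grid, d2_grid, indexing="ij")
    gH = fwdH.g(D1.ravel(), D2.ravel()).reshape(D1.shape)
    gL = fwdL.g(D1.ravel(), D2.ravel()).reshape(D1.shape)
    # the origin entry is exactly zero up to normalisation rounding; snap it
    gH[np.abs(gH) < 1e-14] = 0.0
    gL[np.abs(gL) < 1e-14] = 0.0
    for name, tab in (("gH", gH), ("gL", gL)):
        if not (np.all(np.diff(tab, axis=0) > 0) and np.all(np.diff(tab, axis=1) > 0)):
            raise LUTBuildError(f"{name} table not strictly increasing along both axes")
    return DecompositionLUT(d1_grid, d2_grid, gH, gL, basis, (sH, sL))


def _newton_invert(
    lut: DecompositionLUT, gH: np.ndarray, gL: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Damped Newton refinement of the LUT initial guess, vectorized."""
    gH = np.asarray(gH, float).ravel()
    gL = np.asarray(gL, float).ravel()
    d1, d2 = lut._initial_guess(gH, gL)
    fH, fL = lut._fwdH, lut._fwdL

    def residual_norm(a, b, tH, tL):
        hH, hL = fH.g(a, b), fL.g(a, b)
        return np.maximum(np.abs(hH - tH), np.abs(hL - tL))

    res = residual_norm(d1, d2, gH, gL)
    for _ in range(NEWTON_MAX_ITER):
        active = res > NEWTON_TOL_G
        if not np.any(active):
            break
        a, b = d1[active], d2[active]
        hH, jH1, jH2 = fH.g_and_jac(a, b)
        hL, jL1, jL2 = fL.g_and_jac(a, b)
        rH = hH - gH[active]
        rL = hL - gL[active]
        det = jH1 * jL2 - jH2 * jL1
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s1 = (rH * jL2 - rL * jH2) / det
        s2 = (rL * jH1 - rH * jL1) / det
        # backtracking: halve the step where the residual would grow
        lam = np.ones_like(s1)
        cur = res[active]
        tH, tL = gH[active], gL[active]
        new1, new2 = a - s1, b - s2
        new_res = residual_norm(new1, new2, tH, tL)
        for _bt in range(6):
            worse = new_res > cur
            if not np.any(worse):
                break
            lam[worse] *= 0.5
            new1 = a - lam * s1
            new2 = b - lam * s2
            new_res[worse] = residual_norm(new1[worse], new2[worse], tH[worse], tL[worse])
        d1[active], d2[active] = new1, new2
        res[active] = new_res
    n_bad = int(np.count_nonzero(res > NEWTON_TOL_G))
    # exact vacuum rays: identity at the origin
    zero = (gH == 0.0) & (gL == 0.0)
    d1[zero] = 0.0
    d2[zero] = 0.0
    return d1, d2, n_bad


def invert_pair(lut: DecompositionLUT, gH: float, gL: float) -> tuple[float, float]:
    """Invert a single (gH, gL) pair into basis path lengths (d1, d2) in mm."""
    if not (np.isfinite(gH) and np.isfinite(gL)):
        raise ValueError("gH and gL must be finite")
    d1, d2, _ = _newton_invert(lut, np.array([gH]), np.array([gL]))
    return float(d1[0]), float(d2[0])


def decompose(
    projH: ProjectionSet, projL: ProjectionSet, lut: DecompositionLUT,
    chunk_size: int = 1 << 16,
) -> BasisProjections:
    """Element-wise inversion of a dual-energy projection pair.

    Non-converged pixels (residual above tolerance after the iteration cap)
    keep their best iterate and are counted in ``n_nonconverged``.
    """
    if projH.geometry != projL.geometry:
        raise ValueError("high- and low-energy projections have different geometries")
    shape = projH.values.shape
    gH = projH.values.ravel()
    gL = projL.values.ravel()
    B1 = np.empty_like(gH)
    B2 = np.empty_like(gL)
    n_bad = 0
    for lo in range(0, gH.size, chunk_size):
        hi = min(lo + chunk_size, gH.size)
        b1, b2, nb = _newton_invert(lut, gH[lo:hi], gL[lo:hi])
        B1[lo:hi], B2[lo:hi] = b1, b2
        n_bad += nb
    return BasisProjections(
        B1.reshape(shape), B2.reshape(shape), projH.geometry,
        provenance=f"lut[{projH.spectrum_id} / {projL.spectrum_id}]",
        n_nonconverged=n_bad,
    )
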