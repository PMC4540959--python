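"""Filtered backprojection for the circular full-arc geometry.

Two reconstructors share the same weighting and ramp filter:

* ``fbp_fan``: exact flat-detector fan-beam FBP of a single detector row,
  used for central-slice (2-D) work.
* ``fdk_reconstruct``: the Feldkamp-Davis-Kress extension for a 2-D flat
  panel - cosine pre-weighting, row-wise ramp filtering, distance-weighted
  backprojection - which reduces to the fan formula on the central plane.

Detector coordinates are rescaled to the isocenter line (u * SAD/SDD), the
band-limited ramp (Ram-Lak) kernel is applied by FFT convolution with zero
padding, and backprojection uses linear interpolation.  A full 360-degree
arc is required; each line is measured twice, which the angular weighting
accounts for.  Reconstruction is linear in the sinogram, so basis-coefficient
sinograms can be reconstructed channel by channel and combined afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import ScanGeometry
from .projector import ProjectionSet

__all__ = ["Volume", "fbp_fan", "fdk_reconstruct", "to_hu", "ramp_kernel"]

QUANTITIES = ("b1", "b2", "mu", "HU", "rho_e")


@dataclass
class Volume:
    """Reconstructed scalar field: 2-D (ny, nx) or 3-D (nz, ny, nx), mm units.

    ``origin`` is the world position of the (0, ..., 0) voxel center.
    """

    values: np.ndarray
    voxel_size: float
    origin: tuple
    quantity: str
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    def xy_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World x (per column) and y (per row) voxel-center coordinates."""
        ny, nx = self.values.shape[-2:]
        ox, oy = self.origin[0], self.origin[1]
        x = ox + np.arange(nx) * self.voxel_size
        y = oy + np.arange(ny) * self.voxel_size
        return x, y


def _centered_grid(n: int, voxel_size: float) -> float:
    """Origin (first voxel center) of an n-voxel axis centered on the isocenter."""
    return -(n - 1) / 2.0 * voxel_size


def ramp_kernel(n: int, spacing: float) -> np.ndarray:
    """Band-limited spatial ramp filter kernel on 2n-1 taps, sample spacing ``spacing``."""
    k = np.arange(-(n - 1), n)
    h = np.zeros(k.shape)
    h[k == 0] = 1.0 / (4.0 * spacing**2)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi**2 * k[odd].astype(float) ** 2 * spacing**2)
    return h


def _filter_rows(rows: np.ndarray, spacing: float) -> np.ndarray:
    """Ramp-filter each row (last axis) by FFT convolution, including the
    half weight for the doubly-covered full arc and the quadrature spacing."""
    n = rows.shape[-1]
    h = ramp_kernel(n, spacing)
    # linear (non-circular) convolution needs nfft >= 3n-2
    nfft = int(2 ** np.ceil(np.log2(3 * n)))
    H = np.fft.rfft(h, nfft)
    R = np.fft.rfft(rows, nfft, axis=-1)
    full = np.fft.irfft(R * H, nfft, axis=-1)
    out = full[..., n - 1: 2 * n - 1]
    return out * spacing * 0.5


def _check_full_arc(geom: ScanGeometry) -> None:
    if abs(geom.arc - 360.0) > 1e-6:
        raise ValueError("only full 360-degree arcs are supported")


def fbp_fan(
    sinogram: np.ndarray,
    geom: ScanGeometry,
    n_voxels: int = 256,
    voxel_size: float = 1.0,
    quantity: str = "mu",
) -> Volume:
    """Flat-detector fan-beam FBP of a (n_projections, det_cols) sinogram."""
    _check_full_arc(geom)
    sino = np.asarray(sinogram, dtype=float)
    if sino.shape != (geom.n_projections, geom.det_cols):
        raise ValueError("sinogram shape does not match geometry")
    sad = geom.sad
    du = geom.pixel_size * sad / geom.sdd  # detector sample spacing at isocenter
    u = (np.arange(geom.det_cols) - (geom.det_cols - 1) / 2.0) * du
    pre = sad / np.sqrt(sad**2 + u**2)
    q = _filter_rows(sino * pre[None, :], du)

    origin = _centered_grid(n_voxels, voxel_size)
    xs = origin + np.arange(n_voxels) * voxel_size
    X, Y = np.meshgrid(xs, xs)  # X varies along columns, Y along rows
    out = np.zeros((n_voxels, n_voxels))
    dbeta = np.radians(geom.angular_step)
    for k, ang in enumerate(geom.angles_deg):
        b = np.radians(ang)
        sin_b, cos_b = np.sin(b), np.cos(b)
        L = sad + X * sin_b - Y * cos_b  # source distance along the central ray
        t = X * cos_b + Y * sin_b
        u_iso = t * sad / L
        vals = np.interp(u_iso, u, q[k], left=0.0, right=0.0)
        out += (sad**2 / L**2) * vals
    out *= dbeta
    return Volume(
        out, voxel_size, (origin, origin), quantity,
        provenance={"algorithm": "fan-fbp", "filter": "ram-lak", "interp": "linear",
                    "n_projections": geom.n_projections, "voxel_size": voxel_size},
    )


def fdk_reconstruct(
    projections: ProjectionSet | np.ndarray,
    geom: ScanGeometry | None = None,
    n_voxels: int = 256,
    voxel_size: float = 1.0,
    n_slices: int | None = None,
    slice_thickness: float | None = None,
    quantity: str = "mu",
) -> Volume:
    """FDK reconstruction of a full-arc cone-beam projection set.

    For a single-row (fan) geometry this delegates to :func:`fbp_fan` and
    returns a 2-D volume.  ``projections`` may be a :class:`ProjectionSet`
    or a raw (n_projections, det_rows, det_cols) array with ``geom`` given
    (used for basis-coefficient channels).
    """
    if isinstance(projections, ProjectionSet):
        values = projections.values
        geom = projections.geometry
    else:
        if geom is None:
            raise ValueError("geom is required when passing a raw array")
        values = np.asarray(projections, dtype=float)
    _check_full_arc(geom)
    if geom.det_rows == 1:
        return fbp_fan(values[:, 0, :], geom, n_voxels, voxel_size, quantity)

    sad = geom.sad
    scale = sad / geom.sdd
    du = geom.pixel_size * scale
    dv = du
    u = (np.arange(geom.det_cols) - (geom.det_cols - 1) / 2.0) * du
    v = (np.arange(geom.det_rows) - (geom.det_rows - 1) / 2.0) * dv
    pre = sad / np.sqrt(sad**2 + u[None, :] ** 2 + v[:, None] ** 2)
    q = _filter_rows(values * pre[None, :, :], du)

    if n_slices is None:
        n_slices = max(1, int(round(geom.det_rows * scale * geom.pixel_size / voxel_size)))
    dz = slice_thickness if slice_thickness is not None else voxel_size
    origin = _centered_grid(n_voxels, voxel_size)
    oz = _centered_grid(n_slices, dz)
    xs = origin + np.arange(n_voxels) * voxel_size
    zs = oz + np.arange(n_slices) * dz
    X, Y = np.meshgrid(xs, xs)
    out = np.zeros((n_slices, n_voxels, n_voxels))
    dbeta = np.radians(geom.angular_step)
    for k, ang in enumerate(geom.angles_deg):
        b = np.radians(ang)
        sin_b, cos_b = np.sin(b), np.cos(b)
        L = sad + X * sin_b - Y * cos_b
        t = X * cos_b + Y * sin_b
        u_iso = t * sad / L
        inside_u = (u_iso >= u[0]) & (u_iso <= u[-1])
        fu = np.clip((u_iso - u[0]) / du, 0.0, geom.det_cols - 1.0)
        iu = np.minimum(fu.astype(int), geom.det_cols - 2)
        wu = fu - iu
        weight = np.where(inside_u, sad**2 / L**2, 0.0)
        for iz, z in enumerate(zs):
            v_iso = z * sad / L
            inside_v = (v_iso >= v[0]) & (v_iso <= v[-1])
            fv = np.clip((v_iso - v[0]) / dv, 0.0, geom.det_rows - 1.0)
            ivx = np.minimum(fv.astype(int), geom.det_rows - 2)
            wv = fv - ivx
            qk = q[k]
            vals = ((1 - wv) * (1 - wu) * qk[ivx, iu]
                    + (1 - wv) * wu * qk[ivx, iu + 1]
                    + wv * (1 - wu) * qk[ivx + 1, iu]
                    + wv * wu * qk[ivx + 1, iu + 1])
            out[iz] += weight * np.where(inside_v, vals, 0.0)
    out *= dbeta
    return Volume(
        out, voxel_size, (origin, origin, oz), quantity,
        provenance={"algorithm": "fdk", "filter": "ram-lak", "interp": "bilinear",
                    "n_projections": geom.n_projections, "voxel_size": voxel_size,
                    "slice_thickness": dz},
    )


def to_hu(v: Volume, mu_water_ref: float) -> Volume:
    """Convert an attenuation volume (1/mm) to Hounsfield units."""
    if v.quantity != "mu":
        raise ValueError("to_hu requires a volume with quantity 'mu'")
    if mu_water_ref <= 0:
        raise ValueError("mu_water_ref must be > 0")
    hu = 1000.0 * (v.values - mu_water_ref) / mu_water_ref
    prov = dict(v.provenance, mu_water_ref=mu_water_ref)
    return Volume(hu, v.voxel_size, v.origin, "HU", prov)
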