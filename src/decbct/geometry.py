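"""Analytic phantoms and circular cone/fan-beam scan geometry.

Coordinates: isocenter origin, millimetres, right-handed, z along the rotation
axis.  The source rotates counter-clockwise; at gantry angle 0 it sits on +y.
Detector pixels are indexed 0-based with coordinates at pixel centers; the
detector u-axis is in-plane, the v-axis along z.

Phantoms are unions of circular cylinders (a background cylinder plus
non-overlapping inserts), so every ray's intersection lengths are exact
line-cylinder chords rather than voxelized approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import Material, get_material

__all__ = [
    "Cylinder",
    "PhantomSpec",
    "ScanGeometry",
    "Ray",
    "build_virtual_phantom",
    "build_uniformity_phantom",
    "make_geometry",
    "ray_path_lengths",
    "path_lengths_batch",
    "detector_pixel_positions",
    "source_position",
]


class GeometryConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder along z: in-plane center, radius, axial half-extent (mm)."""

    center: tuple[float, float]
    radius: float
    material: Material
    half_height: float = 150.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryConfigError("cylinder radius must be > 0")
        if self.half_height <= 0:
            raise GeometryConfigError("cylinder half height must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Background cylinder with cylindrical inserts strictly inside it."""

    background: Cylinder
    inserts: tuple[Cylinder, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inserts", tuple(self.inserts))
        bg = self.background
        for ins in self.inserts:
            d = math.hypot(ins.center[0] - bg.center[0], ins.center[1] - bg.center[1])
            if d + ins.radius >= bg.radius:
                raise GeometryConfigError(
                    f"insert {ins.material.name} at {ins.center} not strictly inside background"
                )
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1:]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise GeometryConfigError(
                        f"inserts {a.material.name} and {b.material.name} overlap"
                    )

    @property
    def materials(self) -> tuple[Material, ...]:
        seen: dict[Material, None] = {self.background.material: None}
        for ins in self.inserts:
            seen.setdefault(ins.material, None)
        return tuple(seen)


@dataclass(frozen=True)
class ScanGeometry:
    """Circular full-arc cone/fan-beam acquisition description (mm, degrees)."""

    sad: float = 1000.0
    sdd: float = 1536.0
    det_cols: int = 512
    det_rows: int = 1
    pixel_size: float = 1.0
    n_projections: int = 600
    angular_step: float = 0.6
    arc: float = 360.0

    def __post_init__(self) -> None:
        if not 0 < self.sad < self.sdd:
            raise GeometryConfigError("require 0 < sad < sdd")
        if self.pixel_size <= 0:
            raise GeometryConfigError("pixel_size must be > 0")
        if self.det_cols < 1 or self.det_rows < 1:
            raise GeometryConfigError("detector must have at least one pixel")
        if self.n_projections < 1:
            raise GeometryConfigError("need at least one projection")
        if abs(self.n_projections * self.angular_step - self.arc) > 0.5 * self.angular_step:
            raise GeometryConfigError(
                f"n_projections*angular_step = {self.n_projections * self.angular_step:g} "
                f"inconsistent with arc = {self.arc:g}"
            )

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * self.angular_step

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def is_fan(self) -> bool:
        return self.det_rows == 1


@dataclass(frozen=True)
class Ray:
    """A straight line from the source point to a detector-pixel point (mm)."""

    source: tuple[float, float, float]
    endpoint: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.source == self.endpoint:
            raise GeometryConfigError("ray source and endpoint coincide")


def make_geometry(config: dict | None = None, **kwargs) -> ScanGeometry:
    """Build a :class:`ScanGeometry` from a config mapping and/or keywords."""
    cfg = dict(config or {})
    cfg.update(kwargs)
    known = {f for f in ScanGeometry.__dataclass_fields__}
    unknown = set(cfg) - known
    if unknown:
        raise GeometryConfigError(f"unknown geometry keys: {sorted(unknown)}")
    return ScanGeometry(**cfg)


def build_virtual_phantom(
    insert_radius: float = 20.0,
    insert_offset: float = 64.0,
    half_height: float = 150.0,
) -> PhantomSpec:
    """Water cylinder, diameter 256 mm, with Si / PMMA / PE / graphite inserts.

    The four inserts sit ``insert_offset`` mm from the axis at 0, 90, 180 and
    270 degrees (Si, PMMA, PE, graphite counter-clockwise from +x).
    """
    water = get_material("water")
    layout = [
        ((insert_offset, 0.0), get_material("silicon")),
        ((0.0, insert_offset), get_material("pmma")),
        ((-insert_offset, 0.0), get_material("polyethylene")),
        ((0.0, -insert_offset), get_material("graphite")),
    ]
    inserts = tuple(
        Cylinder(center, insert_radius, mat, half_height) for center, mat in layout
    )
    return PhantomSpec(Cylinder((0.0, 0.0), 128.0, water, half_height), inserts)


def build_uniformity_phantom(diameter: float = 150.0, half_height: float = 150.0) -> PhantomSpec:
    """Uniform water-equivalent cylinder (CTP 486-style uniformity module)."""
    return PhantomSpec(Cylinder((0.0, 0.0), diameter / 2.0, get_material("water"), half_height))


def source_position(geom: ScanGeometry, angle_deg: float) -> np.ndarray:
    b = math.radians(angle_deg)
    return np.array([-geom.sad * math.sin(b), geom.sad * math.cos(b), 0.0])


def detector_pixel_positions(geom: ScanGeometry, angle_deg: float) -> np.ndarray:
    """Pixel-center world positions, shape (det_rows, det_cols, 3)."""
    b = math.radians(angle_deg)
    s_hat = np.array([-math.sin(b), math.cos(b), 0.0])  # isocenter -> source
    u_hat = np.array([math.cos(b), math.sin(b), 0.0])
    center = -(geom.sdd - geom.sad) * s_hat
    u = (np.arange(geom.det_cols) - (geom.det_cols - 1) / 2.0) * geom.pixel_size
    v = (np.arange(geom.det_rows) - (geom.det_rows - 1) / 2.0) * geom.pixel_size
    pos = (center[None, None, :]
           + u[None, :, None] * u_hat[None, None, :]
           + v[:, None, None] * np.array([0.0, 0.0, 1.0])[None, None, :])
    return pos


def _cylinder_chords(
    cyl: Cylinder, source: np.ndarray, endpoints: np.ndarray
) -> np.ndarray:
    """Exact intersection lengths (mm) of source->endpoint segments with a cylinder.

    ``endpoints`` has shape (..., 3); the result has shape (...,).
    """
    d = endpoints - source  # (..., 3)
    norm = np.linalg.norm(d, axis=-1)
    dx, dy, dz = d[..., 0], d[..., 1], d[..., 2]
    fx = source[0] - cyl.center[0]
    fy = source[1] - cyl.center[1]
    a = dx * dx + dy * dy
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - cyl.radius**2
    disc = b * b - 4.0 * a * c
    axial = (a == 0.0) & (c < 0.0)  # ray parallel to the axis, inside the circle
    hit = ((disc > 0.0) & (a > 0.0)) | axial
    sq = np.sqrt(np.where(disc > 0.0, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = np.where(a > 0.0, (-b - sq) / (2.0 * a), -np.inf)
        t_hi = np.where(a > 0.0, (-b + sq) / (2.0 * a), np.inf)
    t_lo = np.where(hit, t_lo, 0.0)
    t_hi = np.where(hit, t_hi, 0.0)
    # clip by the axial extent |z| <= half_height
    z0, h = source[2], cyl.half_height
    with np.errstate(divide="ignore", invalid="ignore"):
        tz1 = np.where(dz != 0, (-h - z0) / dz, -np.inf)
        tz2 = np.where(dz != 0, (h - z0) / dz, np.inf)
    tz_lo = np.minimum(tz1, tz2)
    tz_hi = np.maximum(tz1, tz2)
    inside_z = (dz != 0) | (np.abs(z0) <= h)
    t_lo = np.maximum(t_lo, np.where(inside_z, tz_lo, np.inf))
    t_hi = np.minimum(t_hi, np.where(inside_z, tz_hi, -np.inf))
    # restrict to the physical source->detector segment
    t_lo = np.maximum(t_lo, 0.0)
    t_hi = np.minimum(t_hi, 1.0)
    length = np.where(hit, np.clip(t_hi - t_lo, 0.0, None) * norm, 0.0)
    return length


def path_lengths_batch(
    phantom: PhantomSpec, source: np.ndarray, endpoints: np.ndarray
) -> dict[Material, np.ndarray]:
    """Per-material path lengths (mm) for a batch of rays sharing one source.

    The background length is its full chord minus the chords of all inserts
    (inserts lie strictly inside the background).
    """
    source = np.asarray(source, dtype=float)
    endpoints = np.asarray(endpoints, dtype=float)
    bg_chord = _cylinder_chords(phantom.background, source, endpoints)
    out: dict[Material, np.ndarray] = {}
    insert_total = np.zeros_like(bg_chord)
    for ins in phantom.inserts:
        chord = _cylinder_chords(ins, source, endpoints)
        insert_total += chord
        mat = ins.material
        out[mat] = out.get(mat, 0.0) + chord
    bg_mat = phantom.background.material
    bg_len = np.clip(bg_chord - insert_total, 0.0, None)
    out[bg_mat] = out.get(bg_mat, 0.0) + bg_len
    return out


def ray_path_lengths(phantom: PhantomSpec, ray: Ray) -> dict[Material, float]:
    """Exact per-material path lengths (mm) along a single ray."""
    res = path_lengths_batch(
        phantom, np.asarray(ray.source, float), np.asarray(ray.endpoint, float)[None, :]
    )
    return {m: float(v[0]) for m, v in res.items() if v[0] > 0.0}
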