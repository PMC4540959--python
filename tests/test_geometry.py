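import numpy as np
import pytest

from decbct.geometry import (
    Cylinder,
    GeometryConfigError,
    PhantomSpec,
    Ray,
    build_uniformity_phantom,
    build_virtual_phantom,
    detector_pixel_positions,
    make_geometry,
    path_lengths_batch,
    ray_path_lengths,
    source_position,
)
from decbct.materials import get_material


def test_virtual_phantom_layout():
    ph = build_virtual_phantom()
    assert ph.background.radius == 128.0
    assert len(ph.inserts) == 4
    names = {ins.material.name for ins in ph.inserts}
    assert names == {"silicon", "pmma", "polyethylene", "graphite"}


def test_overlapping_inserts_rejected(water, graphite):
    bg = Cylinder((0.0, 0.0), 100.0, water)
    a = Cylinder((0.0, 0.0), 20.0, graphite)
    b = Cylinder((30.0, 0.0), 20.0, graphite)
    with pytest.raises(GeometryConfigError):
        PhantomSpec(bg, (a, b))


def test_insert_outside_background_rejected(water, graphite):
    bg = Cylinder((0.0, 0.0), 100.0, water)
    with pytest.raises(GeometryConfigError):
        PhantomSpec(bg, (Cylinder((90.0, 0.0), 20.0, graphite),))


def test_central_chord_is_diameter(water):
    ph = build_uniformity_phantom(150.0)
    ray = Ray((0.0, 1000.0, 0.0), (0.0, -536.0, 0.0))
    lengths = ray_path_lengths(ph, ray)
    assert lengths[water] == pytest.approx(150.0, abs=1e-9)


def test_offset_chord_matches_analytic_and_sampled_oracle(water):
    R, h = 75.0, 40.0
    ph = build_uniformity_phantom(2 * R)
    ray = Ray((h, 1000.0, 0.0), (h, -536.0, 0.0))
    expected = 2.0 * np.sqrt(R**2 - h**2)
    got = ray_path_lengths(ph, ray)[water]
    assert got == pytest.approx(expected, abs=1e-9)
    # independent oracle: dense sampling of the cylinder indicator function
    t = np.linspace(0.0, 1.0, 400001)
    src = np.array([h, 1000.0, 0.0])
    d = np.array([h, -536.0, 0.0]) - src
    pts = src[None, :] + t[:, None] * d[None, :]
    inside = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= R**2
    sampled = inside.mean() * np.linalg.norm(d)
    assert got == pytest.approx(sampled, abs=0.05)


def test_missing_ray_has_zero_lengths():
    ph = build_virtual_phantom()
    ray = Ray((500.0, 1000.0, 0.0), (500.0, -536.0, 0.0))
    assert ray_path_lengths(ph, ray) == {}


def test_path_length_conservation(rng):
    """Material path lengths never exceed the background chord."""
    ph = build_virtual_phantom()
    geom = make_geometry(n_projections=4, angular_step=90.0, det_cols=64,
                         det_rows=1, pixel_size=8.0)
    for ang in geom.angles_deg:
        src = source_position(geom, ang)
        pix = detector_pixel_positions(geom, ang)
        paths = path_lengths_batch(ph, src, pix)
        total = sum(paths.values())
        bg_only = path_lengths_batch(
            PhantomSpec(ph.background), src, pix)[ph.background.material]
        assert np.all(total <= bg_only + 1e-9)


def test_path_lengths_continuous_across_detector(water):
    ph = build_uniformity_phantom(150.0)
    geom = make_geometry(n_projections=1, angular_step=360.0, det_cols=2048,
                         det_rows=1, pixel_size=0.25)
    src = source_position(geom, 0.0)
    pix = detector_pixel_positions(geom, 0.0)
    chord = path_lengths_batch(ph, src, pix)[water][0]
    # chord length changes by a bounded amount between neighbouring pixels
    # except near tangency where the square root is steep
    diffs = np.abs(np.diff(chord))
    interior = chord[:-1] > 30.0
    assert np.all(diffs[interior] < 2.0)


def test_geometry_defaults_and_magnification():
    geom = make_geometry()
    assert geom.sad == 1000.0 and geom.sdd == 1536.0
    assert geom.magnification == pytest.approx(1.536)
    assert geom.n_projections == 600
    assert geom.angular_step == pytest.approx(0.6)


def test_inconsistent_arc_rejected():
    with pytest.raises(GeometryConfigError):
        make_geometry(n_projections=601, angular_step=0.6, arc=360.0)
    with pytest.raises(GeometryConfigError):
        make_geometry(n_projections=0)
    with pytest.raises(GeometryConfigError):
        make_geometry(bogus_key=1)


def test_degenerate_ray_rejected():
    with pytest.raises(GeometryConfigError):
        Ray((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
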