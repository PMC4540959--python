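import numpy as np
import pytest

from decbct.analysis import (
    RoiSpec,
    beam_hardening_metric,
    default_bh_rois,
    electron_density_image,
    evaluate_virtual_phantom,
    roi_mean,
)
from decbct.geometry import build_virtual_phantom, make_geometry
from decbct.materials import electron_density, make_basis_pair
from decbct.reconstruction import Volume, fbp_fan


def grid_volume(values, voxel_size=1.0):
    n = values.shape[-1]
    o = -(n - 1) / 2.0 * voxel_size
    return Volume(values, voxel_size, (o, o), "rho_e")


def test_roi_mean_constant_field():
    vol = grid_volume(np.full((101, 101), 3.25))
    assert roi_mean(vol, RoiSpec((10.0, -20.0))) == 3.25


def test_roi_mean_single_voxel():
    vals = np.zeros((101, 101))
    vals[50, 50] = 7.0  # voxel at world (0, 0)
    vol = grid_volume(vals)
    assert roi_mean(vol, RoiSpec((0.0, 0.0), (0.5, 0.5))) == 7.0


def test_roi_mean_checkerboard():
    ix = np.indices((100, 100)).sum(axis=0)
    vol = grid_volume((ix % 2).astype(float))
    assert roi_mean(vol, RoiSpec((0.0, 0.0), (10.0, 10.0))) == pytest.approx(0.5)


def test_roi_outside_volume_rejected():
    vol = grid_volume(np.zeros((50, 50)))
    with pytest.raises(ValueError):
        roi_mean(vol, RoiSpec((30.0, 0.0)))


def _volume_with_roi_values(center_val, periph_vals, r=40.0):
    xs = -(101 - 1) / 2.0 + np.arange(101)
    X, Y = np.meshgrid(xs, xs)
    vals = np.full((101, 101), float(center_val))
    centers = [(r, 0.0), (0.0, r), (-r, 0.0), (0.0, -r)]
    for (cx, cy), v in zip(centers, periph_vals):
        m = (np.abs(X - cx) <= 3.0) & (np.abs(Y - cy) <= 3.0)
        vals[m] = v
    return grid_volume(vals)


def test_beam_hardening_metric_cases():
    center = RoiSpec((0.0, 0.0))
    periph = tuple(RoiSpec(c) for c in [(40.0, 0.0), (0.0, 40.0), (-40.0, 0.0), (0.0, -40.0)])
    uniform = grid_volume(np.full((101, 101), 50.0))
    assert beam_hardening_metric(uniform, center, periph) == 0.0
    cupped = _volume_with_roi_values(100.0, [104.73] * 4)
    assert beam_hardening_metric(cupped, center, periph) == pytest.approx(4.73)
    balanced = _volume_with_roi_values(100.0, [96.0, 104.0, 96.0, 104.0])
    assert beam_hardening_metric(balanced, center, periph) == pytest.approx(0.0, abs=1e-12)


def test_beam_hardening_requires_four_rois_and_nonzero_center():
    center = RoiSpec((0.0, 0.0))
    periph = tuple(RoiSpec(c) for c in [(40.0, 0.0), (0.0, 40.0), (-40.0, 0.0)])
    vol = grid_volume(np.ones((101, 101)))
    with pytest.raises(ValueError):
        beam_hardening_metric(vol, center, periph)
    zeroed = grid_volume(np.zeros((101, 101)))
    with pytest.raises(ZeroDivisionError):
        beam_hardening_metric(zeroed, center, periph + (RoiSpec((0.0, -40.0)),))


def test_default_bh_roi_placement():
    center, periph = default_bh_rois(75.0)
    assert center.center == (0.0, 0.0)
    assert len(periph) == 4
    assert periph[0].center == (60.0, 0.0)


def test_electron_density_image_combines_basis_volumes(basis):
    ones = grid_volume(np.ones((32, 32)))
    zeros = grid_volume(np.zeros((32, 32)))
    b1 = Volume(ones.values, 1.0, ones.origin, "b1")
    b2 = Volume(zeros.values, 1.0, zeros.origin, "b2")
    rho = electron_density_image(b1, b2, basis)
    assert np.allclose(rho.values, basis.rho_e1)
    assert rho.quantity == "rho_e"
    half = Volume(np.full((32, 32), 0.5), 1.0, ones.origin, "b1")
    rho2 = electron_density_image(half, Volume(half.values, 1.0, half.origin, "b2"), basis)
    assert np.allclose(rho2.values, 0.5 * (basis.rho_e1 + basis.rho_e2))
    with pytest.raises(ValueError):
        electron_density_image(b1, Volume(np.zeros((16, 16)), 1.0, (0, 0), "b2"), basis)


def test_density_synthesis_commutes_with_reconstruction(basis, rng):
    """FBP linearity: combining before or after reconstruction is identical."""
    geom = make_geometry(n_projections=90, angular_step=4.0, det_cols=64,
                         det_rows=1, pixel_size=2.0)
    B1 = rng.random((90, 64))
    B2 = rng.random((90, 64))
    v1 = fbp_fan(B1, geom, n_voxels=32, voxel_size=2.0, quantity="b1")
    v2 = fbp_fan(B2, geom, n_voxels=32, voxel_size=2.0, quantity="b2")
    combined_after = electron_density_image(v1, v2, basis)
    combined_before = fbp_fan(B1 * basis.rho_e1 + B2 * basis.rho_e2, geom,
                              n_voxels=32, voxel_size=2.0, quantity="rho_e")
    scale = np.abs(combined_before.values).max()
    assert np.allclose(combined_after.values, combined_before.values, atol=1e-10 * scale)


def test_evaluation_report_on_painted_phantom():
    """Painting exact theoretical values into the grid gives zero error, r = 1."""
    ph = build_virtual_phantom()
    n, vs = 256, 1.0
    o = -(n - 1) / 2.0 * vs
    xs = o + np.arange(n) * vs
    X, Y = np.meshgrid(xs, xs)
    vals = np.zeros((n, n))
    inside = X**2 + Y**2 <= ph.background.radius**2
    vals[inside] = electron_density(ph.background.material)
    for ins in ph.inserts:
        m = (X - ins.center[0]) ** 2 + (Y - ins.center[1]) ** 2 <= ins.radius**2
        vals[m] = electron_density(ins.material)
    vol = Volume(vals, vs, (o, o), "rho_e")
    report = evaluate_virtual_phantom(vol, ph)
    assert len(report.rows) == 5
    assert report.max_error_pct == pytest.approx(0.0, abs=1e-12)
    assert report.correlation == pytest.approx(1.0, abs=1e-12)


def test_evaluation_error_formula_matches_hand_computation():
    """A polyethylene reading of 1.0559 against theory 1.0608 is a 0.46% error."""
    ph = build_virtual_phantom()
    n, vs = 256, 1.0
    o = -(n - 1) / 2.0 * vs
    vals = np.full((n, n), 1.1102)
    pe = next(i for i in ph.inserts if i.material.name == "polyethylene")
    xs = o + np.arange(n) * vs
    X, Y = np.meshgrid(xs, xs)
    m = (X - pe.center[0]) ** 2 + (Y - pe.center[1]) ** 2 <= pe.radius**2
    vals[m] = 1.0559
    vol = Volume(vals, vs, (o, o), "rho_e")
    report = evaluate_virtual_phantom(vol, ph)
    row = report.rows.set_index("material").loc["polyethylene"]
    theor = electron_density(pe.material)
    assert row["error_pct"] == pytest.approx(abs(1.0559 - theor) / theor * 100.0)
    assert round(row["error_pct"], 2) == 0.46
    # self-consistency of the whole column
    recomputed = (report.rows["calculated"] - report.rows["theoretical"]).abs() \
        / report.rows["theoretical"] * 100.0
    assert np.allclose(report.rows["error_pct"], recomputed)
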