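import numpy as np
import pytest

from decbct.decomposition import build_lut, decompose, invert_pair
from decbct.geometry import Cylinder, PhantomSpec, build_uniformity_phantom, make_geometry
from decbct.materials import electron_density, get_material, linear_attenuation, make_basis_pair
from decbct.projector import polychromatic_projection
from decbct.spectrum import delta_spectrum


def brute_force_dual_energy_projection(d1, d2, basis, spectrum):
    """Independent oracle: plain-Python energy sum of the two-slab model."""
    total = 0.0
    for e, w in zip(spectrum.energies, spectrum.weights):
        mu1 = linear_attenuation(basis.material1, float(e))
        mu2 = linear_attenuation(basis.material2, float(e))
        total += w * np.exp(-d1 * mu1 - d2 * mu2)
    return -np.log(total)


def test_lut_origin_is_zero(lut):
    i = np.where(lut.d1_grid == 0.0)[0][0]
    j = np.where(lut.d2_grid == 0.0)[0][0]
    assert lut.gH_table[i, j] == 0.0
    assert lut.gL_table[i, j] == 0.0


def test_lut_tables_strictly_monotone(lut):
    for tab in (lut.gH_table, lut.gL_table):
        assert np.all(np.diff(tab, axis=0) > 0)
        assert np.all(np.diff(tab, axis=1) > 0)


def test_lut_matches_independent_integration_oracle(lut, basis, spectra_hl):
    sH, sL = spectra_hl
    rng = np.random.default_rng(11)
    for _ in range(5):
        d1 = rng.uniform(-20.0, 300.0)
        d2 = rng.uniform(-10.0, 50.0)
        gH, gL = lut.forward(d1, d2)
        assert gH == pytest.approx(brute_force_dual_energy_projection(d1, d2, basis, sH), abs=1e-12)
        assert gL == pytest.approx(brute_force_dual_energy_projection(d1, d2, basis, sL), abs=1e-12)


def test_monochromatic_lut_entry_is_linear_slab(basis):
    sH, sL = delta_spectrum(80.0), delta_spectrum(50.0)
    lut = build_lut(basis, sH, sL, d1_grid=np.arange(0.0, 101.0, 10.0),
                    d2_grid=np.arange(0.0, 21.0, 1.0))
    mu1 = linear_attenuation(basis.material1, 80.0)
    i = np.where(lut.d1_grid == 10.0)[0][0]
    j = np.where(lut.d2_grid == 0.0)[0][0]
    assert lut.gH_table[i, j] == pytest.approx(10.0 * mu1, rel=1e-12)


def test_invert_identity_at_origin(lut):
    assert invert_pair(lut, 0.0, 0.0) == (0.0, 0.0)


def test_round_trip_lattice(lut):
    """invert(forward(d1, d2)) recovers the pair within 0.01 mm, on- and off-grid."""
    d1 = np.linspace(0.0, 400.0, 10)
    d2 = np.linspace(0.0, 60.0, 10) + 0.137  # deliberately off-grid
    d2[-1] = 60.0
    D1, D2 = np.meshgrid(d1, d2, indexing="ij")
    gH, gL = lut.forward(D1.ravel(), D2.ravel())
    from decbct.decomposition import _newton_invert

    r1, r2, n_bad = _newton_invert(lut, gH, gL)
    assert n_bad == 0
    assert np.max(np.abs(r1 - D1.ravel())) < 0.01
    assert np.max(np.abs(r2 - D2.ravel())) < 0.01


def test_monochromatic_inversion_matches_linear_solve(basis):
    eH, eL = 80.0, 50.0
    lut = build_lut(basis, delta_spectrum(eH), delta_spectrum(eL),
                    d1_grid=np.arange(-20.0, 201.0, 5.0),
                    d2_grid=np.arange(-10.0, 41.0, 1.0))
    A = np.array([
        [linear_attenuation(basis.material1, eH), linear_attenuation(basis.material2, eH)],
        [linear_attenuation(basis.material1, eL), linear_attenuation(basis.material2, eL)],
    ])
    rng = np.random.default_rng(5)
    for _ in range(10):
        d_true = rng.uniform([0.0, 0.0], [150.0, 30.0])
        g = A @ d_true
        d1, d2 = invert_pair(lut, g[0], g[1])
        d_lin = np.linalg.solve(A, g)
        assert abs(d1 - d_lin[0]) < 1e-8
        assert abs(d2 - d_lin[1]) < 1e-8


def test_pure_graphite_phantom_decomposes_onto_first_axis(lut, graphite, spectra_hl):
    """A graphite-only object needs no aluminum: B2 ~ 0 and B1 equals the chord."""
    sH, sL = spectra_hl
    ph = PhantomSpec(Cylinder((0.0, 0.0), 30.0, graphite))
    geom = make_geometry(n_projections=2, angular_step=180.0, det_cols=129,
                         det_rows=1, pixel_size=1.0)
    projH = polychromatic_projection(ph, geom, sH)
    projL = polychromatic_projection(ph, geom, sL)
    bp = decompose(projH, projL, lut)
    assert np.max(np.abs(bp.B2)) < 0.1
    from decbct.geometry import detector_pixel_positions, path_lengths_batch, source_position

    src = source_position(geom, 0.0)
    pix = detector_pixel_positions(geom, 0.0)
    chord = path_lengths_batch(ph, src, pix)[graphite]
    assert np.allclose(bp.B1[0], chord, atol=0.1)


def test_water_path_maps_to_equivalent_electron_density(lut, water, spectra_hl):
    """B1*rho_e1 + B2*rho_e2 reproduces the electron-density line integral of water."""
    sH, sL = spectra_hl
    ph = build_uniformity_phantom(100.0)
    geom = make_geometry(n_projections=1, angular_step=360.0, det_cols=9,
                         det_rows=1, pixel_size=1.0)
    projH = polychromatic_projection(ph, geom, sH)
    projL = polychromatic_projection(ph, geom, sL)
    bp = decompose(projH, projL, lut)
    basis = lut.basis
    central = bp.B1[0, 0, 4] * basis.rho_e1 + bp.B2[0, 0, 4] * basis.rho_e2
    # detector column 4 of 9 is the exact central ray: 100 mm of water
    expected = electron_density(water) * 100.0
    assert central == pytest.approx(expected, rel=0.01)


def test_geometry_mismatch_rejected(lut, spectra_hl):
    sH, sL = spectra_hl
    ph = build_uniformity_phantom(100.0)
    gA = make_geometry(n_projections=2, angular_step=180.0, det_cols=16,
                       det_rows=1, pixel_size=8.0)
    gB = make_geometry(n_projections=4, angular_step=90.0, det_cols=16,
                       det_rows=1, pixel_size=8.0)
    pA = polychromatic_projection(ph, gA, sH)
    pB = polychromatic_projection(ph, gB, sL)
    with pytest.raises(ValueError):
        decompose(pA, pB, lut)


def test_grid_validation():
    basis = make_basis_pair()
    sH, sL = delta_spectrum(80.0), delta_spectrum(50.0)
    with pytest.raises(ValueError):
        build_lut(basis, sH, sL, d1_grid=np.array([5.0, 1.0, 10.0]),
                  d2_grid=np.arange(0.0, 5.0))
    with pytest.raises(ValueError):
        build_lut(basis, sH, sL, d1_grid=np.array([1.0, 2.0]),
                  d2_grid=np.arange(0.0, 5.0))
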