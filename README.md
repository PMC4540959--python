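# decbct — dual-energy CBCT electron-density imaging

`decbct` simulates and reconstructs **dual-energy cone-beam CT (CBCT)
electron-density images** of the kind used for dose calculation in
image-guided and adaptive radiotherapy. Conventional CBCT converts CT numbers
(HU) to electron density through a calibration curve, which is confounded by
beam hardening and by the dependence of HU on effective atomic number. The
dual-energy approach implemented here measures electron density directly from
two scans at different tube potentials, and removes most of the
beam-hardening (cupping) artifact as a side effect.

It is aimed at medical-physics researchers who want a fully controllable,
analytic test bench for projection-domain dual-energy decomposition: every
stage — spectra, phantom, forward projection, look-up table, inversion,
filtered backprojection, evaluation — is open and exact, with no scanner
data required.

## Method

In the diagnostic energy range the linear attenuation of any material is
well approximated by a linear combination of two basis materials (graphite
and aluminum here):

    μ(E) = b₁ μ₁(E) + b₂ μ₂(E)

Scanning the object at high and low tube potentials (120 and 70 kVp) gives
two polychromatic log-projections per ray,

    g_H = −ln ∫ S_H(E) exp(−B₁μ₁(E) − B₂μ₂(E)) dE
    g_L = −ln ∫ S_L(E) exp(−B₁μ₁(E) − B₂μ₂(E)) dE

where Bᵢ = ∫ bᵢ dl are the line integrals of the basis coefficients. The
same forward model evaluated for pure two-slab paths (d₁, d₂) defines a
**look-up table** (d₁, d₂) → (g_H, g_L); inverting it per pixel turns the
measured projection pair into (B₁, B₂) sinograms. Because the table is built
with the same polychromatic spectra used for scanning, beam hardening is
baked into the calibration and cancels in the inversion. The basis
coefficient images b₁, b₂ are reconstructed by filtered backprojection
(FDK for cone beams), and the electron-density image follows voxel-wise:

    ρe = b₁ ρe₁ + b₂ ρe₂

Electron densities are expressed in units of N_A/2 electrons per cm³
(ρe = 2ρ Σᵢ wᵢ Zᵢ/Aᵢ), so water = 1.1102. Cupping is quantified as
BH = (mean_periphery − mean_center)/mean_center × 100 over five square ROIs.

## Worked example

Simulate a 256 mm water cylinder with silicon, PMMA, polyethylene and
graphite inserts, scanned at 120/70 kVp (fan-beam central slice, 360 views,
512-pixel detector, 256² image at 1 mm):

```python
from decbct import preset_config, run_pipeline

result = run_pipeline(preset_config("desk"))
print(result.report)
```

prints (runtime ≈ 10 s):

```
Electron-density evaluation (units of N_A/2 electrons/cm^3)

    material  calculated  theoretical  error_pct
     silicon      2.3180       2.3229     0.2141
        pmma      1.2829       1.2837     0.0594
polyethylene      1.0588       1.0608     0.1878
    graphite      1.6985       1.6984     0.0063
       water      1.1101       1.1102     0.0103

Pearson correlation (calculated vs theoretical): 0.999996
BH[70kVp] = 5.02
BH[120kVp] = 4.77
BH[dual_rho_e] = -0.02
```

Every insert's reconstructed electron density lands within 1% of the
theoretical value, and the cupping metric drops from ~5% in the
single-energy attenuation images to essentially zero in the dual-energy
electron-density image — the core of what the method buys you.

The same pipeline is available from the shell:

```
decbct run-all --preset desk --outdir out/
decbct run-all --preset desk --phantom uniformity --outdir out-uniform/
```

which writes projections and the LUT as HDF5, volumes as MetaImage (.mha)
and the evaluation report as CSV/text. Individual stages are exposed as
`simulate-projections`, `build-lut`, `decompose`, `reconstruct` and
`evaluate` subcommands.

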