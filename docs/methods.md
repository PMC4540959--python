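# Methods

This note records the physical model, the numerical choices and the known
limits of the `decbct` pipeline, in the order the data flows through it.

## Attenuation data and materials

Elemental mass attenuation coefficients μ/ρ(E) for H, C, N, O, Al and Si are
packaged as CSV tables on the standard reference grid
(10, 15, 20, 30, 40, 50, 60, 80, 100, 150 keV) and interpolated
**log-log linearly** between grid points. In the 10–150 keV window these
cross sections are smooth power-law-like curves with no K-edges for these
elements, so log-log interpolation on the native grid is accurate and is the
standard way attenuation tables are consumed. Compounds use the mixture rule
Σ wᵢ (μ/ρ)ᵢ with mass fractions derived from chemical formulas and standard
atomic masses.

Electron densities are reported throughout in units of **N_A/2 electrons per
cm³**, i.e. ρe = 2ρ Σ wᵢ Zᵢ/Aᵢ, which makes water 1.1102 and graphite
(1.700 g/cm³) 1.6984; `electron_density_per_cm3` converts to absolute
electrons/cm³. Default densities are common reference values
(water 1.000, graphite 1.700, aluminum 2.699, silicon 2.330, PMMA 1.190,
polyethylene 0.930 g/cm³) and every material's density can be overridden at
load time; published theoretical values for Si and PMMA that assume slightly
different densities (≈2.335 and ≈1.200) can be reproduced that way rather
than by changing the defaults.

## Spectra

The default tube model is **Kramers bremsstrahlung**, N(E) ∝ (kVp − E)/E on a
1 keV grid from 10 keV to the peak potential, hardened through 2.5 mm of
aluminum (inherent filtration) by Beer–Lambert and renormalized. Tungsten
characteristic lines and detector energy response are omitted: the
decomposition look-up table is built with the *same* spectra used for
projection, so a residual spectrum-model error cancels in the inversion and
only affects how closely the simulated beam resembles a particular physical
tube. Projections are fluence-weighted (∫S(E)·exp(…)dE). Measured spectra
can be supplied as two-column text files and used verbatim.

## Phantoms, geometry and forward projection

Phantoms are analytic: a background cylinder plus non-overlapping cylindrical
inserts, so all ray path lengths are exact line–cylinder chords (no
voxelization error in the data). The scan geometry is the clinical CBCT
layout: SAD 1000 mm, SDD 1536 mm, circular full 360° arc, flat detector.
The virtual evaluation phantom is a 256 mm water cylinder with four 40 mm
inserts (Si, PMMA, PE, graphite) centred 64 mm from the axis at 0°, 90°,
180°, 270°; the insert radius and positions are this package's stated layout
choice (symmetric and well separated) — only the insert materials and the
background diameter are fixed by the method itself. A 150 mm
uniform water cylinder emulates a CT uniformity module for cupping studies.

The projector computes g = −ln Σ_E S(E) exp(−Σ_m μ_m(E) d_m) with a
rectangle-rule sum on the spectrum's own 1 keV grid; quadrature error is
negligible against the spectrum model itself. The sign convention
g = −ln(I/I₀) ≥ 0 is fixed and recorded on every projection set. Optional
Poisson noise resamples I₀e^{−g} at a given photon count (zero counts are
clamped to one); the default study conditions are noiseless. No X-ray
scatter is simulated anywhere — deliberately, since the method itself does
not correct scatter.

## Look-up table and inversion

The table spans d₁ ∈ [−50, 400] mm (graphite) × d₂ ∈ [−20, 60] mm
(aluminum) at 2 mm / 0.5 mm spacing, anchored exactly at 0. Negative path
lengths are intentional: the basis expansion is algebraic, and materials
less attenuating than graphite (polyethylene, lung-like tissue) decompose
to b₂ < 0. A physical step-wedge calibration cannot realize d < 0 — grids
matching that experimental sampling (10 mm graphite slabs, 1 mm aluminum
steps, non-negative) are provided as presets.

Inversion of a measured (g_H, g_L) pair proceeds in two stages:

1. **initial guess** — piecewise-linear interpolation of the *inverse* map
   built from the tabulated grid points (nearest-neighbour fallback outside
   the convex hull of tabulated g-pairs);
2. **damped Newton** — 2-D Newton iteration on the smooth forward model with
   its analytic Jacobian (computed from the same energy sum), with
   step-halving backtracking; convergence at |Δg| < 1e−6, cap 50 iterations.

Newton refinement removes grid-resolution bias, so the result is exact to
solver tolerance for on- and off-grid values; round-trips recover path
lengths to better than 0.01 mm across the full grid range. Non-converged
pixels keep their best iterate and are counted, never silently accepted;
in the shipped configurations the count is zero.

## Reconstruction

Fan-beam FBP (flat, equispaced detector): detector coordinates are rescaled
to the isocenter line, projections are cosine pre-weighted
(SAD/√(SAD²+u²)), filtered with the band-limited spatial **Ram-Lak ramp**
kernel via zero-padded FFT convolution (no apodization; cutoff at Nyquist),
and backprojected with linear interpolation and SAD²/L² distance weighting;
the angular sum carries a factor ½ because a 360° orbit measures every line
twice. FDK extends this with the cosine row weight SAD/√(SAD²+u²+v²) and
bilinear interpolation; on the central plane it reproduces the fan result to
float accuracy (regression-tested at 0.1% RMS). Points projecting outside
the detector contribute zero. Arcs other than 360° are rejected.
Reconstruction is linear in the sinogram, so combining basis channels before
or after reconstruction is equivalent; the pipeline reconstructs b₁ and b₂
separately and combines them voxel-wise into ρe.

A monochromatic reconstruction of a centred uniform cylinder recovers the
known μ at the center to within 2% at 180 views × 256 detector pixels; the
residual is ordinary FBP discretization (view sampling, ramp-filter DC
behaviour), not modelling error.

## Evaluation

ROI means are taken over voxels whose centers fall in 5 × 5 mm² squares: one
per insert center plus one at the background axis for accuracy, and one
central plus four peripheral ROIs at 80% of the phantom radius (0°/90°/
180°/270°, configurable) for the cupping metric
BH = (mean_periphery − mean_center)/mean_center × 100. Accuracy is
summarized by per-material percent errors and the Pearson correlation
between calculated and theoretical ρe (five materials for the virtual
phantom).

BH is applied to the attenuation image for the single-energy arms and to the
ρe image for the dual-energy arm. Applying it to a raw HU image of a
water-like object would divide by a near-zero central mean (the metric's
own error contract rejects that); since HU is an affine rescale of μ, the
μ-image BH equals the BH of HU + 1000 and preserves the comparison.

## Study conditions and problem sizes

The `desk` configuration — the package's standard evaluation run — is the
central-slice fan-beam scan: 360 views over 360°, 512-pixel detector row at
1 mm, 256² voxels at 1 mm, noiseless 120/70 kVp Kramers spectra with 2.5 mm
Al. The `full-scale` configuration uses the clinical acquisition settings
(600 views at 0.6°, 0.5 mm voxels, 512² grid; cone-beam available via
`mode="cone3d"`). Both FOVs comfortably cover the 256 mm phantom at 1.536
magnification. On the desk scale the method's accuracy (max ρe error ≈0.2%,
r > 0.9999) is already converged; the full scale mainly sharpens edges.

## What the simulation does and does not show

Passing the accuracy and cupping checks on these analytic phantoms shows
that the decomposition, inversion and reconstruction chain is correct and
that the LUT removes the beam hardening it was built to encode. It does
**not** show robustness to X-ray scatter (not simulated, not corrected),
detector lag/glare/energy response, focal-spot blur, spectrum drift between
calibration and scan, or anatomical complexity — on real cone-beam systems
scatter is the dominant residual error, and measured accuracy there is
expected to be worse (percent-level differences rather than the
sub-percent values seen in simulation). The basis-material model itself is
an approximation: two bases span photoelectric + Compton behaviour, so
materials of very high Z or at energies near K-edges are out of scope, as
are three-material decomposition and image-domain (post-reconstruction)
decomposition.
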