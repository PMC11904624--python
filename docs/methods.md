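# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `fibrosynth`, in the spirit of a model-description
document: what the package computes, why the defaults are what they are,
and what its tests do and do not demonstrate.

## The double distance map

Synthesis operates on `I = d̂(solid) − d̂(pore) + 1`, where `d̂` is the
Euclidean distance of each in-phase voxel to the nearest voxel *centre* of
the opposite phase, divided by that field's maximum over the volume.

Two conventions matter:

* **Voxel-centre distances.** Interface-adjacent voxels get distance 1,
  never 0, so every voxel sits strictly on its own side of `I = 1` and the
  σ = 0 threshold inverts the map exactly (verified by a round-trip
  property test on random volumes).
* **Per-phase normalization.** Each phase's distance field is scaled by its
  own maximum, so both phases span equal intensity amplitude (solid in
  (1, 2], pore in [0, 1)). We also evaluated normalizing both fields by a
  single shared maximum, which makes the two phases' *spatial* gradients
  equal instead; on thin-fibre microstructures this leaves the solid phase
  with so little intensity amplitude that patch blending and the final
  Gaussian smoothing systematically erase fibres (porosity drifts upward
  by ≈ +0.13 at our reference conditions). Per-phase normalization keeps
  thresholding robust and is the default and only mode.

The price of per-phase normalization is that when the two phases have very
different characteristic thicknesses, the map's gradient is steeper on the
thin-phase side, and *any* interpolating operation (trilinear rotation,
intensity shift, seam blending, smoothing) drifts the interface slightly
toward the thick phase. This is visible as a small porosity deficit in the
transformed patch dataset and is partly compensated by the feature filter;
see "Fidelity" below.

## Transformations and the patch dataset

The seven transforms are: identity; ±8° rotations about the third array
axis; opening, closing, erosion and dilation (grayscale, spherical element
of diameter 3 voxels) composed with ±8° rotations about the second and
first axes. Morphology is applied before rotation. Rotated volumes are
cropped to the largest centred axis-aligned box of valid voxels (computed
in closed form, minus a 2-voxel interpolation guard). Each transformed
volume is then intensity-shifted by U(−0.1, 0.1) and scaled by
U(0.9, 1.1); the scale acts on the deviations about the interface level 1,
so rescaling never moves the phase boundary itself. Shift and scale are
drawn once per transformed volume, not per patch.

Per-patch features: porosity (pore-voxel fraction after σ = 0
thresholding), specific surface (interface face count × voxel area /
patch volume, 1/mm), and maximum inscribed pore diameter (2 × max pore
distance transform × voxel size, μm). The (α, β, γ) coordinates are
min–max normalized over the *unfiltered* dataset and frozen, so filter
targets always refer to the same frame; a feature with zero range maps to
0.5 (neutral under a centred target). The filter keeps the ⌈P/8⌉ patches
nearest the target, ties broken by dataset order.

## Reconstruction

A stored patch of size s is treated as "core plus margin": grid corner c
owns the core cell of size s − 2m and its patch covers canvas voxels
[c − m, c − m + s), so adjacent windows overlap by 2m and the windows tile
the output volume. Matching error is the mean absolute difference over
the occupied voxels of the window (exhaustive scan over the dataset;
lowest index wins ties; an empty overlap draws a uniform random patch).
Blending weights are the Euclidean distance of occupied voxels to the
nearest unoccupied voxel — computed with context beyond the window so that
interior depth saturates correctly — normalized by the window maximum;
unoccupied voxels have weight 0. The window becomes
`existing·w + patch·(1 − w)`. An occupancy mask is tracked explicitly
because a legitimate map value can be exactly 0 and cannot double as an
"empty" sentinel. Finally the canvas is cropped, smoothed (σ = 0.5) and
thresholded at 1 (exact ties fall to pore).

Determinism: one `numpy` PCG64 generator seeded from the config drives the
placement permutation and all random patch draws; identical config +
dataset + seed give bit-identical volumes.

## Pore-network model

Extraction: Euclidean distance transform of the pore phase → Gaussian
pre-smoothing (σ = 0.4 voxels) → h-maxima suppression (h = 1 voxel,
configurable) → marker-based watershed of the negated field. The pore
phase is treated with maximal (26-)connectivity throughout; with face
connectivity, diagonal-contact voxels appear as isolated one-voxel "pores"
of connectivity zero and corrupt the network statistics. Isolated pore
components that lose all markers to suppression get one marker at their
distance-map argmax, so the watershed always partitions the full pore
space.

Conventions: pore centre = position of the region's distance-map maximum;
pore radius = that maximum (inscribed sphere); throat radius = the
maximum over the two regions' shared boundary of the *smaller* of the two
facing voxels' distances, which keeps every throat no wider than either
of its pores; throat length = centre-to-centre distance; Table-style pore
radius is volume-weighted by default (arithmetic available).

Flow: Hagen–Poiseuille conductances g = πr⁴/(8μl) on throats; boundary
pores additionally couple to the inlet/outlet faces through half-throat
conductances built from the pore's own radius and its centre-to-face
distance. This choice makes a single spanning cylindrical channel
reproduce the closed form K = πr⁴/(8A) exactly, which is the oracle used
in testing. A unit pressure drop is applied; the sparse linear system is
solved directly, interior mass-conservation residuals are checked to
≤ 1e−10 (relative), and non-percolating directions report K = 0 with a
flag. Units are SI internally and Darcy (9.869 × 10⁻¹³ m²) / μm in
reports. Viscosity cancels from K and only affects intermediate fluxes.

## Phantom generator

The generator emulates the fibrous microstructure of meniscal tissue at
6.25 μm voxels: straight fibres with blue-noise cross-sectional placement
(minimum separation 2.5 fibre radii), orientation jitter about a dominant
axis, slow sinusoidal caliber variation along each fibre (±25%,
wavelength 24–48 voxels ≈ 150–300 μm), and a global radius rescaling
found by bisection to hit the target porosity (±0.03; rescaling is
limited to 0.25–4× nominal so the structure stays fibre-like, and an
explicit error names the achieved porosity when the target is out of
reach). Because the generator stands in for *scanned* exemplars — which
are binarized band-limited images, not analytic indicator functions — the
solid indicator is finally blurred with the imaging point-spread function
(Gaussian σ = 0.5 voxels ≈ 1-voxel FWHM, configurable) and re-thresholded
at 0.5; without this the phantom carries stair-step surface roughness no
scan would show, which reads as artificially narrow throat
constrictions.

Defaults were fixed once against published morphology of meniscal tissue
at this resolution: fibre radius 2.5 ± 0.6 voxels (≈ 16 μm) and 25°
jitter give porosity-0.61 phantoms with volume-weighted pore radius
≈ 44 μm, throat radius ≈ 13 μm, coordination number ≈ 8 and a
longitudinal/transverse permeability ratio ≈ 2 — close to reported tissue
values (≈ 34 μm, ≈ 19 μm, ≈ 6.5, ratio ≈ 2). Two deliberate
simplifications: smooth cylinders cannot reach tissue-level specific
surface (≈ 88/mm) at realistic fibre radii, so the phantom sits near
52/mm; and fibre paths are straight (no crimp), so anisotropy is driven by
orientation jitter alone. The caliber variation exists for realism *and*
regularization: constant-radius fibres produce pore channels whose
distance-map ridge is flat over tens of voxels, making watershed pore
statistics ill-defined.

What phantom-based tests do **not** show: performance on real μCT data
with imaging noise, partial-volume surfaces, proteoglycan-phase texture or
multi-scale fibril architecture.

## Fidelity at the reference conditions

At the reference study conditions (96³ exemplar at porosity 0.61, patch
24³, margin 6, N = 200 per transform, unbiased target, 10 seeds) the
seed-averaged reconstruction errors are ≈ 1% for porosity and within 10%
for pore radius, throat radius and specific surface, but ≈ 20% for
connectivity and ≈ 50% for permeability (all computed by
`scripts/acceptance.py` and the acceptance test suite at run time; the
exact values vary a few points with the seed). The error hierarchy has a
simple structure: the reconstructed texture is slightly smoother and
coarser than the exemplar — six of the seven dataset transforms pass
through trilinear interpolation, seams are blended, and the final
Gaussian acts once more — and permeability amplifies the residual
throat-radius and connectivity biases roughly quartically. On
fine-textured phantoms the permeability of small volumes is additionally
dominated by a few spanning channels, so it is the least reproducible
property, consistent with it being the worst case in tissue-based
validation as well.

Similarly, the qualitative expectation that permeability correlates more
strongly with the *product* of pore size and connectivity than with
either factor alone does not hold on our scaled-down conditioned
ensembles (102 reconstructions of 48³): watershed connectivity at these
volume sizes is noisy and saturates with porosity, so the product gains
nothing over pore size alone. The corresponding acceptance test asserts
the ordering and currently documents this divergence rather than hiding
it.

## Numerical choices and degenerate inputs

* Threshold ties (`I = 1` exactly) resolve to pore.
* Single-phase volumes are rejected for distance mapping; single-phase
  patches get total-function features (porosity 0/1, surface 0, inscribed
  diameter 0 or the block minimum edge).
* All-pore volumes form a single pore bounded by the volume faces.
* Throat lengths are floored at half a voxel to avoid degenerate
  conductances.
* Feature columns with zero range normalize to 0.5.
* Sub-seeds for pipeline stages come from `numpy.random.SeedSequence`
  with fixed stage indices, so adding a stage never changes the
  randomness of earlier stages.
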