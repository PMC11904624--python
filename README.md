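# fibrosynth

Adaptive exemplar-based synthesis and hydraulic analysis of fibrous porous
microstructures.

Fibrous soft tissues such as the knee meniscus owe their load-bearing and
fluid-transport behaviour to a highly organized collagen-fibre
microstructure. Studying structure–property relationships in such tissues
is limited by how few real micro-CT samples can ever be acquired.
`fibrosynth` addresses this with *data augmentation by synthesis*: given one
binary exemplar volume (solid = 1, pore = 0), it generates arbitrarily many
statistically similar 3D realizations — either unbiased, or deliberately
biased toward higher/lower porosity, specific surface, or pore size — and
analyses each realization's pore network and Darcy permeability. It is
aimed at researchers in tissue biomechanics, porous-media physics and
biomimetic scaffold design.

## Method

**Double distance map.** A binary volume cannot be interpolated, so it is
first converted to a grayscale field

    I = d̂(I₀) − d̂(1 − I₀) + 1,

where `d̂` is the Euclidean distance transform of each phase normalized by
its own maximum. `I` runs continuously from 0 (deep pore) through 1 (the
interface) to 2 (deep solid), and thresholding `(G_σ(I) − 1) > 0` recovers
the binary volume exactly when σ = 0.

**Patch dataset.** Seven geometric transformations g(I, i), i ∈ {1..7} —
identity, ±8° rotations about each axis, and grayscale
opening/closing/erosion/dilation (spherical element, diameter 3 voxels)
composed with those rotations — plus a random intensity shift (±0.1) and
scale (±10%) diversify the exemplar. N random cubic patches of size
s₁×s₂×s₃ from each transform give a dataset D of exactly 7N patches. Each
patch gets three features — porosity, specific surface (1/mm), maximum
inscribed pore diameter (μm) — min–max normalized to coordinates
(α, β, γ) ∈ [0,1]³. Conditioned synthesis keeps the 1/8 of patches nearest
a target (α*, β*, γ*); the centre (0.5, 0.5, 0.5) is the unbiased setting.

**Quilting reconstruction.** Grid corners spaced Δ = s − 2m apart (overlap
margin m, default 6 voxels) are visited in seeded random order. At each
corner the candidate patch minimizing the mean absolute mismatch over the
already-occupied window voxels is chosen by exhaustive scan and blended in
with weights that ramp from the unoccupied frontier (new patch wins) into
the occupied interior (existing content wins). Cropping, Gaussian
smoothing (σ = 0.5) and thresholding yield the final binary volume.

**Pore-network analysis.** Marker-based watershed of the pore-phase
distance map (Gaussian pre-smoothing σ = 0.4 voxels, h-maxima suppression
h = 1 voxel) partitions the pore space into pores and throats. Flow is
solved with Hagen–Poiseuille conductances g = πr⁴/(8μl) and mass
conservation at every pore under a unit pressure drop, giving directional
permeabilities in Darcy via K = QμL/(AΔP).

**Closed-form correlations.** Porosity-only predictors for permeability
along and across the fibre direction and for the normalized Young's
modulus:

    K_L = exp(4.719·ln φ + φ + 5.097)      [Darcy]
    K_T = exp(5.567·ln φ + φ + 4.239)      [Darcy]
    E_n = 1 − 1.1456·φ² + 0.0853·φ

with E_n(0) = 1 exactly. These can be broadcast over a porosity map derived
from a 2D CT image via a user-calibrated linear CT-number → porosity
mapping.

A built-in phantom generator (`fibrosynth.phantom`) produces fibrous binary
volumes — quasi-parallel, blue-noise-placed fibres with orientation jitter
and caliber variation, tuned to a target porosity — so the whole pipeline
runs and is tested without any real imaging data.

## Worked example

```
$ fibrosynth phantom --shape 64 --porosity 0.61 --seed 1 -o exemplar.tif
wrote exemplar.tif (porosity 0.610)

$ fibrosynth reconstruct --exemplar exemplar.tif --out recon.tif \
    --shape 64 --patch 16 --margin 4 --n-per-transform 60 \
    --alpha 0.5 --beta 0.5 --gamma 0.5 --seed 7
wrote recon.tif (porosity 0.625)

$ fibrosynth analyze recon.tif -o net
{
 "pore_radius_um": 39.026197751702924,
 "throat_radius_um": 17.25604241382179,
 "pore_connectivity": 4.926829268292683,
 "porosity": 0.6249237060546875,
 "specific_surface_per_mm": 35.7977294921875,
 "K_longitudinal_darcy": 65.6850276054506,
 "K_transverse_x_darcy": 2.7173580242051565,
 "K_transverse_y_darcy": 2.9975042509217635,
 "permeability_darcy": 23.79996329352584
}

$ fibrosynth predict --phi 0.61
{
 "KL_darcy": 29.207211774419324,
 "KT_darcy": 8.143763148633298,
 "En": 0.62575524
}
```

The unbiased reconstruction reproduces the exemplar's porosity to within a
few percent (0.625 vs 0.610 here); `analyze` reports Table-style
morphology (volume-weighted mean pore radius and mean throat radius in μm,
mean coordination number, porosity, specific surface in 1/mm) and the
directional permeabilities plus their arithmetic mean in Darcy — note the
strong longitudinal/transverse anisotropy of the aligned-fibre geometry,
and that the permeability of a single small volume is dominated by a few
spanning channels and varies substantially between realizations. `predict`
evaluates the closed-form porosity correlations: at φ = 0.61 the
longitudinal permeability is ≈ 3.6× the transverse one, and the tissue
retains ≈ 63% of its dense-material stiffness.

A full end-to-end run (phantom → dataset → n reconstructions → averaged
summaries → hash manifest) is

```
fibrosynth pipeline --out-dir run1 --shape 96 --patch 24 \
    --n-per-transform 200 --n-realizations 10 --seed 1
```

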