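# Methods

This note documents the models, numerical choices, and limitations behind
`scatterct`, in the order the pipeline uses them.

## Illumination model

The physical system translates one large pre-characterized binary mask
(nominally 1480 × 1480 pixels over 160 mm, pitch ≈ 108 µm, 1:1
transmission–absorption ratio) between exposures. The package models the
mask as an i.i.d. Bernoulli(duty) grid, duty 0.5 by default, and extracts
pattern windows at offsets drawn without replacement ("random-shift", the
software analogue of mask translation) or on a raster ("tile"). Rows of the
measurement matrix **A** are flattened windows; row-major flattening,
0-based (row, col) offsets throughout, recorded in every file sidecar.

The **autocorrelation width** — the FWHM of the mean-subtracted,
peak-normalized linear autocorrelation, measured along the horizontal lag
axis with linear interpolation at half maximum — is the theoretical
resolution length of the illumination: features closer than this see
statistically indistinguishable patterns. For an i.i.d. mask it is about one
pixel pitch. Mean subtraction leaves a small negative lag-1 term, so the
estimate can land a few percent below one pitch. The estimator is direct
summation for masks up to 512², FFT-based beyond; the two agree to 1e-8.
Note that this particular estimator is one of several reasonable
conventions (axis choice, interpolation, whether the reconstruction
algorithm's own response is folded in), and other conventions yield
somewhat larger lengths for the same mask.

## Phantom and scatter physics

The synthetic test object is a vertical bone-like cylinder: a cortical shell
(outer 18 % of the radius) at full attenuation `mu_bone` (default
0.06 mm⁻¹, roughly compact bone at 60 keV) and electron density `rho_bone`,
a trabecular interior at 55 % of both with 2 % seeded multiplicative
texture, and one conical through-hole on the axis tapering linearly from
2000 µm diameter at the top to 1200 µm at the bottom. Background voxels are
exactly zero. These two materials stand in for a full tissue-composition
model deliberately: the reconstruction chain, not dosimetry, is the object
of study.

The forward model is **single-scatter and monoenergetic** (default 60 keV,
a representative effective energy for an 80 kVp tungsten spectrum; the
polychromatic spectrum is out of scope). For each transverse beam pixel,
voxels along the beam (+y) contribute

```
x(z, x) = Σ_k ρ_e · T_in · (dσ/dΩ)(θ) · T_out · Δ
```

with `T_in` the Beer–Lambert attenuation from the entry face to the voxel
center (half of the voxel's own attenuation included), `dσ/dΩ` the
Klein–Nishina cross section `(1/2) r_e² (λ/λ')² [λ/λ' + λ'/λ − sin²θ]`
evaluated at the detector angle θ (default 90°, where the cross section is
deliberately small — the stringent test case), `T_out` the straight-line
attenuation toward the detector direction, and Δ the voxel length (so the
discrete sum converges under voxel refinement; verified to <2 % on smooth
objects). Axis-aligned exit directions use exact cumulative sums; oblique
exits are ray-marched at half-voxel steps with trilinear sampling. Multiple
scatter, coherent scatter, detector solid-angle variation across the object,
and detector energy response are all neglected; an
`average_response_maps` hook exists for multi-detector self-absorption
compensation but no multi-detector study is implemented.

Object rotation for a projection is nearest-voxel resampling about the
vertical axis (deterministic; trilinear optional; multiples of 90° are
exact array rotations).

**Bucket noise** is Poisson with one knob: `scale`, the expected photon
count at the brightest bucket (default 10⁴, about 1 % relative noise there).
Bucket values are then counts; all solvers are scale-equivariant so the unit
change is immaterial. An optional per-pattern normalization (divide by the
pattern's pixel sum) mirrors the sum-over-pixels normalization used with
physical masks; it is off by default in simulation, where patterns are
exactly binary.

## Ghost-imaging solvers

All solvers accept the differential-measurement preprocessing standard in
ghost imaging — mean-centering **A** over patterns and **S** over readings —
with the lost DC component restored afterwards by a one-dimensional
least-squares fit along `A·1`. Centering is default-on for the TV and
untrained-network solvers and default-off for the linear oracles, whose
contract is exact recovery on exactly determined systems (centering makes
the DC component unidentifiable and would break that contract).

* **pinv** — minimum-norm least squares (`numpy.linalg.lstsq`).
* **cgls** — conjugate gradient on the normal equations, stopping at
  `|Ax−S|/|S| ≤ tol` or `max_iter`; residual norms decrease monotonically.
* **tv-least-squares** — ISTA on the dimensionless objective
  `|B x̂ − b|² + τ·TV(x̂)` where `b` is the unit-norm data and `x̂` the image
  in units of the CGLS solution's peak. The proximal map of anisotropic TV
  is computed by 40 dual projection iterations; a step is accepted only if
  the objective does not increase (halving the step otherwise), so the
  recorded objective is non-increasing. Deterministic.
* **gidc-style untrained network** — the weights φ of a small CNN are
  optimized by Adam so that its output satisfies the measurement equation
  plus a TV penalty: `argmin_φ |A T_φ(x₀) − S|² + τ·TV(T_φ(x₀))`. The
  network input x₀ is the CGLS reconstruction normalized to unit peak; the
  data term is the squared *relative* residual, making τ scale-free. The
  best-loss iterate is returned (untrained-prior optimizations degrade
  late), and runs are bit-reproducible for a fixed seed.

The network is written directly in numpy (explicit forward/backward passes,
Adam): a two-scale encoder–decoder — two 3×3 conv layers, 2× average
pooling, two conv layers at double width, nearest-neighbor upsampling, an
additive skip connection, two more conv layers — with a residual output
`input + net(input)` whose final 1-channel convolution starts near zero, so
optimization begins at the linear reconstruction. Leaky-ReLU (0.1)
activations, He initialization, 16 base channels. This architecture is this
package's own choice of a small image prior, kept deliberately modest.
Image dimensions must be powers of two (the pooling stage and the
upstream resizing convention both assume it); `resize_to_pow2` provides
exact area-weighted, intensity-preserving resampling to such shapes
(e.g. 184 × 163 → 128 × 128).

**TV flavor** is anisotropic ℓ1 forward differences without wraparound,
recorded in each reconstruction's metadata. **TV strength:** the reference
operating point lists learning rate 0.002, TV strength 10^−3.9, and 1501
steps for 128×128 images, and those are the package defaults; because this
package's objective is normalized differently from the reference code
(whose internal scaling is not published), the effective τ is not
numerically transferable. The desk-scale profiles therefore use τ calibrated
on the synthetic benchmark — 5e-4 at 64×64 and 2e-3 at 32×32 under the
normalized objective — chosen once by reconstruction quality against ground
truth, the same calibration-by-image-quality procedure the experimental
workflow itself uses.

## Tomographic stage

Per-angle images — ghost-imaging scatter reconstructions, transmission
negatives (`max − image`, rescaled to [0, 1]), or their normalized average
(robust 1st–99th percentile normalization, equal weights by default) — are
assembled by **SART-TV** under parallel-beam geometry over the fixed
28-angle acquisition schedule (coarse-to-fine angular coverage starting
0, 180, 90, 270, …).

The projector is ray-driven: per detector bin, sample points at half-voxel
steps along the beam, bilinear interpolation, materialized as a sparse
matrix per angle so the SART backprojection is the exact transpose (adjoint
consistency holds to machine precision). Ray-driven sampling of the
bilinear kernel on a rotated lattice aliases mass by a few percent at some
angles; SART's row/column normalization absorbs this bias. Scatter images
are fed to the same parallel-beam model as transmission negatives — a
knowing physical simplification (scatter formation is not a line integral
of the reconstructed quantity), adequate at the fidelity targeted here.

Each SART sweep visits angles in acquisition order with relaxation 0.3
(unspecified upstream; a conventional value), then applies `tv_iter`
gradient-descent steps on smoothed TV (ε and the step are relative to the
volume's intensity scale, so the flow is invariant under rescaling the
data), then projects onto the non-negative orthant. The nominal CT
parameters (500 iterations, TV lambda 1000, TViter 1000) map to an
effective TV weight of `tv_lambda × 1e-5`; this scaling is the package's
own definition and makes no claim of numeric equivalence with the external
CT toolbox those nominal values come from.

Before the scatter stack enters SART, each image has a constant background
floor removed (median of its one-pixel border — the true scatter response
vanishes outside the object's footprint) and is clipped at zero: GI
reconstructions carry an arbitrary DC offset that otherwise reconstructs as
coherent haze.

## Resolution and quality metrics

**FRC**: rings of 1 pixel width on the shifted 2D FFT, DC excluded,
frequencies at ring centers up to Nyquist `1/(2·pixel)`; the numerator uses
the real part of the cross-spectrum. The threshold is the standard half-bit
information criterion `(0.2071 + 1.9102/√n) / (1.2071 + 0.9102/√n)`. The
cutoff is the first crossing of FRC below the threshold, linearly
interpolated (an exact touch at a ring center returns that ring); no
crossing returns Nyquist with a flag. Resolution is `1/(2 f_c)` — the
convention under which a 0.001 µm⁻¹ cutoff means 500 µm, and resolution at
Nyquist equals the pixel pitch. The split-pattern protocol (two
reconstructions from disjoint halves of the pattern set) provides the two
independent images. 2D FRC on tomogram slices only; 3D Fourier shell
correlation is out of scope.

**Image metrics** are Pearson correlation, RMSE, and PSNR against the
truth's dynamic range (capped at 300 dB for exact reconstructions).

**Hole-taper measurement.** The reconstructed hole diameter is measured on
band-averaged slices near the volume ends (where the cone's diameter
difference is largest) in two ways: the full width at half depth of the
central profile (averaged over the three central rows), and a
*mass-deficit equivalent width* — the intensity deficit of the contiguous
central dip divided by the local baseline. Blur spreads a dip without
changing its deficit, so the deficit width remains monotone in the true
hole size even when reconstruction smears a small hole shallow; the
taper-sign check uses it, with the half-depth widths reported alongside.

## Pipeline profiles and determinism

Two named presets:

| | paper | desk |
|---|---|---|
| patterns | 3468 × (128×128) | 864 × (64×64) |
| sampling rate | 0.2117 | 0.2109 |
| phantom | 128³ | 32³ (0.25 mm voxels) |
| angles | the 28-angle schedule | 8 (every 45°) |
| network steps | 1501 | 300 |
| SART iterations | 500 | 100 (TV inner steps 10) |
| noise | Poisson 10⁴ | Poisson 10⁴ |

The desk profile images the 32³ phantom on a 64×64 pattern grid (response
maps area-resampled 2×): the finer transverse sampling quadruples the
per-angle measurements at the same sampling rate and makes the 1.2–2 mm
hole span 10–16 pixels. A full desk run takes roughly two to three minutes
on one CPU; the problem sizes were chosen so the whole chain, including
tests, runs comfortably on a laptop.

Every stochastic stage receives a seed derived deterministically from one
master seed (`stage_seed = (master · 1000003 + crc32(stage)) mod (2³¹−1)`);
no stage reads global random state, and rerunning a config reproduces the
run report bit-for-bit apart from timings. Configs are YAML; semantically
equal configs hash equal (SHA-256 of canonical JSON).

## What the synthetic tests do and do not show

The generator emulates the geometry and statistics of a scatter-CGI
experiment — binary structured illumination, Compton-weighted single
scatter with self-absorption, Poisson counting noise, sparse-angle
tomography — so passing tests demonstrate that the *reconstruction chain*
is correct and that the untrained-network solver beats linear inversion
under undersampling and noise, as claimed for the method. They do not
demonstrate performance on real detectors (energy response, ground-loop
noise, mask fabrication defects, beam polychromaticity) or validate the
single-scatter approximation against full photon transport; experimental
resolution figures measured on hardware are not reproducible from synthetic
data and are not claimed. The reported desk-scale FRC resolution
(≈1.2–1.7 mm at 125 µm pixels) characterizes the synthetic benchmark, not
any physical instrument.

## Known limitations

* Single-scatter, monoenergetic physics; no coherent scatter, fluorescence,
  or detector model.
* Scatter projections treated as parallel-beam line integrals inside SART.
* The untrained-network solver is CPU-bound numpy; paper-scale 128×128
  runs at 1501 steps are minutes per angle.
* The TV-strength and CT-parameter scalings are package-defined
  conventions; nominal values from external tools do not transfer
  numerically.
* `combine_modalities` assumes pre-registered stacks; no cross-modality
  registration is performed.
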