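# scatterct

**Scatter-radiation computational ghost-imaging CT** — a simulation and
reconstruction toolkit for X-ray computed tomography built from *scattered*
(Compton) radiation measured with a single-pixel detector.

## The problem

Conventional CT images the transmitted beam and discards scattered photons —
or worse, lets them blur the image. Computational ghost imaging (CGI) turns
scatter into signal: the beam is spatially structured by a known binary mask,
and for each mask position a single-pixel ("bucket") detector mounted at an
angle θ to the beam records one scalar — the total scattered intensity. With
the patterns stacked as rows of a measurement matrix **A** and the bucket
readings as a vector **S**, the per-angle scatter image **x** of the object
solves the imaging equation

```
A x = S
```

Repeating the measurement while rotating the object gives one scatter image
per projection angle; an iterative CT solver (SART with a total-variation
penalty) assembles them into a 3D volume. Because the spatial information
comes from the illumination rather than from detector pixels, the approach is
robust to the blur that defeats pixelated scatter cameras.

This package implements the full chain on synthetic data:

* **`scatterct.mask`** — random binary masks (1:1 transmission–absorption
  ratio), window extraction into the measurement matrix, mask
  autocorrelation width (the theoretical resolution length).
* **`scatterct.physics`** — voxel phantoms (a bone-like cylinder with a
  conical through-hole tapering from ~2000 µm to ~1200 µm), the Klein–Nishina
  differential cross section, a single-scatter forward model with
  Beer–Lambert entrance/exit attenuation, and Poisson bucket noise.
* **`scatterct.gi`** — solvers for `A x = S`: minimum-norm least squares,
  CGLS, a proximal-gradient TV baseline, and a self-supervised
  **untrained-network** solver that optimizes the weights φ of a small CNN
  under the loss `|A·T_φ(x)−S|² + τ·TV(T_φ(x))` (no training data; the
  network architecture itself acts as the image prior).
* **`scatterct.ct`** — a parallel-beam ray-driven projector with exact
  adjoint and **SART-TV** volume reconstruction over a 28-angle schedule.
* **`scatterct.frc`** — Fourier ring correlation with the half-bit
  threshold; the cutoff frequency f_c maps to spatial resolution as
  `1/(2 f_c)` (0.001 µm⁻¹ ↔ 500 µm).
* **`scatterct.pipeline`** — YAML-configured end-to-end runs with fully
  deterministic seeding, plus the `scatterct` command-line interface.

## Worked example

One projection of the tapered-hole bone phantom, measured at sampling rate
0.211 with Poisson noise of 10⁴ expected photons at the brightest bucket:

```python
from scatterct import (
    generate_mask, extract_patterns, autocorrelation_width,
    make_bone_phantom, ScatterGeometry, scatter_response_map,
    ResponseMap, resize_to_pow2, bucket_signals,
    GidcParams, reconstruct_gidc, reconstruct_linear, image_metrics,
)

mask = generate_mask(256, 256, pitch_um=125.0, duty=0.5, seed=0)
print(f"mask duty {mask.duty:.3f}, autocorrelation width "
      f"{autocorrelation_width(mask):.0f} um")

A = extract_patterns(mask, n_patterns=864, pattern_shape=(64, 64), seed=1)
print(f"measurement matrix: {A.rows} patterns x {A.cols} pixels "
      f"(sampling rate {A.sampling_rate:.3f})")

phantom = make_bone_phantom((32, 32, 32), voxel_mm=0.25,
                            hole_top_um=2000, hole_bottom_um=1200, seed=2)
geom = ScatterGeometry(photon_energy_keV=60, detector_angle_deg=90)
x_true = ResponseMap(resize_to_pow2(
    scatter_response_map(phantom, geom).values, (64, 64)), 125.0)
S = bucket_signals(A, x_true, noise="poisson", scale=1e4, seed=3)

linear = reconstruct_linear(A, S, method="cgls", max_iter=30, center=True)
prior = reconstruct_gidc(A, S, GidcParams(image_shape=(64, 64), n_steps=300,
                                          tv_strength=5e-4, seed=4))
for name, rec in [("cgls", linear), ("gidc", prior)]:
    print(f"{name}: pearson {image_metrics(rec.image, x_true.values)['pearson']:.3f}")
```

prints

```
mask duty 0.501, autocorrelation width 125 um
measurement matrix: 864 patterns x 4096 pixels (sampling rate 0.211)
cgls: pearson 0.244
gidc: pearson 0.937
```

At a fivefold-undersampled, noisy measurement the plain least-squares
inversion barely correlates with the true scatter map (0.24), while the
TV-constrained untrained-network solver recovers it at Pearson 0.94 — the
core motivation for pairing ghost imaging with a deep-image-prior solver.

The same chain end-to-end, from a shell:

```bash
scatterct run --preset desk --seed 1 -o runs/desk    # simulate → GI → SART-TV → metrics
scatterct slices runs/desk/volume_scatter.h5 -o runs/desk/slices
```

The `desk` preset (32³ phantom, 8 angles, 300 network steps) finishes in a
few minutes on one CPU; the `paper` preset carries the full-scale operating
point (128×128 patterns, 3468 samplings, 28 angles, 1501 steps, 500 SART
iterations).

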