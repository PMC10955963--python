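"""Seeded reconstruction benchmarks shared by the test suite and the
acceptance script.

The standard benchmark emulates one projection of the tapered-hole bone
object: a piecewise-constant disk-with-hole image (cortical rim at full
intensity, trabecular interior at half, an off-axis hole at zero), measured
with binary patterns at sampling rate 216/1024 ≈ 0.211 and Poisson noise of
10⁴ expected photons at the brightest bucket — then reconstructed with each
solver route.
"""

from __future__ import annotations

import numpy as np

from . import frc, gi, mask as mask_mod, physics

__all__ = ["piecewise_phantom_image", "solver_benchmark"]


def piecewise_phantom_image(shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Piecewise-constant disk with a rim and a circular hole, values {0, ½, 1}."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    r = np.hypot(yy - cy, xx - cx)
    R = 0.4 * min(h, w)
    img = np.zeros(shape)
    img[r <= R] = 0.5
    img[(r <= R) & (r > 0.8 * R)] = 1.0
    hole = np.hypot(yy - cy, xx - (cx - 0.35 * R)) <= 0.18 * R
    img[hole] = 0.0
    return img


def solver_benchmark(
    seed: int,
    shape: tuple[int, int] = (64, 64),
    rate: float = 216.0 / 1024.0,
    photons: float = 1e4,
    gidc_steps: int = 400,
) -> dict[str, dict[str, float]]:
    """Reconstruct the standard phantom with cgls, TV, and the untrained-network
    solver under identical data; returns per-solver rmse and pearson."""
    h, w = shape
    n = h * w
    m_patterns = int(round(rate * n))
    big = mask_mod.generate_mask(4 * h, 4 * w, 100.0, 0.5, seed)
    A = mask_mod.extract_patterns(big, m_patterns, shape, seed=seed + 1)
    truth = piecewise_phantom_image(shape)
    S = physics.bucket_signals(A, truth, noise="poisson", scale=photons,
                               seed=seed + 2)
    # Poisson counts rescaled back to the truth's intensity units
    vmax = float((A.as_float() @ truth.ravel()).max())
    S = physics.BucketSeries(S.values * vmax / photons, noise_model="none")

    out = {}
    rec_lin = gi.reconstruct_linear(A, S, "cgls", max_iter=30, tol=1e-6,
                                    center=True)
    out["cgls"] = frc.image_metrics(rec_lin.image, truth)
    rec_tv = gi.reconstruct_tv_least_squares(A, S, tau=2e-3, n_steps=200)
    out["tv"] = frc.image_metrics(rec_tv.image, truth)
    params = gi.GidcParams(image_shape=shape, n_steps=gidc_steps, seed=seed,
                           tv_strength=5e-4)
    rec_gidc = gi.reconstruct_gidc(A, S, params)
    out["gidc"] = frc.image_metrics(rec_gidc.image, truth)
    return out
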