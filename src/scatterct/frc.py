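"""Fourier ring correlation and image-quality metrics.

Resolution is estimated by correlating two independent reconstructions of the
same object in Fourier space, ring by ring:

    FRC(r) = Re{ Σ_r F₁·conj(F₂) } / sqrt( Σ_r |F₁|² · Σ_r |F₂|² )

The frequency at which the FRC curve first drops below the half-bit
information threshold

    T(r) = (0.2071 + 1.9102/√n_r) / (1.2071 + 0.9102/√n_r)

is the cutoff f_c, and the spatial resolution is 1/(2 f_c) — the convention
under which a 0.001 µm⁻¹ cutoff corresponds to 500 µm, and the resolution at
Nyquist equals the pixel pitch.

Conventions: 2D FRC on tomogram slices (not a 3D shell correlation); real
part of the cross-spectrum in the numerator; 1-pixel rings at ring-center
frequencies; DC ring excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "FRCCurve",
    "Cutoff",
    "frc_curve",
    "halfbit_threshold",
    "cutoff_frequency",
    "resolution_from_cutoff",
    "image_metrics",
    "write_frc_csv",
    "read_frc_csv",
]

#: Sentinel PSNR (dB) reported when the reconstruction is exact (rmse = 0).
PSNR_CAP_DB = 300.0


@dataclass(frozen=True)
class FRCCurve:
    """Per-ring correlation vs spatial frequency with its half-bit threshold."""

    freqs: np.ndarray          # µm⁻¹, ring centers, strictly increasing
    frc: np.ndarray            # correlation per ring, in [-1, 1]
    halfbit: np.ndarray        # threshold value per ring
    n_per_ring: np.ndarray     # Fourier samples per ring
    pixel_um: float
    zero_power: np.ndarray = None  # rings where either image had no power

    def __post_init__(self):
        if self.zero_power is None:
            object.__setattr__(self, "zero_power",
                               np.zeros(len(self.freqs), dtype=bool))

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_um)


@dataclass(frozen=True)
class Cutoff:
    frequency_per_um: float
    crossed: bool  # False: FRC never dropped below the threshold (Nyquist returned)


def halfbit_threshold(n_per_ring: np.ndarray) -> np.ndarray:
    """Half-bit information threshold as a function of ring sample count."""
    n = np.asarray(n_per_ring, dtype=np.float64)
    if (n < 1).any():
        raise InvalidArgumentError("ring sample counts must be >= 1")
    rt = np.sqrt(n)
    return (0.2071 + 1.9102 / rt) / (1.2071 + 0.9102 / rt)


def frc_curve(
    image1: np.ndarray,
    image2: np.ndarray,
    pixel_um: float,
    ring_width_px: int = 1,
) -> FRCCurve:
    """Fourier ring correlation of two images of the same field of view."""
    a = np.asarray(image1, dtype=np.float64)
    b = np.asarray(image2, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidArgumentError("images must share one shape")
    if min(a.shape) < 16:
        raise InvalidArgumentError("images must be at least 16x16")
    if not pixel_um > 0:
        raise InvalidArgumentError("pixel_um must be positive")
    if ring_width_px < 1:
        raise InvalidArgumentError("ring_width_px must be >= 1")

    F1 = np.fft.fftshift(np.fft.fft2(a))
    F2 = np.fft.fftshift(np.fft.fft2(b))
    H, W = a.shape
    cy, cx = H // 2, W // 2
    yy, xx = np.ogrid[:H, :W]
    # radius in units of the smaller axis' frequency step
    N = min(H, W)
    ry = (yy - cy) * (N / H)
    rx = (xx - cx) * (N / W)
    r = np.hypot(ry, rx)
    ring = np.round(r / ring_width_px).astype(np.int64)

    kmax = (N // 2) // ring_width_px
    ks = np.arange(1, kmax + 1)
    num = np.real(F1 * np.conj(F2)).ravel()
    p1 = (np.abs(F1) ** 2).ravel()
    p2 = (np.abs(F2) ** 2).ravel()
    ringf = ring.ravel()
    sel = (ringf >= 1) & (ringf <= kmax)
    n_per = np.bincount(ringf[sel], minlength=kmax + 1)[1:]
    s_num = np.bincount(ringf[sel], weights=num[sel], minlength=kmax + 1)[1:]
    s_p1 = np.bincount(ringf[sel], weights=p1[sel], minlength=kmax + 1)[1:]
    s_p2 = np.bincount(ringf[sel], weights=p2[sel], minlength=kmax + 1)[1:]

    denom = np.sqrt(s_p1 * s_p2)
    zero_power = denom == 0
    frc = np.divide(s_num, denom, out=np.zeros_like(s_num), where=~zero_power)
    freqs = ks * ring_width_px / (N * pixel_um)
    return FRCCurve(
        freqs=freqs,
        frc=frc,
        halfbit=halfbit_threshold(np.maximum(n_per, 1)),
        n_per_ring=n_per,
        pixel_um=float(pixel_um),
        zero_power=zero_power,
    )


def cutoff_frequency(curve: FRCCurve) -> Cutoff:
    """Frequency where FRC first drops below the half-bit threshold.

    Linearly interpolated between adjacent rings; an exact touch at a ring
    center returns that ring's frequency.  If the curve never crosses, the
    Nyquist frequency is returned with ``crossed=False``.
    """
    if len(curve.freqs) == 0:
        raise InvalidArgumentError("empty FRC curve")
    d = curve.frc - curve.halfbit
    for i in range(len(d)):
        if d[i] == 0.0:
            return Cutoff(float(curve.freqs[i]), True)
        if d[i] < 0.0:
            if i == 0:
                return Cutoff(float(curve.freqs[0]), True)
            f = curve.freqs[i - 1] + d[i - 1] * (
                curve.freqs[i] - curve.freqs[i - 1]
            ) / (d[i - 1] - d[i])
            return Cutoff(float(f), True)
    return Cutoff(curve.nyquist, False)


def resolution_from_cutoff(f_c: float) -> float:
    """Spatial resolution (µm) from an FRC cutoff frequency (µm⁻¹): 1/(2 f_c)."""
    if not f_c > 0:
        raise InvalidArgumentError("cutoff frequency must be positive")
    return 1.0 / (2.0 * f_c)


def image_metrics(recon: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Pearson correlation, RMSE, and PSNR (relative to the truth's dynamic
    range, capped at PSNR_CAP_DB for an exact reconstruction)."""
    r = np.asarray(recon, dtype=np.float64).ravel()
    t = np.asarray(truth, dtype=np.float64).ravel()
    if r.shape != t.shape:
        raise InvalidArgumentError("images must share one shape")
    if t.std() == 0:
        raise DegenerateInputError("pearson undefined for a constant truth image")
    rmse = float(np.sqrt(np.mean((r - t) ** 2)))
    drange = float(t.max() - t.min())
    if rmse == 0:
        psnr = PSNR_CAP_DB
    else:
        psnr = min(PSNR_CAP_DB, 20.0 * np.log10(drange / rmse))
    pearson = float(np.corrcoef(r, t)[0, 1]) if r.std() > 0 else 0.0
    return {"pearson": pearson, "rmse": rmse, "psnr": float(psnr)}


def write_frc_csv(curve: FRCCurve, path: str | Path) -> None:
    lines = ["freq_per_um,frc,halfbit,n_per_ring"]
    for f, c, h, n in zip(curve.freqs, curve.frc, curve.halfbit, curve.n_per_ring):
        lines.append(f"{float(f)!r},{float(c)!r},{float(h)!r},{int(n)}")
    Path(path).write_text(
        "\n".join(lines) + f"\n# pixel_um={float(curve.pixel_um)!r}\n")


def read_frc_csv(path: str | Path) -> FRCCurve:
    text = Path(path).read_text().strip().splitlines()
    pixel_um = float("nan")
    rows = []
    for line in text[1:]:
        if line.startswith("# pixel_um="):
            pixel_um = float(line.split("=")[1])
        elif line:
            rows.append([float(v) for v in line.split(",")])
    arr = np.array(rows)
    return FRCCurve(
        freqs=arr[:, 0], frc=arr[:, 1], halfbit=arr[:, 2],
        n_per_ring=arr[:, 3].astype(int), pixel_um=pixel_um,
    )
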