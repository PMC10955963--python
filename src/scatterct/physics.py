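"""Synthetic phantoms and the single-scatter X-ray forward model.

The imaging setup this emulates: a pencil of structured X-ray illumination
passes through an object; a single-pixel scintillation detector mounted at an
angle θ to the beam collects Compton-scattered photons, producing one scalar
("bucket") reading per illumination pattern.  The per-angle scatter response
map x assigns to each transverse beam pixel the scattered intensity reaching
the detector from the material column under that pixel:

    x(i, j) = Σ_k ρ_e(i, j, k) · T_in(i, j, k) · (dσ/dΩ)(θ) · T_out(i, j, k) · Δ

with T_in / T_out Beer–Lambert attenuation along the entrance and exit paths,
dσ/dΩ the Klein–Nishina differential cross section, and Δ the voxel length.
Bucket signals then follow the ghost-imaging measurement equation S = A x.

Approximations (deliberate — this is a desk-scale analytic surrogate, not
Monte-Carlo transport): single scatter only; monoenergetic beam; straight-line
exit attenuation toward the detector's nominal direction; no detector
solid-angle variation across the object; no coherent scatter or fluorescence.

Axis convention for all volumes: ``values[z, y, x]`` with the beam travelling
along +y, the vertical (rotation) axis z, and the detector in the horizontal
x–y plane.  A response map is indexed ``[z, x]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import constants, ndimage

from .exceptions import InvalidArgumentError
from .mask import PatternMatrix

__all__ = [
    "Phantom",
    "ScatterGeometry",
    "ResponseMap",
    "BucketSeries",
    "make_bone_phantom",
    "energy_to_wavelength_pm",
    "compton_wavelength",
    "klein_nishina",
    "rotate_volume_z",
    "scatter_response_map",
    "transmission_projection",
    "bucket_signals",
    "average_response_maps",
    "mc_budget",
    "write_phantom",
    "read_phantom",
    "write_buckets",
    "read_buckets",
]

#: Compton wavelength of the electron h/(m_e c), in picometres.
COMPTON_WAVELENGTH_PM = constants.value("Compton wavelength") * 1e12
#: Classical electron radius, in metres.
ELECTRON_RADIUS_M = constants.value("classical electron radius")
_HC_KEV_PM = constants.h * constants.c / (constants.e * 1e3) * 1e12  # keV·pm


@dataclass(frozen=True)
class Phantom:
    """Voxelized object: attenuation and relative electron density.

    mu is the linear attenuation coefficient in mm^-1; rho_e the relative
    electron (scatter) density, dimensionless; voxel_mm the isotropic voxel
    edge length.
    """

    mu: np.ndarray
    rho_e: np.ndarray
    voxel_mm: float
    seed: int = -1

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=np.float64)
        rho = np.asarray(self.rho_e, dtype=np.float64)
        if mu.shape != rho.shape or mu.ndim != 3:
            raise InvalidArgumentError("mu and rho_e must be 3D arrays of one shape")
        if (mu < 0).any() or (rho < 0).any():
            raise InvalidArgumentError("mu and rho_e must be non-negative")
        if not self.voxel_mm > 0:
            raise InvalidArgumentError("voxel_mm must be positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "rho_e", rho)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mu.shape


@dataclass(frozen=True)
class ScatterGeometry:
    """Beam energy, detector placement, and object rotation for one projection.

    detector_angle_deg is the scatter angle θ of the single-pixel detector
    measured from the beam axis (+y) toward +x in the horizontal plane; the
    experimental default is ~90°, detector 50 mm from the object.
    """

    photon_energy_keV: float = 60.0
    detector_angle_deg: float = 90.0
    detector_distance_mm: float = 50.0
    beam_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    rotation_angle_deg: float = 0.0

    def __post_init__(self):
        if not self.photon_energy_keV > 0:
            raise InvalidArgumentError("photon_energy_keV must be positive")
        if not 0 <= self.detector_angle_deg <= 360:
            raise InvalidArgumentError("detector_angle_deg must lie in [0, 360]")

    @property
    def wavelength_pm(self) -> float:
        return energy_to_wavelength_pm(self.photon_energy_keV)


@dataclass(frozen=True)
class ResponseMap:
    """Per-angle 2D object response (the vector x of S = A x), indexed [z, x]."""

    values: np.ndarray
    pixel_um: float
    angle_deg: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise InvalidArgumentError("response map must be 2D")
        if not np.isfinite(values).all():
            raise InvalidArgumentError("response map must be finite")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BucketSeries:
    """Single-pixel detector readings, one per illumination pattern."""

    values: np.ndarray
    angle_deg: float = 0.0
    noise_model: str = "none"
    seed: int = -1

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise InvalidArgumentError("bucket series must be 1D")
        if self.noise_model == "poisson" and (values < 0).any():
            raise InvalidArgumentError("poisson buckets must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def make_bone_phantom(
    shape: tuple[int, int, int],
    voxel_mm: float,
    hole_top_um: float = 2000.0,
    hole_bottom_um: float = 1200.0,
    mu_bone: float = 0.06,
    rho_bone: float = 1.0,
    seed: int = 0,
    radius_fraction: float = 0.4,
    shell_fraction: float = 0.18,
    interior_level: float = 0.55,
    texture: float = 0.02,
) -> Phantom:
    """Bone-like cylinder with a cortical shell and one conical through-hole.

    The hole runs vertically through the cylinder axis, tapering linearly from
    ``hole_top_um`` diameter at the top slice to ``hole_bottom_um`` at the
    bottom — the tapered test feature (~2000 µm narrowing to ~1200 µm) a
    tomographic reconstruction should resolve.  The cortical shell (outer
    ``shell_fraction`` of the radius) carries full ``mu_bone`` / ``rho_bone``;
    the trabecular interior a fraction ``interior_level`` of both, with mild
    seeded multiplicative texture.  Background voxels are exactly zero.
    """
    nz, ny, nx = map(int, shape)
    if min(nz, ny, nx) < 1:
        raise InvalidArgumentError("phantom shape must be positive")
    if not voxel_mm > 0:
        raise InvalidArgumentError("voxel_mm must be positive")
    if hole_top_um < 0 or hole_bottom_um < 0:
        raise InvalidArgumentError("hole diameters must be non-negative")
    transverse_um = min(ny, nx) * voxel_mm * 1000.0
    if max(hole_top_um, hole_bottom_um) > transverse_um:
        raise InvalidArgumentError("hole larger than the phantom transverse extent")

    rng = np.random.default_rng(seed)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r = np.hypot(yy - cy, xx - cx)  # voxels, transverse distance from axis
    R = radius_fraction * min(ny, nx)
    inner = R * (1.0 - shell_fraction)

    mu = np.zeros((nz, ny, nx))
    rho = np.zeros((nz, ny, nx))
    voxel_um = voxel_mm * 1000.0
    tex = rng.normal(1.0, texture, size=(nz, ny, nx)).clip(0.5, 1.5)
    for k in range(nz):
        frac = k / max(nz - 1, 1)  # 0 at top slice, 1 at bottom
        hole_d_vox = (hole_top_um + (hole_bottom_um - hole_top_um) * frac) / voxel_um
        solid = r <= R
        shell = solid & (r > inner)
        interior = solid & ~shell
        mu_k = np.zeros((ny, nx))
        rho_k = np.zeros((ny, nx))
        mu_k[shell] = mu_bone
        rho_k[shell] = rho_bone
        mu_k[interior] = interior_level * mu_bone * tex[k][interior]
        rho_k[interior] = interior_level * rho_bone * tex[k][interior]
        in_hole = r <= hole_d_vox / 2.0
        mu_k[in_hole] = 0.0
        rho_k[in_hole] = 0.0
        mu[k], rho[k] = mu_k, rho_k
    return Phantom(mu=mu, rho_e=rho, voxel_mm=float(voxel_mm), seed=int(seed))


# ---------------------------------------------------------------------------
# Scatter physics
# ---------------------------------------------------------------------------

def energy_to_wavelength_pm(energy_keV: float) -> float:
    """Photon wavelength (pm) for a given energy (keV): λ = hc/E."""
    if not energy_keV > 0:
        raise InvalidArgumentError("energy must be positive")
    return _HC_KEV_PM / energy_keV


def compton_wavelength(lambda_in_pm: float, theta_deg: float) -> float:
    """Scattered-photon wavelength λ' = λ + λ_C (1 − cos θ), in pm."""
    lam = np.asarray(lambda_in_pm, dtype=np.float64)
    if (lam <= 0).any():
        raise InvalidArgumentError("lambda_in must be positive")
    theta = np.deg2rad(theta_deg)
    out = lam + COMPTON_WAVELENGTH_PM * (1.0 - np.cos(theta))
    return float(out) if out.ndim == 0 else out


def klein_nishina(lambda_in_pm: float, theta_deg: float) -> float:
    """Klein–Nishina differential cross section dσ/dΩ, in m² sr⁻¹.

    (1/2) r_e² (λ/λ')² [λ/λ' + λ'/λ − sin²θ], with λ' the Compton-shifted
    wavelength.  At θ = 0 this is exactly r_e²; as λ → ∞ it approaches the
    Thomson limit (r_e²/2)(1 + cos²θ).
    """
    lam = np.asarray(lambda_in_pm, dtype=np.float64)
    if (lam <= 0).any():
        raise InvalidArgumentError("lambda_in must be positive")
    lam_p = compton_wavelength(lam, theta_deg)
    ratio = lam / lam_p
    theta = np.deg2rad(theta_deg)
    out = 0.5 * ELECTRON_RADIUS_M**2 * ratio**2 * (
        ratio + 1.0 / ratio - np.sin(theta) ** 2
    )
    return float(out) if np.ndim(out) == 0 else out


def rotate_volume_z(
    vol: np.ndarray, angle_deg: float, interpolation: str = "nearest"
) -> np.ndarray:
    """Rotate a (z, y, x) volume about the vertical z axis.

    Exact (no resampling) for multiples of 90°; otherwise nearest-voxel by
    default (deterministic) or trilinear with ``interpolation="trilinear"``.
    """
    a = float(angle_deg) % 360.0
    if np.isclose(a, 0.0) or np.isclose(a, 360.0):
        return vol.copy()
    if np.isclose(a % 90.0, 0.0):
        return np.rot90(vol, k=int(round(a / 90.0)), axes=(1, 2)).copy()
    order = {"nearest": 0, "trilinear": 1}.get(interpolation)
    if order is None:
        raise InvalidArgumentError(f"unknown interpolation {interpolation!r}")
    return ndimage.rotate(
        vol, a, axes=(1, 2), reshape=False, order=order, mode="constant",
        cval=0.0, prefilter=False,
    )


def _entrance_transmission(mu: np.ndarray, voxel_mm: float) -> np.ndarray:
    # Beer-Lambert along +y to each voxel centre (half of the voxel itself)
    path = np.cumsum(mu, axis=1) - 0.5 * mu
    return np.exp(-path * voxel_mm)


def _exit_transmission(
    mu: np.ndarray, voxel_mm: float, theta_deg: float, step_frac: float = 0.5
) -> np.ndarray:
    """Attenuation from each voxel centre to the boundary toward the detector."""
    theta = np.deg2rad(theta_deg)
    dy, dx = np.cos(theta), np.sin(theta)
    # axis-aligned fast paths (exact cumulative sums)
    if np.isclose(dx, 0.0, atol=1e-12) and dy > 0:
        path = np.cumsum(mu[:, ::-1, :], axis=1)[:, ::-1, :] - 0.5 * mu
        return np.exp(-path * voxel_mm)
    if np.isclose(dx, 0.0, atol=1e-12) and dy < 0:
        path = np.cumsum(mu, axis=1) - 0.5 * mu
        return np.exp(-path * voxel_mm)
    if np.isclose(dy, 0.0, atol=1e-12) and dx > 0:
        path = np.cumsum(mu[:, :, ::-1], axis=2)[:, :, ::-1] - 0.5 * mu
        return np.exp(-path * voxel_mm)
    if np.isclose(dy, 0.0, atol=1e-12) and dx < 0:
        path = np.cumsum(mu, axis=2) - 0.5 * mu
        return np.exp(-path * voxel_mm)
    # generic horizontal exit ray, marched at step_frac voxels per step
    nz, ny, nx = mu.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    n_steps = int(np.ceil(np.hypot(ny, nx) / step_frac)) + 1
    path = np.zeros(mu.shape)
    yf = yy.astype(np.float64)
    xf = xx.astype(np.float64)
    zf = zz.astype(np.float64).ravel()
    for s in range(n_steps):
        t = (s + 0.5) * step_frac
        coords = np.stack(
            [zf, (yf + t * dy).ravel(), (xf + t * dx).ravel()]
        )
        path += ndimage.map_coordinates(
            mu, coords, order=1, mode="constant", cval=0.0
        ).reshape(mu.shape) * step_frac
    return np.exp(-path * voxel_mm)


def scatter_response_map(
    phantom: Phantom,
    geom: ScatterGeometry,
    interpolation: str = "nearest",
) -> ResponseMap:
    """Single-scatter response toward the detector, per transverse beam pixel.

    The phantom is rotated to ``geom.rotation_angle_deg`` about the vertical
    axis, the beam traverses +y, and each voxel contributes its electron
    density attenuated along the entrance path, weighted by the Klein–Nishina
    cross section at the detector angle, and attenuated again along the
    straight exit path toward the detector.
    """
    mu = rotate_volume_z(phantom.mu, geom.rotation_angle_deg, interpolation)
    rho = rotate_volume_z(phantom.rho_e, geom.rotation_angle_deg, interpolation)
    kn = klein_nishina(geom.wavelength_pm, geom.detector_angle_deg)
    t_in = _entrance_transmission(mu, phantom.voxel_mm)
    t_out = _exit_transmission(mu, phantom.voxel_mm, geom.detector_angle_deg)
    values = (rho * t_in * t_out).sum(axis=1) * phantom.voxel_mm * kn
    return ResponseMap(
        values=values,
        pixel_um=phantom.voxel_mm * 1000.0,
        angle_deg=geom.rotation_angle_deg,
    )


def transmission_projection(
    phantom: Phantom,
    rotation_angle_deg: float = 0.0,
    interpolation: str = "nearest",
) -> ResponseMap:
    """Parallel-beam Beer–Lambert transmission image exp(−∫μ dl), indexed [z, x]."""
    mu = rotate_volume_z(phantom.mu, rotation_angle_deg, interpolation)
    values = np.exp(-mu.sum(axis=1) * phantom.voxel_mm)
    return ResponseMap(
        values=values,
        pixel_um=phantom.voxel_mm * 1000.0,
        angle_deg=rotation_angle_deg,
    )


def bucket_signals(
    A: PatternMatrix,
    x: ResponseMap | np.ndarray,
    noise: str = "none",
    scale: float = 1e4,
    seed: int = 0,
    normalize: bool = False,
) -> BucketSeries:
    """Single-pixel bucket readings S = A·flatten(x), optionally Poisson-noisy.

    With ``noise="poisson"`` each noiseless value v is replaced by a Poisson
    draw of mean ``scale·v/max(v)`` — ``scale`` is the expected photon count
    at the brightest bucket, the one SNR knob.  ``normalize`` divides each
    bucket by its pattern's pixel sum (the sum-over-all-pixels measurement
    normalization used with physical masks of uneven illumination).
    """
    xv = x.values if isinstance(x, ResponseMap) else np.asarray(x, dtype=np.float64)
    angle = x.angle_deg if isinstance(x, ResponseMap) else 0.0
    if A.cols != xv.size:
        raise InvalidArgumentError(
            f"pattern matrix has {A.cols} columns but x has {xv.size} pixels"
        )
    values = A.as_float() @ xv.ravel()
    if normalize:
        row_sums = A.as_float().sum(axis=1)
        values = np.divide(values, row_sums, out=np.zeros_like(values),
                           where=row_sums > 0)
    if noise == "none":
        return BucketSeries(values=values, angle_deg=angle, noise_model="none")
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        vmax = values.max()
        mean = scale * values / vmax if vmax > 0 else np.zeros_like(values)
        drawn = rng.poisson(mean).astype(np.float64)
        return BucketSeries(
            values=drawn, angle_deg=angle,
            noise_model=f"poisson(scale={scale:g})", seed=int(seed),
        )
    raise InvalidArgumentError(f"unknown noise model {noise!r}")


def average_response_maps(maps: list[ResponseMap]) -> ResponseMap:
    """Average the responses of several detectors at one projection angle.

    Entry point for multi-detector self-absorption compensation: detectors at
    different azimuths see different exit attenuation, and their average is
    less biased toward the near side of the object.
    """
    if not maps:
        raise InvalidArgumentError("need at least one response map")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise InvalidArgumentError("response maps must share one shape")
    values = np.mean([m.values for m in maps], axis=0)
    return ResponseMap(values=values, pixel_um=maps[0].pixel_um,
                       angle_deg=maps[0].angle_deg)


def mc_budget(n_realizations: int, primaries_per_realization: float) -> float:
    """Total primary particles of a Monte-Carlo campaign (bookkeeping)."""
    if n_realizations < 0 or primaries_per_realization < 0:
        raise InvalidArgumentError("counts must be non-negative")
    return float(n_realizations) * float(primaries_per_realization)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_phantom(phantom: Phantom, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mu", data=phantom.mu)
        f.create_dataset("rho_e", data=phantom.rho_e)
        f.attrs["voxel_mm"] = phantom.voxel_mm
        f.attrs["seed"] = phantom.seed


def read_phantom(path: str | Path) -> Phantom:
    with h5py.File(path, "r") as f:
        return Phantom(
            mu=f["mu"][()],
            rho_e=f["rho_e"][()],
            voxel_mm=float(f.attrs["voxel_mm"]),
            seed=int(f.attrs.get("seed", -1)),
        )


def write_buckets(buckets: BucketSeries, path: str | Path) -> None:
    path = Path(path)
    lines = ["pattern_index,value"]
    lines += [f"{i},{float(v)!r}" for i, v in enumerate(buckets.values)]
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "angle_deg": buckets.angle_deg,
        "noise_model": buckets.noise_model,
        "seed": buckets.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_buckets(path: str | Path) -> BucketSeries:
    path = Path(path)
    rows = path.read_text().strip().splitlines()[1:]
    values = np.array([float(r.split(",")[1]) for r in rows])
    meta = json.loads(path.with_suffix(".json").read_text())
    return BucketSeries(
        values=values,
        angle_deg=meta.get("angle_deg", 0.0),
        noise_model=meta.get("noise_model", "none"),
        seed=meta.get("seed", -1),
    )
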