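"""End-to-end orchestration: configuration, seeding, and the full workflow.

One :class:`RunConfig` describes a complete experiment — mask, phantom,
geometry, ghost-imaging solver, CT stage, angle schedule, noise, and a single
master seed from which every stochastic stage derives its own seed
deterministically.  :func:`run_pipeline` then chains

    simulate (per angle) → GI reconstruct (per angle) → SART-TV → metrics

for three modalities (scatter, transmission negative, combined) and writes a
JSON run report.  Two named presets are shipped: ``paper`` — the full-scale
operating point (128×128 patterns, 3468 samplings, 28 angles, 1501 solver
steps, 500 CT iterations) — and ``desk``, a small profile (32³ phantom,
32×32 patterns at sampling rate 0.211, 8 angles, 300 solver steps) sized so
a complete run takes minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ct, frc, gi, mask as mask_mod, physics
from .exceptions import InvalidArgumentError, StageError

__all__ = [
    "RunConfig",
    "MaskSpec",
    "PatternSpec",
    "PhantomSpec",
    "GeometrySpec",
    "SolverSpec",
    "CtSpec",
    "NoiseSpec",
    "desk_config",
    "paper_config",
    "derive_seed",
    "config_hash",
    "save_config",
    "load_config",
    "run_pipeline",
    "make_fixtures",
    "measure_hole_width",
]


@dataclass(frozen=True)
class MaskSpec:
    height_px: int = 1480
    width_px: int = 1480
    pitch_um: float = 160_000.0 / 1480.0
    duty: float = 0.5


@dataclass(frozen=True)
class PatternSpec:
    n_patterns: int = 3468
    shape: tuple[int, int] = (128, 128)
    strategy: str = "random-shift"


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 0.125
    hole_top_um: float = 2000.0
    hole_bottom_um: float = 1200.0
    mu_bone: float = 0.06
    rho_bone: float = 1.0


@dataclass(frozen=True)
class GeometrySpec:
    photon_energy_keV: float = 60.0
    detector_angle_deg: float = 90.0
    detector_distance_mm: float = 50.0


@dataclass(frozen=True)
class SolverSpec:
    method: str = "gidc"  # gidc | cgls | pinv | tv
    learning_rate: float = 0.002
    tv_strength: float = 10.0 ** -3.9
    n_steps: int = 1501


@dataclass(frozen=True)
class CtSpec:
    n_iterations: int = 500
    tv_lambda: float = 1000.0
    tv_iter: int = 1000
    relaxation: float = 0.3


@dataclass(frozen=True)
class NoiseSpec:
    model: str = "none"  # none | poisson
    scale: float = 1e4


@dataclass(frozen=True)
class RunConfig:
    mask: MaskSpec = field(default_factory=MaskSpec)
    patterns: PatternSpec = field(default_factory=PatternSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    solver: SolverSpec = field(default_factory=SolverSpec)
    ct: CtSpec = field(default_factory=CtSpec)
    angles: tuple[float, ...] | str = "paper"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    master_seed: int = 0
    output_root: str = "runs/run0"

    def angle_list(self) -> list[float]:
        if self.angles == "paper":
            return ct.paper_angle_list()
        return [float(a) for a in self.angles]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["angles"], tuple):
            d["angles"] = list(d["angles"])
        for key in ("patterns", "phantom"):
            d[key]["shape"] = list(d[key]["shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        angles = d.get("angles", "paper")
        if not isinstance(angles, str):
            angles = tuple(float(a) for a in angles)
        p = dict(d.get("patterns", {}))
        if "shape" in p:
            p["shape"] = tuple(p["shape"])
        ph = dict(d.get("phantom", {}))
        if "shape" in ph:
            ph["shape"] = tuple(ph["shape"])
        return cls(
            mask=MaskSpec(**d.get("mask", {})),
            patterns=PatternSpec(**p),
            phantom=PhantomSpec(**ph),
            geometry=GeometrySpec(**d.get("geometry", {})),
            solver=SolverSpec(**d.get("solver", {})),
            ct=CtSpec(**d.get("ct", {})),
            angles=angles,
            noise=NoiseSpec(**d.get("noise", {})),
            master_seed=int(d.get("master_seed", 0)),
            output_root=str(d.get("output_root", "runs/run0")),
        )


def desk_config(output_root: str = "runs/desk", master_seed: int = 0) -> RunConfig:
    """Small-profile preset: 32³ tapered-hole phantom imaged on a 64×64
    pattern grid at sampling rate 864/4096 ≈ 0.211, 8 angles, 300 solver
    steps."""
    return RunConfig(
        mask=MaskSpec(height_px=256, width_px=256, pitch_um=125.0),
        patterns=PatternSpec(n_patterns=864, shape=(64, 64)),
        phantom=PhantomSpec(shape=(32, 32, 32), voxel_mm=0.25),
        solver=SolverSpec(method="gidc", n_steps=300, tv_strength=5e-4),
        ct=CtSpec(n_iterations=100, tv_lambda=1000.0, tv_iter=10),
        angles=tuple(float(a) for a in range(0, 360, 45)),
        noise=NoiseSpec(model="poisson", scale=1e4),
        master_seed=master_seed,
        output_root=output_root,
    )


def paper_config(output_root: str = "runs/paper", master_seed: int = 0) -> RunConfig:
    """Full-scale preset mirroring the reference operating point."""
    return RunConfig(master_seed=master_seed, output_root=output_root,
                     noise=NoiseSpec(model="poisson", scale=1e4))


# ---------------------------------------------------------------------------
# Seeds, hashing, serialization
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed, always below 2^31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form; key order does not matter."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Measurements on reconstructed volumes
# ---------------------------------------------------------------------------

def _center_profile(volume_slice: np.ndarray) -> np.ndarray:
    sl = np.asarray(volume_slice, dtype=np.float64)
    cy = sl.shape[0] // 2
    return sl[max(cy - 1, 0) : cy + 2].mean(axis=0)


def measure_hole_width(volume_slice: np.ndarray, pixel_um: float) -> float:
    """Width (µm) of the central hole in one tomogram slice.

    Measured on the horizontal profile through the slice center (averaged
    over the three central rows) as the full width at half depth: the dip at
    the center against a baseline taken as the 80th percentile of the central
    half of the profile, with linear interpolation at the half-depth
    crossings.
    """
    p = _center_profile(volume_slice)
    c = p.shape[0] // 2
    q = p.shape[0] // 4
    baseline = float(np.percentile(p[q : p.shape[0] - q], 80))
    depth = baseline - p[c]
    if depth <= 0:
        return 0.0
    thr = baseline - depth / 2.0
    # walk outward from the center to the first samples back above threshold
    left = 0.0
    for i in range(c, 0, -1):
        if p[i - 1] >= thr:
            frac = (thr - p[i]) / (p[i - 1] - p[i])
            left = c - (i - frac)
            break
    else:
        left = float(c)
    right = 0.0
    for i in range(c, p.shape[0] - 1):
        if p[i + 1] >= thr:
            frac = (thr - p[i]) / (p[i + 1] - p[i])
            right = (i + frac) - c
            break
    else:
        right = float(p.shape[0] - 1 - c)
    return (left + right) * pixel_um


def measure_hole_width_deficit(volume_slice: np.ndarray, pixel_um: float) -> float:
    """Mass-deficit equivalent width (µm) of the central hole.

    The intensity deficit of the contiguous dip around the slice center,
    normalized by the local baseline: ``Σ max(baseline − p, 0) / baseline``.
    Blur spreads a dip without changing its deficit, so unlike a half-depth
    width this estimator stays monotone in the true hole size even when the
    reconstruction smears a small hole shallow — it is what the taper-sign
    comparison uses.
    """
    p = _center_profile(volume_slice)
    n = p.shape[0]
    c, q = n // 2, n // 4
    baseline = float(np.percentile(p[q : n - q], 80))
    if baseline <= 0:
        return 0.0
    lo = c
    while lo > 0 and p[lo - 1] < baseline:
        lo -= 1
    hi = c
    while hi < n - 1 and p[hi + 1] < baseline:
        hi += 1
    area = float(np.clip(baseline - p[lo : hi + 1], 0.0, None).sum())
    return area / baseline * pixel_um


# ---------------------------------------------------------------------------
# The end-to-end run
# ---------------------------------------------------------------------------

def _reconstruct_scatter(config, A, buckets, stage_seed):
    method = config.solver.method
    if method in ("cgls", "pinv"):
        return gi.reconstruct_linear(A, buckets, method=method)
    if method == "tv":
        return gi.reconstruct_tv_least_squares(
            A, buckets, tau=config.solver.tv_strength,
            n_steps=min(config.solver.n_steps, 500),
        )
    if method == "gidc":
        params = gi.GidcParams(
            image_shape=config.patterns.shape,
            learning_rate=config.solver.learning_rate,
            tv_strength=config.solver.tv_strength,
            n_steps=config.solver.n_steps,
            seed=stage_seed,
        )
        return gi.reconstruct_gidc(A, buckets, params)
    raise InvalidArgumentError(f"unknown solver method {method!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate → reconstruct → CT → metrics and return the run report.

    Outputs land under ``config.output_root``; the report (also written as
    ``report.json``) is bit-identical across reruns of an identical config,
    apart from its ``timings`` section.  A failing stage raises
    :class:`StageError` naming the stage; prior outputs are preserved.
    """
    out = Path(config.output_root)
    out.mkdir(parents=True, exist_ok=True)
    angles = config.angle_list()
    report: dict = {
        "config_hash": config_hash(config),
        "seeds": {},
        "stages": {},
        "timings": {},
    }
    timings = report["timings"]

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("mask"):
        seed = derive_seed(config.master_seed, "mask")
        report["seeds"]["mask"] = seed
        m = mask_mod.generate_mask(
            config.mask.height_px, config.mask.width_px,
            config.mask.pitch_um, config.mask.duty, seed,
        )
        mask_mod.write_mask(m, out / "mask.tif")
        pseed = derive_seed(config.master_seed, "patterns")
        report["seeds"]["patterns"] = pseed
        A = mask_mod.extract_patterns(
            m, config.patterns.n_patterns, config.patterns.shape,
            strategy=config.patterns.strategy, seed=pseed,
        )
        mask_mod.write_patterns(A, out / "patterns.tif")
        report["stages"]["mask"] = {
            "duty": m.duty,
            "sampling_rate": A.sampling_rate,
            "autocorrelation_width_um": mask_mod.autocorrelation_width(m),
        }

    with stage("phantom"):
        seed = derive_seed(config.master_seed, "phantom")
        report["seeds"]["phantom"] = seed
        phantom = physics.make_bone_phantom(
            config.phantom.shape, config.phantom.voxel_mm,
            config.phantom.hole_top_um, config.phantom.hole_bottom_um,
            config.phantom.mu_bone, config.phantom.rho_bone, seed,
        )
        physics.write_phantom(phantom, out / "phantom.h5")

    scatter_images, trans_neg_images = [], []
    per_angle = {}
    with stage("simulate_reconstruct"):
        (out / "buckets").mkdir(exist_ok=True)
        (out / "recon").mkdir(exist_ok=True)
        for a in angles:
            geom = physics.ScatterGeometry(
                photon_energy_keV=config.geometry.photon_energy_keV,
                detector_angle_deg=config.geometry.detector_angle_deg,
                detector_distance_mm=config.geometry.detector_distance_mm,
                rotation_angle_deg=a,
            )
            smap = physics.scatter_response_map(phantom, geom)
            x = gi.resize_to_pow2(smap.values, config.patterns.shape) \
                if smap.shape != tuple(config.patterns.shape) else smap.values
            bseed = derive_seed(config.master_seed, f"buckets:{a}")
            buckets = physics.bucket_signals(
                A, physics.ResponseMap(x, smap.pixel_um, a),
                noise=config.noise.model, scale=config.noise.scale, seed=bseed,
            )
            physics.write_buckets(buckets, out / "buckets" / f"angle_{a:07.2f}.csv")
            rseed = derive_seed(config.master_seed, f"solver:{a}")
            recon = _reconstruct_scatter(config, A, buckets, rseed)
            gi.write_reconstruction(recon, out / "recon" / f"scatter_{a:07.2f}.tif")
            tmap = physics.transmission_projection(phantom, a)
            tvals = gi.resize_to_pow2(tmap.values, config.patterns.shape) \
                if tmap.shape != tuple(config.patterns.shape) else tmap.values
            scatter_images.append(recon.image)
            trans_neg_images.append(ct.negative_transmission(tvals))
            per_angle[f"{a:g}"] = {
                "bucket_seed": bseed,
                "solver_seed": rseed,
                "scatter_pearson_vs_truth": frc.image_metrics(
                    recon.image, x.reshape(recon.image.shape)
                )["pearson"],
            }
        report["stages"]["per_angle"] = per_angle

    with stage("ct"):
        # projection pixel pitch: phantom transverse extent over pattern width
        pix = phantom.voxel_mm * 1000.0 * phantom.shape[2] / config.patterns.shape[1]
        angs = tuple(a % 360.0 for a in angles)
        scatter_stack = ct.ProjectionStack(
            np.stack([ct.subtract_background(im) for im in scatter_images]),
            angs, "scatter", pix)
        trans_stack = ct.ProjectionStack(
            np.stack(trans_neg_images), angs, "transmission-negative", pix)
        combined_stack = ct.combine_modalities(trans_stack, scatter_stack)
        params = ct.SartParams(
            n_iterations=config.ct.n_iterations, tv_lambda=config.ct.tv_lambda,
            tv_iter=config.ct.tv_iter, relaxation=config.ct.relaxation,
        )
        h, w = config.patterns.shape
        vshape = (h, w, w)
        volumes = {}
        for name, stack in (("scatter", scatter_stack),
                            ("transmission_negative", trans_stack),
                            ("combined", combined_stack)):
            ct.write_projection_stack(stack, out / f"stack_{name}.tif")
            vol = ct.sart_tv(stack, params, vshape)
            ct.write_volume(vol, out / f"volume_{name}.h5")
            volumes[name] = vol
        report["stages"]["ct"] = {"volume_shape": list(vshape)}

    with stage("metrics"):
        truth = phantom.rho_e
        if truth.shape != volumes["scatter"].shape:
            from scipy import ndimage as _ndi

            factors = [t / s for t, s in zip(volumes["scatter"].shape, truth.shape)]
            truth = _ndi.zoom(truth, factors, order=0)
        vol = volumes["scatter"].values
        metrics = frc.image_metrics(vol.ravel(), truth.ravel())
        nz = vol.shape[0]
        pix_um = phantom.voxel_mm * 1000.0 * phantom.shape[2] / vol.shape[2]
        # taper from mass-deficit widths of band-averaged slices near the
        # volume ends, where the conical hole's diameter difference is largest
        top_slice = vol[nz // 32 : nz // 16 + nz // 5].mean(axis=0)
        bot_slice = vol[nz - nz // 16 - nz // 5 : nz - nz // 32].mean(axis=0)
        hole_top = measure_hole_width_deficit(top_slice, pix_um)
        hole_bot = measure_hole_width_deficit(bot_slice, pix_um)
        fwhm_top = measure_hole_width(top_slice, pix_um)
        fwhm_bot = measure_hole_width(bot_slice, pix_um)

        # split-pattern FRC resolution at angle 0
        half = A.rows // 2
        A1 = mask_mod.PatternMatrix(A.values[:half], A.pattern_shape, A.pitch_um)
        A2 = mask_mod.PatternMatrix(A.values[half:], A.pattern_shape, A.pitch_um)
        geom0 = physics.ScatterGeometry(
            photon_energy_keV=config.geometry.photon_energy_keV,
            detector_angle_deg=config.geometry.detector_angle_deg,
            rotation_angle_deg=angles[0],
        )
        smap0 = physics.scatter_response_map(phantom, geom0)
        x0 = gi.resize_to_pow2(smap0.values, config.patterns.shape) \
            if smap0.shape != tuple(config.patterns.shape) else smap0.values
        rm0 = physics.ResponseMap(x0, smap0.pixel_um, angles[0])
        recs = []
        for sub, tag in ((A1, "frc1"), (A2, "frc2")):
            b = physics.bucket_signals(
                sub, rm0, noise=config.noise.model, scale=config.noise.scale,
                seed=derive_seed(config.master_seed, tag),
            )
            recs.append(gi.reconstruct_tv_least_squares(sub, b).image)
        curve = frc.frc_curve(recs[0], recs[1], pix_um)
        frc.write_frc_csv(curve, out / "frc.csv")
        cut = frc.cutoff_frequency(curve)
        report["stages"]["metrics"] = {
            "scatter_volume_pearson": metrics["pearson"],
            "scatter_volume_rmse": metrics["rmse"],
            "hole_width_top_um": hole_top,
            "hole_width_bottom_um": hole_bot,
            "hole_fwhm_top_um": fwhm_top,
            "hole_fwhm_bottom_um": fwhm_bot,
            "taper_sign_correct": bool(hole_top > hole_bot),
            "frc_cutoff_per_um": cut.frequency_per_um,
            "frc_crossed": cut.crossed,
            "frc_resolution_um": frc.resolution_from_cutoff(cut.frequency_per_um),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the small canonical test set and return its manifest.

    Contents: a 16×16 toy mask, an 8³ phantom (mu and rho as CSV), a
    12-pattern / 16-pixel toy system with its expected bucket values, and the
    hand-checkable FRC curve whose cutoff interpolates to 0.0026 µm⁻¹.
    All files are plain text; the manifest maps file names to SHA-256 hashes
    and is identical across regenerations with one seed.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"fixture directory {out_dir} is not writable: {e}") from e

    m = mask_mod.generate_mask(16, 16, 100.0, 0.5, seed)
    np.savetxt(out_dir / "toy_mask.csv", m.grid, fmt="%d", delimiter=",")

    phantom = physics.make_bone_phantom((8, 8, 8), 0.5, 1500.0, 1000.0, seed=seed)
    np.savetxt(out_dir / "phantom_mu.csv",
               phantom.mu.reshape(8, 64), delimiter=",")
    np.savetxt(out_dir / "phantom_rho.csv",
               phantom.rho_e.reshape(8, 64), delimiter=",")

    A = mask_mod.extract_patterns(m, 12, (4, 4), strategy="random-shift", seed=seed)
    rng = np.random.default_rng(derive_seed(seed, "fixture-x"))
    x = rng.random((4, 4))
    buckets = physics.bucket_signals(A, x)
    np.savetxt(out_dir / "toy_patterns.csv", A.values, fmt="%d", delimiter=",")
    np.savetxt(out_dir / "toy_x.csv", x, delimiter=",")
    np.savetxt(out_dir / "toy_buckets.csv", buckets.values, delimiter=",")

    curve = frc.FRCCurve(
        freqs=np.array([0.001, 0.002, 0.003]),
        frc=np.array([0.9, 0.8, 0.3]),
        halfbit=np.array([0.5, 0.5, 0.5]),
        n_per_ring=np.array([8, 16, 24]),
        pixel_um=100.0,
    )
    frc.write_frc_csv(curve, out_dir / "frc_example.csv")

    manifest = {"seed": int(seed), "files": {}}
    for p in sorted(out_dir.iterdir()):
        if p.name == "manifest.json" or p.name.startswith("."):
            continue
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
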