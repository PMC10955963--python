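"""Binary illumination masks and the ghost-imaging measurement matrix.

A computational ghost-imaging system illuminates the object with a sequence of
known binary intensity patterns.  In hardware the patterns come from a single
large pre-characterized transmission mask that is translated between
exposures; each detector reading is paired with the mask window that was in
the beam.  This module models that mask, extracts pattern stacks from it, and
packs them into the measurement matrix ``A`` whose rows are flattened
illumination patterns — the operator of the imaging equation ``A x = S``.

Coordinate convention (used by every file this module writes): row-major
flattening, 0-based offsets, (row, col) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import (
    CapacityError,
    DegenerateInputError,
    InvalidArgumentError,
    OutOfBoundsError,
)

__all__ = [
    "Mask",
    "PatternMatrix",
    "generate_mask",
    "extract_patterns",
    "autocorrelation_width",
    "sampling_rate",
    "write_mask",
    "read_mask",
    "write_patterns",
    "read_patterns",
]

_CONVENTION = "row-major flattening, 0-based offsets, (row, col) order"


@dataclass(frozen=True)
class Mask:
    """A binary transmission mask.

    Attributes
    ----------
    grid : ndarray of uint8, shape (H, W)
        1 = transmitting, 0 = absorbing.
    pitch_um : float
        Physical pixel pitch in micrometres.
    seed : int
        RNG seed the mask was generated from (-1 for externally supplied).
    """

    grid: np.ndarray
    pitch_um: float
    seed: int = -1

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise InvalidArgumentError("mask grid must be 2D")
        if not np.isin(grid, (0, 1)).all():
            raise InvalidArgumentError("mask grid must contain only 0 and 1")
        if not self.pitch_um > 0:
            raise InvalidArgumentError("pitch_um must be positive")
        object.__setattr__(self, "grid", grid.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def duty(self) -> float:
        """Fraction of transmitting pixels."""
        return float(self.grid.mean())


@dataclass(frozen=True)
class PatternMatrix:
    """Measurement matrix ``A``: one flattened illumination pattern per row."""

    values: np.ndarray
    pattern_shape: tuple[int, int]
    pitch_um: float
    offsets: tuple[tuple[int, int], ...] = field(default=())
    seed: int = -1

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InvalidArgumentError("pattern matrix must be 2D (m x n)")
        h, w = self.pattern_shape
        if values.shape[1] != h * w:
            raise InvalidArgumentError(
                f"cols {values.shape[1]} != prod(pattern_shape) {h * w}"
            )
        if not np.isin(values, (0, 1)).all():
            raise InvalidArgumentError("pattern matrix entries must be binary")
        object.__setattr__(self, "values", values.astype(np.uint8))
        object.__setattr__(self, "pattern_shape", (int(h), int(w)))

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_rate(self) -> float:
        return sampling_rate(self.rows, self.cols)

    def pattern(self, k: int) -> np.ndarray:
        """Return row ``k`` reshaped to ``pattern_shape`` (lossless)."""
        return self.values[k].reshape(self.pattern_shape)

    def as_float(self) -> np.ndarray:
        return self.values.astype(np.float64)


def generate_mask(
    height_px: int,
    width_px: int,
    pitch_um: float,
    duty: float = 0.5,
    seed: int = 0,
) -> Mask:
    """Generate an i.i.d. Bernoulli(duty) binary mask.

    The physical mask this emulates has a 1:1 transmission–absorption ratio,
    i.e. ``duty = 0.5``.  Reproducible for a fixed ``seed``.
    """
    if height_px < 1 or width_px < 1:
        raise InvalidArgumentError("mask dimensions must be >= 1")
    if not pitch_um > 0:
        raise InvalidArgumentError("pitch_um must be positive")
    if not 0 < duty <= 1:
        raise InvalidArgumentError("duty must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    grid = (rng.random((height_px, width_px)) < duty).astype(np.uint8)
    return Mask(grid=grid, pitch_um=float(pitch_um), seed=int(seed))


def extract_patterns(
    mask: Mask,
    n_patterns: int,
    pattern_shape: tuple[int, int],
    offsets: list[tuple[int, int]] | None = None,
    strategy: str = "random-shift",
    seed: int = 0,
) -> PatternMatrix:
    """Cut ``n_patterns`` windows out of the mask and stack them as rows of A.

    This is the software analogue of translating one physical mask between
    exposures.  With ``strategy="random-shift"`` the window offsets are drawn
    without replacement from all valid positions; ``strategy="tile"`` walks
    the valid positions in row-major order.  Explicit ``offsets`` override the
    strategy.
    """
    h, w = map(int, pattern_shape)
    H, W = mask.shape
    if h < 1 or w < 1:
        raise InvalidArgumentError("pattern_shape must be positive")
    if h > H or w > W:
        raise OutOfBoundsError(
            f"pattern window {h}x{w} exceeds mask bounds {H}x{W}"
        )
    n_valid = (H - h + 1) * (W - w + 1)

    if offsets is not None:
        offsets = [(int(r), int(c)) for r, c in offsets]
        if len(set(offsets)) != len(offsets):
            raise InvalidArgumentError("offsets must be unique")
        n_patterns = len(offsets)
        for r, c in offsets:
            if r < 0 or c < 0 or r + h > H or c + w > W:
                raise OutOfBoundsError(f"offset {(r, c)} puts window outside mask")
    else:
        if n_patterns < 1:
            raise InvalidArgumentError("n_patterns must be >= 1")
        if n_patterns > n_valid:
            raise CapacityError(
                f"requested {n_patterns} unique offsets but only {n_valid} exist"
            )
        if strategy == "random-shift":
            rng = np.random.default_rng(seed)
            flat = rng.choice(n_valid, size=n_patterns, replace=False)
            offsets = [(int(f) // (W - w + 1), int(f) % (W - w + 1)) for f in flat]
        elif strategy == "tile":
            offsets = [
                (f // (W - w + 1), f % (W - w + 1)) for f in range(n_patterns)
            ]
        else:
            raise InvalidArgumentError(f"unknown strategy {strategy!r}")

    values = np.empty((n_patterns, h * w), dtype=np.uint8)
    for k, (r, c) in enumerate(offsets):
        values[k] = mask.grid[r : r + h, c : c + w].ravel()
    return PatternMatrix(
        values=values,
        pattern_shape=(h, w),
        pitch_um=mask.pitch_um,
        offsets=tuple(offsets),
        seed=int(seed),
    )


def _autocorr_profile_direct(g: np.ndarray) -> np.ndarray:
    # horizontal-lag profile of the linear autocorrelation, lags 0..W-1
    W = g.shape[1]
    prof = np.empty(W)
    for dx in range(W):
        prof[dx] = float(np.sum(g[:, : W - dx] * g[:, dx:]))
    return prof

def _autocorr_profile_fft(g: np.ndarray) -> np.ndarray:
    H, W = g.shape
    F = np.fft.rfft2(g, s=(2 * H, 2 * W))
    ac = np.fft.irfft2(np.abs(F) ** 2, s=(2 * H, 2 * W))
    return ac[0, :W]  # row 0 = zero vertical lag; cols 0..W-1 = horizontal lags


def autocorrelation_profile(mask: Mask) -> np.ndarray:
    """Mean-subtracted autocorrelation along the horizontal axis through the
    central peak, normalized to peak 1; index = lag in pixels.

    Computed by direct summation for masks up to 512x512 and by FFT beyond
    (the two agree to better than 1e-8 where both apply).
    """
    g = mask.grid.astype(np.float64)
    g -= g.mean()
    if not np.any(g):
        raise DegenerateInputError("constant mask has no autocorrelation width")
    if g.size <= 512 * 512:
        prof = _autocorr_profile_direct(g)
    else:
        prof = _autocorr_profile_fft(g)
    return prof / prof[0]


def autocorrelation_width(mask: Mask) -> float:
    """FWHM (µm) of the mask autocorrelation central peak.

    The autocorrelation width of the illumination patterns sets the theoretical
    resolution of a ghost-imaging system: two object features closer than this
    length see statistically indistinguishable illumination.  Measured along
    the horizontal lag axis with linear interpolation at half maximum.
    """
    H, W = mask.shape
    if H < 2 or W < 2:
        raise InvalidArgumentError("mask must have at least 2 pixels per axis")
    prof = autocorrelation_profile(mask)
    half = 0.5
    below = np.nonzero(prof < half)[0]
    if below.size == 0:
        # peak never decays to half within the mask: width is the full extent
        return 2.0 * (W - 1) * mask.pitch_um
    i = int(below[0])  # first lag strictly below half; i >= 1 since prof[0]=1
    frac = (prof[i - 1] - half) / (prof[i - 1] - prof[i])
    half_width_px = (i - 1) + frac
    return 2.0 * half_width_px * mask.pitch_um


def sampling_rate(n_patterns: int, n_pixels: int) -> float:
    """Number of patterns divided by number of reconstructed pixels.

    Below 1 the ghost-imaging inverse problem is underdetermined.
    """
    if n_pixels < 1:
        raise InvalidArgumentError("n_pixels must be >= 1")
    if n_patterns < 0:
        raise InvalidArgumentError("n_patterns must be >= 0")
    return n_patterns / n_pixels


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return Path(path).with_suffix(".json")


def write_mask(mask: Mask, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.grid)
    meta = {
        "convention": _CONVENTION,
        "pitch_um": mask.pitch_um,
        "seed": mask.seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_mask(path: str | Path) -> Mask:
    path = Path(path)
    grid = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return Mask(grid=grid, pitch_um=meta["pitch_um"], seed=meta.get("seed", -1))


def write_patterns(patterns: PatternMatrix, path: str | Path) -> None:
    """One TIFF page per pattern; offsets/pitch/seed in the JSON sidecar."""
    path = Path(path)
    stack = patterns.values.reshape((patterns.rows, *patterns.pattern_shape))
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "convention": _CONVENTION,
        "pitch_um": patterns.pitch_um,
        "seed": patterns.seed,
        "offsets": [list(o) for o in patterns.offsets],
        "pattern_shape": list(patterns.pattern_shape),
        "sampling_rate": patterns.sampling_rate,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_patterns(path: str | Path) -> PatternMatrix:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(_sidecar(path).read_text())
    h, w = meta.get("pattern_shape", stack.shape[1:])
    return PatternMatrix(
        values=stack.reshape(stack.shape[0], -1),
        pattern_shape=(int(h), int(w)),
        pitch_um=meta["pitch_um"],
        offsets=tuple(tuple(o) for o in meta.get("offsets", [])),
        seed=meta.get("seed", -1),
    )
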