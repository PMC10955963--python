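"""Ghost-imaging reconstruction: recover the response map x from (A, S).

Four solver routes for the measurement equation ``A x = S``:

* ``pinv`` — minimum-norm least squares (direct, exact oracle).
* ``cgls`` — conjugate gradient on the normal equations (iterative oracle).
* ``tv-least-squares`` — monotone proximal-gradient minimization of
  ``|A x − S|² + τ·TV(x)`` directly over pixels (network-free TV baseline).
* ``gidc`` — the self-supervised untrained-network solver: the weights φ of a
  small CNN are optimized so its output T_φ(x₀) satisfies
  ``argmin_φ |A T_φ(x₀) − S|² + τ·TV(T_φ(x₀))``, where x₀ is the linear
  reconstruction.  No training data is used; the best-loss iterate is kept.

Differential-measurement preprocessing (mean-centering A over patterns and S
over readings) is the standard ghost-imaging trick for removing the common
background term; it is default-on for the GI-style solvers (gidc, TV) and
default-off for the exact linear oracles, and the lost DC component is
restored by a one-dimensional least-squares fit along A·1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import (
    DegenerateSystemError,
    InvalidArgumentError,
    OptimizationFailureError,
)
from .mask import PatternMatrix
from .nn import ImagePriorNet
from .physics import BucketSeries

__all__ = [
    "GidcParams",
    "Reconstruction",
    "reconstruct_linear",
    "reconstruct_gidc",
    "reconstruct_tv_least_squares",
    "tv_norm",
    "resize_to_pow2",
    "write_reconstruction",
    "read_reconstruction",
]


def _is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class GidcParams:
    """Hyperparameters of the untrained-network solver.

    Defaults mirror the reference operating point: learning rate 0.002,
    TV strength 10^-3.9, 1501 optimization steps, 128x128 images.  A smaller
    test profile (64x64 or below, a few hundred steps) is used throughout the
    test suite.  Image dimensions must be powers of two.
    """

    image_shape: tuple[int, int]
    learning_rate: float = 0.002
    tv_strength: float = 10.0 ** -3.9
    n_steps: int = 1501
    seed: int = 0
    channels: int = 16

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise InvalidArgumentError("learning_rate must be positive")
        if self.tv_strength < 0:
            raise InvalidArgumentError("tv_strength must be non-negative")
        if self.n_steps < 1:
            raise InvalidArgumentError("n_steps must be >= 1")
        h, w = self.image_shape
        if not (_is_pow2(h) and _is_pow2(w)):
            raise InvalidArgumentError(
                f"image_shape {self.image_shape} must be powers of two per axis"
            )
        object.__setattr__(self, "image_shape", (int(h), int(w)))


@dataclass(frozen=True)
class Reconstruction:
    """Solver output: the image, the per-step objective, and provenance."""

    image: np.ndarray
    loss_history: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "image", np.asarray(self.image, dtype=np.float64))
        object.__setattr__(
            self, "loss_history", np.asarray(self.loss_history, dtype=np.float64)
        )


def _check_system(A: PatternMatrix, S: BucketSeries):
    if A.rows != len(S):
        raise InvalidArgumentError(
            f"A has {A.rows} rows but S has {len(S)} readings"
        )
    if not A.values.any():
        raise DegenerateSystemError("measurement matrix is identically zero")


def _center(Af: np.ndarray, Sv: np.ndarray):
    return Af - Af.mean(axis=0), Sv - Sv.mean()


def _restore_dc(image_flat: np.ndarray, Af: np.ndarray, Sv: np.ndarray):
    """Add the constant offset that best explains the raw (uncentered) data."""
    u = Af.sum(axis=1)
    uu = float(u @ u)
    if uu == 0:
        return image_flat
    gamma = float(u @ (Sv - Af @ image_flat)) / uu
    return image_flat + gamma


def _cgls(Af: np.ndarray, b: np.ndarray, max_iter: int, tol: float):
    """Conjugate gradient for least squares; returns (x, residual-norm history)."""
    n = Af.shape[1]
    x = np.zeros(n)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return x, np.array([0.0])
    r = b.copy()
    s = Af.T @ r
    p = s.copy()
    gamma = float(s @ s)
    history = [np.linalg.norm(r)]
    for _ in range(max_iter):
        q = Af @ p
        qq = float(q @ q)
        if qq == 0:
            break
        alpha = gamma / qq
        x += alpha * p
        r -= alpha * q
        history.append(np.linalg.norm(r))
        if history[-1] / bnorm <= tol:
            break
        s = Af.T @ r
        gamma_new = float(s @ s)
        if gamma_new == 0:
            break
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return x, np.array(history)


def reconstruct_linear(
    A: PatternMatrix,
    S: BucketSeries,
    method: str = "cgls",
    max_iter: int = 500,
    tol: float = 1e-10,
    center: bool = False,
) -> Reconstruction:
    """Least-squares ghost-imaging reconstruction (the linear oracles).

    ``pinv`` returns the minimum-norm least-squares solution; ``cgls`` the
    conjugate-gradient iterate meeting ``|A x − S|/|S| ≤ tol`` or
    ``max_iter``.  CGLS residual norms decrease monotonically, so the final
    iterate attains the minimum of the recorded history.
    """
    _check_system(A, S)
    Af = A.as_float()
    Sv = S.values
    As, Ss = _center(Af, Sv) if center else (Af, Sv)
    if method == "pinv":
        x, *_ = np.linalg.lstsq(As, Ss, rcond=None)
        history = np.array([np.linalg.norm(As @ x - Ss)])
    elif method == "cgls":
        x, history = _cgls(As, Ss, max_iter=max_iter, tol=tol)
    else:
        raise InvalidArgumentError(f"unknown linear method {method!r}")
    if center:
        x = _restore_dc(x, Af, Sv)
    return Reconstruction(
        image=x.reshape(A.pattern_shape),
        loss_history=history,
        method=method,
        meta={"center": center, "tol": tol, "max_iter": max_iter},
    )


# ---------------------------------------------------------------------------
# Total variation
# ---------------------------------------------------------------------------

def tv_norm(image: np.ndarray) -> float:
    """Anisotropic total variation: sum of |forward differences|, both axes,
    no wraparound."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise InvalidArgumentError("tv_norm needs a 2D image of at least 2x2")
    return float(np.abs(np.diff(image, axis=0)).sum()
                 + np.abs(np.diff(image, axis=1)).sum())


def _grad_ops(x: np.ndarray):
    return np.diff(x, axis=0), np.diff(x, axis=1)


def _grad_adjoint(dv: np.ndarray, dh: np.ndarray, shape):
    out = np.zeros(shape)
    out[1:, :] += dv
    out[:-1, :] -= dv
    out[:, 1:] += dh
    out[:, :-1] -= dh
    return out


def _tv_smoothed_grad(x: np.ndarray, eps: float = 1e-6):
    dv, dh = _grad_ops(x)
    return _grad_adjoint(dv / np.sqrt(dv * dv + eps * eps),
                         dh / np.sqrt(dh * dh + eps * eps), x.shape)


def _prox_tv(y: np.ndarray, lam: float, n_iter: int = 40) -> np.ndarray:
    """prox of lam*TV (anisotropic) via dual gradient projection."""
    if lam <= 0:
        return y
    pv = np.zeros((y.shape[0] - 1, y.shape[1]))
    ph = np.zeros((y.shape[0], y.shape[1] - 1))
    sigma = 1.0 / 8.0
    for _ in range(n_iter):
        x = y - _grad_adjoint(pv, ph, y.shape)
        dv, dh = _grad_ops(x)
        pv = np.clip(pv + sigma * dv, -lam, lam)
        ph = np.clip(ph + sigma * dh, -lam, lam)
    return y - _grad_adjoint(pv, ph, y.shape)


def _spectral_norm_sq(Af: np.ndarray, n_iter: int = 60) -> float:
    v = np.ones(Af.shape[1]) / np.sqrt(Af.shape[1])
    lam = 0.0
    for _ in range(n_iter):
        w = Af.T @ (Af @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 0.0
        v = w / lam
    return lam  # largest eigenvalue of A^T A


def reconstruct_tv_least_squares(
    A: PatternMatrix,
    S: BucketSeries,
    tau: float = 10.0 ** -3.9,
    n_steps: int = 300,
    step: float | None = None,
    center: bool = True,
) -> Reconstruction:
    """Proximal-gradient (ISTA) minimization of ``|A x − S|² + τ·TV(x)``.

    Deterministic; initialized at the CGLS solution; a candidate step is
    accepted only if the objective does not increase (the step is halved
    otherwise), so the recorded objective is non-increasing.
    """
    _check_system(A, S)
    if tau < 0:
        raise InvalidArgumentError("tau must be non-negative")
    Af = A.as_float()
    Sv = S.values
    As, Ss = _center(Af, Sv) if center else (Af, Sv)

    # dimensionless objective |B xh - b|^2 + tau*TV(xh): b is the unit-norm
    # data, xh the image in units of the linear solution's peak, so the data
    # term is the squared relative residual and tau is scale-free
    x0 = _cgls(As, Ss, max_iter=200, tol=1e-12)[0]
    c = float(np.abs(x0).max()) or 1.0
    s_norm = float(np.linalg.norm(Ss)) or 1.0
    B = As * (c / s_norm)
    b = Ss / s_norm
    x = x0 / c

    L = 2.0 * _spectral_norm_sq(B)
    if L == 0:
        raise DegenerateSystemError("measurement matrix has zero spectral norm")
    t = (1.0 / L) if step is None else step

    def objective(xf):
        r = B @ xf - b
        return float(r @ r) + tau * tv_norm(xf.reshape(A.pattern_shape))

    history = [objective(x)]
    for _ in range(n_steps):
        grad = 2.0 * (B.T @ (B @ x - b))
        cand = _prox_tv((x - t * grad).reshape(A.pattern_shape),
                        tau * t).ravel()
        f_cand = objective(cand)
        if f_cand <= history[-1]:
            x = cand
            history.append(f_cand)
        else:
            t *= 0.5
            history.append(history[-1])
    x = x * c
    if center:
        x = _restore_dc(x, Af, Sv)
    return Reconstruction(
        image=x.reshape(A.pattern_shape),
        loss_history=np.array(history),
        method="tv-least-squares",
        meta={"tau": tau, "center": center, "tv_flavor": "anisotropic-l1"},
    )


# ---------------------------------------------------------------------------
# Untrained-network solver
# ---------------------------------------------------------------------------

def reconstruct_gidc(
    A: PatternMatrix,
    S: BucketSeries,
    params: GidcParams,
    init: Reconstruction | None = None,
    center: bool = True,
) -> Reconstruction:
    """Self-supervised untrained-network reconstruction.

    The network input is the linear (CGLS) reconstruction, normalized to
    unit peak; the loss is the relative data term
    ``|A T − S|²/|S|²`` plus ``τ·TV(T)`` on the normalized image.  Adam
    updates the network weights for ``n_steps``; the best-loss iterate is
    returned (untrained-prior optimizations degrade late).  Bit-reproducible
    for a fixed seed.
    """
    _check_system(A, S)
    h, w = params.image_shape
    if A.cols != h * w:
        raise InvalidArgumentError(
            f"A has {A.cols} columns but image_shape implies {h * w} pixels"
        )
    Af = A.as_float()
    Sv = S.values
    As, Ss = _center(Af, Sv) if center else (Af, Sv)

    if init is not None:
        x0 = init.image.ravel().astype(np.float64)
    else:
        x0 = _cgls(As, Ss, max_iter=200, tol=1e-12)[0]
    scale = float(np.abs(x0).max()) or 1.0
    x0n = (x0 / scale).reshape(h, w)
    Sn = Ss / scale
    s_norm2 = float(Sn @ Sn) or 1.0

    net = ImagePriorNet(channels=params.channels, seed=params.seed)
    tau = params.tv_strength
    best_loss = np.inf
    best_image = x0n.copy()
    best_step = -1
    history = np.empty(params.n_steps)
    for k in range(params.n_steps):
        T = net.forward(x0n)
        r = As @ T.ravel() - Sn
        data = float(r @ r) / s_norm2
        loss = data + tau * tv_norm(T)
        if not np.isfinite(loss):
            raise OptimizationFailureError(
                f"gidc loss became non-finite at step {k}", last_finite_step=k - 1
            )
        history[k] = loss
        if loss < best_loss:
            best_loss, best_image, best_step = loss, T.copy(), k
        g_img = (2.0 / s_norm2) * (As.T @ r).reshape(h, w) + tau * _tv_smoothed_grad(T)
        net.adam_step(net.backward(g_img), params.learning_rate)

    image = (best_image * scale).ravel()
    if center:
        image = _restore_dc(image, Af, Sv)
    return Reconstruction(
        image=image.reshape(h, w),
        loss_history=history,
        method="gidc",
        meta={
            "params": {
                "learning_rate": params.learning_rate,
                "tv_strength": params.tv_strength,
                "n_steps": params.n_steps,
                "seed": params.seed,
                "channels": params.channels,
            },
            "center": center,
            "best_step": best_step,
            "best_loss": best_loss,
            "tv_flavor": "anisotropic-l1",
        },
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _overlap_matrix(n_in: int, n_out: int) -> np.ndarray:
    # M[i, j] = length of input cell j inside output cell i (input-pixel units);
    # columns sum to 1, so total intensity is preserved exactly.
    scale = n_in / n_out
    M = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            M[i, j] = max(0.0, min(hi, j + 1) - max(lo, j)) / 1.0
    return M


def resize_to_pow2(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Area-weighted resampling to a power-of-two shape, preserving the total
    intensity (each input pixel's value is distributed over the output cells
    it overlaps)."""
    image = np.asarray(image, dtype=np.float64)
    th, tw = map(int, target)
    if not (_is_pow2(th) and _is_pow2(tw)):
        raise InvalidArgumentError(f"target {target} must be powers of two")
    if image.shape == (th, tw):
        return image.copy()
    Mh = _overlap_matrix(image.shape[0], th)
    Mw = _overlap_matrix(image.shape[1], tw)
    return Mh @ image @ Mw.T


# ---------------------------------------------------------------------------
# I/O: 32-bit TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def write_reconstruction(recon: Reconstruction, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, recon.image.astype(np.float32))
    meta = {
        "method": recon.method,
        "final_loss": float(recon.loss_history[-1]),
        "best_loss": float(recon.loss_history.min()),
        **{k: v for k, v in recon.meta.items() if not isinstance(v, np.ndarray)},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True,
                                                    default=str))


def read_reconstruction(path: str | Path) -> Reconstruction:
    path = Path(path)
    image = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Reconstruction(
        image=image,
        loss_history=np.array([meta.get("final_loss", np.nan)]),
        method=meta.get("method", "unknown"),
        meta=meta,
    )
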