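"""Minimal untrained convolutional network with explicit backpropagation.

This is the image-prior engine behind the self-supervised ghost-imaging
solver: a small two-scale encoder–decoder with an additive skip connection
and a residual output, written directly in numpy (forward pass, analytic
gradients, Adam).  No training data is involved — the network weights are the
optimization variables and the only "prior" is the architecture itself plus
an explicit total-variation penalty applied by the caller.

All convolutions are 3x3, stride 1, zero-padded ("same").  Tensors are
(channels, height, width); batch size is always 1.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ImagePriorNet"]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (C, H, W); W: (O, C, 3, 3); b: (O,)
    C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    y = np.zeros((W.shape[0], H, Wd))
    for di in range(3):
        for dj in range(3):
            y += np.tensordot(W[:, :, di, dj], xp[:, di : di + H, dj : dj + Wd],
                              axes=(1, 0))
    return y + b[:, None, None]


def _conv_backward(x, W, gy):
    C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    gW = np.zeros_like(W)
    gxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            gW[:, :, di, dj] = np.tensordot(gy, xp[:, di : di + H, dj : dj + Wd],
                                            axes=([1, 2], [1, 2]))
            gxp[:, di : di + H, dj : dj + Wd] += np.tensordot(
                W[:, :, di, dj].T, gy, axes=(1, 0)
            )
    gb = gy.sum(axis=(1, 2))
    return gW, gb, gxp[:, 1:-1, 1:-1]


def _lrelu(x, alpha=0.1):
    return np.where(x > 0, x, alpha * x)


def _lrelu_grad(x, gy, alpha=0.1):
    return np.where(x > 0, gy, alpha * gy)


def _avgpool2(x):
    C, H, W = x.shape
    return x.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))


def _avgpool2_grad(gy):
    return np.repeat(np.repeat(gy, 2, axis=1), 2, axis=2) / 4.0


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_grad(gy):
    C, H, W = gy.shape
    return gy.reshape(C, H // 2, 2, W // 2, 2).sum(axis=(2, 4))


class ImagePriorNet:
    """Two-scale encoder–decoder: conv–conv / pool / conv–conv / upsample /
    conv (+skip) / conv / conv-to-1, residual output ``input + net(input)``.

    ``channels`` is the base channel count (doubled at the coarse scale).
    The final 1-channel convolution is initialized near zero so the initial
    output equals the input image — optimization starts from the linear
    reconstruction it is given.
    """

    def __init__(self, channels: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        c, c2 = channels, 2 * channels

        def he(o, i):
            return rng.normal(0.0, np.sqrt(2.0 / (i * 9)), size=(o, i, 3, 3))

        self.params: dict[str, np.ndarray] = {
            "W1": he(c, 1), "b1": np.zeros(c),
            "W2": he(c, c), "b2": np.zeros(c),
            "W3": he(c2, c), "b3": np.zeros(c2),
            "W4": he(c2, c2), "b4": np.zeros(c2),
            "W5": he(c, c2), "b5": np.zeros(c),
            "W6": he(c, c), "b6": np.zeros(c),
            "W7": 1e-3 * he(1, c), "b7": np.zeros(1),
        }
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0
        self._cache: dict[str, np.ndarray] = {}

    def forward(self, image: np.ndarray) -> np.ndarray:
        """image: (H, W) with H, W even; returns (H, W)."""
        p, C = self.params, self._cache
        x0 = image[None]
        C["x0"] = x0
        C["z1"] = _conv_forward(x0, p["W1"], p["b1"]); C["a1"] = _lrelu(C["z1"])
        C["z2"] = _conv_forward(C["a1"], p["W2"], p["b2"]); C["a2"] = _lrelu(C["z2"])
        C["pool"] = _avgpool2(C["a2"])
        C["z3"] = _conv_forward(C["pool"], p["W3"], p["b3"]); C["a3"] = _lrelu(C["z3"])
        C["z4"] = _conv_forward(C["a3"], p["W4"], p["b4"]); C["a4"] = _lrelu(C["z4"])
        C["up"] = _upsample2(C["a4"])
        C["z5"] = _conv_forward(C["up"], p["W5"], p["b5"]); C["a5"] = _lrelu(C["z5"])
        C["skip"] = C["a5"] + C["a2"]
        C["z6"] = _conv_forward(C["skip"], p["W6"], p["b6"]); C["a6"] = _lrelu(C["z6"])
        C["z7"] = _conv_forward(C["a6"], p["W7"], p["b7"])
        return (C["z7"] + x0)[0]

    def backward(self, g_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt every parameter, given dLoss/dOutput."""
        p, C = self.params, self._cache
        g = {}
        gy = g_out[None]
        g["W7"], g["b7"], ga6 = _conv_backward(C["a6"], p["W7"], gy)
        gz6 = _lrelu_grad(C["z6"], ga6)
        g["W6"], g["b6"], gskip = _conv_backward(C["skip"], p["W6"], gz6)
        ga5 = gskip
        ga2_skip = gskip
        gz5 = _lrelu_grad(C["z5"], ga5)
        g["W5"], g["b5"], gup = _conv_backward(C["up"], p["W5"], gz5)
        ga4 = _upsample2_grad(gup)
        gz4 = _lrelu_grad(C["z4"], ga4)
        g["W4"], g["b4"], ga3 = _conv_backward(C["a3"], p["W4"], gz4)
        gz3 = _lrelu_grad(C["z3"], ga3)
        g["W3"], g["b3"], gpool = _conv_backward(C["pool"], p["W3"], gz3)
        ga2 = _avgpool2_grad(gpool) + ga2_skip
        gz2 = _lrelu_grad(C["z2"], ga2)
        g["W2"], g["b2"], ga1 = _conv_backward(C["a1"], p["W2"], gz2)
        gz1 = _lrelu_grad(C["z1"], ga1)
        g["W1"], g["b1"], _ = _conv_backward(C["x0"], p["W1"], gz1)
        return g

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._t += 1
        for k, gk in grads.items():
            self._m[k] = beta1 * self._m[k] + (1 - beta1) * gk
            self._v[k] = beta2 * self._v[k] + (1 - beta2) * gk * gk
            mhat = self._m[k] / (1 - beta1**self._t)
            vhat = self._v[k] / (1 - beta2**self._t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k] = v.copy()
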