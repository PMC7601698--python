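"""Neural-network layers on the numpy autodiff tape.

Layout convention is NHWC: images are ``(batch, height, width, channels)``.
Convolutions are implemented with im2col/col2im; the transposed convolution
follows the usual output-size rule
``H_out = (H_in - 1)·stride - 2·padding + kernel + output_padding``.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, make_op

__all__ = [
    "Parameter", "Dense", "Conv2d", "ConvTranspose2d", "BatchNorm", "Adam",
    "conv2d", "conv_transpose2d",
]


def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional convolutions
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, H, W, C) -> (N, Ho, Wo, kh*kw*C) patch matrix (x already padded)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]                      # (N, Ho, Wo, C, kh, kw)
    win = win.transpose(0, 1, 2, 4, 5, 3)                 # (N, Ho, Wo, kh, kw, C)
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, ho, wo, kh * kw * x.shape[3])


def conv2d(x, w, b, stride: int = 1, padding: int = 0):
    """2-D convolution; ``w`` has shape (kh, kw, c_in, c_out)."""
    xd = x.data if isinstance(x, Tensor) else np.asarray(x, float)
    wd, bd = w.data, b.data
    kh, kw, cin, cout = wd.shape
    if xd.ndim != 4 or xd.shape[3] != cin:
        raise ValueError(f"conv2d: input {xd.shape} incompatible with weight {wd.shape}")
    xp = np.pad(xd, ((0, 0), (padding, padding), (padding, padding), (0, 0))) if padding else xd
    if xp.shape[1] < kh or xp.shape[2] < kw:
        raise ValueError(
            f"conv2d: spatial size {xp.shape[1]}x{xp.shape[2]} smaller than kernel {kh}x{kw}"
        )
    cols = _im2col(xp, kh, kw, stride)                    # (N, Ho, Wo, K)
    n, ho, wo, K = cols.shape
    wmat = wd.reshape(K, cout)
    out_data = cols.reshape(-1, K) @ wmat + bd
    out_data = out_data.reshape(n, ho, wo, cout)

    out = make_op(out_data, (x, w, b))
    if out.requires_grad:
        def _bw():
            g = out.grad.reshape(-1, cout)
            if w.requires_grad:
                w._accum((cols.reshape(-1, K).T @ g).reshape(wd.shape))
            if b.requires_grad:
                b._accum(out.grad.sum(axis=(0, 1, 2)))
            if isinstance(x, Tensor) and x.requires_grad:
                dcols = (g @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + ho * stride:stride, j:j + wo * stride:stride, :] += \
                            dcols[:, :, :, i, j, :]
                if padding:
                    dxp = dxp[:, padding:-padding, padding:-padding, :]
                x._accum(dxp)
        out._backward = _bw
    return out


def conv_transpose2d(x, w, b, stride: int = 2, padding: int = 0, output_padding: int = 0):
    """Transposed 2-D convolution; ``w`` has shape (kh, kw, c_in, c_out)."""
    xd = x.data if isinstance(x, Tensor) else np.asarray(x, float)
    wd, bd = w.data, b.data
    kh, kw, cin, cout = wd.shape
    if xd.ndim != 4 or xd.shape[3] != cin:
        raise ValueError(f"conv_transpose2d: input {xd.shape} incompatible with weight {wd.shape}")
    n, h, wdth, _ = xd.shape
    hfull = (h - 1) * stride + kh
    wfull = (wdth - 1) * stride + kw
    hout = (h - 1) * stride - 2 * padding + kh + output_padding
    wout = (wdth - 1) * stride - 2 * padding + kw + output_padding
    if hout < 1 or wout < 1 or padding + hout > hfull or padding + wout > wfull:
        raise ValueError("conv_transpose2d: inconsistent geometry")

    prod = np.tensordot(xd, wd, axes=([3], [2]))          # (N, H, W, kh, kw, cout)
    full = np.zeros((n, hfull, wfull, cout), dtype=prod.dtype)
    for i in range(kh):
        for j in range(kw):
            full[:, i:i + h * stride:stride, j:j + wdth * stride:stride, :] += prod[:, :, :, i, j, :]
    out_data = full[:, padding:padding + hout, padding:padding + wout, :] + bd

    out = make_op(out_data, (x, w, b))
    if out.requires_grad:
        def _bw():
            gfull = np.zeros((n, hfull, wfull, cout), dtype=out.grad.dtype)
            gfull[:, padding:padding + hout, padding:padding + wout, :] = out.grad
            if b.requires_grad:
                b._accum(out.grad.sum(axis=(0, 1, 2)))
            dprod = np.empty((n, h, wdth, kh, kw, cout), dtype=out.grad.dtype)
            for i in range(kh):
                for j in range(kw):
                    dprod[:, :, :, i, j, :] = gfull[:, i:i + h * stride:stride,
                                                    j:j + wdth * stride:stride, :]
            if w.requires_grad:
                # dW[kh,kw,cin,cout] = sum_{n,h,w} x[n,h,w,cin] * dprod[n,h,w,kh,kw,cout]
                dw = np.tensordot(xd, dprod, axes=([0, 1, 2], [0, 1, 2]))  # (cin, kh, kw, cout)
                w._accum(dw.transpose(1, 2, 0, 3))
            if isinstance(x, Tensor) and x.requires_grad:
                dx = np.tensordot(dprod, wd, axes=([3, 4, 5], [0, 1, 3]))  # (n,h,w,cin)
                x._accum(dx)
        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def parameters(self):
        return [(n, p) for n, p in self.__dict__.items() if isinstance(p, Tensor) and p.requires_grad]

    def buffers(self):
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, w_sd: float = 0.02):
        self.W = Parameter(rng.normal(0.0, w_sd, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x):
        return x @ self.W + self.b


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, w_sd: float = 0.02):
        self.W = Parameter(rng.normal(0.0, w_sd, size=(kernel, kernel, c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x):
        return conv2d(x, self.W, self.b, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 0, output_padding: int = 0, w_sd: float = 0.02):
        self.W = Parameter(rng.normal(0.0, w_sd, size=(kernel, kernel, c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def __call__(self, x):
        return conv_transpose2d(x, self.W, self.b, stride=self.stride,
                                padding=self.padding, output_padding=self.output_padding)


class BatchNorm(Layer):
    """Batch normalisation over all axes but the last (channel) axis."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def load_buffers(self, mean, var):
        self.running_mean = np.asarray(mean, float).copy()
        self.running_var = np.asarray(var, float).copy()

    def __call__(self, x, training: bool):
        xd = x.data if isinstance(x, Tensor) else np.asarray(x, float)
        axes = tuple(range(xd.ndim - 1))
        if not training:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
            return self.gamma * xhat + self.beta
        mu = xd.mean(axes)
        var = xd.var(axes)
        m = self.momentum
        self.running_mean = m * self.running_mean + (1 - m) * mu
        self.running_var = m * self.running_var + (1 - m) * var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * inv
        if not isinstance(x, Tensor):
            return self.gamma.data * xhat + self.beta.data
        # fused op: one backward closure instead of a chain of elementwise nodes
        gamma, beta = self.gamma, self.beta
        out = make_op(gamma.data * xhat + beta.data, (x, gamma, beta))
        if out.requires_grad:
            n = xd.size // xd.shape[-1]

            def _bw():
                g = out.grad
                sum_g = g.sum(axes)
                sum_gx = (g * xhat).sum(axes)
                if beta.requires_grad:
                    beta._accum(sum_g)
                if gamma.requires_grad:
                    gamma._accum(sum_gx)
                if x.requires_grad:
                    x._accum((gamma.data * inv / n) * (n * g - sum_g - xhat * sum_gx))
            out._backward = _bw
        return out


class Adam:
    """Adaptive-moment optimiser (the GAN trains with lr 2e-4 under Adam)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / corr1
            vhat = self.v[i] / corr2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(m, dtype=p.data.dtype) for m, p in zip(state["m"], self.params)]
        self.v = [np.array(v, dtype=p.data.dtype) for v, p in zip(state["v"], self.params)]
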