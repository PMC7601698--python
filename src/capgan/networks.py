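"""Generator and discriminator assemblies.

The generator is a DCGAN-style transposed-convolution stack: a latent
vector is projected to a 4x4 seed feature map and repeatedly doubled in
spatial size (5x5 kernels, stride 2) until the target image size is
reached, with batch normalisation + ReLU on hidden layers and Tanh on the
output so pixels live in [-1, 1].

The capsule discriminator replaces the usual strided-conv stack:

1. a conventional convolution (large kernel) + batch norm + LeakyReLU to
   extract low-level features;
2. a "primary capsule" convolution whose output channels are reshaped into
   8-dimensional capsule vectors and squashed;
3. dynamic routing from the primary capsules to a single output capsule
   (real/fake is one entity); routing activations default to LeakyReLU,
   with a flag restoring squash everywhere for the classic network;
4. the L2 norm of the output capsule is the realness score.

A plain convolutional discriminator is included as the DCGAN/LSGAN
baseline for comparison runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor, no_grad
from ._layers import Dense, Conv2d, ConvTranspose2d, BatchNorm
from .capsule import squash, leaky_relu, predict_vectors, dynamic_routing, capsule_length
from ._layers import Parameter

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "Generator",
    "CapsuleDiscriminator", "ConvDiscriminator",
    "to_pixels", "from_pixels", "sample_latent",
]

_SUPPORTED_SIZES = (16, 32, 64)


def _check_image_size(s: int) -> None:
    if s < 8 or (s & (s - 1)) != 0:
        raise ValueError(f"image_size must be a power of two >= 8, got {s}")


# ---------------------------------------------------------------------------
# pixel-range conversions
# ---------------------------------------------------------------------------

def to_pixels(img, round_to_uint8: bool = True):
    """Map model-range images in [-1, 1] to file range [0, 255].

    ``y = (x + 1) * 127.5``.  With ``round_to_uint8`` the result is rounded
    half-up to 8-bit (so the midpoint 127.5 becomes 128).
    """
    x = np.asarray(T.raw(img), dtype=float)
    if x.min() < -1.0 - 1e-9 or x.max() > 1.0 + 1e-9:
        raise ValueError(f"model-range image expected in [-1, 1], got [{x.min()}, {x.max()}]")
    y = (x + 1.0) * 127.5
    if round_to_uint8:
        return np.floor(y + 0.5).clip(0, 255).astype(np.uint8)
    return y


def from_pixels(img):
    """Inverse map: file range [0, 255] to model range, ``x = y/127.5 - 1``."""
    y = np.asarray(img, dtype=float)
    if y.min() < -1e-9 or y.max() > 255.0 + 1e-9:
        raise ValueError(f"file-range image expected in [0, 255], got [{y.min()}, {y.max()}]")
    return y / 127.5 - 1.0


def sample_latent(rng: np.random.Generator, n: int, latent_dim: int, prior: str = "gaussian"):
    if prior == "gaussian":
        return rng.standard_normal((n, latent_dim))
    if prior == "uniform":
        return rng.uniform(-1.0, 1.0, size=(n, latent_dim))
    raise ValueError(f"unknown latent prior {prior!r}")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    image_size: int = 64
    latent_dim: int = 100
    base_channels: int | None = None   # channels of the 4x4 seed map; None -> size default
    kernel_size: int = 5
    prior: str = "gaussian"            # 'gaussian' or 'uniform'
    seed: int = 0

    def __post_init__(self):
        _check_image_size(self.image_size)
        if self.base_channels is None:
            # 1024 at 64x64 (halved per deconv stage), scaled down with image size
            self.base_channels = {16: 64, 32: 512}.get(self.image_size, 1024)
        if self.latent_dim < 1 or self.base_channels < 1:
            raise ValueError("latent_dim and base_channels must be positive")
        if self.prior not in ("gaussian", "uniform"):
            raise ValueError(f"unknown latent prior {self.prior!r}")

    @property
    def n_stages(self) -> int:
        return int(math.log2(self.image_size // 4))


@dataclass
class DiscriminatorConfig:
    image_size: int = 64
    conv1_kernel: int | None = None    # None -> 9 at >=32, 5 at 16
    conv1_filters: int | None = None   # None -> 64 at >=32, 32 at 16
    primary_kernel: int | None = None
    primary_stride: int = 2
    primary_groups: int | None = None  # groups of 8-D capsules; None -> 8 at >=32, 2 at 16
    capsule_dim: int = 8
    out_capsule_dim: int = 16
    routing_iters: int = 3
    leaky_slope: float = 0.2
    activation_mode: str = "leaky_relu"   # routing activation; 'squash' = classic network
    routing_w_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        _check_image_size(self.image_size)
        small = self.image_size < 32
        if self.conv1_kernel is None:
            self.conv1_kernel = 5 if small else 9
        if self.conv1_filters is None:
            self.conv1_filters = 16 if small else 64
        if self.primary_kernel is None:
            self.primary_kernel = 5 if small else 9
        if self.primary_groups is None:
            self.primary_groups = 2 if small else 8
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.activation_mode not in ("leaky_relu", "squash"):
            raise ValueError(f"unknown activation_mode {self.activation_mode!r}")

    def geometry(self) -> tuple[int, int, int]:
        """(conv1 output side, primary output side, number of primary capsules)."""
        s1 = self.image_size - self.conv1_kernel + 1
        if s1 < self.primary_kernel:
            raise ValueError(
                f"image_size {self.image_size} too small for kernels "
                f"{self.conv1_kernel}/{self.primary_kernel}"
            )
        s2 = (s1 - self.primary_kernel) // self.primary_stride + 1
        n_caps = s2 * s2 * self.primary_groups
        return s1, s2, n_caps


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _Network:
    """Common parameter bookkeeping for the three assemblies."""

    def __init__(self):
        self._layers: dict[str, object] = {}

    def _add(self, name: str, layer):
        self._layers[name] = layer
        return layer

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out = []
        for lname, layer in self._layers.items():
            for pname, p in layer.parameters():
                out.append((f"{lname}.{pname}", p))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for lname, layer in self._layers.items():
            for bname, buf in layer.buffers():
                state[f"{lname}.{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            if name not in state:
                raise ValueError(f"checkpoint is missing parameter {name!r}")
            val = np.asarray(state[name], float)
            if val.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: checkpoint {val.shape} vs model {p.data.shape}"
                )
            p.data = val.astype(p.data.dtype)
        for lname, layer in self._layers.items():
            if isinstance(layer, BatchNorm):
                layer.load_buffers(state[f"{lname}.running_mean"], state[f"{lname}.running_var"])


class Generator(_Network):
    """Latent vector -> grayscale image in [-1, 1]."""

    def __init__(self, config: GeneratorConfig | None = None):
        super().__init__()
        self.config = config or GeneratorConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.fc = self._add("fc", Dense(cfg.latent_dim, 4 * 4 * c, rng))
        self.bn0 = self._add("bn0", BatchNorm(c))
        self.stages = []
        pad = (cfg.kernel_size - 1) // 2
        opad = cfg.kernel_size % 2  # stride-2 exact doubling for odd kernels
        for i in range(cfg.n_stages):
            last = i == cfg.n_stages - 1
            c_out = 1 if last else max(c // 2, 8)
            deconv = self._add(f"deconv{i}", ConvTranspose2d(
                c, c_out, cfg.kernel_size, rng, stride=2, padding=pad, output_padding=opad))
            bn = None if last else self._add(f"bn{i + 1}", BatchNorm(c_out))
            self.stages.append((deconv, bn))
            c = c_out

    def forward(self, z, training: bool = False):
        """Return images (batch, H, W, 1); ndarray in, ndarray out (Tensor likewise)."""
        was_array = not isinstance(z, Tensor)
        if was_array and not training:
            with no_grad():
                return self.forward(Tensor(z), training=False).data
        zt = Tensor(z) if was_array else z
        if zt.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent dim mismatch: got {zt.shape[-1]}, expected {self.config.latent_dim}"
            )
        h = self.fc(zt).reshape((-1, 4, 4, self.config.base_channels))
        h = T.relu(self.bn0(h, training))
        for deconv, bn in self.stages:
            h = deconv(h)
            if bn is not None:
                h = T.relu(bn(h, training))
            else:
                h = T.tanh(h)
        return h.data if (was_array and not training) else h

    __call__ = forward


class CapsuleDiscriminator(_Network):
    """Image in [-1, 1] -> nonnegative realness score (output-capsule length)."""

    def __init__(self, config: DiscriminatorConfig | None = None):
        super().__init__()
        self.config = config or DiscriminatorConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        _, _, n_caps = cfg.geometry()
        self.n_caps = n_caps
        self.conv1 = self._add("conv1", Conv2d(1, cfg.conv1_filters, cfg.conv1_kernel, rng))
        self.bn1 = self._add("bn1", BatchNorm(cfg.conv1_filters))
        self.primary = self._add("primary", Conv2d(
            cfg.conv1_filters, cfg.primary_groups * cfg.capsule_dim,
            cfg.primary_kernel, rng, stride=cfg.primary_stride))
        # routing transform W: "initial W ... set to the random value", logits to 0
        self.routing_W = Parameter(rng.normal(
            0.0, cfg.routing_w_sd, size=(n_caps, 1, cfg.out_capsule_dim, cfg.capsule_dim)))
        self._layers["routing"] = _RoutingHolder(self.routing_W)

    def forward(self, img, training: bool = False):
        cfg = self.config
        was_array = not isinstance(img, Tensor)
        if was_array and not training:
            with no_grad():
                return self.forward(Tensor(np.asarray(img, float)), training=False).data
        x = Tensor(np.asarray(img, float)) if was_array else img
        if x.ndim != 4 or x.shape[1] != cfg.image_size or x.shape[3] != 1:
            raise ValueError(
                f"expected (batch, {cfg.image_size}, {cfg.image_size}, 1), got {x.shape}"
            )
        h = leaky_relu(self.bn1(self.conv1(x), training), cfg.leaky_slope)
        h = self.primary(h)                                      # (N, s2, s2, groups*dim)
        u = h.reshape((-1, self.n_caps, cfg.capsule_dim))
        u = squash(u)                                            # primary capsules
        u_hat = predict_vectors(u, self.routing_W)               # (N, n_caps, 1, out_dim)
        v = dynamic_routing(u_hat, r=cfg.routing_iters,
                            activation=cfg.activation_mode, slope=cfg.leaky_slope)
        score = capsule_length(v).reshape((-1,))                 # (N,)
        return score.data if (was_array and not training) else score

    __call__ = forward


class _RoutingHolder:
    """Exposes the routing transform through the layer-parameter protocol."""

    def __init__(self, W: Tensor):
        self.W = W

    def parameters(self):
        return [("W", self.W)]

    def buffers(self):
        return []


class ConvDiscriminator(_Network):
    """DCGAN/LSGAN-style strided-conv discriminator baseline."""

    def __init__(self, image_size: int = 64, base_filters: int = 64,
                 head: str = "linear", leaky_slope: float = 0.2, seed: int = 0):
        super().__init__()
        _check_image_size(image_size)
        if head not in ("linear", "sigmoid"):
            raise ValueError(f"unknown head {head!r}")
        self.image_size, self.head, self.leaky_slope, self.seed = image_size, head, leaky_slope, seed
        rng = np.random.default_rng(seed)
        self.convs = []
        c, size, f = 1, image_size, base_filters
        i = 0
        while size > 4:
            conv = self._add(f"conv{i}", Conv2d(c, f, 5, rng, stride=2, padding=2))
            bn = self._add(f"bn{i}", BatchNorm(f)) if i > 0 else None
            self.convs.append((conv, bn))
            c, f, size, i = f, f * 2, size // 2, i + 1
        self.fc = self._add("fc", Dense(4 * 4 * c, 1, rng))
        self._flat = 4 * 4 * c

    def forward(self, img, training: bool = False):
        was_array = not isinstance(img, Tensor)
        x = Tensor(np.asarray(img, float)) if was_array else img
        if x.ndim != 4 or x.shape[1] != self.image_size:
            raise ValueError(f"expected (batch, {self.image_size}, {self.image_size}, 1), got {x.shape}")
        h = x
        for conv, bn in self.convs:
            h = conv(h)
            if bn is not None:
                h = bn(h, training)
            h = leaky_relu(h, self.leaky_slope)
        score = self.fc(h.reshape((-1, self._flat))).reshape((-1,))
        if self.head == "sigmoid":
            score = T.sigmoid(score)
        return score.data if (was_array and not training) else score

    __call__ = forward
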