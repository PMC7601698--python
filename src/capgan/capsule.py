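"""Capsule-vector mathematics: squash, routing-by-agreement, margin loss.

A capsule is a group of neurons whose output is a vector: the vector's
length encodes the probability that the entity the capsule represents is
present, and its orientation encodes pose.  Capsules in successive layers
are connected by *routing by agreement*: each lower capsule ``i`` proposes
a prediction ``u_hat[i, j] = W[i, j] @ u[i]`` for every upper capsule
``j``; coupling coefficients ``c[i, j]`` (a softmax over routing logits
``b[i, j]``) decide how much of each prediction the upper capsule
receives, and the logits are increased where prediction and output agree
(dot product), iteratively.

All functions here accept either plain numpy arrays (for analysis and test
oracles) or :class:`capgan._tensor.Tensor` (so the same code is
differentiable inside the discriminator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "CapsuleBatch",
    "RoutingState",
    "MarginLossParams",
    "squash",
    "leaky_relu",
    "routing_softmax",
    "predict_vectors",
    "dynamic_routing",
    "capsule_length",
    "margin_loss",
]

_NORM_EPS = 1e-16  # below one ulp of any norm of interest; keeps sqrt(0) finite


@dataclass
class CapsuleBatch:
    """A batch of capsule vectors, shape ``(batch, n_capsules, dim)``."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"expected (batch, n_capsules, dim), got shape {v.shape}")
        if v.shape[1] < 1 or v.shape[2] < 1:
            raise ValueError("need at least one capsule of dimension >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("capsule vectors must be finite")
        self.vectors = v

    @property
    def n_capsules(self) -> int:
        return self.vectors.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[2]


@dataclass
class RoutingState:
    """Transform weights, logits and couplings for one routing pass."""

    W: np.ndarray          # (n_in, n_out, dim_out, dim_in)
    b: np.ndarray          # (..., n_in, n_out) routing logits
    c: np.ndarray          # (..., n_in, n_out) coupling coefficients
    r: int = 0             # completed iterations

    def validate(self) -> None:
        if self.r < 0:
            raise ValueError("iteration counter must be >= 0")
        if np.any(self.c < 0):
            raise ValueError("coupling coefficients must be nonnegative")
        sums = self.c.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("coupling coefficients must sum to 1 per input capsule")


@dataclass
class MarginLossParams:
    """Margins and down-weighting of the per-class hinge-squared loss."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.m_plus < 1.0 and 0.0 < self.m_minus < 1.0):
            raise ValueError("margins must lie in (0, 1)")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def _check_finite(x, what: str) -> None:
    if not np.all(np.isfinite(T.raw(x))):
        raise ValueError(f"{what} must be finite")


def squash(s, axis: int = -1):
    """Nonlinearity scaling a vector's norm into [0, 1) while keeping direction.

    ``v = (‖s‖² / (1 + ‖s‖²)) · s / ‖s‖``; the zero vector maps to itself.
    """
    _check_finite(s, "squash input")
    n2 = T.tsum(s * s, axis=axis, keepdims=True)
    return s * (n2 / (1.0 + n2)) / T.sqrt(n2 + _NORM_EPS)


def leaky_relu(x, slope: float = 0.2, mode: str = "multiplicative"):
    """Leaky rectifier: identity for x >= 0, scaled negatives otherwise.

    ``mode='multiplicative'`` uses the conventional ``slope * x`` on the
    negative branch.  ``mode='literal'`` divides by the slope instead
    (``x / slope``), which amplifies negatives; it is provided so the exact
    printed form of the activation can be exercised, but the multiplicative
    convention is the default.
    """
    if not np.isscalar(slope) or slope <= 0:
        raise ValueError("slope must be a positive scalar")
    if mode not in ("multiplicative", "literal"):
        raise ValueError(f"unknown leaky_relu mode {mode!r}")
    factor = slope if mode == "multiplicative" else 1.0 / slope
    if isinstance(x, Tensor):
        return x.leaky_relu(factor)
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, factor * x, x)


def routing_softmax(b, axis: int = -1):
    """Coupling coefficients from routing logits: softmax over output capsules."""
    arr = T.raw(b)
    if arr.size == 0:
        raise ValueError("cannot normalise an empty logit row")
    _check_finite(b, "routing logits")
    m = arr.max(axis=axis, keepdims=True)  # constant shift for stability
    e = T.exp(b - m)
    return e / T.tsum(e, axis=axis, keepdims=True)


def predict_vectors(u, W):
    """Prediction vectors ``u_hat[..., i, j, :] = W[i, j] @ u[..., i, :]``.

    ``u``: (batch, n_in, dim_in) array/Tensor or a :class:`CapsuleBatch`;
    ``W``: (n_in, n_out, dim_out, dim_in).
    """
    if isinstance(u, CapsuleBatch):
        u = u.vectors
    Wd, ud = T.raw(W), T.raw(u)
    if Wd.ndim != 4:
        raise ValueError(f"W must be (n_in, n_out, dim_out, dim_in), got {Wd.shape}")
    if ud.shape[-1] != Wd.shape[-1] or ud.shape[-2] != Wd.shape[0]:
        raise ValueError(
            f"shape mismatch: u {ud.shape} vs W {Wd.shape} "
            "(need u[..., n_in, dim_in])"
        )
    out_data = np.einsum("ijod,...id->...ijo", Wd, ud)
    if not (isinstance(u, Tensor) or isinstance(W, Tensor)):
        return out_data
    out = T.make_op(out_data, (u, W))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if isinstance(u, Tensor) and u.requires_grad:
                u._accum(np.einsum("...ijo,ijod->...id", g, Wd))
            if isinstance(W, Tensor) and W.requires_grad:
                gb = g.reshape(-1, *g.shape[-3:])
                ub = ud.reshape(-1, *ud.shape[-2:])
                W._accum(np.einsum("bijo,bid->ijod", gb, ub))
        out._backward = _bw
    return out


def _expand(x, axis: int):
    shape = list(T.raw(x).shape)
    shape.insert(axis % (len(shape) + 1), 1)
    return T.reshape(x, tuple(shape))


def dynamic_routing(u_hat, r: int = 3, activation: str = "squash",
                    slope: float = 0.2, return_state: bool = False):
    """Iterative routing-by-agreement.

    ``u_hat``: prediction vectors, shape ``(..., n_in, n_out, dim_out)``.
    Repeats ``r`` times: couplings ``c = softmax(b)`` over output capsules,
    weighted sum ``s_j = Σ_i c_ij · u_hat_ij``, output ``v_j = act(s_j)``,
    agreement update ``b_ij += u_hat_ij · v_j`` (skipped after the final
    iteration).  Logits start at zero.  ``activation`` is ``'squash'`` for
    the classic capsule network or ``'leaky_relu'`` for the
    artifact-reducing variant used in this model's discriminator.

    Returns the output capsules ``(..., n_out, dim_out)``; with
    ``return_state=True`` also a :class:`RoutingState` snapshot (numpy).
    """
    if r < 1:
        raise ValueError("routing requires at least one iteration")
    if activation == "squash":
        act = lambda s: squash(s, axis=-1)
    elif activation == "leaky_relu":
        act = lambda s: leaky_relu(s, slope=slope)
    else:
        raise ValueError(f"unknown routing activation {activation!r}")

    shape = T.raw(u_hat).shape  # (..., n_in, n_out, d)
    b = np.zeros(shape[:-1])
    is_tensor = isinstance(u_hat, Tensor)
    if is_tensor:
        b = Tensor(b)
    v = None
    for it in range(r):
        c = routing_softmax(b, axis=-1)
        s = T.tsum(_expand(c, -1) * u_hat, axis=-3)      # (..., n_out, d)
        v = act(s)
        if it < r - 1:
            b = b + T.tsum(u_hat * _expand(v, -3), axis=-1)
    if return_state:
        state = RoutingState(W=None, b=T.raw(b).copy(), c=T.raw(routing_softmax(b)).copy(), r=r)
        return v, state
    return v


def capsule_length(v, axis: int = -1):
    """Euclidean norm of capsule vectors along ``axis``."""
    _check_finite(v, "capsule vectors")
    return T.sqrt(T.tsum(v * v, axis=axis, keepdims=False) + _NORM_EPS)


def margin_loss(lengths, targets, params: MarginLossParams | None = None):
    """Per-class hinge-squared loss on capsule lengths.

    ``L_k = T_k · max(0, m⁺ − ‖v_k‖)² + λ (1 − T_k) · max(0, ‖v_k‖ − m⁻)²``
    summed over classes (last axis) and averaged over any leading batch axes.
    """
    params = params or MarginLossParams()
    lengths_d = T.raw(lengths)
    if np.any(lengths_d < 0):
        raise ValueError("capsule lengths must be nonnegative")
    t = np.asarray(T.raw(targets), dtype=float)
    pos = t * T.relu(params.m_plus - lengths) ** 2
    neg = params.lam * (1.0 - t) * T.relu(lengths - params.m_minus) ** 2
    total = T.tsum(pos + neg, axis=-1)
    return T.tmean(total) if T.raw(total).ndim > 0 else total
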