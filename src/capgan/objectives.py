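"""Adversarial objectives and their analytic cross-checks.

The model is trained with least-squares losses: the discriminator is pushed
to score real images at 1 and generated images at 0,

    V(D) = 1/2 E[(D(x) - 1)^2] + 1/2 E[D(G(z))^2],

while the generator is pushed to make its samples score 1,

    V(G) = 1/2 E[(D(G(z)) - 1)^2].

The original minimax value E[log D(x)] + E[log(1 - D(G(z)))] is kept as a
cross-entropy baseline.  Its fixed-point theory — the optimal discriminator
p_data/(p_data + p_g) and the generator cost -log 4 + 2·JSD(p_data ‖ p_g)
at that optimum — is implemented for use as an exact test oracle on
discrete toy densities.
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T

__all__ = [
    "gan_value", "ls_discriminator_loss", "ls_generator_loss",
    "optimal_discriminator", "generator_cost_from_jsd", "jsd_discrete",
]

_LOG_EPS = 1e-7


def gan_value(d_real, d_fake, eps: float = _LOG_EPS):
    """Original minimax value: mean log D(x) + mean log(1 - D(G(z))).

    Scores are probabilities; values at exactly 0 or 1 are clamped to
    [eps, 1 - eps] so the logs stay finite.
    """
    dr = T.clip(d_real, eps, 1.0 - eps)
    df = T.clip(d_fake, eps, 1.0 - eps)
    return T.tmean(T.log(dr)) + T.tmean(T.log(1.0 - df))


def ls_discriminator_loss(d_real, d_fake):
    """Least-squares discriminator loss: ½E[(D(x)−1)²] + ½E[D(G(z))²]."""
    _require_finite(d_real, d_fake)
    return 0.5 * T.tmean((d_real - 1.0) ** 2) + 0.5 * T.tmean(d_fake ** 2)


def ls_generator_loss(d_fake):
    """Least-squares generator loss: ½E[(D(G(z))−1)²]."""
    _require_finite(d_fake)
    return 0.5 * T.tmean((d_fake - 1.0) ** 2)


def _require_finite(*scores) -> None:
    for s in scores:
        if not np.all(np.isfinite(T.raw(s))):
            raise ValueError("discriminator scores must be finite")


def optimal_discriminator(p_data, p_g):
    """Fixed-generator optimum D*(x) = p_data(x) / (p_data(x) + p_g(x)).

    Accepts scalars or arrays evaluated pointwise on a common support.
    """
    pd = np.asarray(p_data, dtype=float)
    pg = np.asarray(p_g, dtype=float)
    if np.any(pd < 0) or np.any(pg < 0):
        raise ValueError("densities must be nonnegative")
    tot = pd + pg
    if np.any(tot == 0):
        raise ValueError("both densities vanish somewhere on the support")
    return pd / tot


def generator_cost_from_jsd(jsd: float) -> float:
    """Generator cost at the optimal discriminator: C(G) = −ln 4 + 2·JSD."""
    if jsd < 0:
        raise ValueError("Jensen-Shannon divergence cannot be negative")
    return -np.log(4.0) + 2.0 * float(jsd)


def jsd_discrete(p, q) -> float:
    """Jensen-Shannon divergence (nats) between two probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    for v in (p, q):
        if np.any(v < 0) or not np.isclose(v.sum(), 1.0):
            raise ValueError("inputs must be probability vectors")
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
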