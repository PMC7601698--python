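"""Independent brute-force references used by the tests.

Everything here is written with explicit Python loops and textbook
formulas, deliberately sharing no code with the package implementation.
"""

import numpy as np


def squash_reference(s):
    n = np.linalg.norm(s)
    if n == 0:
        return np.zeros_like(np.asarray(s, float))
    return (n ** 2 / (1.0 + n ** 2)) * (np.asarray(s, float) / n)


def leaky_reference(s, slope):
    s = np.asarray(s, float)
    return np.where(s < 0, slope * s, s)


def routing_reference(u_hat, r, activation="squash", slope=0.2):
    """Step-by-step routing-by-agreement on one sample.

    u_hat: (n_in, n_out, d).  Returns (n_out, d).
    """
    n_in, n_out, d = u_hat.shape
    act = squash_reference if activation == "squash" else (lambda s: leaky_reference(s, slope))
    b = np.zeros((n_in, n_out))
    v = np.zeros((n_out, d))
    for it in range(r):
        c = np.zeros((n_in, n_out))
        for i in range(n_in):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        s = np.zeros((n_out, d))
        for j in range(n_out):
            for i in range(n_in):
                s[j] += c[i, j] * u_hat[i, j]
        for j in range(n_out):
            v[j] = act(s[j])
        if it < r - 1:
            for i in range(n_in):
                for j in range(n_out):
                    b[i, j] += float(u_hat[i, j] @ v[j])
    return v


def kl_reference(p, q):
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * np.log(pi / qi)
    return total
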