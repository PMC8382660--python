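"""Seeded synthetic system generators for property tests and benchmarks.

``random_stable_lti`` draws generic stable LTI triples for exercising the
classical balancing path.  ``random_p_dominant_nonlinear`` constructs
nonlinear systems that are p-dominant *by construction* — a block-split
linear part with a known spectral gap about the rate line plus a
bounded-derivative nonlinearity — together with their ground-truth
certificate, so the certification and reduction pipelines can be checked
against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dominance import RateFunction
from .systems import LinearSystem, NonlinearSystem

__all__ = ["FixtureSpec", "random_stable_lti", "random_p_dominant_nonlinear"]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "stable_lti"           # or "p_dominant_nonlinear"
    n: int = 4
    m: int = 1
    l: int = 1
    p: int = 0
    seed: int = 0
    # spectral shaping
    re_range: tuple[float, float] = (-3.0, -0.3)  # stable_lti real parts
    rate: float = 1.0                  # constant rate lambda* (p-dominant kind)
    gap: float = 1.0                   # spectral gap about -rate
    lipschitz: float = 0.1             # derivative bound of the nonlinearity

    def __post_init__(self):
        if self.n < 1 or self.m < 1 or self.l < 1:
            raise ValueError("n, m, l must be >= 1")
        if not 0 <= self.p <= self.n:
            raise ValueError("p must lie in [0, n]")


def _random_spectrum_matrix(rng, n, re_lo, re_hi) -> np.ndarray:
    """Real matrix with eigenvalue real parts drawn in [re_lo, re_hi]:
    random 1x1/2x2 real-normal blocks conjugated by a well-conditioned
    similarity."""
    blocks = []
    k = 0
    while k < n:
        if n - k >= 2 and rng.random() < 0.5:
            a = rng.uniform(re_lo, re_hi)
            b = rng.uniform(0.2, 2.0)
            blocks.append(np.array([[a, b], [-b, a]]))
            k += 2
        else:
            blocks.append(np.array([[rng.uniform(re_lo, re_hi)]]))
            k += 1
    D = np.zeros((n, n))
    k = 0
    for blk in blocks:
        s = blk.shape[0]
        D[k:k + s, k:k + s] = blk
        k += s
    V = rng.standard_normal((n, n)) * 0.3 + np.eye(n)
    return V @ D @ np.linalg.inv(V)


def random_stable_lti(spec: FixtureSpec) -> LinearSystem:
    """Seed-deterministic stable LTI triple with eigenvalue real parts in
    ``spec.re_range``; generically minimal."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.re_range
    if hi >= 0:
        raise ValueError("re_range must be strictly negative for stability")
    A = _random_spectrum_matrix(rng, spec.n, lo, hi)
    B = rng.standard_normal((spec.n, spec.m))
    C = rng.standard_normal((spec.l, spec.n))
    return LinearSystem(A=A, B=B, C=C)


def random_p_dominant_nonlinear(spec: FixtureSpec):
    """Nonlinear system that is p-dominant by construction.

    The linear part is block diagonal: a p-block whose symmetric part is
    (-rate + gap/2) I (dominant: real parts above -rate) and an
    (n-p)-block with symmetric part (-rate - gap/2) I (transient), each
    plus a random skew term.  The nonlinearity g(x) = L W tanh(V x) has
    derivative norm at most ``lipschitz``; the construction requires
    lipschitz < gap/2 so that P* = diag(-I_p, I_{n-p}) remains a valid
    certificate with rate lambda* and some eps > 0.

    Returns (system, rate_fn, P_star).
    """
    if spec.lipschitz >= spec.gap / 2:
        raise ValueError(
            f"Lipschitz bound {spec.lipschitz} must be below half the "
            f"spectral gap {spec.gap / 2}")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p
    lam = spec.rate

    def skew(k):
        S = rng.standard_normal((k, k))
        return 0.5 * (S - S.T)

    A = np.zeros((n, n))
    if p:
        A[:p, :p] = (-lam + spec.gap / 2) * np.eye(p) + skew(p)
    if n - p:
        A[p:, p:] = (-lam - spec.gap / 2) * np.eye(n - p) + skew(n - p)

    W = rng.standard_normal((n, n))
    V = rng.standard_normal((n, n))
    scale = spec.lipschitz / (np.linalg.norm(W, 2) * np.linalg.norm(V, 2))
    W = W * scale

    def f(x):
        return A @ x + W @ np.tanh(V @ x)

    def jac(x):
        sech2 = 1.0 / np.cosh(np.clip(V @ x, -30, 30)) ** 2
        return A + (W * sech2) @ V

    B = rng.standard_normal((n, spec.m))
    C = rng.standard_normal((spec.l, n))
    system = NonlinearSystem(f=f, jacobian=jac, B=B, C=C)
    P_star = np.diag(np.concatenate([-np.ones(p), np.ones(n - p)]))
    return system, RateFunction.constant(lam), P_star
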