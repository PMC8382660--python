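"""p-dominance certification from sampled linearizations.

A nonlinear system is p-dominant with rate lambda(x) >= 0 if its
variational dynamics contract a fixed quadratic form V(dx) = dx' P dx of
inertia (p, 0, n-p):

    df(x)' P + P df(x) + 2 lambda(x) P + eps I  <=  0   for x in S.

The p "dominant" modes (negative directions of P) govern the asymptotic
behavior; for p <= 2 the admissible attractors are severely constrained
(unique equilibrium, possibly non-unique equilibria, or a simple
attractor including limit cycles).  The inequality is imposed on a finite
sample of states along a trajectory — the standard gridding relaxation
for state-dependent LMIs — and the inertia of the solution is classified
a posteriori.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np

from .lmi import (LMIBlocks, LMIInfeasibleError, make_blocks, solve_margin,
                  sym_basis, vec_to_mat)
from .systems import SteadyStateSamples

__all__ = [
    "RateFunction",
    "DominanceCertificate",
    "CertificateError",
    "InertiaMismatchError",
    "inertia",
    "spectral_split",
    "dominance_lmi",
    "select_rate_heuristic",
    "classify_attractor",
    "differential_lyapunov_value",
]


class CertificateError(RuntimeError):
    """No dominance certificate could be produced."""


class InertiaMismatchError(CertificateError):
    """The LMI was feasible but the solution has the wrong inertia."""

    def __init__(self, requested: tuple[int, int, int],
                 achieved: tuple[int, int, int]):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"certificate inertia {achieved} differs from requested {requested}")


@dataclass(frozen=True)
class RateFunction:
    """Affine dominance rate lambda(x) = c0 + c'x (constant when c = 0).

    The rate shifts the spectrum of the linearization: dominance splits
    eigenvalues about the moving line Re(s) = -lambda(x).
    """

    c0: float = 0.0
    c: np.ndarray | None = None

    def __post_init__(self):
        if self.c is not None:
            object.__setattr__(self, "c", np.asarray(self.c, dtype=float))

    @property
    def kind(self) -> str:
        return "constant" if (self.c is None or not np.any(self.c)) else "affine"

    def __call__(self, x: np.ndarray) -> float:
        v = float(self.c0)
        if self.c is not None:
            v += float(np.dot(self.c, x))
        if not np.isfinite(v):
            raise ValueError("rate evaluated to a non-finite value")
        return v

    @staticmethod
    def constant(value: float) -> "RateFunction":
        return RateFunction(c0=float(value))


def goldbeter_rate(params=None) -> RateFunction:
    """Default dominance rate for the Goldbeter example,
    lambda(x) = 0.4 - k_1 x_4 + k_2 x_5.

    On the limit cycle this equals 0.4 minus the net nuclear-import flux
    of PER (which is the time derivative of x5 and has zero mean over a
    period), so the rate stays in roughly [0.29, 0.59] > 0 there and
    separates the two slow oscillation modes from the three fast
    phosphorylation/degradation modes.
    """
    from .systems import GoldbeterParameters
    p = params or GoldbeterParameters()
    c = np.zeros(5)
    c[3] = -p.k_1
    c[4] = p.k_2
    return RateFunction(c0=0.4, c=c)


@dataclass(frozen=True)
class DominanceCertificate:
    P: np.ndarray
    p: int
    epsilon: float
    rate: RateFunction
    inertia: tuple[int, int, int]
    margin: float


def inertia(M: np.ndarray, zero_tol: float | None = None) -> tuple[int, int, int]:
    """Inertia (n_minus, n_zero, n_plus) of a symmetric matrix.

    zero_tol defaults to 1e-6 * ||M||_2; eigenvalues within +-zero_tol
    count as zero.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (M + M.T))
    if zero_tol is None:
        zero_tol = 1e-6 * max(np.abs(w).max(), 1e-300)
    n_minus = int(np.sum(w < -zero_tol))
    n_plus = int(np.sum(w > zero_tol))
    return (n_minus, len(w) - n_minus - n_plus, n_plus)


def spectral_split(samples: SteadyStateSamples,
                   gap_tol: float = 1e-9) -> dict:
    """Per-sample counts of Jacobian eigenvalues above/below -lambda(x).

    Returns a dict with 'above' and 'below' integer arrays (length N) and
    'boundary_flags' marking samples where some eigenvalue's real part
    lies within gap_tol of -lambda(x); also 'min_gap', the smallest
    distance from any eigenvalue real part to the splitting line.
    """
    if samples.N < 1:
        raise ValueError("empty sample set")
    above = np.zeros(samples.N, dtype=int)
    below = np.zeros(samples.N, dtype=int)
    flags = np.zeros(samples.N, dtype=bool)
    min_gap = np.inf
    for k in range(samples.N):
        re = np.linalg.eigvals(samples.jacobians[k]).real
        thr = -samples.rate_values[k]
        above[k] = int(np.sum(re > thr + gap_tol))
        below[k] = int(np.sum(re < thr - gap_tol))
        gap = np.abs(re - thr).min()
        flags[k] = gap <= gap_tol
        min_gap = min(min_gap, gap)
    return {"above": above, "below": below, "boundary_flags": flags,
            "min_gap": float(min_gap)}


def dominance_lmi(samples: SteadyStateSamples,
                  p: int,
                  epsilon: float = 1e-3,
                  rate: RateFunction | None = None,
                  kappa: float = 100.0) -> DominanceCertificate:
    """Solve the sampled dominance LMI and certify inertia (p, 0, n-p).

    The margin-maximizing solution within the norm box ||P|| <= kappa is
    returned (the LMI family fixes P only up to scale, so the box sets the
    scale and the margin objective centers the certificate).  Inertia is
    classified a posteriori; a mismatch raises
    :class:`InertiaMismatchError` carrying the achieved inertia.

    Rate values are taken from ``samples.rate_values`` (``rate`` is kept
    for the certificate record only).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    n = samples.n
    if not 0 <= p <= n:
        raise ValueError(f"p must be in [0, {n}]")
    lams = samples.rate_values
    if np.any(lams < 0):
        neg = np.flatnonzero(lams < 0)
        warnings.warn(
            f"rate is negative at {len(neg)} of {samples.N} samples "
            f"(first at t = {samples.sample_times[neg[0]]:.3g}); a dominance "
            "rate should be nonnegative on the region of interest",
            RuntimeWarning, stacklevel=2)
    basis = sym_basis(n)
    lmis = make_blocks(basis, samples.jacobians, lams,
                       epsilon * np.eye(n), side="obs")
    try:
        x, margin = solve_margin(lmis, basis, kappa=kappa)
    except LMIInfeasibleError as exc:
        raise CertificateError(
            f"no dominance certificate at this rate/epsilon: {exc}") from exc
    P = vec_to_mat(x, basis)
    ine = inertia(P)
    if ine != (p, 0, n - p):
        raise InertiaMismatchError((p, 0, n - p), ine)
    return DominanceCertificate(P=P, p=p, epsilon=epsilon,
                                rate=rate or RateFunction.constant(0.0),
                                inertia=ine, margin=float(margin))


def select_rate_heuristic(samples: SteadyStateSamples,
                          p_candidates: Sequence[int],
                          rate_family: Sequence[RateFunction],
                          gap_tol: float = 1e-9) -> list[tuple[int, RateFunction, float]]:
    """Grid-search rate selection: admissible (p, lambda) pairs ranked by
    worst-case spectral gap.

    A candidate rate is admissible for p if every (non-boundary) sample
    splits the Jacobian spectrum into exactly p eigenvalues above and
    n - p below -lambda(x).  Candidates are ranked by the minimum over
    samples of the distance from the splitting line to the nearest
    eigenvalue real part (larger is better).  This is a pragmatic
    reconstruction of a rate-selection step that is usually done by
    inspection of the sampled spectra.
    """
    if len(rate_family) == 0:
        raise ValueError("empty rate candidate set")
    n = samples.n
    ranked: list[tuple[int, RateFunction, float]] = []
    for rf in rate_family:
        lams = np.array([rf(x) for x in samples.sample_states])
        resampled = SteadyStateSamples(
            sample_times=samples.sample_times,
            sample_states=samples.sample_states,
            jacobians=samples.jacobians,
            rate_values=lams)
        split = spectral_split(resampled, gap_tol=gap_tol)
        ok = ~split["boundary_flags"]
        if not np.any(ok):
            continue
        ups = np.unique(split["above"][ok])
        downs = np.unique(split["below"][ok])
        if len(ups) != 1 or len(downs) != 1:
            continue
        p = int(ups[0])
        if p + int(downs[0]) != n or p not in p_candidates:
            continue
        ranked.append((p, rf, split["min_gap"]))
    ranked.sort(key=lambda t: -t[2])
    return ranked


def classify_attractor(p: int) -> str:
    """Admissible asymptotic behavior of a p-dominant system for constant
    inputs (bounded solutions only)."""
    if p == 0:
        return "unique equilibrium"
    if p == 1:
        return "(possibly non-unique) equilibrium point"
    if p == 2:
        return ("simple attractor (equilibrium, arcs of equilibria, "
                "or limit cycle)")
    return "no classification (attractor theorem covers p <= 2)"


def differential_lyapunov_value(P: np.ndarray, dx: np.ndarray) -> float:
    """Quadratic form V(dx) = dx' P dx; V >= 0 is the cone of transient
    directions, V <= 0 the cone of dominant ones."""
    P = np.asarray(P, dtype=float)
    dx = np.asarray(dx, dtype=float)
    if P.shape[0] != P.shape[1] or P.shape[0] != dx.shape[0]:
        raise ValueError("dimension mismatch")
    return float(dx @ P @ dx)
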