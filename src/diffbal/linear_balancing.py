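"""Classical balanced truncation for stable LTI systems.

Gramians from the Lyapunov equations, principal-axis balancing by the
square-root method, truncation, and the standard L2 error bound
2 * (sigma_{r+1} + ... + sigma_n).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg as sla

from .systems import LinearSystem

__all__ = [
    "lyapunov_gramians",
    "balance_spd",
    "truncate_linear",
    "l2_error_bound",
]


def lyapunov_gramians(sys: LinearSystem) -> tuple[np.ndarray, np.ndarray]:
    """Reachability and observability gramians of a stable LTI system.

    Solves A P + P A' + B B' = 0 and A' Q + Q A + C' C = 0.  Raises on
    unstable A; warns when either gramian is numerically near singular
    (non-minimal realization).
    """
    if not sys.is_stable():
        raise ValueError("stability required for the Lyapunov-equation gramians")
    P = sla.solve_continuous_lyapunov(sys.A, -sys.B @ sys.B.T)
    Q = sla.solve_continuous_lyapunov(sys.A.T, -sys.C.T @ sys.C)
    P = 0.5 * (P + P.T)
    Q = 0.5 * (Q + Q.T)
    for name, M in (("P", P), ("Q", Q)):
        if np.linalg.cond(M) > 1e12:
            warnings.warn(f"gramian {name} is near singular "
                          "(realization may be non-minimal)", RuntimeWarning,
                          stacklevel=2)
    return P, Q


def balance_spd(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis balancing of an SPD gramian pair (square-root method).

    Returns (T, sigma) with T^{-1} P T^{-T} = T' Q T = diag(sigma) and
    sigma sorted descending.  Factors P = L L' (Cholesky), takes the SVD
    of R' L where Q = R R', and assembles T = L V S^{-1/2}.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    try:
        L = np.linalg.cholesky(0.5 * (P + P.T))
        R = np.linalg.cholesky(0.5 * (Q + Q.T))
    except np.linalg.LinAlgError as exc:
        raise ValueError("balance_spd requires symmetric positive definite "
                         "gramians") from exc
    U, s, Vt = np.linalg.svd(R.T @ L)
    T = L @ Vt.T @ np.diag(s ** -0.5)
    return T, s


def truncate_linear(sys: LinearSystem, T: np.ndarray, sigma: np.ndarray,
                    r: int) -> LinearSystem:
    """Balanced truncation to order r: keep the leading r balanced states."""
    n = sys.n
    if not 1 <= r <= n:
        raise ValueError(f"reduction order r must satisfy 1 <= r <= {n}")
    Ti = np.linalg.inv(T)
    Ab = Ti @ sys.A @ T
    Bb = Ti @ sys.B
    Cb = sys.C @ T
    return LinearSystem(A=Ab[:r, :r], B=Bb[:r, :], C=Cb[:, :r])


def l2_error_bound(sigma: np.ndarray, r: int) -> float:
    """A priori L2-gain bound on the truncation error:
    ||y - yhat||_2 <= 2 * sum_{j>r} sigma_j * ||u||_2."""
    sigma = np.asarray(sigma, dtype=float)
    if r > len(sigma):
        raise ValueError("r exceeds the number of Hankel singular values")
    return float(2.0 * np.sum(sigma[r:]))
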