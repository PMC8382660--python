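"""Frequency-domain diagnostics for families of sampled linearizations.

Along a sampled trajectory each Jacobian defines a transfer function
G(s, x_k) = C (sI - df(x_k))^{-1} B; comparing the families of the full
and reduced models gives the error family E = G - Ghat whose magnitude
quantifies reduction quality.

For dominant systems the natural evaluation contour is the *shifted*
D-contour Re(s) = -lambda(x_k): the dominance splitting guarantees no
eigenvalue of df(x_k) lies near that line, whereas the plain imaginary
axis may pass arbitrarily close to the dominant modes of an oscillator
(pointwise eigenvalues of a limit-cycle Jacobian cross Re = 0), making
the unshifted response blow up at the resonance.  Pass per-sample shifts
to evaluate on the shifted contour; shift=0 recovers the classical axis.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "TransferFamily",
    "transfer_family",
    "error_family",
    "nyquist_curve",
    "bode_magnitude",
    "default_frequency_grid",
]


def default_frequency_grid(wmin: float = 1e-3, wmax: float = 1e3,
                           n: int = 400) -> np.ndarray:
    """Log-spaced positive frequency grid (rad/h).  The default brackets a
    ~24 h oscillation (w ~ 0.26 rad/h) by three decades on each side."""
    return np.logspace(np.log10(wmin), np.log10(wmax), n)


@dataclass(frozen=True)
class TransferFamily:
    """Per-sample frequency responses on a common frequency grid.

    values[k, w] is the l-by-m response of sample k at s = -shift_k + i w
    (for real-coefficient systems the response at -i w is the conjugate).
    """

    omega: np.ndarray            # (nw,) positive frequencies
    shifts: np.ndarray           # (N,) per-sample real contour shifts
    values: np.ndarray           # (N, nw, l, m) complex

    @property
    def N(self) -> int:
        return self.values.shape[0]

    def magnitude(self) -> np.ndarray:
        """Largest singular value per sample and frequency, shape (N, nw)."""
        if self.values.shape[2] == 1 and self.values.shape[3] == 1:
            return np.abs(self.values[:, :, 0, 0])
        return np.linalg.svd(self.values, compute_uv=False)[..., 0]

    def sup_magnitude(self) -> float:
        return float(self.magnitude().max())


def transfer_family(jacobians: np.ndarray,
                    B: np.ndarray,
                    C: np.ndarray,
                    omega: np.ndarray,
                    shifts: np.ndarray | float = 0.0) -> TransferFamily:
    """Evaluate G(s, x_k) = C (sI - J_k)^{-1} B on s = -shift_k + i omega.

    Uses batched linear solves (no explicit inverse).  Grid points that
    collide with an eigenvalue of some J_k are dropped with a warning.
    """
    jacobians = np.asarray(jacobians, dtype=float)
    if jacobians.ndim == 2:
        jacobians = jacobians[None]
    N, n, _ = jacobians.shape
    B = np.atleast_2d(np.asarray(B, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    omega = np.asarray(omega, dtype=float)
    shifts = np.broadcast_to(np.asarray(shifts, dtype=float), (N,))

    # drop grid points too close to a shifted eigenvalue
    keep = np.ones(len(omega), dtype=bool)
    for k in range(N):
        ev = np.linalg.eigvals(jacobians[k]) + shifts[k]
        for e in ev:
            d = np.abs(1j * omega - e)
            keep &= d > 1e-9 * max(1.0, np.abs(e))
    if not np.all(keep):
        warnings.warn(f"dropped {int(np.sum(~keep))} frequency grid points "
                      "colliding with linearization poles", RuntimeWarning,
                      stacklevel=2)
        omega = omega[keep]
    nw = len(omega)

    vals = np.empty((N, nw, C.shape[0], B.shape[1]), dtype=complex)
    I = np.eye(n)
    for k in range(N):
        s = -shifts[k] + 1j * omega
        M = s[:, None, None] * I - jacobians[k]
        X = np.linalg.solve(M, np.broadcast_to(B, (nw, n, B.shape[1])))
        vals[k] = C @ X
    return TransferFamily(omega=omega, shifts=np.array(shifts), values=vals)


def error_family(full: TransferFamily, reduced: TransferFamily) -> TransferFamily:
    """Pointwise difference E = G - Ghat of two families on matching grids."""
    if full.values.shape[:2] != reduced.values.shape[:2]:
        raise ValueError(
            f"family shapes differ: {full.values.shape} vs {reduced.values.shape}")
    if not np.allclose(full.omega, reduced.omega):
        raise ValueError("frequency grids differ")
    return TransferFamily(omega=full.omega, shifts=full.shifts,
                          values=full.values - reduced.values)


def nyquist_curve(jacobian: np.ndarray,
                  B: np.ndarray,
                  C: np.ndarray,
                  omega: np.ndarray | None = None,
                  shift: float = 0.0) -> np.ndarray:
    """Closed SISO Nyquist path along the (shifted) D-contour.

    Traverses s = -shift + i w for w from -wmax to +wmax on a symmetric
    log grid; the arc at infinity maps to the origin for strictly proper
    systems, closing the path.  Raises if a pole lies on the contour.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if B.shape[1] != 1 or C.shape[0] != 1:
        raise ValueError("nyquist_curve is SISO; evaluate channels separately")
    if omega is None:
        omega = default_frequency_grid()
    ev = np.linalg.eigvals(np.asarray(jacobian, dtype=float)) + shift
    dmin = np.min(np.abs(ev.real))
    if dmin < 1e-9:
        raise ValueError(
            "pole on the contour; indent the contour or increase the shift "
            f"(closest pole real part after shift: {dmin:.3e})")
    fam_pos = transfer_family(jacobian, B, C, omega, shifts=shift)
    gpos = fam_pos.values[0, :, 0, 0]
    # conjugate symmetry holds about the shifted axis for real systems
    path = np.concatenate([np.conj(gpos[::-1]), gpos, [0.0 + 0.0j]])
    return path


def bode_magnitude(family: TransferFamily) -> dict:
    """Magnitude table of a family: absolute units and dB, per sample."""
    mag = family.magnitude()
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag)
    return {"omega": family.omega, "magnitude": mag, "magnitude_db": db,
            "sup": float(mag.max())}
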