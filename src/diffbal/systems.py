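"""State-space systems, the Goldbeter circadian oscillator, simulation and sampling.

Linear systems are plain (A, B, C) triples; nonlinear systems are
input-affine, ``xdot = f(x) + B u``, ``y = C x``, carrying an analytic
Jacobian of the drift.  The Goldbeter model of *per*-gene expression in
Drosophila (5 states: per mRNA M, the three phosphorylation states of PER
protein P0, P1, P2 and nuclear PER P_N) is built in with its standard
parameter set; a stable ~24 h limit cycle emerges from the Hill-type
transcriptional repression by nuclear PER.

Steady-state sampling evaluates states, Jacobians and the dominance rate
on an equally spaced time grid inside a window where the solution has
settled onto its attractor; the sampled Jacobians feed the LMI machinery
in :mod:`diffbal.dominance` and :mod:`diffbal.differential_balancing`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LinearSystem",
    "NonlinearSystem",
    "GoldbeterParameters",
    "Trajectory",
    "SteadyStateSamples",
    "goldbeter_vector_field",
    "goldbeter_jacobian",
    "goldbeter_system",
    "simulate",
    "sample_steady_state",
]


@dataclass(frozen=True)
class LinearSystem:
    """LTI system ``xdot = A x + B u``, ``y = C x``."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got {A.shape}")
        if B.shape[0] != A.shape[0]:
            raise ValueError(f"B has {B.shape[0]} rows, expected {A.shape[0]}")
        if C.shape[1] != A.shape[0]:
            raise ValueError(f"C has {C.shape[1]} columns, expected {A.shape[0]}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @property
    def l(self) -> int:
        return self.C.shape[0]

    def is_stable(self, tol: float = 0.0) -> bool:
        return bool(np.max(np.linalg.eigvals(self.A).real) < -tol)


@dataclass(frozen=True)
class NonlinearSystem:
    """Input-affine nonlinear system ``xdot = f(x) + B u``, ``y = C x``.

    ``jacobian(x)`` must return the n-by-n derivative of ``f`` at ``x``;
    it is what the variational (linearized) dynamics and every LMI in the
    package are built from, so it should be analytic, not numeric.
    """

    f: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        if B.shape[0] != C.shape[1]:
            raise ValueError("B rows and C columns must both equal the state dimension")

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @property
    def l(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class GoldbeterParameters:
    """Kinetic parameters of the Goldbeter per-gene oscillator.

    Units: v_s, v_m, v_d, V_1..V_4 in uM/h; k_s, k_1, k_2 in 1/h;
    K_d, K_I, K_m, K_1..K_4 in uM; hill_n dimensionless.  Defaults are the
    standard published set for which the model has a unique unstable
    equilibrium surrounded by a stable limit cycle of ~23.7 h period.
    """

    v_s: float = 0.76
    v_m: float = 0.65
    v_d: float = 0.95
    k_s: float = 0.38
    k_1: float = 1.9
    k_2: float = 1.3
    V_1: float = 3.2
    V_2: float = 1.58
    V_3: float = 5.0
    V_4: float = 2.5
    K_d: float = 0.2
    K_I: float = 1.0
    K_m: float = 0.5
    K_1: float = 2.0
    K_2: float = 2.0
    K_3: float = 2.0
    K_4: float = 2.0
    hill_n: int = 4

    def __post_init__(self):
        for name in ("v_s", "v_m", "v_d", "k_s", "k_1", "k_2", "V_1", "V_2",
                     "V_3", "V_4", "K_d", "K_I", "K_m", "K_1", "K_2", "K_3", "K_4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be a positive integer")


def goldbeter_vector_field(x: np.ndarray, u: float = 0.0,
                           params: GoldbeterParameters | None = None) -> np.ndarray:
    """Drift of the Goldbeter model, with the exogenous input entering the
    mRNA balance only.

    State ordering is ``x = (M, P0, P1, P2, P_N)`` in uM; returns
    concentration rates in uM/h.
    """
    p = params or GoldbeterParameters()
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError(f"state must be a 5-vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state")
    if np.any(x < 0):
        warnings.warn("negative state component (solver transient?); the rate "
                      "law is evaluated as-is", RuntimeWarning, stacklevel=2)
    M, P0, P1, P2, PN = x
    n = p.hill_n
    hill = p.v_s * p.K_I**n / (p.K_I**n + PN**n)
    v1 = p.V_1 * P0 / (p.K_1 + P0)
    v2 = p.V_2 * P1 / (p.K_2 + P1)
    v3 = p.V_3 * P1 / (p.K_3 + P1)
    v4 = p.V_4 * P2 / (p.K_4 + P2)
    return np.array([
        hill - p.v_m * M / (p.K_m + M) + u,
        p.k_s * M - v1 + v2,
        v1 - v2 - v3 + v4,
        v3 - v4 - p.k_1 * P2 + p.k_2 * PN - p.v_d * P2 / (p.K_d + P2),
        p.k_1 * P2 - p.k_2 * PN,
    ])


def goldbeter_jacobian(x: np.ndarray,
                       params: GoldbeterParameters | None = None) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`goldbeter_vector_field` (drift only)."""
    p = params or GoldbeterParameters()
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError(f"state must be a 5-vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state")
    M, P0, P1, P2, PN = x
    n = p.hill_n
    J = np.zeros((5, 5))
    J[0, 0] = -p.v_m * p.K_m / (p.K_m + M) ** 2
    J[0, 4] = -n * p.v_s * p.K_I**n * PN ** (n - 1) / (p.K_I**n + PN**n) ** 2
    J[1, 0] = p.k_s
    d1 = p.V_1 * p.K_1 / (p.K_1 + P0) ** 2
    d2 = p.V_2 * p.K_2 / (p.K_2 + P1) ** 2
    d3 = p.V_3 * p.K_3 / (p.K_3 + P1) ** 2
    d4 = p.V_4 * p.K_4 / (p.K_4 + P2) ** 2
    J[1, 1] = -d1
    J[1, 2] = d2
    J[2, 1] = d1
    J[2, 2] = -d2 - d3
    J[2, 3] = d4
    J[3, 2] = d3
    J[3, 3] = -p.k_1 - d4 - p.v_d * p.K_d / (p.K_d + P2) ** 2
    J[3, 4] = p.k_2
    J[4, 3] = p.k_1
    J[4, 4] = -p.k_2
    return J


def goldbeter_system(params: GoldbeterParameters | None = None) -> NonlinearSystem:
    """Goldbeter oscillator as a :class:`NonlinearSystem`.

    Input: additive forcing of the mRNA balance (B = e1); output: nuclear
    PER concentration (C = e5^T).
    """
    p = params or GoldbeterParameters()
    B = np.zeros((5, 1))
    B[0, 0] = 1.0
    C = np.zeros((1, 5))
    C[0, 4] = 1.0
    return NonlinearSystem(
        f=lambda x: goldbeter_vector_field(x, 0.0, p),
        jacobian=lambda x: goldbeter_jacobian(x, p),
        B=B, C=C,
    )


@dataclass(frozen=True)
class Trajectory:
    """Solution of a simulation with dense-output interpolant attached."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    input_u: float
    _interp: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states in trajectory")

    def at(self, t: np.ndarray) -> np.ndarray:
        """States at arbitrary times via the integrator's dense output,
        shape (len(t), n)."""
        if self._interp is None:
            raise ValueError("trajectory has no dense-output interpolant")
        return np.atleast_2d(np.asarray(self._interp(np.asarray(t, dtype=float))).T)


@dataclass(frozen=True)
class SteadyStateSamples:
    """Equally spaced samples of a trajectory with Jacobians and rate values."""

    sample_times: np.ndarray
    sample_states: np.ndarray   # (N, n)
    jacobians: np.ndarray       # (N, n, n)
    rate_values: np.ndarray     # (N,)

    @property
    def N(self) -> int:
        return len(self.sample_times)

    @property
    def n(self) -> int:
        return self.jacobians.shape[1]


def simulate(system: NonlinearSystem | LinearSystem,
             x0: np.ndarray,
             u: float = 0.0,
             t_span: tuple[float, float] = (0.0, 100.0),
             rtol: float = 1e-8,
             atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate a system under constant input with a stiff-capable adaptive
    scheme and dense output.

    Tight default tolerances keep the trajectory error far below the LMI
    slack used downstream (sample states feed matrix inequalities with
    eps ~ 1e-3).
    """
    t_span = (float(t_span[0]), float(t_span[1]))
    if not t_span[1] > t_span[0]:
        raise ValueError("t_span must be increasing")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))

    if isinstance(system, LinearSystem):
        A, B = system.A, system.B
        uvec = np.full(system.m, float(u))

        def rhs(t, x):
            return A @ x + B @ uvec

        def jac(t, x):
            return A
    else:
        B = system.B
        uvec = np.full(system.m, float(u))
        Bu = B @ uvec

        def rhs(t, x):
            return system.f(x) + Bu

        def jac(t, x):
            return system.jacobian(x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = solve_ivp(rhs, t_span, x0, method=method, jac=jac,
                        rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise RuntimeError(
            f"integration failed near t = {sol.t[-1]:.6g}: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, input_u=float(u),
                      _interp=sol.sol)


def sample_steady_state(traj: Trajectory,
                        system: NonlinearSystem | LinearSystem,
                        rate: "Callable[[np.ndarray], float]",
                        t_1: float = 87.0,
                        t_N: float = 100.0,
                        N: int = 75) -> SteadyStateSamples:
    """Sample a trajectory at N equally spaced instants in [t_1, t_N] and
    evaluate the Jacobian and the dominance rate at each sampled state.

    The defaults (window [87, 100] h, N = 75) are the protocol used for
    the Goldbeter worked example: the window covers a bit more than half a
    period of the settled oscillation.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    lo, hi = traj.times[0], traj.times[-1]
    if t_1 < lo - 1e-12 or t_N > hi + 1e-12 or t_N < t_1:
        raise ValueError(
            f"sampling window [{t_1}, {t_N}] outside trajectory range [{lo}, {hi}]")
    ts = np.full(1, t_1) if N == 1 else np.linspace(t_1, t_N, N)
    X = traj.at(ts)
    if isinstance(system, LinearSystem):
        jacs = np.broadcast_to(system.A, (N, system.n, system.n)).copy()
    else:
        jacs = np.array([system.jacobian(x) for x in X])
    lams = np.array([float(rate(x)) for x in X])
    return SteadyStateSamples(sample_times=ts, sample_states=X,
                              jacobians=jacs, rate_values=lams)
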