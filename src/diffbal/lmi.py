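"""A small dense semidefinite/LMI solver for sampled Lyapunov inequalities.

All matrix inequalities in this package have the form

    F_j(x) = G_j + sum_i x_i M_{ji}  <=  0   (negative semidefinite),

with ``x`` the vector of free entries of one (or more) symmetric matrices
and every block F_j small (the state dimension of the system).  The
problems are tiny by SDP standards — tens of variables, at most a few
hundred blocks — so a dense two-phase method is adequate and has no
external dependencies beyond scipy:

Phase 1 (feasibility): Kelley's cutting-plane method.  Each violated
block contributes linear cuts ``v' F_j(x) v + t <= 0`` from its top
eigenvectors; the LPs are solved with HiGHS.  Terminates with a strictly
feasible point (positive margin) or a proof-by-exhaustion of
infeasibility (the LP relaxation, which outer-approximates the feasible
set, becomes infeasible or its margin upper bound falls below zero).

Phase 2 (optimality): a log-det barrier interior-point path for a convex
quadratic-plus-linear objective over the LMI blocks, damped Newton on
each centering problem.  Supported objectives: maximize the common
margin, minimize the Frobenius norm, minimize the sum of squared block
residuals ("least residual": solve the inequalities as close to
equalities as possible), or minimize distance to an anchor point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "LMIBlocks",
    "LMIInfeasibleError",
    "sym_basis",
    "vec_to_mat",
    "mat_to_vec",
    "solve_feasible",
    "solve_margin",
    "solve_least_residual",
    "solve_min_norm",
]


class LMIInfeasibleError(RuntimeError):
    """The sampled matrix inequalities admit no (strictly) feasible solution."""


def sym_basis(n: int) -> np.ndarray:
    """Basis of symmetric n-by-n matrices, upper-triangle ordering,
    shape (n(n+1)/2, n, n).  Off-diagonal elements have both symmetric
    entries set to 1."""
    Es = []
    for i in range(n):
        for j in range(i, n):
            E = np.zeros((n, n))
            E[i, j] = E[j, i] = 1.0
            Es.append(E)
    return np.array(Es)


def vec_to_mat(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return np.tensordot(x, basis, axes=(0, 0))


def mat_to_vec(M: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Coordinates of symmetric M in ``basis`` (least squares, exact when M
    lies in the span)."""
    G = np.einsum("iab,jab->ij", basis, basis)
    b = np.einsum("iab,ab->i", basis, M)
    return np.linalg.solve(G, b)


@dataclass
class LMIBlocks:
    """Affine matrix-inequality constraints sharing one variable vector.

    ``maps`` has shape (n_blocks, d, nb, nb) when all blocks have equal
    size; otherwise store per-block (maps_j, G_j) tuples via ``blocks``.
    """

    blocks: list[tuple[np.ndarray, np.ndarray]]  # [(maps (d,nb,nb), G (nb,nb))]
    d: int

    def evaluate(self, x: np.ndarray) -> list[np.ndarray]:
        return [G + np.tensordot(x, maps, axes=(0, 0)) for maps, G in self.blocks]

    def max_eig(self, x: np.ndarray) -> float:
        return max(np.linalg.eigvalsh(F).max() for F in self.evaluate(x))

    def strictly_feasible(self, x: np.ndarray) -> bool:
        return self.max_eig(x) < 0.0


def make_blocks(basis: np.ndarray,
                jacobians: np.ndarray,
                rate_values: np.ndarray,
                constant: np.ndarray,
                side: str) -> LMIBlocks:
    """Sampled differential Lyapunov inequality blocks.

    side='reach':  J_k P + P J_k' + 2 lam_k P + constant <= 0
    side='obs':    J_k' Q + Q J_k + 2 lam_k Q + constant <= 0
    """
    if side not in ("reach", "obs"):
        raise ValueError("side must be 'reach' or 'obs'")
    blocks = []
    for Jk, lk in zip(jacobians, rate_values):
        A = Jk if side == "reach" else Jk.T
        maps = np.einsum("ab,ibc->iac", A, basis)
        maps = maps + np.transpose(maps, (0, 2, 1)) + 2.0 * lk * basis
        blocks.append((maps, constant.copy()))
    return LMIBlocks(blocks=blocks, d=basis.shape[0])


def box_blocks(basis: np.ndarray, kappa: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Norm-box constraints -kappa I <= sum x_i E_i <= kappa I as two blocks."""
    n = basis.shape[1]
    return [(basis.copy(), -kappa * np.eye(n)),
            (-basis.copy(), -kappa * np.eye(n))]


# ---------------------------------------------------------------------------
# Phase 1: cutting planes


def solve_feasible(lmis: LMIBlocks,
                   kappa: float = 500.0,
                   max_iter: int = 300,
                   n_cuts: int = 2,
                   target_margin: float = 1e-6) -> tuple[np.ndarray, float]:
    """Find a strictly feasible point via Kelley cuts on the margin LP.

    Maximizes t subject to v' F_j(x) v <= -t over accumulated eigenvector
    cuts, with variable box |x_i| <= kappa.  Returns (x, margin) with
    margin > 0, or raises :class:`LMIInfeasibleError`.
    """
    d = lmis.d
    c = np.zeros(d + 1)
    c[-1] = -1.0  # maximize t
    bounds = [(-kappa, kappa)] * d + [(None, None)]
    cuts_A: list[np.ndarray] = []
    cuts_b: list[float] = []
    x = np.zeros(d + 1)
    best_margin, best_x = -np.inf, x[:d].copy()
    for it in range(max_iter):
        worst = np.inf
        for maps, G in lmis.blocks:
            F = G + np.tensordot(x[:d], maps, axes=(0, 0))
            w, V = np.linalg.eigh(F)
            worst = min(worst, -w[-1])
            for k in range(1, n_cuts + 1):
                if w[-k] > -1e-12 or it == 0:
                    v = V[:, -k]
                    a = np.empty(d + 1)
                    a[:d] = np.einsum("a,iab,b->i", v, maps, v)
                    a[-1] = 1.0
                    cuts_A.append(a)
                    cuts_b.append(-v @ G @ v)
        if worst > best_margin:
            best_margin, best_x = worst, x[:d].copy()
        if best_margin > 0 and (it >= 3 or best_margin > target_margin):
            return best_x, best_margin
        res = linprog(c, A_ub=np.array(cuts_A), b_ub=np.array(cuts_b),
                      bounds=bounds, method="highs")
        if res.status == 2:  # LP infeasible => original problem infeasible
            raise LMIInfeasibleError("cutting-plane relaxation infeasible")
        if res.status != 0:
            raise RuntimeError(f"LP solve failed: {res.message}")
        if res.x[-1] < target_margin:
            # upper bound on the achievable margin is (numerically) nonpositive
            raise LMIInfeasibleError(
                f"no strictly feasible point (margin upper bound "
                f"{res.x[-1]:.3e} within the |x| <= {kappa:g} box)")
        x = res.x
    if best_margin > 0:
        return best_x, best_margin
    raise LMIInfeasibleError(
        f"cutting planes did not reach strict feasibility in {max_iter} "
        f"iterations (best margin {best_margin:.3e})")


# ---------------------------------------------------------------------------
# Phase 2: barrier path


def _barrier_path(lmis_obj: LMIBlocks,
                  extra_blocks: list[tuple[np.ndarray, np.ndarray]],
                  x0: np.ndarray,
                  H0: np.ndarray,
                  g0: np.ndarray,
                  mu0: float = 100.0,
                  mu_factor: float = 0.15,
                  mu_min: float = 1e-8,
                  newton_tol: float = 1e-10,
                  max_center: int = 100) -> np.ndarray:
    """Minimize (1/2) x'H0 x + g0'x over the blocks, log-det barrier path.

    ``extra_blocks`` (e.g. a norm box) join the barrier but not the
    objective.  x0 must be strictly feasible for all blocks.
    """
    all_blocks = lmis_obj.blocks + extra_blocks
    d = len(x0)
    x = x0.copy()

    def feasible(xt):
        return all(
            np.linalg.eigvalsh(G + np.tensordot(xt, maps, axes=(0, 0))).max() < 0
            for maps, G in all_blocks)

    if not feasible(x):
        raise LMIInfeasibleError("barrier start point not strictly feasible")
    mu = mu0
    while True:
        for _ in range(max_center):
            gb = np.zeros(d)
            Hb = np.zeros((d, d))
            for maps, G in all_blocks:
                S = -(G + np.tensordot(x, maps, axes=(0, 0)))
                Si = np.linalg.inv(S)
                gb += np.einsum("iab,ba->i", maps, Si)
                V = np.einsum("ab,ibc->iac", Si, maps)
                Hb += np.einsum("iab,lba->il", V, V)
            g = H0 @ x + g0 + mu * gb
            H = H0 + mu * Hb
            try:
                dx = -np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                dx = -np.linalg.lstsq(H, g, rcond=None)[0]
            if float(-g @ dx) < newton_tol * max(1.0, mu):
                break
            alpha = 1.0
            for _ in range(80):
                if feasible(x + alpha * dx):
                    break
                alpha *= 0.5
            else:
                break
            x = x + alpha * dx
        if mu < mu_min:
            return x
        mu *= mu_factor


def solve_margin(lmis: LMIBlocks,
                 basis: np.ndarray,
                 kappa: float = 100.0) -> tuple[np.ndarray, float]:
    """Maximize the common negative-definiteness margin t subject to
    F_j(x) <= -t I and the norm box ||sum x_i E_i|| <= kappa.

    Returns (x, margin).  This is the certificate-style objective: the
    result is strictly feasible with the largest uniform slack the box
    allows, which makes the a-posteriori inertia classification robust.
    """
    d = lmis.d
    nb0 = lmis.blocks[0][1].shape[0]
    # augment variable vector with t; each LMI block gains +t I
    aug = []
    for maps, G in lmis.blocks:
        nb = G.shape[0]
        maps_aug = np.concatenate([maps, np.eye(nb)[None]], axis=0)
        aug.append((maps_aug, G))
    for maps, G in box_blocks(basis, kappa):
        nb = G.shape[0]
        maps_aug = np.concatenate([maps, np.zeros((1, nb, nb))], axis=0)
        aug.append((maps_aug, G))
    aug_lmis = LMIBlocks(blocks=aug, d=d + 1)
    boxed = LMIBlocks(blocks=lmis.blocks + box_blocks(basis, 0.95 * kappa),
                      d=d)
    x0, _ = solve_feasible(boxed, kappa=kappa)
    margin0 = -lmis.max_eig(x0)
    z0 = np.concatenate([x0, [0.5 * margin0]])
    g0 = np.zeros(d + 1)
    g0[-1] = -1.0  # maximize t
    # mild proximal regularization keeps the Newton systems well posed on
    # the (possibly non-unique) optimal face
    H0 = np.eye(d + 1) * 1e-9
    z = _barrier_path(aug_lmis, [], z0, H0, g0)
    return z[:d], float(z[-1])


def solve_least_residual(lmis: LMIBlocks,
                         kappa: float = 500.0) -> np.ndarray:
    """Minimize sum_j ||F_j(x)||_F^2 subject to F_j(x) <= 0.

    The solution is the feasible point closest (in least squares) to
    solving every sampled inequality as an equality — for a single stable
    LTI sample this reproduces the classical Lyapunov-equation gramian up
    to the slack the constant term requires.
    """
    d = lmis.d
    H0 = np.zeros((d, d))
    g0 = np.zeros(d)
    for maps, G in lmis.blocks:
        H0 += 2.0 * np.einsum("iab,jab->ij", maps, maps)
        g0 += 2.0 * np.einsum("iab,ab->i", maps, G)
    x0, _ = solve_feasible(lmis, kappa=kappa)
    return _barrier_path(lmis, [], x0, H0, g0)


def solve_min_norm(lmis: LMIBlocks,
                   basis: np.ndarray,
                   anchor: np.ndarray | None = None,
                   kappa: float = 500.0) -> np.ndarray:
    """Minimize ||M - anchor||_F^2 (anchor defaults to 0) over the blocks."""
    d = lmis.d
    G = np.einsum("iab,jab->ij", basis, basis)
    H0 = 2.0 * G
    if anchor is None:
        g0 = np.zeros(d)
    else:
        g0 = -2.0 * G @ mat_to_vec(anchor, basis)
    x0, _ = solve_feasible(lmis, kappa=kappa)
    return _barrier_path(lmis, [], x0, H0, g0)
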