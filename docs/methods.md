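# Methods

## Scope

`diffbal` performs model order reduction for nonlinear input-affine
systems whose behavior is not limited to a stable equilibrium —
multistable systems and limit-cycle oscillators in particular.  The
method is a differential (variational) enhancement of classical balanced
truncation: instead of requiring stability, it requires *p-dominance*,
certifies it with linear matrix inequalities (LMIs) over sampled
Jacobians, balances an indefinite gramian pair of fixed inertia, and
truncates in a way that provably preserves p-dominance — and with it the
class of attractors the reduced model can display.

## Dominance model

For `xdot = f(x) + Bu`, `y = Cx`, the variational dynamics along a
trajectory are `d(dx)/dt = df(x) dx + B du`.  The system is p-dominant
with rate `lambda(x) >= 0` if there are `eps >= 0` and a symmetric `P`
with inertia `(p, 0, n-p)` such that

    df(x)' P + P df(x) + 2 lambda(x) P + eps I <= 0     for x in S.

The quadratic form `V(dx) = dx' P dx` then decays like a Lyapunov
function transversally to a p-dimensional dominant cone: n-p modes are
transient, p modes dominate.  For constant inputs, bounded solutions
converge to a unique equilibrium (p=0), some equilibrium (p=1), or a
simple attractor — equilibria, arcs of equilibria, or a limit cycle
(p=2).  Eigenvalue-wise, dominance shows up as a uniform splitting of
the sampled Jacobian spectra about the moving line `Re(s) = -lambda(x)`.

The inequality is imposed on a finite sample `x(t_1)..x(t_N)` of a
trajectory near the attractor (the standard gridding relaxation for
state-dependent LMIs).  All certificates are therefore *sampled*
certificates: they guarantee the inequalities at the samples, and by
continuity in a neighborhood, not globally.

## The Goldbeter worked example

The built-in example is the five-state Goldbeter model of circadian
*per* expression (mRNA M; PER phosphoforms P0, P1, P2; nuclear PER P_N),
with Hill-type repression of transcription by nuclear PER and
Michaelis–Menten phosphorylation/degradation kinetics.  Default
parameters are the standard published set (all rates in uM/h or 1/h,
Michaelis constants in uM); the Hill coefficient, not part of that
table, defaults to n = 4, the standard value for this model.  Input:
additive forcing of the mRNA balance; output: nuclear PER.

Protocol defaults: integrate from the origin with `u = 0` over
[0, 100] h; sample N = 75 equally spaced states on [87, 100] h (the
settled oscillation; period ~23.7 h); `eps = 1e-3`; rate

    lambda(x) = 0.4 - k1 x4 + k2 x5 .

Because `k1 x4 - k2 x5` is exactly `dx5/dt`, which averages to zero over
a period, this rate stays within about [0.29, 0.59] on the cycle —
nonnegative, as a dominance rate must be — and splits every sampled
spectrum into 2 eigenvalues above and 3 below `-lambda(x)`.

## LMI solver

No SDP library is used; the package ships a small dense solver suited to
these problems (tens of variables, 5x5 blocks):

* **Phase 1** — Kelley cutting planes: each violated block contributes
  linear cuts `v' F_j(x) v + t <= 0` from its top eigenvectors; the
  margin LPs are solved with HiGHS (`scipy.optimize.linprog`).
  Terminates with a strictly feasible point or a certified failure (the
  outer LP relaxation becomes infeasible or its margin bound falls below
  zero).
* **Phase 2** — a log-det barrier interior-point path (damped Newton per
  centering step, geometric reduction of the barrier weight) for a
  convex quadratic/linear objective over the same blocks.

Inertia is never imposed during the solve (it is non-convex); it is
classified afterwards with `zero_tol = 1e-6 * ||P||` and mismatches are
reported as errors carrying the achieved inertia.

## Solution concept for the gramians

The gramian inequalities

    df P + P df' + 2 lam P + B B' + eps I <= 0      (reachability)
    df' Q + Q df + 2 lam Q + C' C + eps I <= 0      (observability)

fix P and Q only up to a large convex solution set, and not every
feasible pair is balanceable: simultaneous diagonalization requires
`eig(PQ)` real and positive.  Two design questions were genuinely open
and were settled as follows.

**Which feasible point?**  The reachability gramian is the
*least-residual* solution: minimize `sum_k ||LHS_k||_F^2` subject to the
inequalities.  For a stable LTI sample the classical Lyapunov-equation
gramian is the unique zero-residual point, so this objective is the
natural generalization of classical balanced truncation; it also keeps
the gramian shaped by B (the input geometry) rather than by the
feasibility set's recession cone.  Margin maximization under a norm box
— a plausible alternative — was implemented and rejected: the
inequalities are nearly homogeneous in P, so the margin objective
inflates the solution onto the norm box, erases the influence of B and
C, and produced pairs with complex `eig(PQ)` (no balancing exists).
Plain minimum-norm and trace-slack objectives were also inferior
(either complex product spectra or reductions with an order of magnitude
larger frequency-domain error).

**How to guarantee balanceability?**  After solving for P, the
observability inequality is solved in the congruence basis in which P is
the signature matrix `diag(-I_p, I_{n-p})`, with the *linear* constraint
that Q is block-diagonal with respect to P's dominant/transient
splitting.  Then `PQ` is similar to `diag(-Q_--, Q_++)` scaled by the
signature, whose spectrum is `eig(Q_--) U eig(Q_++)` — real, and
positive exactly when the inertias match.  This mirrors the square-root
method of classical balancing (factor one gramian, transform the other)
and makes existence of the balancing transformation a structural
guarantee rather than numerical luck.

## Balancing, truncation, verification

`simultaneous_diagonalize` eigendecomposes `PQ` (real positive spectrum
checked; near-degenerate eigenvalues — relative gap below 1e-8 — are an
error, since the eigenvector scaling is then ill-conditioned), exploits
Q-orthogonality of the eigenvectors, scales column i by
`eig_i^{1/4} / sqrt(|v_i' Q v_i|)`, and sets
`sigma_i = sign(v_i' Q v_i) sqrt(eig_i)`.  Postconditions (both
transformed gramians diagonal and equal, off-diagonal residual below
`1e-6 * max|sigma|`) are verified numerically.  Ordering: negative
characteristic values first, each group by descending magnitude, so the
retained block is always leading.

Truncation to order `r >= p` keeps all p negative characteristic values
plus the `r - p` largest positive ones; the reduced vector field is the
Petrov–Galerkin projection `S1bar f(S1 xi)` with `S1` the first r
columns of T and `S1bar` the first r rows of its inverse.
`verify_reduced_dominance` substitutes the retained diagonal block into
the three reduced inequalities along the projected samples and reports
the worst eigenvalue of each left-hand side.  The PASS threshold is
`1e-3 * max(1, max|sigma1|)`: the least-residual gramians are *active*
at some sample constraints (that is the point of the objective), so the
reduced inequalities hold with near-zero rather than large margins, and
the diagonalization residual propagates through `T' (.) T`.  A stricter
threshold would reject exact full-order self-checks for purely numerical
reasons.

Two conventions for the reduced sample family were possible, since the
projection `S1 S1bar x_k` of a sample is not itself a sample:
evaluating the reduced Jacobian as the projection of the *sampled*
Jacobian, `S1bar df(x_k) S1`, or re-evaluating `df` at the projected
state.  The default is the former, which keeps the reduced family
pointwise consistent with the certified full family (and is what makes
the frequency-domain error small); re-evaluation is available via
`jacobian_eval="projected_state"`.

## Frequency diagnostics

Along the samples, `G(s, x_k) = C (sI - df(x_k))^{-1} B` and its reduced
counterpart form transfer-function families; their difference E is the
reduction-quality diagnostic.  For a limit-cycle oscillator the
pointwise Jacobians have an eigenvalue pair crossing `Re = 0`, so on the
literal imaginary axis the families have near-singular resonances and
`sup|E|` is dominated by pole mismatch noise (the full family itself
peaks in the hundreds).  The meaningful contour for a dominant system is
the *shifted* D-contour `Re(s) = -lambda(x_k)`: the dominance splitting
guarantees all poles stay a finite distance (>= 0.26 for the Goldbeter
protocol) from it.  Diagnostics default to the shifted contour
(`shifts=samples.rate_values`); `shift=0` recovers the classical axis.
The grid is 400 log-spaced points in [1e-3, 1e3] rad/h — three decades
on each side of the ~0.26 rad/h oscillation — and the arc at infinity
contributes nothing for strictly proper systems.  Conjugate symmetry
makes the negative-frequency half redundant for magnitudes.

For the Goldbeter protocol this yields `sup|E| ~ 0.04` at order 4 and
`~ 0.20` at order 3 (recomputed by `scripts/acceptance.py`, not stored).

## Synthetic generators

`random_stable_lti` draws stable triples from random real-normal-form
blocks conjugated by a well-conditioned similarity — enough genericity
to exercise minimality-dependent code paths without pathological
conditioning.  `random_p_dominant_nonlinear` builds p-dominance in by
construction: a block-split linear part whose symmetric parts sit at
`-rate +/- gap/2`, plus a `tanh`-based nonlinearity with derivative
bound below `gap/2`, so `P* = diag(-I_p, I_{n-p})` is a ground-truth
certificate.  These fixtures emulate the *structure* the theory needs
(uniform spectral splitting, bounded nonlinear coupling); they do not
emulate the stiffness, positivity constraints, or parameter correlations
of real kinetic models, so passing tests demonstrate correctness of the
algebra and the solver, not robustness on arbitrary biochemical networks.

## Numerical choices

* Integration: LSODA, `rtol=1e-8`, `atol=1e-10`, dense output (cubic
  interpolant) for reproducible equally spaced sampling; trajectory
  error is then far below the LMI slack `eps = 1e-3`.
* Negative solver transients in the Goldbeter rate laws warn but do not
  clamp: the rate functions are defined for all real states and clamping
  would corrupt Jacobian sampling.
* Barrier path: `mu` reduced by 0.15 per stage down to 1e-8; Newton
  tolerance 1e-10 on the decrement.  All stages are deterministic, so
  repeated runs agree to machine precision.
* `eig(PQ)` realness tolerance 1e-8 relative to the spectral radius.
* Boundary eigenvalues in the spectral split are flagged at 1e-9
  absolute distance and excluded from rate-selection ranking.

## Known limitations

* All certificates are sample-based and local to a neighborhood of the
  sampled region; no continuity radius is computed.
* No a priori error bound exists for the nonlinear reduction (the L2
  bound applies to the LTI path only); the frequency-domain error family
  is an a posteriori diagnostic.
* The rate-selection heuristic is a grid search over a user-declared
  family, ranked by worst-case spectral gap — a documented reconstruction
  of what is normally done by inspection, not a canonical algorithm.
* Repeated characteristic values are rejected rather than block-handled.
* Evaluating the reduced vector field still costs O(n) work per step
  (constant projections around the full `f`), so the reduction speeds up
  analysis, not necessarily simulation.
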