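import numpy as np
import pytest

from conftest import samples_at_states
from diffbal.differential_balancing import (BalancingError, GramianPair,
                                            differential_gramians,
                                            order_and_partition,
                                            simultaneous_diagonalize,
                                            truncate_nonlinear,
                                            verify_reduced_dominance)
from diffbal.dominance import RateFunction, inertia
from diffbal.fixtures import FixtureSpec, random_stable_lti
from diffbal.linear_balancing import balance_spd, lyapunov_gramians
from diffbal.reference import goldbeter_reference_gramians
from diffbal.systems import (NonlinearSystem, SteadyStateSamples,
                             goldbeter_system, simulate)


def const_samples(A, lam=0.0):
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    return SteadyStateSamples(np.zeros(1), np.zeros((1, n)), A[None].copy(),
                              np.array([lam]))


def pair_from(P, Q, eps=1e-3):
    return GramianPair(P=P, Q=Q, inertia_P=inertia(P), inertia_Q=inertia(Q),
                       epsilon=eps)


class TestDifferentialGramians:
    def test_goldbeter_inertias(self, goldbeter_report):
        pair = goldbeter_report["gramians"]
        assert pair.inertia_P == (2, 0, 3)
        assert pair.inertia_Q == (2, 0, 3)

    def test_goldbeter_inequalities_hold_at_every_sample(self, goldbeter_report):
        pair = goldbeter_report["gramians"]
        s = goldbeter_report["samples"]
        eps = pair.epsilon
        B = np.array([[1.0, 0, 0, 0, 0]]).T
        C = np.array([[0.0, 0, 0, 0, 1]])
        for J, lam in zip(s.jacobians, s.rate_values):
            lp = J @ pair.P + pair.P @ J.T + 2 * lam * pair.P \
                + B @ B.T + eps * np.eye(5)
            lq = J.T @ pair.Q + pair.Q @ J + 2 * lam * pair.Q \
                + C.T @ C + eps * np.eye(5)
            assert np.linalg.eigvalsh(lp).max() <= 1e-9
            assert np.linalg.eigvalsh(lq).max() <= 1e-9

    def test_feasible_gramians_imply_dominance_inequality(self, goldbeter_report):
        """Either gramian, substituted into the bare dominance inequality,
        satisfies it (the BB'/C'C terms only add slack)."""
        pair = goldbeter_report["gramians"]
        s = goldbeter_report["samples"]
        eps = pair.epsilon
        for J, lam in zip(s.jacobians, s.rate_values):
            for M, side in ((pair.P, "reach"), (pair.Q, "obs")):
                A = J if side == "reach" else J.T
                lhs = A @ M + M @ A.T + 2 * lam * M + eps * np.eye(5)
                assert np.linalg.eigvalsh(lhs).max() <= 1e-9

    def test_stable_lti_constant_sample_gives_spd_pair(self):
        sys_ = random_stable_lti(FixtureSpec(n=4, m=1, l=1, seed=31))
        s = const_samples(sys_.A)
        pair = differential_gramians(s, sys_.B, sys_.C, epsilon=1e-4)
        assert pair.inertia_P == (0, 0, 4)
        assert pair.inertia_Q == (0, 0, 4)

    def test_contracting_zero_io_case(self):
        s = const_samples(-np.eye(3))
        pair = differential_gramians(s, np.zeros((3, 1)), np.zeros((1, 3)),
                                     epsilon=1e-3)
        assert pair.inertia_P == (0, 0, 3)

    def test_wrong_expected_inertia_rejected(self, goldbeter_samples):
        B = np.array([[1.0, 0, 0, 0, 0]]).T
        C = np.array([[0.0, 0, 0, 0, 1]])
        with pytest.raises(BalancingError):
            differential_gramians(goldbeter_samples, B, C, epsilon=1e-3, p=1)


class TestSimultaneousDiagonalization:
    def test_reference_pair_product_spectrum(self):
        P, Q = goldbeter_reference_gramians()
        w = np.linalg.eigvals(P @ Q)
        assert np.abs(w.imag).max() < 1e-8 * np.abs(w).max()
        np.testing.assert_allclose(
            np.sort(w.real)[::-1],
            [2847.3, 1590.1, 984.4, 161.3, 21.6], rtol=0.01)

    def test_reference_pair_characteristic_values(self):
        P, Q = goldbeter_reference_gramians()
        real = simultaneous_diagonalize(pair_from(P, Q))
        sig = real.char_values
        assert real.p == 2
        np.testing.assert_allclose(
            np.sort(np.abs(sig))[::-1],
            [53.360, 39.877, 31.376, 12.699, 4.651], rtol=0.01)
        # most negative and largest positive values
        assert sig[0] == pytest.approx(-39.877, rel=0.01)
        assert max(sig) == pytest.approx(53.360, rel=0.01)

    def test_spd_pair_reduces_to_classical_balancing(self):
        sys_ = random_stable_lti(FixtureSpec(n=4, m=2, l=2, seed=41))
        P, Q = lyapunov_gramians(sys_)
        _, s_classic = balance_spd(P, Q)
        real = simultaneous_diagonalize(pair_from(P, Q))
        assert real.p == 0
        np.testing.assert_allclose(real.char_values, s_classic, rtol=1e-8)

    def test_characteristic_values_squared_equal_product_spectrum(self,
                                                                  goldbeter_report):
        pair = goldbeter_report["gramians"]
        real = goldbeter_report["realization"]
        np.testing.assert_allclose(
            np.sort(real.char_values ** 2),
            np.sort(np.linalg.eigvals(pair.P @ pair.Q).real), rtol=1e-8)

    def test_diagonalization_postconditions(self, goldbeter_report):
        pair = goldbeter_report["gramians"]
        real = goldbeter_report["realization"]
        smax = np.abs(real.char_values).max()
        D = np.diag(real.char_values)
        assert np.abs(real.T_inv @ pair.P @ real.T_inv.T - D).max() < 1e-6 * smax
        assert np.abs(real.T.T @ pair.Q @ real.T - D).max() < 1e-6 * smax
        assert np.abs(real.T @ real.T_inv - np.eye(5)).max() < 1e-8
        assert int(np.sum(real.char_values < 0)) == 2

    def test_complex_product_spectrum_rejected(self):
        # an unaligned indefinite pair whose product has complex eigenvalues
        P = np.diag([-1.0, 1.0])
        R = np.array([[np.cos(1.0), -np.sin(1.0)], [np.sin(1.0), np.cos(1.0)]])
        Q = R @ np.diag([-1.0, 1.0]) @ R.T
        assert np.abs(np.linalg.eigvals(P @ Q).imag).max() > 1e-3
        with pytest.raises(BalancingError):
            simultaneous_diagonalize(pair_from(P, Q))


class TestOrderAndPartition:
    def test_goldbeter_discard_sets(self):
        P, Q = goldbeter_reference_gramians()
        real = simultaneous_diagonalize(pair_from(P, Q))
        s1, s2 = order_and_partition(real, 4)
        np.testing.assert_allclose(np.sort(s2), [4.651], rtol=0.01)
        s1, s2 = order_and_partition(real, 3)
        np.testing.assert_allclose(np.sort(s2), [4.651, 12.699], rtol=0.01)
        assert inertia(np.diag(s1)) == (2, 0, 1)

    def test_full_order_keeps_everything(self, goldbeter_report):
        real = goldbeter_report["realization"]
        s1, s2 = order_and_partition(real, 5)
        assert len(s2) == 0
        assert inertia(np.diag(s1)) == (2, 0, 3)

    def test_r_below_p_rejected(self, goldbeter_report):
        with pytest.raises(ValueError):
            order_and_partition(goldbeter_report["realization"], 1)


class TestTruncateNonlinear:
    def test_full_order_reduction_reproduces_output(self, goldbeter_report):
        """r = n truncation is only a coordinate change: the simulated
        output must match the original."""
        real = goldbeter_report["realization"]
        sys_ = goldbeter_system()
        rom = truncate_nonlinear(sys_, real, 5)
        t_eval = np.linspace(0, 50, 200)
        x0 = np.full(5, 0.5)
        traj_full = simulate(sys_, x0, t_span=(0, 50))
        traj_red = simulate(rom.reduced_system(), rom.S1bar @ x0, t_span=(0, 50))
        y_full = traj_full.at(t_eval) @ sys_.C.T
        y_red = traj_red.at(t_eval) @ rom.C1.T
        np.testing.assert_allclose(y_red, y_full, rtol=1e-6, atol=1e-8)

    def test_order4_reduction_tracks_oscillation(self, goldbeter_report):
        """The r=4 reduced model stays bounded, keeps oscillating with the
        right period, and tracks the full output closely."""
        real = goldbeter_report["realization"]
        sys_ = goldbeter_system()
        rom = truncate_nonlinear(sys_, real, 4)
        traj_full = simulate(sys_, np.zeros(5), t_span=(0, 100))
        traj_red = simulate(rom.reduced_system(), np.zeros(4), t_span=(0, 100))
        ts = np.linspace(60, 100, 400)
        y_full = (traj_full.at(ts) @ sys_.C.T)[:, 0]
        y_red = (traj_red.at(ts) @ rom.C1.T)[:, 0]
        assert np.all(np.isfinite(y_red))
        assert y_red.max() - y_red.min() > 0.5 * (y_full.max() - y_full.min())
        assert np.max(np.abs(y_full - y_red)) < 0.5 * (y_full.max() - y_full.min())

    def test_reduced_jacobian_matches_finite_differences(self, goldbeter_report):
        real = goldbeter_report["realization"]
        sys_ = goldbeter_system()
        rom = truncate_nonlinear(sys_, real, 4)
        rng = np.random.default_rng(5)
        h = 1e-6
        for _ in range(10):
            xi = rng.uniform(0.1, 1.0, 4)
            J = rom.jacobian(xi)
            Jfd = np.empty((4, 4))
            for j in range(4):
                e = np.zeros(4)
                e[j] = h
                Jfd[:, j] = (rom.f(xi + e) - rom.f(xi - e)) / (2 * h)
            np.testing.assert_allclose(J, Jfd, rtol=1e-5, atol=1e-7)


class TestVerifyReducedDominance:
    @pytest.mark.parametrize("r", [5, 4, 3])
    def test_goldbeter_reductions_preserve_dominance(self, goldbeter_report, r):
        real = goldbeter_report["realization"]
        rom = truncate_nonlinear(goldbeter_system(), real, r)
        rep = verify_reduced_dominance(rom, goldbeter_report["samples"],
                                       epsilon=1e-3)
        assert rep["pass"], rep
        assert rep["inertia_sigma1"] == (2, 0, r - 2)

    def test_corrupted_sigma_fails(self, goldbeter_report):
        real = goldbeter_report["realization"]
        rom = truncate_nonlinear(goldbeter_system(), real, 4)
        bad = rom.sigma1.copy()
        bad[0] = -bad[0]  # flip the leading dominant value
        import dataclasses
        rom_bad = dataclasses.replace(rom, sigma1=bad)
        rep = verify_reduced_dominance(rom_bad, goldbeter_report["samples"],
                                       epsilon=1e-3)
        assert not rep["pass"]
        assert max(rep["max_lhs_eig"].values()) > 0
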