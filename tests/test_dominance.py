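import numpy as np
import pytest

from conftest import samples_at_states
from diffbal.dominance import (CertificateError, RateFunction,
                               classify_attractor,
                               differential_lyapunov_value, dominance_lmi,
                               inertia, select_rate_heuristic, spectral_split)
from diffbal.fixtures import FixtureSpec, random_stable_lti
from diffbal.reference import goldbeter_reference_certificate
from diffbal.systems import SteadyStateSamples


def const_samples(A, lam=0.0):
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    return SteadyStateSamples(np.zeros(1), np.zeros((1, n)), A[None].copy(),
                              np.array([lam]))


class TestInertia:
    def test_diagonal_cases(self):
        assert inertia(np.diag([-1.0, 2.0, 3.0])) == (1, 0, 2)
        assert inertia(np.eye(5)) == (0, 0, 5)
        assert inertia(np.diag([-1.0, 0.0, 1.0])) == (1, 1, 1)

    def test_reference_certificate_inertia(self):
        P = goldbeter_reference_certificate()
        n_minus, _, n_plus = inertia(P)
        assert (n_minus, n_plus) == (2, 3)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            inertia(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_congruence_invariance(self):
        # Sylvester's law: inertia survives congruence transforms
        rng = np.random.default_rng(0)
        M = np.diag([-2.0, -1.0, 0.5, 3.0])
        for _ in range(5):
            S = rng.standard_normal((4, 4)) + 2 * np.eye(4)
            assert inertia(S @ M @ S.T) == (2, 0, 2)


class TestSpectralSplit:
    def test_goldbeter_protocol_split(self, goldbeter_samples):
        split = spectral_split(goldbeter_samples)
        assert np.all(split["above"] == 2)
        assert np.all(split["below"] == 3)
        assert not split["boundary_flags"].any()

    def test_stable_constant_case(self):
        split = spectral_split(const_samples(np.diag([-1.0, -2.0]), 0.0))
        assert split["above"][0] == 0 and split["below"][0] == 2

    def test_matches_direct_eigenvalue_count(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = rng.standard_normal((5, 5))
            lam = 0.3
            split = spectral_split(const_samples(A, lam))
            re = np.linalg.eigvals(A).real
            assert split["above"][0] == np.sum(re > -lam)
            assert split["below"][0] == np.sum(re < -lam)


class TestDominanceLmi:
    def test_goldbeter_certificate(self, goldbeter_report):
        cert = goldbeter_report["certificate"]
        assert cert.inertia == (2, 0, 3)
        assert cert.margin > 0
        # the certificate satisfies every sampled inequality
        samples = goldbeter_report["samples"]
        eps = cert.epsilon
        for J, lam in zip(samples.jacobians, samples.rate_values):
            lhs = J.T @ cert.P + cert.P @ J + 2 * lam * cert.P + eps * np.eye(5)
            assert np.linalg.eigvalsh(lhs).max() <= 1e-9

    def test_contracting_sample_is_zero_dominant(self):
        cert = dominance_lmi(const_samples(-np.eye(3)), p=0, epsilon=1e-3)
        assert cert.inertia == (0, 0, 3)

    def test_expanding_sample_cannot_be_zero_dominant(self):
        with pytest.raises(CertificateError):
            dominance_lmi(const_samples(np.eye(3)), p=0, epsilon=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_lti_zero_dominance_iff_stable(self, seed):
        sys_ = random_stable_lti(FixtureSpec(n=4, seed=seed))
        cert = dominance_lmi(const_samples(sys_.A), p=0, epsilon=1e-3)
        assert cert.inertia == (0, 0, 4)
        shift = np.abs(np.linalg.eigvals(sys_.A).real).max() + 0.5
        with pytest.raises(CertificateError):
            dominance_lmi(const_samples(sys_.A + shift * np.eye(4)),
                          p=0, epsilon=1e-3)

    def test_negative_rate_warns(self):
        s = const_samples(-np.eye(2), lam=-0.5)
        with pytest.warns(RuntimeWarning):
            dominance_lmi(s, p=0, epsilon=1e-4)


class TestRateHeuristic:
    def test_goldbeter_family_recovers_default_rate(self, goldbeter_samples):
        # scan the offset in lambda(x) = c - k1 x4 + k2 x5
        family = [RateFunction(c0=c, c=np.array([0, 0, 0, -1.9, 1.3]))
                  for c in np.arange(0.1, 1.01, 0.1)]
        ranked = select_rate_heuristic(goldbeter_samples, [2], family)
        admissible_offsets = {round(rf.c0, 2) for p, rf, gap in ranked}
        assert 0.4 in admissible_offsets
        assert all(p == 2 for p, _, _ in ranked)

    def test_stable_lti_zero_rate_admissible(self):
        sys_ = random_stable_lti(FixtureSpec(n=3, seed=2))
        s = const_samples(sys_.A)
        ranked = select_rate_heuristic(s, [0], [RateFunction.constant(0.0)])
        assert len(ranked) == 1 and ranked[0][0] == 0

    def test_split_tracks_known_unstable_mode(self):
        A = np.diag([0.5, -2.0, -3.0])
        s = const_samples(A)
        ranked = select_rate_heuristic(
            s, [0, 1], [RateFunction.constant(v) for v in (0.0, 1.0)])
        by_rate = {rf.c0: p for p, rf, _ in ranked}
        assert by_rate[0.0] == 1  # one eigenvalue above the unshifted axis
        assert by_rate[1.0] == 1  # still above Re = -1

    def test_empty_family_rejected(self, goldbeter_samples):
        with pytest.raises(ValueError):
            select_rate_heuristic(goldbeter_samples, [2], [])


class TestAttractorClassification:
    @pytest.mark.parametrize("p,needle", [
        (0, "unique equilibrium"),
        (1, "equilibrium"),
        (2, "limit cycle"),
        (3, "no classification"),
    ])
    def test_classification_text(self, p, needle):
        assert needle in classify_attractor(p)


class TestDifferentialLyapunov:
    def test_quadratic_form_values(self):
        assert differential_lyapunov_value(np.eye(2), np.array([1.0, 0])) == 1.0
        assert differential_lyapunov_value(np.diag([-1.0, 1.0]),
                                           np.array([1.0, 0])) == -1.0
        with pytest.raises(ValueError):
            differential_lyapunov_value(np.eye(2), np.ones(3))

    def test_certified_decrease_along_samples(self, goldbeter_report):
        """dV/dt <= -2 lam V - eps |dx|^2 for the linearized flow at each
        sample, by direct substitution of the certificate."""
        cert = goldbeter_report["certificate"]
        samples = goldbeter_report["samples"]
        rng = np.random.default_rng(12)
        for k in range(0, samples.N, 5):
            J, lam = samples.jacobians[k], samples.rate_values[k]
            for _ in range(20):
                dx = rng.standard_normal(5)
                lhs = dx @ (J.T @ cert.P + cert.P @ J) @ dx
                rhs = (-2 * lam * differential_lyapunov_value(cert.P, dx)
                       - cert.epsilon * dx @ dx)
                assert lhs <= rhs + 1e-9
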