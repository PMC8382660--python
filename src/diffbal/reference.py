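"""Known reference solutions for the Goldbeter worked example.

These matrices are a known-good feasible solution set of the sampled
dominance and gramian inequalities for the Goldbeter model under the
standard protocol (rate lambda(x) = 0.4 - k1 x4 + k2 x5, eps = 1e-3,
75 samples on [87, 100] h).  They serve as regression fixtures: the
certificate has inertia (2, 0, 3); the gramian pair is simultaneously
diagonalizable with eig(PQ) ~ {2847.3, 1590.1, 984.4, 161.3, 21.6} and
characteristic values ~ {-39.877, -31.376, 53.360, 12.699, 4.651}.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "goldbeter_reference_certificate",
    "goldbeter_reference_gramians",
]


def goldbeter_reference_certificate() -> np.ndarray:
    """A 5x5 dominance certificate for the Goldbeter model, inertia (2,0,3)."""
    return np.array([
        [-1.028, -1.795,  0.894,  0.730,  0.128],
        [-1.795,  2.269, -3.279, -1.944,  0.535],
        [ 0.894, -3.279,  7.863, -4.262, -0.663],
        [ 0.730, -1.944, -4.262, 10.561, -4.572],
        [ 0.128,  0.535, -0.663, -4.572,  1.992],
    ])


def goldbeter_reference_gramians() -> tuple[np.ndarray, np.ndarray]:
    """Reference (P, Q) gramian pair for the Goldbeter model.

    Both have inertia (2, 0, 3); their product has a real positive
    spectrum, so a balancing transformation exists.
    """
    P = np.array([
        [-30.284, -42.356, -12.762,   8.616,  27.678],
        [-42.356,  10.001,  -7.797, -22.240, -38.751],
        [-12.762,  -7.797,   8.157,  -9.426, -24.427],
        [  8.616, -22.240,  -9.426,   1.1810, -6.579],
        [ 27.678, -38.751, -24.427,  -6.579,  10.946],
    ])
    Q = np.array([
        [ -7.463, -18.749,  -2.445,   7.607,  13.193],
        [-18.749,  10.261, -11.346, -15.919, -16.251],
        [ -2.445, -11.346,  -2.357,  -6.946,  -9.414],
        [  7.607, -15.919,  -6.946,  -0.179,  -3.875],
        [ 13.193, -16.251,  -9.414,  -3.875,  -0.263],
    ])
    return P, Q
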