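"""Independent oracles shared across test modules.

These deliberately avoid the library's own code paths: RMSD by direct
numerical minimisation over rotations, stationary distributions by
power iteration.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(a, b, n_starts=60, seed=0):
    """Minimum RMSD over rotations by multi-start Nelder-Mead search on
    the rotation vector (no closed-form superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def power_iteration_pi(T, iterations=20000):
    """Stationary distribution of a row-stochastic matrix by repeated
    left-multiplication from the uniform start."""
    T = np.asarray(T, dtype=float)
    v = np.full(T.shape[0], 1.0 / T.shape[0])
    for _ in range(iterations):
        v = v @ T
    return v / v.sum()


def second_order_labels(n, seed, p=0.9):
    """A deliberately non-Markov binary process: s[t+1] = s[t-1] w.p. p."""
    rng = np.random.default_rng(seed)
    s = np.empty(n, dtype=int)
    s[0], s[1] = rng.integers(2, size=2)
    flips = rng.random(n) > p
    for t in range(2, n):
        s[t] = 1 - s[t - 2] if flips[t] else s[t - 2]
    return s
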