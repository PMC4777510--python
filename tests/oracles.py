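"""Independent reference computations used by the tests.

These deliberately avoid the package's own code paths: brute-force grid
search for linear separability, exhaustive permutation enumeration for the
trait-index null, and direct arithmetic on tiny fixtures.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np


def grid_min_error(X: np.ndarray, y: np.ndarray, n_grid: int = 21) -> tuple[float, np.ndarray]:
    """Minimum training error over a dense (w, b) grid in [-1, 1]^(d+1).

    Separating hyperplanes are scale-invariant, so a grid over directions
    suffices to certify separability of small fixtures.  The decision rule
    matches the perceptron's: activation > 0 -> label 1, ties -> label 0.
    Returns (min error, one achieving weight vector [w..., b]).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    d = X.shape[1]
    g = np.linspace(-1.0, 1.0, n_grid)
    axes = np.meshgrid(*([g] * (d + 1)), indexing="ij")
    V = np.stack([a.ravel() for a in axes], axis=1)  # (G, d+1)
    act = X @ V[:, :d].T + V[:, d]
    err = ((act > 0).astype(int) != y[:, None]).mean(axis=0)
    best = int(np.argmin(err))
    return float(err[best]), V[best]


def novikoff_update_bound(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """Perceptron update bound (R^2 ||v||^2 / gamma^2) given a separator ``v``.

    ``v`` is an augmented weight vector [w..., b] achieving zero error; R is
    the largest augmented input norm.  Infinite when the separator has a
    zero-margin point (label-0 activations exactly at threshold).
    """
    X_aug = np.hstack([X, np.ones((len(X), 1))])
    ys = 2 * np.asarray(y, dtype=int) - 1
    margins = ys * (X_aug @ v)
    gamma = margins.min()
    if gamma <= 0:
        return float("inf")
    R = np.linalg.norm(X_aug, axis=1).max()
    return (R ** 2) * float(v @ v) / float(gamma ** 2)


def enumerate_index_null(R: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Exact trait-index null: all joint per-row stimulus permutations.

    For an (n_units x n_stimuli) matrix, enumerates the (n_stimuli!)^n_units
    joint assignments of independent row permutations and returns the
    population index for each.  Only feasible for tiny fixtures.
    """
    n_units, n_stimuli = R.shape
    perms = list(permutations(range(n_stimuli)))
    per_row = [
        np.array([abs(R[i, list(p)] @ contrast) for p in perms])
        for i in range(n_units)
    ]
    null = []
    for combo in product(*[range(len(perms))] * n_units):
        null.append(np.mean([per_row[i][combo[i]] for i in range(n_units)]))
    return np.asarray(null)


def binomial_interval(n: int, p: float = 0.5, conf: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial interval on the success *fraction*."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
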