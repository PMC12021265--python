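"""Model-agnostic Shapley attribution by weighted linear regression.

For a prediction function f, a sample x and a background set B, the
coalition value is the interventional expectation
``v(S) = mean_b f(x_S, b_notS)``.  Shapley values are recovered by the
kernel-weighted least squares fit over coalition indicators with the
constraints ``phi_0 = v(empty)`` and ``sum phi = v(full) - v(empty)``;
the constraints make local accuracy hold exactly by construction.

All 2^M coalitions are enumerated when M <= ``exact_limit`` (then the
result is the exact interventional Shapley value); larger models fall
back to paired coalition sampling.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

EXACT_LIMIT = 13


def _coalition_values(f, x, background, Z):
    """v for each coalition row of Z (mean over background completions)."""
    n_bg = background.shape[0]
    vals = np.empty(Z.shape[0])
    for k, z in enumerate(Z):
        synth = np.array(background, copy=True)
        synth[:, z.astype(bool)] = x[z.astype(bool)]
        vals[k] = float(np.mean(f(synth)))
    return vals


def _kernel_weight(M: int, s: int) -> float:
    return (M - 1) / (comb(M, s) * s * (M - s))


def kernel_shap(
    f,
    x: np.ndarray,
    background: np.ndarray,
    n_coalitions: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """(attributions, base value) for one sample.

    ``f`` maps an (n, M) array to n predictions; ``background`` is the
    reference sample defining the missing-feature distribution.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    M = x.shape[0]
    v0 = float(np.mean(f(background)))
    v1 = float(np.mean(f(x[None, :])))
    if M == 1:
        return np.array([v1 - v0]), v0

    if M <= EXACT_LIMIT:
        Z = []
        for s in range(1, M):
            for idx in combinations(range(M), s):
                z = np.zeros(M)
                z[list(idx)] = 1.0
                Z.append(z)
        Z = np.array(Z)
        weights = np.array([_kernel_weight(M, int(z.sum())) for z in Z])
    else:
        rng = np.random.default_rng(seed)
        budget = n_coalitions or min(2 * M + 2048, 2**M - 2)
        sizes = np.arange(1, M)
        p = np.array([(M - 1) / (s * (M - s)) for s in sizes])
        p /= p.sum()
        Z = []
        while len(Z) < budget:
            s = int(rng.choice(sizes, p=p))
            idx = rng.choice(M, size=s, replace=False)
            z = np.zeros(M)
            z[idx] = 1.0
            Z.append(z)
            Z.append(1.0 - z)  # paired complement stabilizes the fit
        Z = np.array(Z[:budget])
        weights = np.array([_kernel_weight(M, int(z.sum())) for z in Z])

    v = _coalition_values(f, x, background, Z)

    # eliminate the last coefficient with the additivity constraint
    delta = v1 - v0
    Zp = Z[:, :-1] - Z[:, -1:]
    y = v - v0 - Z[:, -1] * delta
    W = weights
    A = Zp.T @ (W[:, None] * Zp)
    b = Zp.T @ (W * y)
    A += 1e-10 * np.eye(M - 1)  # numerical guard; exact enumeration is full rank
    phi_head = np.linalg.solve(A, b)
    phi = np.empty(M)
    phi[:-1] = phi_head
    phi[-1] = delta - phi_head.sum()
    return phi, v0


def kernel_shap_matrix(f, X, background, n_coalitions=None, seed: int = 0):
    """Kernel attribution for every row of X -> (n, M) matrix and base."""
    X = np.asarray(X, dtype=float)
    phis = np.empty_like(X)
    base = None
    for i in range(X.shape[0]):
        phis[i], base = kernel_shap(f, X[i], background, n_coalitions, seed)
    return phis, base
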