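"""Independent oracles used by the test suite only."""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss


def brute_force_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-loop intersection/union on binary masks (no vectorisation)."""
    inter = union = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            ai, bi = abs(a[i, j]), abs(b[i, j])
            inter += min(ai, bi)
            union += max(ai, bi)
    return inter / union


def quadrature_loglik(
    y: np.ndarray,
    X: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    qa: int,
    qb: int,
    beta: np.ndarray,
    sd_a: float,
    sd_b: float,
    nodes: int = 15,
) -> float:
    """Marginal log-likelihood of the crossed random-intercepts logistic model
    by tensor-product Gauss-Hermite quadrature over every random effect.

    Exact up to quadrature error (15 nodes per dimension resolve the
    near-Gaussian integrands involved far beyond 1e-6); tractable only for
    tiny numbers of levels, which is exactly the oracle's role.
    """
    x, w = hermgauss(nodes)
    dims = qa + qb
    idx = np.stack(
        [g.ravel() for g in np.meshgrid(*([np.arange(nodes)] * dims), indexing="ij")],
        axis=1,
    )
    logw = np.log(w / np.sqrt(np.pi))
    logW = logw[idx].sum(axis=1)
    pts = x[idx]
    ua = np.sqrt(2.0) * sd_a * pts[:, :qa]
    ub = np.sqrt(2.0) * sd_b * pts[:, qa:]
    eta = X @ beta
    E = eta[None, :] + ua[:, ia] + ub[:, ib]
    ll_pts = E @ y - np.logaddexp(0.0, E).sum(axis=1)
    m = (ll_pts + logW).max()
    return float(m + np.log(np.exp(ll_pts + logW - m).sum()))


def tiny_crossed_design(seed: int, n: int = 30, qa: int = 2, qb: int = 2):
    """A small balanced crossed logistic design with one similarity feature."""
    rng = np.random.default_rng(seed)
    ia = np.arange(n) % qa
    ib = (np.arange(n) // qa) % qb
    sim = rng.random(n)
    X = np.column_stack([np.ones(n), sim])
    from scipy.special import expit

    y = (rng.random(n) < expit(X @ np.array([-0.5, 1.5]))).astype(float)
    if y.min() == y.max():  # degenerate draw; reseed deterministically
        return tiny_crossed_design(seed + 1000, n=n, qa=qa, qb=qb)
    return y, X, ia, ib, qa, qb
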