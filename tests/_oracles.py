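"""Independent oracle implementations used only for cross-checking.

Nothing here shares code with the package's solver path: the convex oracle is
an accelerated proximal-gradient (FISTA) method with singular-value
soft-thresholding, and the objective oracle is a naive term-by-term loop.
"""

from __future__ import annotations

import numpy as np


def objective_direct(X, Y, W, b, lam, gam, delta):
    """Naive recomputation of the joint objective, term by term."""
    n, m, d = X.shape
    total = 0.0
    for i in range(m):
        resid = X[:, i, :] @ W[:, i] + b[i] * np.ones(n) - Y
        total += float(resid @ resid)
    for i in range(m):
        total += lam * float(W[:, i] @ W[:, i])
    # smoothed trace-norm term via SVD of the symmetric gram matrix
    evals, evecs = np.linalg.eigh(W @ W.T + delta * np.eye(d))
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    total += gam * float(np.trace(W.T @ inv_sqrt @ W))
    return total


def nuclear_norm_svd(W):
    return float(np.linalg.svd(np.asarray(W, float), compute_uv=False).sum())


def ridge_with_intercept(X, Y, lam):
    """Closed-form centered ridge: w = (Xc'Xc + lam I)^-1 Xc'Yc, b = ybar - xbar'w."""
    mu = X.mean(axis=0)
    Xc = X - mu
    Yc = Y - Y.mean()
    w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ Yc)
    b = float(Y.mean() - mu @ w)
    return w, b


def _svt(Z, tau):
    """Singular value soft-thresholding (prox of tau * nuclear norm)."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def fista_nuclear(X, Y, lam, gam, n_iter=3000, tol=1e-13):
    """FISTA on min_W sum_i ||Xc_i w_i - Yc||^2 + lam ||W||_F^2 + gam ||W||_*.

    The per-trial biases are eliminated analytically (optimal b_i is the mean
    residual, equivalent to centering X_i and Y). Returns (W, b).
    """
    n, m, d = X.shape
    Yc = Y - Y.mean()
    Xc = X - X.mean(axis=0, keepdims=True)
    L = 2.0 * (max(np.linalg.norm(Xc[:, i, :], 2) ** 2 for i in range(m)) + lam)

    def grad(W):
        G = np.empty_like(W)
        for i in range(m):
            G[:, i] = 2.0 * Xc[:, i, :].T @ (Xc[:, i, :] @ W[:, i] - Yc) + 2.0 * lam * W[:, i]
        return G

    def smooth_obj(W):
        return sum(
            float(np.sum((Xc[:, i, :] @ W[:, i] - Yc) ** 2)) for i in range(m)
        ) + lam * float(np.sum(W ** 2))

    W = np.zeros((d, m))
    Z = W.copy()
    t = 1.0
    prev = None
    for _ in range(n_iter):
        W_new = _svt(Z - grad(Z) / L, gam / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = W_new + ((t - 1.0) / t_new) * (W_new - W)
        W, t = W_new, t_new
        cur = smooth_obj(W) + gam * nuclear_norm_svd(W)
        if prev is not None and abs(prev - cur) <= tol * max(1.0, abs(prev)):
            break
        prev = cur
    b = np.array([float(np.mean(Y - X[:, i, :] @ W[:, i])) for i in range(m)])
    return W, b


def random_instance(rng, n=30, d=5, m=4, noise=0.5, rank=2):
    """A small random multi-trial problem with planted low-rank structure."""
    X = rng.standard_normal((n, m, d))
    U = rng.standard_normal((d, rank))
    V = rng.standard_normal((rank, m))
    W0 = U @ V / np.sqrt(rank * d)
    Y = np.einsum("nid,di->ni", X, W0).mean(axis=1) + noise * rng.standard_normal(n)
    return X, Y
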