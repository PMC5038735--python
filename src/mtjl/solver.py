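"""Core solver for multi-trial joint learning (MTJL).

The model fits one linear predictor per reading trial while coupling the
stacked weight matrix ``W = [w_1 ... w_m]`` (shape D x m) through a nuclear
norm (trace norm) penalty, the convex surrogate of matrix rank:

    J(W, b) = sum_i ||X_i w_i + 1 b_i - Y||^2
              + lam * sum_i ||w_i||^2
              + gam * ||W||_*

The nuclear norm is handled by the smoothed trace identity
``||W||_* ~= Trace(W^T (W W^T + delta I)^{-1/2} W)``, which yields an
iteratively-reweighted scheme with closed-form per-trial updates:

    w_i = (X_i^T X_i + lam I + gam D_r)^{-1} (X_i^T Y - X_i^T 1 b_i)
    b_i = mean(Y - X_i w_i)
    D_r = (1/2) (W W^T + delta I)^{-1/2}

Each sweep updates every w_i, then every b_i, then D_r, then evaluates J, and
stops when the relative change in J falls below ``tol``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg

from .dataset import MultiTrialDataset

__all__ = [
    "MTJLHyperparams",
    "SolverState",
    "SolverResult",
    "SingularTrialError",
    "NumericalDivergenceError",
    "nuclear_norm",
    "trace_surrogate",
    "objective",
    "update_Dr",
    "update_w",
    "update_b",
    "solve_mtjl",
]


class SingularTrialError(np.linalg.LinAlgError):
    """The per-trial linear system is singular (e.g. lam = gam = 0 with a
    rank-deficient trial matrix)."""


class NumericalDivergenceError(RuntimeError):
    """The objective became non-finite during iteration."""


@dataclasses.dataclass
class MTJLHyperparams:
    """Hyper-parameters of the MTJL objective and its solver.

    lam : weight of the per-trial ridge penalty (default 1).
    gam : weight of the low-rank (nuclear norm) penalty (default 1).
    delta : smoothing of the matrix inverse square root (default 1e-8).
    tol : relative convergence threshold on the objective (default 1e-6).
    max_iter : iteration cap (default 100).
    init : 'ridge_warm_start' (per-trial gam=0 solution) or 'zeros'.
    """

    lam: float = 1.0
    gam: float = 1.0
    delta: float = 1e-8
    tol: float = 1e-6
    max_iter: int = 100
    init: str = "ridge_warm_start"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0 or self.gam < 0:
            raise ValueError("lam and gam must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("ridge_warm_start", "zeros"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclasses.dataclass
class SolverState:
    """One iterate of the alternating solver."""

    W: np.ndarray          # D x m stacked weights, column i = w_i
    b: np.ndarray          # length-m per-trial biases
    Dr: np.ndarray         # D x D reweighting matrix, symmetric PSD
    iteration: int
    objective: float


@dataclasses.dataclass
class SolverResult:
    W: np.ndarray
    b: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool


def _check_finite(W: np.ndarray, name: str = "W") -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError(f"{name} contains non-finite entries")
    return W


def nuclear_norm(W: np.ndarray) -> float:
    """Sum of singular values of ``W`` (trace norm)."""
    W = _check_finite(W)
    return float(np.linalg.svd(W, compute_uv=False).sum())


def _smoothed_gram_eig(W: np.ndarray, delta: float):
    """Eigendecomposition of W W^T + delta I with eigenvalues floored at delta."""
    G = W @ W.T
    G = 0.5 * (G + G.T)
    evals, evecs = scipy.linalg.eigh(G)
    evals = np.clip(evals + delta, delta, None)
    return evals, evecs


def trace_surrogate(W: np.ndarray, delta: float) -> float:
    """Smoothed trace-norm surrogate Trace(W^T (W W^T + delta I)^{-1/2} W).

    Converges to :func:`nuclear_norm` as ``delta -> 0``.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    W = _check_finite(W)
    evals, evecs = _smoothed_gram_eig(W, delta)
    B = evecs.T @ W                      # rotate into the eigenbasis
    return float(np.sum((B ** 2).sum(axis=1) / np.sqrt(evals)))


def update_Dr(W: np.ndarray, delta: float) -> np.ndarray:
    """Reweighting matrix D_r = (1/2) (W W^T + delta I)^{-1/2}.

    Computed by symmetric eigendecomposition; always symmetric positive
    definite thanks to the delta floor.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    W = _check_finite(W)
    evals, evecs = _smoothed_gram_eig(W, delta)
    Dr = (evecs / np.sqrt(evals)) @ evecs.T * 0.5
    return 0.5 * (Dr + Dr.T)


def objective(
    data: MultiTrialDataset | np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    hp: MTJLHyperparams,
    scores: np.ndarray | None = None,
) -> float:
    """Value of the MTJL objective J(W, b) on the given data."""
    X, Y = _coerce_xy(data, scores)
    n, m, d = X.shape
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if W.shape != (d, m) or b.shape != (m,):
        raise ValueError(
            f"W must be {d}x{m} and b length {m}; got {W.shape} and {b.shape}"
        )
    resid = np.einsum("nij,ji->ni", X, W) + b[None, :] - Y[:, None]
    loss = float(np.sum(resid ** 2))
    ridge = hp.lam * float(np.sum(W ** 2))
    lowrank = hp.gam * trace_surrogate(W, hp.delta) if hp.gam > 0 else 0.0
    return loss + ridge + lowrank


def update_w(
    X_i: np.ndarray,
    Y: np.ndarray,
    b_i: float,
    Dr: np.ndarray,
    hp: MTJLHyperparams,
    trial_index: int | None = None,
) -> np.ndarray:
    """Closed-form weight update for one trial.

    Solves (X_i^T X_i + lam I + gam D_r) w_i = X_i^T (Y - b_i) by
    factorization, never by forming the explicit inverse.
    """
    X_i = np.asarray(X_i, dtype=float)
    Y = np.asarray(Y, dtype=float)
    d = X_i.shape[1]
    A = X_i.T @ X_i + hp.lam * np.eye(d)
    if hp.gam > 0:
        A = A + hp.gam * Dr
    rhs = X_i.T @ (Y - b_i)
    try:
        c, low = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve((c, low), rhs)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        label = "?" if trial_index is None else str(trial_index)
        raise SingularTrialError(
            f"singular linear system for trial {label}: the trial matrix is "
            f"rank-deficient and lam = gam = 0 provides no regularization"
        ) from None


def update_b(X_i: np.ndarray, Y: np.ndarray, w_i: np.ndarray) -> float:
    """Closed-form bias update: the mean residual b_i = mean(Y - X_i w_i)."""
    return float(np.mean(Y - X_i @ w_i))


def _coerce_xy(data, scores):
    if isinstance(data, MultiTrialDataset):
        return data.values, data.scores
    X = np.asarray(data, dtype=float)
    if scores is None:
        raise ValueError("scores required when data is a raw array")
    return X, np.asarray(scores, dtype=float)


def _ridge_init(X: np.ndarray, Y: np.ndarray, hp: MTJLHyperparams):
    """Per-trial ridge-with-intercept warm start (the gam = 0 solution)."""
    n, m, d = X.shape
    W = np.zeros((d, m))
    b = np.zeros(m)
    Yc = Y - Y.mean()
    eye = np.eye(d)
    for i in range(m):
        Xi = X[:, i, :]
        mu = Xi.mean(axis=0)
        Xc = Xi - mu
        A = Xc.T @ Xc + hp.lam * eye
        rhs = Xc.T @ Yc
        try:
            c, low = scipy.linalg.cho_factor(A)
            w = scipy.linalg.cho_solve((c, low), rhs)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            # lam = 0 on collinear data: fall back to the least-norm solution
            w = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        W[:, i] = w
        b[i] = float(Y.mean() - mu @ w)
    return W, b


def solve_mtjl(
    data: MultiTrialDataset | np.ndarray,
    hp: MTJLHyperparams,
    scores: np.ndarray | None = None,
) -> SolverResult:
    """Run the alternating closed-form solver until the objective stabilises.

    Sweeps all w_i (using the current D_r and biases), then all b_i, then
    recomputes D_r and the objective; terminates when the relative objective
    change is <= ``hp.tol`` or after ``hp.max_iter`` sweeps.
    """
    X, Y = _coerce_xy(data, scores)
    n, m, d = X.shape
    if np.any(np.isnan(X)):
        raise ValueError(
            "trial matrices contain NaN; impute missing values before fitting"
        )

    if hp.init == "ridge_warm_start":
        W, b = _ridge_init(X, Y, hp)
    else:
        W = np.zeros((d, m))
        b = np.zeros(m)

    # Per-trial Gram matrices and cross-products are fixed across iterations.
    grams = [X[:, i, :].T @ X[:, i, :] for i in range(m)]
    xty = [X[:, i, :].T @ Y for i in range(m)]
    xt1 = [X[:, i, :].sum(axis=0) for i in range(m)]
    eye = np.eye(d)

    Dr = update_Dr(W, hp.delta) if hp.gam > 0 else np.zeros((d, d))
    J = objective(X, W, b, hp, scores=Y)
    trace = [J]
    converged = False
    n_iter = 0

    for t in range(1, hp.max_iter + 1):
        n_iter = t
        for i in range(m):
            A = grams[i] + hp.lam * eye
            if hp.gam > 0:
                A = A + hp.gam * Dr
            rhs = xty[i] - xt1[i] * b[i]
            try:
                c, low = scipy.linalg.cho_factor(A)
                W[:, i] = scipy.linalg.cho_solve((c, low), rhs)
            except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
                raise SingularTrialError(
                    f"singular linear system for trial {i}: set lam > 0 or "
                    f"gam > 0, or remove collinear features"
                ) from None
        for i in range(m):
            b[i] = update_b(X[:, i, :], Y, W[:, i])
        if hp.gam > 0:
            Dr = update_Dr(W, hp.delta)
        J_new = objective(X, W, b, hp, scores=Y)
        if not np.isfinite(J_new):
            raise NumericalDivergenceError(
                f"objective became non-finite at iteration {t}"
            )
        trace.append(J_new)
        if abs(J_new - J) <= hp.tol * max(1.0, abs(J)):
            converged = True
            J = J_new
            break
        J = J_new

    if not converged:
        warnings.warn(
            f"MTJL solver did not converge within {hp.max_iter} iterations "
            f"(last relative change {abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2])):.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return SolverResult(W=W, b=b, objective_trace=trace, n_iter=n_iter, converged=converged)
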