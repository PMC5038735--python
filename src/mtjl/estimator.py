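"""Scikit-learn style estimator for multi-trial joint learning.

``MTJLRegressor`` fits one linear predictor per reading trial with a shared
low-rank coupling on the stacked weight matrix, and predicts a participant's
reading score by aggregating the per-trial predictions.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset import MultiTrialDataset
from .solver import MTJLHyperparams, nuclear_norm, objective, solve_mtjl

__all__ = ["MTJLRegressor", "fit_mtjl"]


class MTJLRegressor(BaseEstimator, RegressorMixin):
    """Multi-trial joint regression with an l2 penalty and a nuclear-norm
    (low-rank) penalty on the stacked weight matrix.

    Parameters
    ----------
    lam : float, default=1.0
        Weight of the per-trial ridge penalty.
    gam : float, default=1.0
        Weight of the nuclear-norm penalty coupling the trials.
    delta : float, default=1e-8
        Smoothing constant for the matrix inverse square root.
    tol : float, default=1e-6
        Relative convergence threshold on the objective.
    max_iter : int, default=100
        Maximum number of alternating sweeps.
    init : {'ridge_warm_start', 'zeros'}, default='ridge_warm_start'
        Initialisation of the weights.
    normalize : bool, default=True
        Z-score each feature within each trial using statistics of the
        training data (population SD); the same statistics are applied at
        prediction time.
    aggregate : {'mean', 'median'}, default='mean'
        How the m per-trial predictions are combined into one score.
    clip : tuple of (low, high) or None, default=None
        Optional clipping range for predicted scores, e.g. ``(0, 100)``.

    Attributes
    ----------
    W_ : ndarray of shape (n_features, n_trials)
        Fitted stacked weight matrix, column i = w_i.
    b_ : ndarray of shape (n_trials,)
        Fitted per-trial biases.
    objective_trace_ : list of float
        Objective value per sweep (non-increasing).
    n_iter_ : int
        Number of sweeps performed.
    converged_ : bool
    feature_names_ : list of str
    normalization_stats_ : dict with 'mean' and 'scale', each (n_trials, n_features)

    Examples
    --------
    >>> from mtjl.synthetic import SyntheticConfig, generate_cohort
    >>> data, truth = generate_cohort(SyntheticConfig(seed=0, missing_fraction=0.0))
    >>> model = MTJLRegressor(lam=1.0, gam=1.0).fit(data)
    >>> model.W_.shape
    (19, 42)
    """

    def __init__(
        self,
        lam: float = 1.0,
        gam: float = 1.0,
        delta: float = 1e-8,
        tol: float = 1e-6,
        max_iter: int = 100,
        init: str = "ridge_warm_start",
        normalize: bool = True,
        aggregate: str = "mean",
        clip: tuple[float, float] | None = None,
    ):
        self.lam = lam
        self.gam = gam
        self.delta = delta
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.normalize = normalize
        self.aggregate = aggregate
        self.clip = clip

    # ------------------------------------------------------------------
    def _hyperparams(self) -> MTJLHyperparams:
        return MTJLHyperparams(
            lam=self.lam, gam=self.gam, delta=self.delta,
            tol=self.tol, max_iter=self.max_iter, init=self.init,
        )

    def _coerce(self, X, y=None):
        """Accept a MultiTrialDataset, a (N, m, D) tensor, or a flat
        (N, m*D) matrix when the trial layout is known from fitting."""
        if isinstance(X, MultiTrialDataset):
            return X.values, (X.scores if y is None else np.asarray(y, float)), X.feature_names
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and hasattr(self, "n_trials_"):
            X = X.reshape(X.shape[0], self.n_trials_, -1)
        if X.ndim != 3:
            raise ValueError(
                "X must be a MultiTrialDataset or an array of shape "
                "(n_participants, n_trials, n_features)"
            )
        y = None if y is None else np.asarray(y, dtype=float)
        return X, y, None

    def fit(self, X, y=None):
        """Fit the model.

        ``X`` is a :class:`MultiTrialDataset` (in which case ``y`` is taken
        from it) or an array of shape (n_participants, n_trials, n_features)
        with ``y`` the length-N score vector.
        """
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        Xv, yv, names = self._coerce(X, y)
        if yv is None:
            raise ValueError("y is required when X is not a MultiTrialDataset")
        if np.any(np.isnan(Xv)):
            raise ValueError(
                "input contains NaN; impute missing cells first "
                "(see mtjl.synthetic.impute_missing)"
            )
        n, m, d = Xv.shape
        hp = self._hyperparams()

        if self.normalize:
            mean = Xv.mean(axis=0)                      # (m, D)
            scale = Xv.std(axis=0)                      # population SD
            zero_var = scale <= 0
            if np.any(zero_var):
                warnings.warn(
                    f"{int(zero_var.sum())} constant trial-feature column(s); "
                    f"centered only",
                    RuntimeWarning,
                    stacklevel=2,
                )
                scale = np.where(zero_var, 1.0, scale)
            Xn = (Xv - mean[None]) / scale[None]
        else:
            mean = np.zeros((m, d))
            scale = np.ones((m, d))
            Xn = Xv

        result = solve_mtjl(Xn, hp, scores=yv)
        self.W_ = result.W
        self.b_ = result.b
        self.objective_trace_ = result.objective_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.n_trials_ = m
        self.n_features_in_ = d
        self.feature_names_ = names or [f"feature_{j}" for j in range(d)]
        self.normalization_stats_ = {"mean": mean, "scale": scale}
        return self

    def _check_fitted(self):
        if not hasattr(self, "W_"):
            raise AttributeError("this MTJLRegressor instance is not fitted yet")

    def predict_per_trial(self, X) -> np.ndarray:
        """Per-trial predictions, shape (n_participants, n_trials)."""
        self._check_fitted()
        Xv, _, _ = self._coerce(X)
        n, m, d = Xv.shape
        if m != self.n_trials_ or d != self.n_features_in_:
            raise ValueError(
                f"expected (n, {self.n_trials_}, {self.n_features_in_}) input, "
                f"got (n, {m}, {d})"
            )
        if np.any(np.isnan(Xv)):
            raise ValueError("input contains NaN; impute missing cells first")
        stats = self.normalization_stats_
        Xn = (Xv - stats["mean"][None]) / stats["scale"][None]
        return np.einsum("nij,ji->ni", Xn, self.W_) + self.b_[None, :]

    def predict(self, X) -> np.ndarray:
        """Predicted reading scores on the 0-100 scale (one per participant)."""
        per_trial = self.predict_per_trial(X)
        if self.aggregate == "median":
            out = np.median(per_trial, axis=1)
        else:
            out = per_trial.mean(axis=1)
        if self.clip is not None:
            out = np.clip(out, *self.clip)
        return out

    # -- diagnostics ---------------------------------------------------
    def objective_value(self, X, y=None) -> float:
        """MTJL objective of the fitted parameters on (normalized) data."""
        self._check_fitted()
        Xv, yv, _ = self._coerce(X, y)
        stats = self.normalization_stats_
        Xn = (Xv - stats["mean"][None]) / stats["scale"][None]
        return objective(Xn, self.W_, self.b_, self._hyperparams(), scores=yv)

    @property
    def weight_nuclear_norm_(self) -> float:
        self._check_fitted()
        return nuclear_norm(self.W_)


def fit_mtjl(
    data: MultiTrialDataset,
    hp: MTJLHyperparams | None = None,
    **overrides,
) -> MTJLRegressor:
    """Functional wrapper: fit an :class:`MTJLRegressor` on a dataset."""
    hp = hp or MTJLHyperparams()
    params = dict(
        lam=hp.lam, gam=hp.gam, delta=hp.delta,
        tol=hp.tol, max_iter=hp.max_iter, init=hp.init,
    )
    params.update(overrides)
    return MTJLRegressor(**params).fit(data)
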