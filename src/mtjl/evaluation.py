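"""Normalization, repeated half-split evaluation and contribution summaries.

The evaluation protocol mirrors the study design: participants are split into
two halves, features are z-scored per trial with training-fold statistics,
missing cells are imputed with training-fold means, the model is fitted on the
training half and the prediction error is measured on the held-out half; the
whole procedure is repeated over many random splits and summarised by the mean
and standard deviation of the per-split error on the 0-100 score scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .dataset import MultiTrialDataset
from .estimator import MTJLRegressor
from .solver import MTJLHyperparams

__all__ = [
    "EvaluationReport",
    "normalize_features",
    "split_half",
    "prediction_error",
    "indicator_contributions",
    "trial_contributions",
    "repeated_evaluation",
]


@dataclasses.dataclass
class EvaluationReport:
    per_run_error: list[float]
    mean_error: float
    std_error: float
    n_runs: int
    n_failed: int
    split_seeds: list[int]
    metric: str
    indicator_contributions: np.ndarray        # final run, sums to 1
    indicator_contributions_mean: np.ndarray   # across-run average
    trial_contributions: np.ndarray            # final run, raw |W| column sums
    trial_contributions_normalized: np.ndarray
    median_iterations: float
    degenerate_std: bool = False
    feature_names: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def normalize_features(
    train: MultiTrialDataset,
    apply_to: MultiTrialDataset | None = None,
):
    """Z-score per feature per trial with training-fold statistics.

    Uses the population SD (ddof=0). Zero-variance columns are centered only,
    with a warning. Returns ``(train_normalized, apply_normalized, stats)``
    where stats holds 'mean' and 'scale' arrays of shape (n_trials, n_features)
    and ``apply_normalized`` is None when no second dataset is given.
    """
    if apply_to is not None and (
        apply_to.n_trials != train.n_trials
        or apply_to.n_features != train.n_features
    ):
        raise ValueError("apply_to fold does not match the training fold's shape")
    vals = np.where(train.missing_mask, np.nan, train.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
        scale = np.nanstd(vals, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    zero_var = ~(scale > 0)
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance column(s); centered only",
            RuntimeWarning,
            stacklevel=2,
        )
    scale = np.where(zero_var, 1.0, scale)
    stats = {"mean": mean, "scale": scale}

    def _apply(ds: MultiTrialDataset) -> MultiTrialDataset:
        out = ds.copy()
        out.values = (out.values - mean[None]) / scale[None]
        out.normalized = True
        return out

    return _apply(train), (None if apply_to is None else _apply(apply_to)), stats


def split_half(data: MultiTrialDataset, seed: int | None = None, stratify: bool = False):
    """Participant-level random partition into halves of ceil(N/2)/floor(N/2).

    All trials of a participant stay on one side. With ``stratify=True`` the
    split balances participants above/below the median score across folds.
    """
    n = data.n_participants
    rng = np.random.default_rng(seed)
    if stratify:
        median = np.median(data.scores)
        high = np.flatnonzero(data.scores >= median)
        low = np.flatnonzero(data.scores < median)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for grp in (high, low):
            perm = rng.permutation(grp)
            half = len(perm) // 2 + (len(perm) % 2 and len(train_idx) <= len(test_idx))
            train_idx.extend(perm[:half])
            test_idx.extend(perm[half:])
        train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    else:
        perm = rng.permutation(n)
        k = (n + 1) // 2
        train_idx, test_idx = np.sort(perm[:k]), np.sort(perm[k:])
    return data.subset(train_idx), data.subset(test_idx)


def prediction_error(pred: np.ndarray, truth: np.ndarray, metric: str = "mae") -> float:
    """MAE (default) or RMSE between predicted and true scores."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if metric == "mae":
        return float(np.mean(np.abs(pred - truth)))
    if metric == "rmse":
        return float(np.sqrt(np.mean((pred - truth) ** 2)))
    raise ValueError(f"unknown metric {metric!r}")


def indicator_contributions(model: MTJLRegressor) -> np.ndarray:
    """Per-indicator contribution: mean absolute weight across trials,
    normalized to sum to 1."""
    W = model.W_
    c = np.abs(W).mean(axis=1)
    total = c.sum()
    if total <= 0:
        warnings.warn("all-zero weight matrix; uniform contributions",
                      RuntimeWarning, stacklevel=2)
        return np.full(W.shape[0], 1.0 / W.shape[0])
    return c / total


def trial_contributions(model: MTJLRegressor):
    """Per-trial contribution: column absolute weight sums, returned as
    ``(raw, max_normalized)``."""
    W = model.W_
    t = np.abs(W).sum(axis=0)
    peak = t.max()
    if peak <= 0:
        warnings.warn("all-zero weight matrix; zero trial contributions",
                      RuntimeWarning, stacklevel=2)
        return t, t
    return t, t / peak


def _prepare_fold(train: MultiTrialDataset, test: MultiTrialDataset | None):
    """Impute both folds with training-fold means (no leakage)."""
    from .synthetic import impute_missing

    vals = np.where(train.missing_mask, np.nan, train.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        train_means = np.nanmean(vals, axis=0)
    if np.any(np.isnan(train_means)):
        j = int(np.argwhere(np.isnan(train_means))[0][1])
        raise ValueError(
            f"column {train.feature_names[j]!r} entirely missing in the training fold"
        )
    stats = {"mean": train_means}
    train_i = impute_missing(train, "train_mean", stats=stats) if train.has_missing else train
    test_i = None
    if test is not None:
        test_i = impute_missing(test, "train_mean", stats=stats) if test.has_missing else test
    return train_i, test_i


def repeated_evaluation(
    data: MultiTrialDataset,
    hp: MTJLHyperparams | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    metric: str = "mae",
    stratify: bool = False,
) -> EvaluationReport:
    """Repeat split/normalize/impute/fit/predict ``n_runs`` times.

    Run k uses split seed ``base_seed + k``. Failed runs (solver errors) are
    excluded from the summaries; more than 20% failures aborts.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    hp = hp or MTJLHyperparams()
    errors: list[float] = []
    seeds: list[int] = []
    iters: list[int] = []
    contrib_runs: list[np.ndarray] = []
    final_model: MTJLRegressor | None = None
    n_failed = 0

    for k in range(n_runs):
        seed = base_seed + k
        train, test = split_half(data, seed=seed, stratify=stratify)
        try:
            train_i, test_i = _prepare_fold(train, test)
            model = MTJLRegressor(
                lam=hp.lam, gam=hp.gam, delta=hp.delta, tol=hp.tol,
                max_iter=hp.max_iter, init=hp.init, normalize=True,
            ).fit(train_i)
            pred = model.predict(test_i)
        except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
            warnings.warn(f"run {k} failed: {exc}", RuntimeWarning, stacklevel=2)
            n_failed += 1
            continue
        errors.append(prediction_error(pred, test_i.scores, metric=metric))
        seeds.append(seed)
        iters.append(model.n_iter_)
        contrib_runs.append(indicator_contributions(model))
        final_model = model

    if n_failed > 0.2 * n_runs or final_model is None:
        raise RuntimeError(
            f"{n_failed}/{n_runs} evaluation runs failed; aborting"
        )

    errs = np.asarray(errors)
    degenerate = len(errs) < 2
    if degenerate:
        warnings.warn("fewer than 2 successful runs; std reported as 0",
                      RuntimeWarning, stacklevel=2)
    raw_t, norm_t = trial_contributions(final_model)
    return EvaluationReport(
        per_run_error=errs.tolist(),
        mean_error=float(errs.mean()),
        std_error=0.0 if degenerate else float(errs.std(ddof=1)),
        n_runs=n_runs,
        n_failed=n_failed,
        split_seeds=seeds,
        metric=metric,
        indicator_contributions=indicator_contributions(final_model),
        indicator_contributions_mean=np.mean(contrib_runs, axis=0),
        trial_contributions=raw_t,
        trial_contributions_normalized=norm_t,
        median_iterations=float(np.median(iters)),
        degenerate_std=degenerate,
        feature_names=list(data.feature_names),
    )
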