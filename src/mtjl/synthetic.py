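"""Synthetic multi-trial eye-tracking cohort generator with known ground truth.

The generator emulates the structure of the reading study the package models:
74 participants split into high/low reading-ability groups, 42 sentence-reading
trials, 16 eye-tracking indicators plus 3 entrance-exam scores (D = 19),
reading scores spanning 48.8-90.83 points, group mean shifts on the sensitive
indicators, sporadic missing blink values, and an exactly rank-r ground-truth
weight matrix W*.

Generative mechanism
--------------------
Each participant has a stable standardized indicator profile ``Z`` (N x D,
unit variance, group-shifted on sensitive indicators). Each trial observes
that profile plus trial-level noise::

    S[n, i, d] = Z[n, d] + trial_noise_frac[d] * E[n, i, d]
    X[n, i, d] = loc[d] + scale[d] * S[n, i, d]

Exam-score features have zero trial noise (they do not vary across trials).
Scores follow the multi-trial linear model on the standardized features::

    Y = mean_i(S_i w*_i + b*_i) + Normal(0, noise_sd)

and are then affinely min-max mapped onto ``score_range``; W*, b* and the
noise realisation are rescaled by the same map, so the generative identity
holds exactly on the reported score scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .dataset import MultiTrialDataset
from .screening import infer_family

__all__ = [
    "FeatureSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_features",
    "generate_cohort",
    "inject_missing",
    "impute_missing",
    "align_weights_to_truth",
]


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    """One simulated indicator.

    loc/scale set the raw measurement units; ``group_effect`` is the signed
    high-minus-low group mean shift in within-group SD units; ``weight`` is
    the feature's relative (signed) contribution to the true score signal;
    ``trial_noise`` is the SD of trial-to-trial variation relative to the
    between-participant SD.
    """

    name: str
    family: str
    unit: str
    loc: float
    scale: float
    group_effect: float = 0.0
    weight: float = 0.0
    trial_noise: float = 0.04


def default_features() -> list[FeatureSpec]:
    """16 eye-tracking indicators + 3 exam scores on study-like scales.

    Locations and scales are plausible magnitudes for the instruments involved
    (pupil size in eye-camera pixels, durations in ms, rates per second,
    amplitudes in visual degrees, exam scores in points); weights echo the
    qualitative contribution ordering reported for the study (fixation rate,
    saccade rate and the Chinese exam score strongest; blink indicators,
    fixation position Y, regression length and reading duration near zero).
    """
    f = FeatureSpec
    return [
        f("pupil diameter", "pupil", "pixels", 1200, 150, -1.0, -0.07),
        f("blink count", "blink", "count", 1.2, 0.8, -1.0, -0.005),
        f("blink rate", "blink", "per s", 0.25, 0.12, -1.0, -0.02),
        f("fixation count", "fixation", "count", 10, 3, -1.0, -0.06),
        f("fixation rate", "fixation", "per s", 3.2, 0.8, -1.0, -0.11),
        f("fixation duration", "fixation", "ms", 240, 50, -1.0, -0.07),
        f("fixation position X", "fixation", "pixels", 512, 90, -1.0, -0.055),
        f("fixation position Y", "fixation", "pixels", 384, 40, 0.0, 0.002),
        f("saccade count", "saccade", "count", 9, 3, -1.0, -0.055),
        f("saccade rate", "saccade", "per s", 2.8, 0.9, -1.0, -0.105),
        f("saccade duration", "saccade", "ms", 45, 10, -1.0, -0.05),
        f("saccade amplitude", "saccade", "deg", 2.1, 0.5, 1.0, 0.055),
        f("regression count", "regression", "count", 2.5, 1.2, -1.0, -0.08),
        f("regression rate", "regression", "per s", 0.5, 0.2, -1.0, -0.085),
        f("regression length", "regression", "pixels", 150, 60, 0.0, -0.01),
        f("reading duration", "other", "ms", 3500, 900, 0.0, -0.005),
        f("chinese exam score", "exam", "points", 105, 15, 1.2, 0.12, 0.0),
        f("math exam score", "exam", "points", 95, 18, 0.3, 0.02, 0.0),
        f("english exam score", "exam", "points", 100, 16, 0.8, 0.06, 0.0),
    ]


@dataclasses.dataclass
class SyntheticConfig:
    """Cohort dimensions, scales and ground-truth structure."""

    n_participants: int = 74
    n_trials: int = 42
    features: list[FeatureSpec] = dataclasses.field(default_factory=default_features)
    true_rank: int = 2
    noise_sd: float = 0.5                # score points (nominal, pre-mapping)
    score_range: tuple[float, float] = (48.8, 90.83)
    signal_sd: float = 12.0              # within-group score-signal spread
    trial_variation: float = 0.015       # relative size of trial-varying weight part
    bias_jitter: float = 0.3             # SD of per-trial true intercept jitter
    missing_fraction: float = 0.1
    missing_families: tuple[str, ...] = ("blink",)
    seed: int | None = None

    def __post_init__(self) -> None:
        d, m = len(self.features), self.n_trials
        if not (1 <= self.true_rank <= min(d, m)):
            raise ValueError(
                f"true_rank must be in [1, min(D={d}, m={m})], got {self.true_rank}"
            )
        if self.true_rank > 1 and self.trial_variation <= 0:
            raise ValueError("trial_variation must be > 0 when true_rank > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        lo, hi = self.score_range
        if not (0 <= lo < hi <= 100):
            raise ValueError("score_range must be within [0, 100] with lo < hi")
        if self.n_participants < 2 or self.n_trials < 1:
            raise ValueError("need n_participants >= 2 and n_trials >= 1")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def families(self) -> dict[str, str]:
        return {f.name: f.family for f in self.features}

    def shifted_features(self, min_shift: float = 1.0) -> list[str]:
        return [f.name for f in self.features if abs(f.group_effect) >= min_shift]

    def null_features(self) -> list[str]:
        return [f.name for f in self.features if f.group_effect == 0.0]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort, on the final score scale."""

    W_star: np.ndarray           # D x m, rank exactly `rank`
    b_star: np.ndarray           # length m
    rank: int
    group_labels: np.ndarray     # length N, 1 = high ability
    noise: np.ndarray            # realized score noise, length N
    noise_sd_nominal: float
    map_scale: float             # slope of the affine map onto score_range
    map_offset: float
    feature_locs: np.ndarray     # length D
    feature_scales: np.ndarray   # length D
    trial_noise_frac: np.ndarray  # length D


def _ground_truth_weights(cfg: SyntheticConfig, rng: np.random.Generator):
    """Rank-r W* = (dominant shared profile) + small trial-varying parts."""
    w = np.array([f.weight for f in cfg.features], dtype=float)
    if not np.any(w):
        raise ValueError("at least one feature must have a nonzero weight")
    u = w / np.linalg.norm(w) * cfg.signal_sd
    m = cfg.n_trials
    W = np.outer(u, np.ones(m))
    basis = [u / np.linalg.norm(u)]
    for _ in range(cfg.true_rank - 1):
        # direction orthogonal to everything so far
        while True:
            v = rng.standard_normal(len(u))
            for q in basis:
                v -= (v @ q) * q
            nv = np.linalg.norm(v)
            if nv > 1e-8:
                v /= nv
                break
        basis.append(v)
        while True:
            c = rng.standard_normal(m)
            c -= c.mean()
            nc = np.linalg.norm(c)
            if nc > 1e-8:
                c /= nc / np.sqrt(m)   # rms 1 across trials
                break
        W += cfg.trial_variation * np.linalg.norm(u) * np.outer(v, c)
    return W


def generate_cohort(cfg: SyntheticConfig | None = None, seed: int | None = None):
    """Draw a synthetic cohort and its ground truth.

    Returns ``(MultiTrialDataset, SyntheticTruth)``. Deterministic for a
    fixed seed (``seed`` argument overrides ``cfg.seed``).
    """
    cfg = cfg or SyntheticConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n, m, d = cfg.n_participants, cfg.n_trials, cfg.n_features

    # balanced high/low groups (within one when N is odd)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[: (n + 1) // 2]] = 1

    effects = np.array([f.group_effect for f in cfg.features])
    frac = np.array([f.trial_noise for f in cfg.features])
    locs = np.array([f.loc for f in cfg.features])
    scales = np.array([f.scale for f in cfg.features])

    Z = rng.standard_normal((n, d)) + (labels - 0.5)[:, None] * effects[None, :]
    S = Z[:, None, :] + frac[None, None, :] * rng.standard_normal((n, m, d))
    X = locs[None, None, :] + scales[None, None, :] * S

    W_star = _ground_truth_weights(cfg, rng)
    lo, hi = cfg.score_range
    center = 0.5 * (lo + hi)
    b_star = center + rng.normal(0.0, cfg.bias_jitter, m)

    preds = np.einsum("nid,di->ni", S, W_star) + b_star[None, :]
    eps = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)
    Y0 = preds.mean(axis=1) + eps

    ptp = Y0.max() - Y0.min()
    if ptp < 1e-12:
        a, c = 1.0, center - Y0[0]
    else:
        a = (hi - lo) / ptp
        c = lo - a * Y0.min()
    Y = a * Y0 + c
    W_star = a * W_star
    b_star = a * b_star + c
    eps = a * eps

    data = MultiTrialDataset(
        values=X,
        scores=Y,
        feature_names=cfg.feature_names(),
        participant_ids=[f"p{i:03d}" for i in range(n)],
    )
    truth = SyntheticTruth(
        W_star=W_star, b_star=b_star, rank=cfg.true_rank,
        group_labels=labels, noise=eps, noise_sd_nominal=cfg.noise_sd,
        map_scale=a, map_offset=c,
        feature_locs=locs, feature_scales=scales, trial_noise_frac=frac,
    )
    if cfg.missing_fraction > 0:
        data = inject_missing(
            data, cfg.missing_fraction, cfg.missing_families,
            rng=rng, families=cfg.families(),
        )
    return data, truth


def inject_missing(
    data: MultiTrialDataset,
    fraction: float,
    target_families: tuple[str, ...] = ("blink",),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    families: dict[str, str] | None = None,
) -> MultiTrialDataset:
    """Mark a random fraction of cells in the target-family columns missing.

    Each eligible cell is dropped independently with probability ``fraction``
    (Bernoulli). Columns of other families are never touched.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    fam_of = families or {name: infer_family(name) for name in data.feature_names}
    known = set(fam_of.values())
    for fam in target_families:
        if fam not in known:
            raise ValueError(
                f"unknown feature family {fam!r}; families present: {sorted(known)}"
            )
    out = data.copy()
    if fraction == 0:
        return out
    rng = rng if rng is not None else np.random.default_rng(seed)
    cols = [j for j, name in enumerate(data.feature_names)
            if fam_of.get(name) in target_families]
    drop = rng.random((data.n_participants, data.n_trials, len(cols))) < fraction
    for k, j in enumerate(cols):
        out.missing_mask[:, :, j] |= drop[:, :, k]
        out.values[:, :, j] = np.where(drop[:, :, k], np.nan, out.values[:, :, j])
    return out


def impute_missing(
    data: MultiTrialDataset,
    strategy: str = "train_mean",
    stats: dict[str, np.ndarray] | None = None,
) -> MultiTrialDataset:
    """Fill every masked cell and clear the mask.

    strategy='train_mean' replaces a missing cell by its trial-feature column
    mean — computed from the observed cells of ``data`` itself, or taken from
    ``stats['mean']`` (shape (n_trials, n_features)) when evaluating a
    held-out fold with training statistics.
    strategy='zero_after_normalization' sets missing cells to 0 and requires
    z-scored data (the two are equivalent on normalized data).
    """
    out = data.copy()
    if not out.has_missing:
        out.missing_mask[:] = False
        return out
    if strategy == "zero_after_normalization":
        if not data.normalized and stats is None:
            raise ValueError(
                "zero_after_normalization requires normalized data or explicit stats"
            )
        fill = np.zeros((data.n_trials, data.n_features))
    elif strategy == "train_mean":
        if stats is not None:
            fill = np.asarray(stats["mean"], dtype=float)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fill = np.nanmean(
                    np.where(out.missing_mask, np.nan, out.values), axis=0
                )
            bad = np.argwhere(np.isnan(fill))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"column {data.feature_names[j]!r} of trial {i} is entirely "
                    f"missing; cannot impute from its own mean"
                )
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    idx = np.nonzero(out.missing_mask)
    out.values[idx] = fill[idx[1], idx[2]]
    out.missing_mask[:] = False
    return out


def align_weights_to_truth(model, truth: SyntheticTruth) -> np.ndarray:
    """Express a fitted weight matrix on the generator's standardized scale.

    The model was fitted on per-trial z-scored features; the ground truth
    W* acts on the generator's population-standardized features
    ``(x - loc) / scale``. Converting with the model's stored normalization
    statistics makes the two directly comparable.
    """
    stats = model.normalization_stats_
    # coefficient on (x - loc)/scale: w_fit * scale_d / sigma_fit[i, d]
    return model.W_ * (truth.feature_scales[:, None] / stats["scale"].T)
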