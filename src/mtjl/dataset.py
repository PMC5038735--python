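"""Multi-trial dataset container.

A cohort of N participants, each of whom completed m sentence-reading trials.
Every trial yields one row of D indicator values per participant, so the cohort
is a tensor of shape ``(n_participants, n_trials, n_features)`` together with a
single reading-ability score per participant on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MultiTrialDataset"]

SCORE_MIN = 0.0
SCORE_MAX = 100.0


@dataclass
class MultiTrialDataset:
    """Per-trial feature matrices with a shared score vector.

    Parameters
    ----------
    values : ndarray of shape (n_participants, n_trials, n_features)
        Indicator values. Cells flagged in ``missing_mask`` may be NaN.
    scores : ndarray of shape (n_participants,)
        Reading-ability scores, points on the 0-100 scale.
    feature_names : list of str
        One label per feature column.
    participant_ids : list of str
        One label per participant row.
    missing_mask : ndarray of bool, same shape as ``values``
        True where the value is absent.
    normalized : bool
        Whether the values have already been z-scored.
    """

    values: np.ndarray
    scores: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    participant_ids: list[str] = field(default_factory=list)
    missing_mask: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be 3-d (participants, trials, features); "
                f"got shape {self.values.shape}"
            )
        n, m, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 participants, got {n}")
        if m < 1 or d < 1:
            raise ValueError(f"need m >= 1 trials and D >= 1 features, got {m}, {d}")
        if self.scores.shape != (n,):
            raise ValueError(
                f"scores must have length {n}, got shape {self.scores.shape}"
            )
        if np.any(~np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if np.any(self.scores < SCORE_MIN) or np.any(self.scores > SCORE_MAX):
            bad = int(np.argmax((self.scores < SCORE_MIN) | (self.scores > SCORE_MAX)))
            raise ValueError(
                f"score {self.scores[bad]} for participant index {bad} is outside "
                f"[{SCORE_MIN}, {SCORE_MAX}]"
            )
        if not self.feature_names:
            self.feature_names = [f"feature_{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match n_features")
        if not self.participant_ids:
            self.participant_ids = [f"p{i:03d}" for i in range(n)]
        if len(self.participant_ids) != n:
            raise ValueError("participant_ids length does not match n_participants")
        if len(set(self.participant_ids)) != n:
            raise ValueError("participant_ids contain duplicates")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        # NaN cells are missing by definition, whatever the caller said.
        self.missing_mask = self.missing_mask | np.isnan(self.values)

    # -- shape accessors ---------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def trial_matrix(self, i: int) -> np.ndarray:
        """The N x D feature matrix of trial ``i``."""
        return self.values[:, i, :]

    @property
    def trial_matrices(self) -> list[np.ndarray]:
        return [self.values[:, i, :] for i in range(self.n_trials)]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    # -- manipulation ------------------------------------------------------
    def subset(self, indices: np.ndarray) -> "MultiTrialDataset":
        """Participant-level subset; all trials of a participant stay together."""
        indices = np.asarray(indices)
        return MultiTrialDataset(
            values=self.values[indices].copy(),
            scores=self.scores[indices].copy(),
            feature_names=list(self.feature_names),
            participant_ids=[self.participant_ids[int(i)] for i in indices],
            missing_mask=self.missing_mask[indices].copy(),
            normalized=self.normalized,
        )

    def copy(self) -> "MultiTrialDataset":
        return replace(
            self,
            values=self.values.copy(),
            scores=self.scores.copy(),
            feature_names=list(self.feature_names),
            participant_ids=list(self.participant_ids),
            missing_mask=self.missing_mask.copy(),
        )
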