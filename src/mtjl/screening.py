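"""One-way ANOVA screening of eye-tracking indicators.

Each indicator is tested for a mean difference between the high- and
low-reading-ability groups; indicators with p below the significance level are
flagged "sensitive". By default indicator values are aggregated to one value
per participant (mean across trials) before testing, to avoid treating
repeated trials of the same participant as independent observations.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import MultiTrialDataset

__all__ = ["AnovaResult", "anova_f", "screen_indicators", "infer_family"]

FAMILIES = ("pupil", "blink", "fixation", "saccade", "regression")


class AnovaResult(NamedTuple):
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


def anova_f(groups: Sequence[np.ndarray]) -> AnovaResult:
    """One-way ANOVA F statistic and p-value across >= 2 groups.

    Degenerate inputs are resolved explicitly: all observations identical
    gives (F=0, p=1); zero within-group variance with distinct group means
    gives (F=inf, p=0) with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    k = len(groups)
    n = sum(g.size for g in groups)
    df_b, df_w = k - 1, n - k

    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)

    if ss_within <= 0:
        if ss_between <= 0:
            return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
        warnings.warn(
            "zero within-group variance with distinct group means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return AnovaResult(float("inf"), 0.0, df_b, df_w, degenerate=True)
    if ss_between <= 0:
        return AnovaResult(0.0, 1.0, df_b, df_w)

    F, p = scipy.stats.f_oneway(*groups)
    return AnovaResult(float(F), float(p), df_b, df_w)


def infer_family(name: str) -> str:
    """Map an indicator name to its family (pupil/blink/fixation/saccade/
    regression), falling back to 'other'."""
    low = name.lower()
    for fam in FAMILIES:
        if fam in low:
            return fam
    return "other"


def screen_indicators(
    data: MultiTrialDataset,
    group_labels: np.ndarray,
    alpha: float = 0.05,
    aggregate: str = "mean",
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Screen every feature of a cohort for between-group sensitivity.

    Parameters
    ----------
    data : MultiTrialDataset
    group_labels : binary array of length n_participants (1 = high ability).
    alpha : significance level; sensitive <=> p < alpha.
    aggregate : 'mean' (per-participant mean across trials, default) or
        'per_trial' (every trial observation enters the ANOVA).
    families : optional explicit name -> family mapping.

    Returns
    -------
    DataFrame with columns indicator, family, F, p, df_between, df_within,
    sensitive, degenerate — one row per feature.
    """
    labels = np.asarray(group_labels).astype(int)
    if labels.shape != (data.n_participants,):
        raise ValueError("group_labels must have one entry per participant")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two non-empty groups are required")
    if aggregate not in ("mean", "per_trial"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    vals = np.where(data.missing_mask, np.nan, data.values)
    rows = []
    for d, name in enumerate(data.feature_names):
        col = vals[:, :, d]                      # (N, m)
        if aggregate == "mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_part = np.nanmean(col, axis=1)
            groups = [per_part[labels == g] for g in uniq]
            groups = [g[~np.isnan(g)] for g in groups]
        else:
            groups = [col[labels == g].ravel() for g in uniq]
            groups = [g[~np.isnan(g)] for g in groups]
        fam = (families or {}).get(name, infer_family(name))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = anova_f(groups)
        sensitive = bool(res.p < alpha) and not (res.degenerate and res.F == 0)
        if res.degenerate and res.F == 0:
            warnings.warn(
                f"indicator {name!r} is constant; marked non-sensitive",
                RuntimeWarning,
                stacklevel=2,
            )
        rows.append(
            dict(
                indicator=name, family=fam, F=res.F, p=res.p,
                df_between=res.df_between, df_within=res.df_within,
                sensitive=sensitive, degenerate=res.degenerate,
            )
        )
    return pd.DataFrame(rows)
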