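"""Reading and writing cohort tables, models and reports.

Cohorts live as one CSV per trial (``trial_000.csv`` ... with a
``participant_id`` column followed by feature columns; empty cells are
missing values) plus a ``scores.csv`` with columns ``participant_id,score``.
Models and evaluation reports are JSON documents that embed the
configuration and seed that produced them.
"""

from __future__ import annotations

import glob
import json
import os

import numpy as np
import pandas as pd

from .dataset import MultiTrialDataset
from .estimator import MTJLRegressor
from .evaluation import EvaluationReport

__all__ = [
    "write_cohort",
    "read_feature_tables",
    "save_model",
    "load_model",
    "write_screening_table",
    "write_report",
]


def write_cohort(
    data: MultiTrialDataset,
    outdir: str,
    truth=None,
    config: dict | None = None,
) -> None:
    """Write one CSV per trial, a score table, and an optional ground-truth
    sidecar JSON."""
    os.makedirs(outdir, exist_ok=True)
    for i in range(data.n_trials):
        mat = np.where(data.missing_mask[:, i, :], np.nan, data.values[:, i, :])
        df = pd.DataFrame(mat, columns=data.feature_names)
        df.insert(0, "participant_id", data.participant_ids)
        df.to_csv(os.path.join(outdir, f"trial_{i:03d}.csv"), index=False)
    scores = pd.DataFrame(
        {"participant_id": data.participant_ids, "score": data.scores}
    )
    scores.to_csv(os.path.join(outdir, "scores.csv"), index=False)
    if truth is not None:
        sidecar = {
            "synthetic": True,
            "W_star": truth.W_star.tolist(),
            "b_star": truth.b_star.tolist(),
            "rank": truth.rank,
            "group_labels": truth.group_labels.tolist(),
            "noise_sd_nominal": truth.noise_sd_nominal,
            "map_scale": truth.map_scale,
            "map_offset": truth.map_offset,
            "feature_locs": truth.feature_locs.tolist(),
            "feature_scales": truth.feature_scales.tolist(),
        }
        if config is not None:
            sidecar["config"] = config
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
    if config is not None:
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(config, fh, indent=1)


def _read_one_table(path: str):
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'participant_id' column")
    ids = df["participant_id"].astype(str).tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicate participant id {dup.iloc[0]!r} "
            f"(row {int(dup.index[0]) + 2})"
        )
    feats = [c for c in df.columns if c != "participant_id"]
    numeric = {}
    for col in feats:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 2}"
            )
        numeric[col] = coerced.to_numpy(dtype=float)
    return ids, feats, numeric


def read_feature_tables(
    path: str,
    scores_path: str | None = None,
) -> MultiTrialDataset:
    """Load a cohort from per-trial CSVs.

    ``path`` is a directory containing ``trial_*.csv`` and ``scores.csv``,
    or a glob pattern of trial tables (in which case ``scores_path`` is
    required). Participant identity is joined on ``participant_id``; row
    order in the files is not trusted. Empty cells become missing-mask
    entries.
    """
    if os.path.isdir(path):
        trial_paths = sorted(glob.glob(os.path.join(path, "trial_*.csv")))
        scores_path = scores_path or os.path.join(path, "scores.csv")
    else:
        trial_paths = sorted(glob.glob(path))
    if not trial_paths:
        raise ValueError(f"no trial tables found under {path!r}")
    if scores_path is None or not os.path.exists(scores_path):
        raise ValueError(f"score table not found (looked for {scores_path!r})")

    sdf = pd.read_csv(scores_path)
    for col in ("participant_id", "score"):
        if col not in sdf.columns:
            raise ValueError(f"{scores_path}: missing required column {col!r}")
    sdf["participant_id"] = sdf["participant_id"].astype(str)
    if sdf["participant_id"].duplicated().any():
        bad = sdf.loc[sdf["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"{scores_path}: duplicate participant id {bad!r}")
    scores = pd.to_numeric(sdf["score"], errors="coerce")
    if scores.isna().any():
        row = int(np.flatnonzero(scores.isna())[0])
        raise ValueError(f"{scores_path}: non-numeric score in row {row + 2}")
    out_of_range = (scores < 0) | (scores > 100)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0])
        raise ValueError(
            f"{scores_path}: score {scores.iloc[row]} outside [0, 100] "
            f"in row {row + 2}"
        )
    participant_ids = sdf["participant_id"].tolist()
    id_index = {pid: i for i, pid in enumerate(participant_ids)}

    tensors = []
    feature_names: list[str] | None = None
    for tp in trial_paths:
        ids, feats, numeric = _read_one_table(tp)
        if feature_names is None:
            feature_names = feats
        elif feats != feature_names:
            raise ValueError(f"{tp}: feature columns differ from the first trial table")
        if set(ids) != set(participant_ids):
            missing = set(participant_ids) ^ set(ids)
            raise ValueError(
                f"{tp}: participant set differs from the score table "
                f"(e.g. {sorted(missing)[:3]})"
            )
        mat = np.full((len(participant_ids), len(feats)), np.nan)
        rows = np.array([id_index[pid] for pid in ids])
        for j, col in enumerate(feats):
            mat[rows, j] = numeric[col]
        tensors.append(mat)

    values = np.stack(tensors, axis=1)  # (N, m, D)
    return MultiTrialDataset(
        values=values,
        scores=scores.to_numpy(dtype=float),
        feature_names=feature_names or [],
        participant_ids=participant_ids,
    )


def save_model(model: MTJLRegressor, path: str, extra: dict | None = None) -> None:
    """Serialize a fitted model to a JSON document."""
    doc = {
        "model": "MTJLRegressor",
        "params": model.get_params(),
        "W": model.W_.tolist(),                       # row-major, D x m
        "b": model.b_.tolist(),
        "feature_names": model.feature_names_,
        "n_trials": model.n_trials_,
        "normalization_stats": {
            "mean": model.normalization_stats_["mean"].tolist(),
            "scale": model.normalization_stats_["scale"].tolist(),
        },
        "objective_trace": model.objective_trace_,
        "n_iter": model.n_iter_,
        "converged": model.converged_,
    }
    if extra:
        doc.update(extra)
    if model.get_params().get("clip") is not None:
        doc["params"]["clip"] = list(doc["params"]["clip"])
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> MTJLRegressor:
    """Reconstruct a fitted model from :func:`save_model` output."""
    with open(path) as fh:
        doc = json.load(fh)
    params = doc["params"]
    if params.get("clip") is not None:
        params["clip"] = tuple(params["clip"])
    model = MTJLRegressor(**params)
    model.W_ = np.asarray(doc["W"], dtype=float)
    model.b_ = np.asarray(doc["b"], dtype=float)
    model.feature_names_ = doc["feature_names"]
    model.n_trials_ = int(doc["n_trials"])
    model.n_features_in_ = model.W_.shape[0]
    model.normalization_stats_ = {
        "mean": np.asarray(doc["normalization_stats"]["mean"], dtype=float),
        "scale": np.asarray(doc["normalization_stats"]["scale"], dtype=float),
    }
    model.objective_trace_ = doc["objective_trace"]
    model.n_iter_ = int(doc["n_iter"])
    model.converged_ = bool(doc["converged"])
    return model


def write_screening_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def write_report(report: EvaluationReport, path: str, extra: dict | None = None) -> None:
    """Evaluation report as JSON; per-run errors also as a flat CSV next to it."""
    doc = report.to_dict()
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    base, _ = os.path.splitext(path)
    pd.DataFrame(
        {"split_seed": report.split_seeds, "error": report.per_run_error}
    ).to_csv(base + "_runs.csv", index=False)
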