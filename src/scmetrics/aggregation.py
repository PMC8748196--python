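"""Metric aggregation, cross-task ranking, and scalability/usability scores.

Raw metric values live in a runs x metrics table per integration task (one
row per method x preprocessing x output-type combination, including an
unintegrated reference row).  Within a task every metric column is min-max
scaled, category means give the bio-conservation and batch-removal partial
scores, and the overall score is their fixed 0.6/0.4 weighted combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .core import ALL_METRICS, BATCH_METRICS, BIO_METRICS, ParameterError

#: weights of the overall score
BIO_WEIGHT, BATCH_WEIGHT = 0.6, 0.4

# scalability AUC bounds: cell-count range and ceiling per resource
SCALABILITY_A, SCALABILITY_B = 1e4, 1e6
SCALABILITY_CEILING = {"time": 1e8, "memory": 1e7}  # seconds / MB


def minmax_scale(column: pd.Series) -> pd.Series:
    """f(Y) = (Y - min) / (max - min), computed over the non-missing
    entries of a metric column; missing values stay missing.  A constant
    column is set to 0 with a warning."""
    vals = column.astype(float)
    present = vals.dropna()
    lo, hi = present.min(), present.max()
    if len(present) < 2 or hi <= lo:
        if len(present):
            warnings.warn(
                f"metric column {column.name!r} is constant; scaled values set to 0"
            )
        return vals.where(vals.isna(), 0.0)
    return (vals - lo) / (hi - lo)


def scale_results(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each metric column within one task's results table."""
    return raw.apply(minmax_scale, axis=0)


def combine_partial_scores(s_bio: float, s_batch: float) -> float:
    """Overall score = 0.6 x bio-conservation + 0.4 x batch-removal."""
    return BIO_WEIGHT * s_bio + BATCH_WEIGHT * s_batch


def partial_scores(row: pd.Series) -> tuple[Optional[float], Optional[float]]:
    """Category means over the metrics computed for a run, irrespective of
    how many metrics were computed."""

    def _mean(names: Sequence[str]) -> Optional[float]:
        vals = [row[m] for m in names if m in row.index and pd.notna(row[m])]
        return float(np.mean(vals)) if vals else None

    return _mean(BIO_METRICS), _mean(BATCH_METRICS)


def overall_scores(raw: pd.DataFrame, scale: bool = True) -> pd.DataFrame:
    """Partial and overall scores for every run in a task table.

    Columns of ``raw`` are metric names; unknown columns are ignored.
    Returns a frame with ``bio_score``, ``batch_score``, ``overall_score``.
    """
    known = [c for c in raw.columns if c in ALL_METRICS]
    table = scale_results(raw[known]) if scale else raw[known]
    rows = {}
    for run, row in table.iterrows():
        s_bio, s_batch = partial_scores(row)
        overall = (
            combine_partial_scores(s_bio, s_batch)
            if s_bio is not None and s_batch is not None
            else None
        )
        rows[run] = {
            "bio_score": s_bio,
            "batch_score": s_batch,
            "overall_score": overall,
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(raw.index)


def rank_methods(
    task_tables: dict,
    unintegrated: str = "Unintegrated",
) -> pd.DataFrame:
    """Cross-task method ranking from per-task overall scores.

    Each table must have ``method`` and ``overall_score`` columns (one row
    per run).  Per task, each method is represented by its best-scoring
    preprocessing/output combination, methods are ranked (rank 1 = best,
    ties averaged), and methods absent from a task inherit the rank of the
    unintegrated reference.  Methods are ordered by mean rank across tasks.
    """
    per_task_ranks = {}
    all_methods: set = set()
    for task, table in task_tables.items():
        if unintegrated not in set(table["method"]):
            raise ParameterError(f"task {task!r} lacks an unintegrated row")
        best = (
            table.dropna(subset=["overall_score"])
            .groupby("method")["overall_score"]
            .max()
        )
        ranks = pd.Series(
            rankdata(-best.to_numpy(), method="average"), index=best.index
        )
        per_task_ranks[task] = ranks
        all_methods |= set(ranks.index)
    out = {}
    for m in sorted(all_methods - {unintegrated}):
        row = {}
        present_somewhere = False
        for task, ranks in per_task_ranks.items():
            if m in ranks.index:
                row[task] = float(ranks[m])
                present_somewhere = True
            else:
                row[task] = float(ranks[unintegrated])
        if not present_somewhere:
            warnings.warn(f"method {m!r} absent from all tasks; excluded")
            continue
        out[m] = row
    df = pd.DataFrame.from_dict(out, orient="index")
    df["mean_rank"] = df.mean(axis=1)
    return df.sort_values("mean_rank")


def compare_scaling_schemes(raw: pd.DataFrame) -> float:
    """Spearman rank correlation of overall-score rankings obtained with
    min-max scaling versus z-score scaling of the metric columns."""
    known = [c for c in raw.columns if c in ALL_METRICS]
    zscored = raw[known].apply(
        lambda col: (col - col.mean()) / col.std(ddof=0)
        if col.std(ddof=0) > 0
        else col * 0.0,
        axis=0,
    )
    o_minmax = overall_scores(raw, scale=True)["overall_score"]
    o_z = overall_scores(zscored, scale=False)["overall_score"]
    keep = o_minmax.notna() & o_z.notna()
    return float(spearmanr(o_minmax[keep], o_z[keep]).statistic)


# ---------------------------------------------------------------- scalability


@dataclass
class ScalabilityRecord:
    """One benchmark run's resource footprint."""

    n_cells: int
    n_features: int
    cpu_time: float  # seconds
    peak_mem: float  # MB

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_features) <= 0 or min(self.cpu_time, self.peak_mem) <= 0:
            raise ParameterError("scalability record values must be positive")


def loglinear_fit(n_cells: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Fit f(x) = a log(x) + b to log-scaled resource use."""
    x = np.log(np.asarray(n_cells, float))
    y = np.log(np.asarray(values, float))
    if len(np.unique(x)) < 2:
        raise ParameterError("need records at >= 2 distinct cell numbers")
    a, b = np.polyfit(x, y, 1)
    return float(a), float(b)


def scalability_score(
    n_cells: Sequence[float],
    values: Sequence[float],
    resource: str,
) -> float:
    """1 minus the scaled area under the log-linear resource curve.

    The fitted curve f is integrated (trapezoid, exact for a line) between
    A = 1e4 and 1e6 cells and scaled by the rectangle of height log(C)
    covering all curves (C = 1e8 s for time, 1e7 MB for memory):
    AUC_scaled = (f(A) + f(B)) / (2 log C); score = 1 - AUC_scaled.
    """
    if resource not in SCALABILITY_CEILING:
        raise ParameterError(f"resource must be one of {sorted(SCALABILITY_CEILING)}")
    a, b = loglinear_fit(n_cells, values)
    f_a = a * np.log(SCALABILITY_A) + b
    f_b = a * np.log(SCALABILITY_B) + b
    auc_scaled = 0.5 * (f_a + f_b) / np.log(SCALABILITY_CEILING[resource])
    return float(np.clip(1.0 - auc_scaled, 0.0, 1.0))


def scalability_scores(records: Sequence[ScalabilityRecord]) -> dict:
    """Time and memory scalability scores from a set of runs."""
    n = [r.n_cells for r in records]
    return {
        "time": scalability_score(n, [r.cpu_time for r in records], "time"),
        "memory": scalability_score(n, [r.peak_mem for r in records], "memory"),
    }


def feature_scaling_fit(
    n_cells: Sequence[float],
    n_features: Sequence[float],
    values: Sequence[float],
) -> tuple[float, float, float]:
    """OLS fit of log(resource) = b0 + b1 log(N) + b2 log(F)."""
    x = np.column_stack(
        [
            np.ones(len(values)),
            np.log(np.asarray(n_cells, float)),
            np.log(np.asarray(n_features, float)),
        ]
    )
    if len(values) < 3 or np.linalg.matrix_rank(x) < 3:
        raise ParameterError(
            "need >= 3 records spanning both cell and feature counts (collinear design)"
        )
    y = np.log(np.asarray(values, float))
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(beta[0]), float(beta[1]), float(beta[2])


# ------------------------------------------------------------------ usability


@dataclass
class UsabilityRecord:
    """Hand-collected usability categories plus GitHub statistics."""

    package_categories: Sequence[float] = field(default_factory=list)
    paper_categories: Sequence[float] = field(default_factory=list)
    closed_issues: int = 0
    repo_age_years: float = 1.0
    median_response_days: float = 0.0

    def __post_init__(self) -> None:
        for v in list(self.package_categories) + list(self.paper_categories):
            if not 0.0 <= v <= 1.0:
                raise ParameterError("category scores must lie in [0, 1]")
        if self.closed_issues < 0 or self.median_response_days < 0:
            raise ParameterError("GitHub statistics must be nonnegative")


def activity_score(closed_issues: int, repo_age_years: float) -> float:
    """Issue activity = log10(closed issues / repository age in years + 1)."""
    if repo_age_years <= 0:
        raise ParameterError("repository age must be positive")
    return float(np.log10(closed_issues / repo_age_years + 1.0))


def response_score(median_response_days: float) -> float:
    """Issue responsiveness = 30 - median days until first response, so
    any repository answering within a month scores positive."""
    return 30.0 - float(median_response_days)


def _rescale(s: pd.Series) -> pd.Series:
    lo, hi = s.min(), s.max()
    if hi <= lo:
        return s.where(s.isna(), 0.0)
    return (s - lo) / (hi - lo)


def usability_table(records: dict) -> pd.DataFrame:
    """Usability scores for a set of methods.

    Activity and response are computed per the printed formulas, then
    min-max rescaled across methods; the package and paper scores are the
    means of their category scores, and the final usability score is their
    sum.
    """
    rows = {}
    for name, rec in records.items():
        rows[name] = {
            "activity_raw": activity_score(rec.closed_issues, rec.repo_age_years),
            "response_raw": response_score(rec.median_response_days),
            "package_score": float(np.mean(rec.package_categories))
            if len(rec.package_categories)
            else np.nan,
            "paper_score": float(np.mean(rec.paper_categories))
            if len(rec.paper_categories)
            else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["activity"] = _rescale(df["activity_raw"])
    df["response"] = _rescale(df["response_raw"])
    df["usability"] = df["package_score"] + df["paper_score"]
    return df
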