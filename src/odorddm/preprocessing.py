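"""Session exclusion, reaction-time normalization, behavioral curves.

Sessions are excluded when they were training sessions (complexity
b < 0.5) or when overall accuracy fell below 70%.  To remove
between-session variation in reaction times (spout positioning etc.),
each session's RTs are divided by the session mean and multiplied back
by the grand mean across sessions, so normalized RTs keep meaningful
units while every session contributes on the same scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .params import TARGET_ON
from .task import REPORT_PRESENT

__all__ = [
    "SessionFilter",
    "RTNormalizer",
    "session_summaries",
    "filter_sessions",
    "normalize_reaction_times",
    "behavioral_curves",
    "across_mouse_curves",
]

MIN_COMPLEXITY = 0.5
MIN_ACCURACY = 0.70

_SESSION_KEYS = ["mouse_id", "session_id"]


def session_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-session trial count, accuracy, mean raw RT, and kept flag."""
    g = trials.groupby(_SESSION_KEYS, sort=True)
    out = g.agg(
        b=("session_b", "first"),
        n_trials=("correct", "size"),
        accuracy=("correct", "mean"),
        mean_rt_raw=("rt_raw", "mean"),
    ).reset_index()
    out["kept"] = (out["b"] >= MIN_COMPLEXITY) & (out["accuracy"] >= MIN_ACCURACY)
    return out


class SessionFilter(BaseEstimator, TransformerMixin):
    """Drop training (b < 0.5) and low-performance (< 70%) sessions.

    ``fit`` computes per-session summaries; ``transform`` returns the
    trials of kept sessions only.  Thresholds are parameters so the
    filter composes with sklearn model selection, but the defaults are
    the study's rules.
    """

    def __init__(
        self,
        min_complexity: float = MIN_COMPLEXITY,
        min_accuracy: float = MIN_ACCURACY,
    ):
        self.min_complexity = min_complexity
        self.min_accuracy = min_accuracy

    def fit(self, X: pd.DataFrame, y=None):
        summaries = session_summaries(X)
        summaries["kept"] = (summaries["b"] >= self.min_complexity) & (
            summaries["accuracy"] >= self.min_accuracy
        )
        self.summaries_ = summaries
        self.n_dropped_ = int((~summaries["kept"]).sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept = self.summaries_.loc[self.summaries_["kept"], _SESSION_KEYS]
        merged = X.merge(kept, on=_SESSION_KEYS, how="inner")
        return merged.reset_index(drop=True)


class RTNormalizer(BaseEstimator, TransformerMixin):
    """Rescale RTs so every session shares the grand mean RT.

    rt_normalized = rt_raw / session_mean * grand_mean.  The grand mean
    is the unweighted mean of session means by default
    (``grand_mean="session"``); ``grand_mean="trial"`` weights sessions
    by their trial counts instead.  After transforming, every session's
    mean normalized RT equals the grand mean, and within-session rank
    order and ratios are untouched.
    """

    def __init__(self, grand_mean: str = "session"):
        self.grand_mean = grand_mean

    def fit(self, X: pd.DataFrame, y=None):
        if X.empty:
            raise ValueError("cannot normalize an empty trial table")
        if self.grand_mean not in ("session", "trial"):
            raise ValueError("grand_mean must be 'session' or 'trial'")
        means = X.groupby(_SESSION_KEYS)["rt_raw"].mean()
        if (means <= 0).any():
            raise ValueError("non-positive session mean RT")
        self.session_means_ = means
        if self.grand_mean == "session":
            self.grand_mean_ = float(means.mean())
        else:
            self.grand_mean_ = float(X["rt_raw"].mean())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        idx = pd.MultiIndex.from_frame(X[_SESSION_KEYS])
        if not idx.isin(self.session_means_.index).all():
            raise ValueError("trial table contains sessions unseen at fit time")
        sess_mean = self.session_means_.loc[idx].to_numpy()
        out = X.copy()
        out["rt_normalized"] = X["rt_raw"].to_numpy() / sess_mean * self.grand_mean_
        return out


def filter_sessions(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(kept trials, session summary table) under the study's rules."""
    flt = SessionFilter().fit(trials)
    return flt.transform(trials), flt.summaries_


def normalize_reaction_times(
    trials: pd.DataFrame, grand_mean: str = "session"
) -> pd.DataFrame:
    """Fill ``rt_normalized`` on kept trials (see RTNormalizer)."""
    return RTNormalizer(grand_mean=grand_mean).fit_transform(trials)


def _rt_column(trials: pd.DataFrame) -> str:
    if "rt_normalized" in trials and trials["rt_normalized"].notna().all():
        return "rt_normalized"
    return "rt_raw"


def behavioral_curves(trials: pd.DataFrame) -> pd.DataFrame:
    """Per mouse and condition: fraction "report present", mean RT, n.

    Empty cells are reported with n = 0 and NaN summaries.  Uses
    normalized RTs when present, raw RTs otherwise.
    """
    rt_col = _rt_column(trials)
    t = trials.assign(report_present=trials["choice"] == REPORT_PRESENT)
    cells = (
        t.groupby(["mouse_id", "trial_type", "n_background"])
        .agg(
            p_report_present=("report_present", "mean"),
            mean_rt=(rt_col, "mean"),
            n=("report_present", "size"),
        )
        .reset_index()
    )
    # make absent cells explicit per mouse
    full = []
    for mouse in cells["mouse_id"].unique():
        for trial_type, counts in ((TARGET_ON, range(6)), ("target_off", range(1, 7))):
            for n in counts:
                full.append((mouse, trial_type, n))
    grid = pd.DataFrame(full, columns=["mouse_id", "trial_type", "n_background"])
    out = grid.merge(cells, how="left", on=["mouse_id", "trial_type", "n_background"])
    out["n"] = out["n"].fillna(0).astype(int)
    return out


def across_mouse_curves(curves: pd.DataFrame) -> pd.DataFrame:
    """Mean of per-mouse curves per (trial type, background count)."""
    return (
        curves.groupby(["trial_type", "n_background"])
        .agg(
            p_report_present=("p_report_present", "mean"),
            mean_rt=("mean_rt", "mean"),
            n_mice=("mouse_id", "nunique"),
        )
        .reset_index()
    )
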