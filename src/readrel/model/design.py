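"""Build the fitting design from a long-format trial table.

The trial table has one row per subject x session x word with the response
and the raw predictor columns.  Building the design z-scores the predictors
over the full fitted dataset (both sessions pooled, population-sd
convention), attaches the session indicator with treatment coding (the first
session label in sort order is the reference level u), and — for spillover
fits — attaches each predictor's value at the previous word within the same
screen, dropping the first word of every screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spec import ModelSpec

__all__ = ["zscore", "DesignMatrixBundle", "build_design"]


def zscore(values, population: bool = True) -> np.ndarray:
    """Standardize to mean 0, sd 1 (population-sd convention by default)."""
    v = np.asarray(values, dtype=float)
    if np.unique(v[np.isfinite(v)]).size < 2:
        raise ValueError("cannot z-score a constant (or empty) column")
    sd = np.nanstd(v, ddof=0 if population else 1)
    return (v - np.nanmean(v)) / sd


@dataclass
class DesignMatrixBundle:
    """Arrays the likelihood consumes; rows are sorted by subject.

    ``delta_v`` is 1 on session-v rows and 0 on session-u rows (so
    ``delta_u = 1 - delta_v``); ``X`` holds the z-scored predictors in
    ``predictors`` order and ``X_lag`` the previous-word values (None when
    spillover is off).
    """

    subject_ids: np.ndarray
    subject_idx: np.ndarray
    delta_v: np.ndarray
    X: np.ndarray
    X_lag: np.ndarray | None
    y: np.ndarray
    predictors: tuple[str, ...]
    session_labels: tuple
    n_rows_u: int
    n_rows_v: int

    @property
    def n_rows(self) -> int:
        return self.y.size

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    def validate(self) -> None:
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite predictor values")
        if self.X_lag is not None and not np.isfinite(self.X_lag).all():
            raise ValueError("non-finite lagged predictor values")
        counts = np.bincount(self.subject_idx, minlength=self.n_subjects)
        if (counts == 0).any():
            raise ValueError("subject with no rows")


def _validate_response(y: pd.Series, family: str) -> tuple[pd.Series, int]:
    """Return a keep-mask-applied response and the number of dropped rows."""
    keep = y.notna()
    if family == "lognormal":
        bad = keep & (y <= 0)
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} non-positive responses for the "
                "lognormal family"
            )
        keep &= ~bad
    elif family == "bernoulli":
        vals = y[keep]
        if not vals.isin([0, 1]).all():
            raise ValueError("bernoulli responses must be 0/1")
    elif family == "zip":
        vals = y[keep]
        if (vals < 0).any() or (vals != vals.round()).any():
            raise ValueError("zip responses must be nonnegative integers")
    n_dropped = int((~keep).sum())
    return keep, n_dropped


def build_design(
    trials: pd.DataFrame,
    spec: ModelSpec,
    subject_col: str = "subject",
    session_col: str = "session",
    screen_col: str = "screen_id",
    word_col: str = "word_index",
    response_col: str = "response",
) -> DesignMatrixBundle:
    """Turn a long-format trial table into a :class:`DesignMatrixBundle`.

    Raises on more or fewer than two session labels or on family/response
    mismatch; subjects observed in only one session are dropped with a
    warning (their cross-session correlation is undefined).
    """
    needed = [subject_col, session_col, response_col, *spec.predictors]
    if spec.spillover:
        needed += [screen_col, word_col]
    missing = [c for c in needed if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")

    df = trials.copy()
    sessions = sorted(df[session_col].unique())
    if len(sessions) != 2:
        raise ValueError(
            f"expected exactly 2 session labels, found {len(sessions)}"
        )
    label_u, label_v = sessions

    # subjects must appear in both sessions
    per_subject = df.groupby(subject_col)[session_col].nunique()
    singletons = per_subject.index[per_subject < 2]
    if len(singletons):
        warnings.warn(
            f"dropping {len(singletons)} subject(s) present in only one "
            f"session: {list(singletons)[:5]}"
        )
        df = df[~df[subject_col].isin(singletons)]
    if df.empty:
        raise ValueError("no subjects observed in both sessions")

    keep, _ = _validate_response(df[response_col], spec.family)
    df = df[keep.to_numpy()]

    if spec.spillover:
        df = df.sort_values([subject_col, session_col, screen_col, word_col])
        grp = df.groupby([subject_col, session_col, screen_col], sort=False)
        for p in spec.predictors:
            df[f"_{p}_lag"] = grp[p].shift(1)
        first_word = df[f"_{spec.predictors[0]}_lag"].isna()
        df = df[~first_word]

    df = df.sort_values([subject_col, session_col]).reset_index(drop=True)
    subject_ids, subject_idx = np.unique(
        df[subject_col].to_numpy(), return_inverse=True
    )
    order = np.argsort(subject_idx, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    subject_idx = subject_idx[order]

    delta_v = (df[session_col] == label_v).to_numpy(dtype=float)
    # z-score over the fitted rows; the lagged column is the same variable at
    # the previous word, so it reuses its predictor's location and scale
    cols, lag_cols = [], []
    for p in spec.predictors:
        v = df[p].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            raise ValueError(f"cannot z-score constant predictor {p!r}")
        mean, sd = v.mean(), v.std(ddof=0)
        cols.append((v - mean) / sd)
        if spec.spillover:
            lag_cols.append((df[f"_{p}_lag"].to_numpy(dtype=float) - mean) / sd)
    X = np.column_stack(cols)
    X_lag = np.column_stack(lag_cols) if spec.spillover else None
    y = df[response_col].to_numpy(dtype=float)

    bundle = DesignMatrixBundle(
        subject_ids=subject_ids,
        subject_idx=subject_idx,
        delta_v=delta_v,
        X=X,
        X_lag=X_lag,
        y=y,
        predictors=spec.predictors,
        session_labels=(label_u, label_v),
        n_rows_u=int((delta_v == 0).sum()),
        n_rows_v=int((delta_v == 1).sum()),
    )
    bundle.validate()
    return bundle
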