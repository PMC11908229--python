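"""Lick-bout segmentation and behavioral session measures.

A lick bout is a cluster of at least ``min_licks`` licks (default 3) whose
consecutive inter-lick gaps are all shorter than ``min_inter_bout_gap_s``
(default 10 s); clusters are separated wherever a gap reaches that
threshold. Smaller clusters are not bouts but their licks still count in
session totals. Bout length is the time from the first to the last lick of
the cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LickwaveError


@dataclass(frozen=True)
class BoutParams:
    """Segmentation rule: >= min_licks licks, gaps < min_inter_bout_gap_s."""

    min_licks: int = 3
    min_inter_bout_gap_s: float = 10.0

    def __post_init__(self) -> None:
        if self.min_licks < 2:
            raise LickwaveError("min_licks must be >= 2")
        if self.min_inter_bout_gap_s <= 0:
            raise LickwaveError("min_inter_bout_gap_s must be > 0")


@dataclass(frozen=True)
class LickBout:
    """One segmented licking episode."""

    start_s: float
    end_s: float
    n_licks: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SessionBehavior:
    """Per-session behavioral summary.

    ``lick_frequency_hz`` is the reciprocal of the median within-bout
    inter-lick interval, pooled over all bouts of the session; NaN when the
    session has no bouts. ``mean_bout_length_s`` is NaN when there are no
    bouts.
    """

    total_licks: int
    n_bouts: int
    mean_bout_length_s: float
    lick_frequency_hz: float


def segment_bouts(licks, params: BoutParams = BoutParams()) -> list[LickBout]:
    """Partition licks into maximal clusters and keep those with enough licks.

    Clusters break wherever the gap between consecutive licks is >=
    ``params.min_inter_bout_gap_s`` ("at least 10 seconds separating one
    bout from another"); clusters with >= ``params.min_licks`` licks become
    bouts, sorted by start time.
    """
    licks = np.asarray(licks, dtype=np.float64)
    if licks.size == 0:
        return []
    if np.any(np.diff(licks) < 0):
        raise LickwaveError("licks must be ascending")
    breaks = np.flatnonzero(np.diff(licks) >= params.min_inter_bout_gap_s) + 1
    bouts = []
    for cluster in np.split(licks, breaks):
        if len(cluster) >= params.min_licks:
            bouts.append(
                LickBout(
                    start_s=float(cluster[0]),
                    end_s=float(cluster[-1]),
                    n_licks=int(len(cluster)),
                )
            )
    return bouts


def bout_licks(licks, bout: LickBout) -> np.ndarray:
    """The lick timestamps belonging to one bout."""
    licks = np.asarray(licks, dtype=np.float64)
    i = np.searchsorted(licks, bout.start_s, side="left")
    j = np.searchsorted(licks, bout.end_s, side="right")
    return licks[i:j]


def session_behavior(licks, bouts: list[LickBout]) -> SessionBehavior:
    """Behavioral summary: totals, bout count/length, within-bout lick rate."""
    licks = np.asarray(licks, dtype=np.float64)
    intervals: list[np.ndarray] = []
    for bout in bouts:
        ilis = np.diff(bout_licks(licks, bout))
        if ilis.size:
            intervals.append(ilis)
    if intervals:
        freq = 1.0 / float(np.median(np.concatenate(intervals)))
    else:
        freq = math.nan
    mean_len = (
        float(np.mean([b.duration_s for b in bouts])) if bouts else math.nan
    )
    return SessionBehavior(
        total_licks=int(licks.size),
        n_bouts=len(bouts),
        mean_bout_length_s=mean_len,
        lick_frequency_hz=freq,
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way within-subjects ANOVA decomposition."""

    F: float
    df1: int
    df2: int
    ss_condition: float
    ss_subject: float
    ss_error: float
    p_value: float


def rm_anova_oneway(
    table: pd.DataFrame,
    subject: str | None = None,
    condition: str | None = None,
    value: str | None = None,
) -> AnovaResult:
    """Classical one-way repeated-measures ANOVA.

    ``table`` is either wide (rows = subjects, columns = conditions) or
    long, in which case ``subject``/``condition``/``value`` name its
    columns. The design must be complete and balanced: every subject in
    every condition exactly once (no imputation).

    F = MS_condition / MS_(condition x subject), with df1 = k - 1 and
    df2 = (k - 1)(n - 1).
    """
    if subject is not None:
        if table.duplicated([subject, condition]).any():
            raise LickwaveError("duplicate (subject, condition) cells")
        table = table.pivot(index=subject, columns=condition, values=value)
    X = table.to_numpy(dtype=np.float64)
    if X.size == 0:
        raise LickwaveError("empty table")
    if np.isnan(X).any():
        raise LickwaveError(
            "incomplete design: every subject needs a value in every condition"
        )
    n, k = X.shape
    if n < 2 or k < 2:
        raise LickwaveError("need >= 2 subjects and >= 2 conditions")
    grand = X.mean()
    ss_cond = n * float(np.sum((X.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((X.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (math.inf if ms_cond > 0 else 0.0)
    from scipy import stats

    p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        ss_condition=ss_cond,
        ss_subject=ss_subj,
        ss_error=ss_err,
        p_value=p,
    )


def behavior_table(sessions_behavior: dict[str, SessionBehavior]) -> pd.DataFrame:
    """Tidy per-session behavior rows (one row per session key)."""
    rows = []
    for key, beh in sessions_behavior.items():
        rows.append(
            {
                "session": key,
                "total_licks": beh.total_licks,
                "n_bouts": beh.n_bouts,
                "mean_bout_length_s": beh.mean_bout_length_s,
                "lick_frequency_hz": beh.lick_frequency_hz,
            }
        )
    return pd.DataFrame(rows)
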