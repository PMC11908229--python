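"""Bootstrap waveform statistics on peri-event snips.

The mean event-aligned waveform is estimated by resampling the pooled
snips with replacement (default 1000 resamples) and taking the 2.5th and
97.5th percentiles of the resample means per bin as a 95% confidence
interval. A "true fluctuation" is a run of at least 6 consecutive bins
(0.6 s, one period of the low-pass filter) whose CI excludes zero; two
groups differ where their CIs are disjoint for at least 6 consecutive
bins. Run boundaries are reported in seconds relative to bout start or
bout end, whichever anchor the bin falls under.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import EmptyInputError, ExcludedSnipError, GridMismatchError
from .snips import Snip, SnipGrid


@dataclass
class BootstrapResult:
    """Mean waveform with per-bin percentile CI."""

    mean_wave: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int
    alpha: float
    n_snips: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.mean_wave)


@dataclass(frozen=True)
class SignificanceRun:
    """A maximal consecutive-bin interval satisfying a significance criterion.

    ``start_s``/``end_s`` are the left edge of the first bin and the right
    edge of the last bin, each in seconds relative to its own anchor
    (``bout_start`` for baseline and early-lick bins, ``bout_end`` for
    late-lick and post bins).
    """

    start_bin: int
    end_bin: int
    sign: Literal["below_zero", "above_zero", "group_difference"]
    start_s: float
    end_s: float
    start_anchor: str
    end_anchor: str


@dataclass(frozen=True)
class EpochAUC:
    """Trapezoidal area of one snip over one behavioral epoch (z * s)."""

    bout_id: int
    epoch: Literal["lick_start", "lick_end", "post_0_5", "post_5_10"]
    auc: float


def _snip_matrix(snips: Sequence[Snip] | np.ndarray) -> np.ndarray:
    if isinstance(snips, np.ndarray):
        X = np.asarray(snips, dtype=np.float64)
        if X.ndim != 2:
            raise GridMismatchError("snip matrix must be 2-D (n_snips, n_bins)")
        return X
    rows = [s.values for s in snips if s.included]
    if not rows:
        raise EmptyInputError("no included snips to bootstrap")
    return np.asarray(rows, dtype=np.float64)


def bootstrap_mean(
    snips: Sequence[Snip] | np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap the mean waveform over snips.

    Each resample draws ``n_snips`` snips with replacement; the CI is the
    per-bin (alpha/2, 1-alpha/2) percentile of the resample means. One
    index matrix is drawn and reused across bins, so the waveform CI is
    coherent in time. Snips are put in a canonical (lexicographic) order
    before resampling, so the result depends only on the multiset of
    snips, not their order.
    """
    X = _snip_matrix(snips)
    if X.shape[0] == 0:
        raise EmptyInputError("no snips")
    # canonical order: result is a function of the snip multiset
    order = np.lexsort(X.T[::-1])
    X = X[order]
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    # row-wise occupancy counts -> resample means via one matmul
    counts = np.zeros((n_boot, n), dtype=np.float64)
    np.add.at(counts, (np.repeat(np.arange(n_boot), n), idx.ravel()), 1.0)
    boot_means = counts @ X / n
    lo, hi = np.percentile(
        boot_means, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
    )
    return BootstrapResult(
        mean_wave=X.mean(axis=0),
        ci_lower=lo,
        ci_upper=hi,
        n_boot=n_boot,
        alpha=alpha,
        n_snips=n,
        seed=seed,
    )


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal (start, end) inclusive index runs of True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def _make_run(start: int, end: int, sign: str, grid: SnipGrid) -> SignificanceRun:
    start_s, start_anchor = grid.bin_time(start, "left")
    end_s, end_anchor = grid.bin_time(end, "right")
    return SignificanceRun(
        start_bin=start,
        end_bin=end,
        sign=sign,  # type: ignore[arg-type]
        start_s=start_s,
        end_s=end_s,
        start_anchor=start_anchor,
        end_anchor=end_anchor,
    )


def significant_runs(
    result: BootstrapResult,
    min_consecutive: int = 6,
    grid: SnipGrid = SnipGrid(),
) -> list[SignificanceRun]:
    """Maximal runs of bins whose CI excludes zero, kept if long enough.

    Strict inequalities: a CI that touches zero exactly counts as
    including zero.
    """
    runs: list[SignificanceRun] = []
    for sign, mask in (
        ("below_zero", result.ci_upper < 0),
        ("above_zero", result.ci_lower > 0),
    ):
        for start, end in _mask_runs(mask):
            if end - start + 1 >= min_consecutive:
                runs.append(_make_run(start, end, sign, grid))
    runs.sort(key=lambda r: r.start_bin)
    return runs


def compare_groups(
    result_a: BootstrapResult,
    result_b: BootstrapResult,
    min_consecutive: int = 6,
    grid: SnipGrid = SnipGrid(),
) -> list[SignificanceRun]:
    """Runs of bins where the two groups' CIs are disjoint.

    Symmetric in (a, b) up to which group sits higher; the run sign is
    always ``group_difference``.
    """
    if len(result_a) != len(result_b):
        raise GridMismatchError(
            f"grids differ: {len(result_a)} vs {len(result_b)} bins"
        )
    disjoint = (result_a.ci_lower > result_b.ci_upper) | (
        result_a.ci_upper < result_b.ci_lower
    )
    return [
        _make_run(start, end, "group_difference", grid)
        for start, end in _mask_runs(disjoint)
        if end - start + 1 >= min_consecutive
    ]


@dataclass(frozen=True)
class WaveformTimes:
    """Event-relative onset/offset readouts of the significant runs.

    ``suppression_onset_s``: start (relative to bout start) of the first
    below-zero run beginning at or after the bout starts.
    ``suppression_offset_s``: end (relative to bout end) of the last
    below-zero run that extends past the bout end.
    ``rebound_onset_s``: start (relative to bout end) of the first
    above-zero run beginning after the bout ends.
    Absent phenomena are None.
    """

    suppression_onset_s: float | None
    suppression_offset_s: float | None
    rebound_onset_s: float | None


def onset_offset(
    runs: Iterable[SignificanceRun], grid: SnipGrid = SnipGrid()
) -> WaveformTimes:
    """Convert significance runs into the event-relative time readouts."""
    onset = offset = rebound = None
    below = [r for r in runs if r.sign == "below_zero"]
    above = [r for r in runs if r.sign == "above_zero"]
    starts = [r for r in below if r.start_bin >= grid.pre_bins]
    if starts:
        onset = grid.bin_time(min(r.start_bin for r in starts), "left")[0]
    post = [r for r in below if r.end_bin >= grid.post_start_bin]
    if post:
        offset = grid.bin_time(max(r.end_bin for r in post), "right")[0]
    reb = [r for r in above if r.start_bin >= grid.post_start_bin]
    if reb:
        rebound = grid.bin_time(min(r.start_bin for r in reb), "left")[0]
    return WaveformTimes(
        suppression_onset_s=onset,
        suppression_offset_s=offset,
        rebound_onset_s=rebound,
    )


EPOCHS = ("lick_start", "lick_end", "post_0_5", "post_5_10")


def auc_epochs(snip: Snip, grid: SnipGrid = SnipGrid()) -> list[EpochAUC]:
    """Trapezoidal AUC of one included snip over the behavioral epochs.

    Epochs: the first-6-s lick zone, the last-2-s lick zone, and the 10 s
    post period split into two equal 5 s windows.
    """
    if not snip.included:
        raise ExcludedSnipError(f"snip has status {snip.status!r}")
    z = np.asarray(snip.values, dtype=np.float64)
    p, ls, le = grid.pre_bins, grid.lick_start_bins, grid.lick_end_bins
    half_post = grid.post_bins // 2
    segments = {
        "lick_start": z[p : p + ls],
        "lick_end": z[p + ls : p + ls + le],
        "post_0_5": z[grid.post_start_bin : grid.post_start_bin + half_post],
        "post_5_10": z[grid.post_start_bin + half_post : grid.total_bins],
    }
    return [
        EpochAUC(
            bout_id=snip.bout_index,
            epoch=name,  # type: ignore[arg-type]
            auc=float(np.trapezoid(seg, dx=grid.bin_width_s)),
        )
        for name, seg in segments.items()
    ]
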