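"""Fixed-layout peri-event traces ("snips") with artifact rejection.

Every qualifying bout yields one snip on a fixed 230-bin grid of 0.1 s
bins: 50 bins (5 s) of baseline before the first lick, 60 bins for the
first 6 s of licking, 20 bins for the last 2 s of licking, and 100 bins
(10 s) after the last lick. Restricting the lick period to its first 6 s
and last 2 s puts bouts of different durations on one comparable layout.

Snips are z-scored against their own 5 s baseline, then screened for
artifacts by the maximum absolute bin-to-bin step. A bout that cannot
produce a valid snip is kept in the output with an exclusion status, so
bout counts are conserved: included + excluded-by-reason = all bouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import GridMismatchError, LickwaveError
from .licking import BoutParams, LickBout, segment_bouts
from .preprocess import BinnedTrace

Status = Literal[
    "included",
    "excluded_short",
    "excluded_artifact",
    "excluded_edge",
    "excluded_zero_sd",
]

#: default artifact threshold, in baseline-SD (z) units
ARTIFACT_THRESHOLD = 12.0


@dataclass(frozen=True)
class SnipGrid:
    """The fixed peri-event bin layout.

    Zones, in bin order: ``[0, pre)`` baseline; ``[pre, pre+lick_start)``
    first 6 s of licking; then the last 2 s of licking; then the post
    period. Bins up to the end of the first-6-s zone are anchored to bout
    start; later bins to bout end.
    """

    bin_width_s: float = 0.1
    pre_bins: int = 50
    lick_start_bins: int = 60
    lick_end_bins: int = 20
    post_bins: int = 100

    @property
    def lick_bins(self) -> int:
        return self.lick_start_bins + self.lick_end_bins

    @property
    def total_bins(self) -> int:
        return self.pre_bins + self.lick_bins + self.post_bins

    @property
    def end_anchor_bin(self) -> int:
        """First bin anchored to bout end (start of the last-2-s zone)."""
        return self.pre_bins + self.lick_start_bins

    @property
    def post_start_bin(self) -> int:
        """First bin after the bout ends."""
        return self.end_anchor_bin + self.lick_end_bins

    def bin_time(self, b: int, edge: str = "left") -> tuple[float, str]:
        """Seconds of a bin edge relative to its anchor.

        Returns ``(seconds, anchor)`` with anchor ``"bout_start"`` for bins
        in the pre/first-6-s zones and ``"bout_end"`` for later bins.
        """
        off = 1 if edge == "right" else 0
        if b < self.end_anchor_bin:
            return ((b + off - self.pre_bins) * self.bin_width_s, "bout_start")
        return ((b + off - self.post_start_bin) * self.bin_width_s, "bout_end")


@dataclass
class Snip:
    """One bout's peri-event trace on the fixed grid."""

    values: np.ndarray | None
    bout: LickBout
    status: Status
    baseline_mean: float = float("nan")
    baseline_sd: float = float("nan")
    warped: bool = False
    bout_index: int = -1

    @property
    def included(self) -> bool:
        return self.status == "included"


def _bin_index(t: float, trace: BinnedTrace, round_up: bool = False) -> int:
    x = (t - trace.t_start_s) / trace.bin_width_s
    if round_up:
        return int(np.ceil(x - 1e-9))
    return int(np.floor(x + 1e-9))


def extract_snip(
    binned: BinnedTrace,
    bout: LickBout,
    grid: SnipGrid = SnipGrid(),
    min_bout_duration_s: float = 8.0,
    short_bout_mode: str = "warp",
) -> Snip:
    """Assemble one raw (not yet z-scored) snip from the binned trace.

    Bouts shorter than ``min_bout_duration_s`` are ``excluded_short``;
    windows reaching past the recording are ``excluded_edge``. For bouts
    between ``min_bout_duration_s`` and 8 s the first-6-s zone has fewer
    than 60 source bins (the last 2 s are always literal); the available
    bins are mapped onto the 60-bin grid either by linear time-warping
    (``short_bout_mode="warp"``, the default) or by nearest-bin resampling
    with duplicates (``"overlap"``); such snips are flagged ``warped``.
    """
    if abs(binned.bin_width_s - grid.bin_width_s) > 1e-12:
        raise GridMismatchError(
            f"trace bin width {binned.bin_width_s} != grid {grid.bin_width_s}"
        )
    if short_bout_mode not in ("warp", "overlap"):
        raise LickwaveError(f"unknown short_bout_mode {short_bout_mode!r}")
    if bout.duration_s < min_bout_duration_s:
        return Snip(values=None, bout=bout, status="excluded_short")
    s0 = _bin_index(bout.start_s, binned)
    e0 = _bin_index(bout.end_s, binned, round_up=True)
    if s0 - grid.pre_bins < 0 or e0 + grid.post_bins > len(binned):
        return Snip(values=None, bout=bout, status="excluded_edge")
    x = binned.values
    pre = x[s0 - grid.pre_bins : s0]
    last = x[e0 - grid.lick_end_bins : e0]
    post = x[e0 : e0 + grid.post_bins]
    n_avail = (e0 - grid.lick_end_bins) - s0
    warped = False
    if n_avail >= grid.lick_start_bins:
        first = x[s0 : s0 + grid.lick_start_bins]
    elif short_bout_mode == "warp":
        src = x[s0 : s0 + n_avail]
        first = np.interp(
            np.linspace(0.0, n_avail - 1.0, grid.lick_start_bins),
            np.arange(n_avail, dtype=float),
            src,
        )
        warped = True
    else:  # overlap: nearest-bin resampling, duplicating bins as needed
        idx = np.round(
            np.linspace(s0, s0 + n_avail - 1, grid.lick_start_bins)
        ).astype(np.intp)
        first = x[idx]
        warped = True
    values = np.concatenate([pre, first, last, post])
    assert values.size == grid.total_bins
    return Snip(values=values, bout=bout, status="included", warped=warped)


def zscore_snip(raw_values: np.ndarray, grid: SnipGrid = SnipGrid()):
    """Z-score a raw snip against its own pre-bout baseline.

    Returns ``(z_values, baseline_mean, baseline_sd)``; ``z_values`` is
    ``None`` with ``baseline_sd == 0`` when the baseline is constant
    (degenerate, snip must be excluded).
    """
    raw_values = np.asarray(raw_values, dtype=np.float64)
    if raw_values.size != grid.total_bins:
        raise GridMismatchError(
            f"expected {grid.total_bins} bins, got {raw_values.size}"
        )
    base = raw_values[: grid.pre_bins]
    mean = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    if sd == 0.0:
        return None, mean, 0.0
    return (raw_values - mean) / sd, mean, sd


def artifact_check(z_values: np.ndarray, threshold: float = ARTIFACT_THRESHOLD) -> bool:
    """True (pass) unless any |z[i+1] - z[i]| strictly exceeds ``threshold``."""
    z_values = np.asarray(z_values, dtype=np.float64)
    if z_values.size < 2:
        return True
    return bool(np.max(np.abs(np.diff(z_values))) <= threshold)


def build_snips(
    licks,
    binned: BinnedTrace,
    grid: SnipGrid = SnipGrid(),
    bout_params: BoutParams = BoutParams(),
    min_bout_duration_s: float = 8.0,
    artifact_threshold: float = ARTIFACT_THRESHOLD,
    short_bout_mode: str = "warp",
    bouts: list[LickBout] | None = None,
) -> tuple[list[Snip], dict[str, int]]:
    """Segment, extract, z-score and screen: one snip record per bout.

    Returns the snip list (included and excluded, in bout order) and a
    count of statuses. Conservation: the statuses partition the bout list.
    """
    if bouts is None:
        bouts = segment_bouts(licks, bout_params)
    snips: list[Snip] = []
    log: dict[str, int] = {}
    for i, bout in enumerate(bouts):
        snip = extract_snip(
            binned, bout, grid, min_bout_duration_s, short_bout_mode
        )
        snip.bout_index = i
        if snip.status == "included":
            z, mean, sd = zscore_snip(snip.values, grid)
            snip.baseline_mean, snip.baseline_sd = mean, sd
            if z is None:
                snip.status = "excluded_zero_sd"
                snip.values = None
            elif not artifact_check(z, artifact_threshold):
                snip.status = "excluded_artifact"
                snip.values = z
            else:
                snip.values = z
        snips.append(snip)
        log[snip.status] = log.get(snip.status, 0) + 1
    return snips, log
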