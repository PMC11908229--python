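"""Control-channel correction, binning, and the in vitro dF/F0 formula.

The 465 nm channel carries sensor fluorescence plus bleaching, motion and
noise; the 405 nm isosbestic channel carries the same bleaching and motion
but no ligand signal. Correction fits the control to the signal channel by
ordinary least squares over the whole session (bleach and motion are
session-scale phenomena), subtracts the fitted control, divides by it to
express the result in dF/F units, and finally applies a zero-phase low-pass
filter. The corrected trace is then averaged into 0.1 s bins — the grid on
which all peri-event statistics are defined (6 bins = 0.6 s, matching the
consecutive-bin significance threshold downstream).

The fit may optionally be restricted to a boolean ``fit_mask`` of baseline
samples. Event-locked sensor transients are variance the control channel
does not share; excluding peri-event windows from the fit removes the small
bias they would otherwise put on the control gain. The default (all samples)
matches common practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateControlError,
    EmptyInputError,
    LengthMismatchError,
    LickwaveError,
    NonPositiveFittedError,
)

#: default zero-phase low-pass cutoff, Hz; period 0.6 s so that the 6-bin
#: consecutive-significance rule spans one filter period
DEFAULT_LOWPASS_HZ = 1.67


@dataclass
class CorrectedTrace:
    """Corrected signal in dF/F units on the raw time grid.

    ``values`` is the low-pass-filtered trace used downstream;
    ``values_raw`` is the same quantity before filtering (useful for
    checking the correction itself). ``fit_params`` is ``(a, b)`` of the
    control fit ``fitted = a * f405 + b``.
    """

    values: np.ndarray
    values_raw: np.ndarray
    fit_params: tuple[float, float]
    fs_hz: float
    method_tag: str = "ols-ratio-lowpass"

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinnedTrace:
    """Trace averaged into fixed-width time bins (default 0.1 s)."""

    values: np.ndarray
    bin_width_s: float = 0.1
    t_start_s: float = 0.0

    def __len__(self) -> int:
        return len(self.values)

    def bin_times(self) -> np.ndarray:
        """Left edges of the bins, seconds."""
        return self.t_start_s + np.arange(len(self.values)) * self.bin_width_s


def fit_control(f465: np.ndarray, f405: np.ndarray) -> tuple[float, float]:
    """Ordinary-least-squares fit of the control to the signal channel.

    Returns ``(a, b)`` minimising ``sum((f465 - a*f405 - b)**2)``.
    """
    f465 = np.asarray(f465, dtype=np.float64)
    f405 = np.asarray(f405, dtype=np.float64)
    if len(f465) != len(f405):
        raise LengthMismatchError(
            f"channel lengths differ: {len(f465)} vs {len(f405)}"
        )
    if len(f465) < 2:
        raise EmptyInputError("need at least 2 samples to fit the control channel")
    if np.ptp(f405) == 0:
        raise DegenerateControlError(
            "405 nm channel is constant; the control fit is undefined"
        )
    design = np.column_stack([f405, np.ones_like(f405)])
    (a, b), *_ = np.linalg.lstsq(design, f465, rcond=None)
    return float(a), float(b)


def correct_signal(
    f465: np.ndarray,
    f405: np.ndarray,
    fs_hz: float,
    lowpass_cut_hz: float | None = DEFAULT_LOWPASS_HZ,
    fit_mask: np.ndarray | None = None,
) -> CorrectedTrace:
    """Correct the 465 nm channel with the 405 nm control.

    ``corrected = (f465 - fitted) / fitted`` with ``fitted = a*f405 + b``
    from :func:`fit_control`, followed by a zero-phase (forward-backward
    Butterworth) low-pass at ``lowpass_cut_hz`` (``None`` disables the
    filter). ``fit_mask`` optionally restricts the fit to baseline samples;
    the correction itself is always applied to every sample.
    """
    f465 = np.asarray(f465, dtype=np.float64)
    f405 = np.asarray(f405, dtype=np.float64)
    if lowpass_cut_hz is not None and lowpass_cut_hz >= fs_hz / 2:
        raise LickwaveError(
            f"lowpass_cut_hz={lowpass_cut_hz} must be below Nyquist ({fs_hz / 2})"
        )
    if fit_mask is not None:
        fit_mask = np.asarray(fit_mask, dtype=bool)
        if len(fit_mask) != len(f465):
            raise LengthMismatchError("fit_mask length must match the channels")
        a, b = fit_control(f465[fit_mask], f405[fit_mask])
    else:
        a, b = fit_control(f465, f405)
    fitted = a * f405 + b
    bad = np.flatnonzero(fitted <= 0)
    if bad.size:
        raise NonPositiveFittedError(bad[0])
    raw = (f465 - fitted) / fitted
    if lowpass_cut_hz is None:
        filtered = raw.copy()
        tag = "ols-ratio"
    else:
        sos = sps.butter(2, lowpass_cut_hz, btype="low", fs=fs_hz, output="sos")
        filtered = sps.sosfiltfilt(sos, raw)
        tag = "ols-ratio-lowpass"
    return CorrectedTrace(
        values=filtered,
        values_raw=raw,
        fit_params=(a, b),
        fs_hz=fs_hz,
        method_tag=tag,
    )


def bin_trace(
    values: np.ndarray,
    fs_hz: float,
    bin_width_s: float = 0.1,
    t_start_s: float = 0.0,
) -> BinnedTrace:
    """Average raw samples into fixed-width bins.

    Bin ``k`` is the mean of the samples whose timestamps (relative to the
    trace start) fall in ``[k*w, (k+1)*w)``; a trailing partial bin is
    dropped.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EmptyInputError("cannot bin an empty trace")
    if fs_hz * bin_width_s < 1:
        raise LickwaveError(
            f"bin width {bin_width_s}s holds <1 sample at fs={fs_hz} Hz"
        )
    t_rel = np.arange(values.size) / fs_hz
    idx = np.floor(t_rel / bin_width_s + 1e-9).astype(np.intp)
    n_bins = int(np.floor(values.size / fs_hz / bin_width_s + 1e-9))
    if n_bins == 0:
        raise EmptyInputError("trace shorter than one bin")
    keep = idx < n_bins
    sums = np.bincount(idx[keep], weights=values[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    return BinnedTrace(
        values=sums / counts, bin_width_s=bin_width_s, t_start_s=t_start_s
    )


def dff_invitro(F: np.ndarray, ligand_index: int, n_baseline: int = 10) -> np.ndarray:
    """In vitro dF/F0: (F(t) - F0)/F0 with F0 the mean of the ``n_baseline``
    samples immediately before ligand addition."""
    F = np.asarray(F, dtype=np.float64)
    if ligand_index < n_baseline:
        raise LickwaveError(
            f"need at least {n_baseline} pre-ligand samples; "
            f"ligand_index={ligand_index}"
        )
    f0 = float(np.mean(F[ligand_index - n_baseline : ligand_index]))
    if f0 == 0:
        raise LickwaveError("baseline F0 is zero; dF/F0 undefined")
    return (F - f0) / f0
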