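"""Synthetic lick trains and dual-channel photometry with known ground truth.

The forward model mirrors the recording the pipeline analyses:

* a bout-structured lick train (bouts of >= 3 licks at ~7 Hz, separated by
  >= 10 s so the segmentation rule can recover them exactly);
* a 465 nm channel ``bleach(t) * (1 + k(t)) + motion(t) + noise`` where
  ``k(t)`` is the event-locked "histamine" kernel in dF/F units —
  suppression during licking, then either a delayed rebound above baseline
  or sustained suppression, the two qualitative post-bout modes seen in
  PVH vs VMH recordings;
* a 405 nm isosbestic channel ``control_gain * bleach(t) + motion(t) +
  noise`` sharing bleach and motion but carrying no kernel.

Bleaching is a shared double exponential; motion artifacts are sparse
biexponential transients added identically to both channels so that
control-channel correction can remove them. The kernel's ``suppression
depth`` is nominally in baseline-SD (z) units of the corrected, binned
trace: the default channel noise is calibrated so one kernel unit maps to
about one baseline SD after correction, 1.67 Hz low-pass and 0.1 s
binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import LickwaveError, SessionTooShortError
from .licking import BoutParams, segment_bouts
from .session import Session

logger = logging.getLogger(__name__)

#: gamma shape of within-bout inter-lick intervals (CV ~ 0.35)
ILI_GAMMA_SHAPE = 8.0


@dataclass(frozen=True)
class LickTrainParams:
    """Bout-structured lick-train generator parameters.

    Bout durations are lognormal with the given mean/SD (seconds); licks
    within a bout follow gamma inter-lick intervals around
    ``1/intra_bout_rate_hz`` (7 Hz by convention — a typical rodent lick
    rate). ``inter_bout_gap_min_s`` must stay >= 10 s so the generated
    bouts are exactly recoverable by the segmentation rule.
    """

    n_bouts: int = 30
    bout_duration_mean_s: float = 10.0
    bout_duration_sd_s: float = 3.0
    intra_bout_rate_hz: float = 7.0
    inter_bout_gap_min_s: float = 10.0
    session_length_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.n_bouts < 0:
            raise LickwaveError("n_bouts must be >= 0")
        if self.intra_bout_rate_hz <= 0:
            raise LickwaveError("intra_bout_rate_hz must be > 0")
        if self.inter_bout_gap_min_s < 10.0:
            raise LickwaveError(
                "inter_bout_gap_min_s must be >= 10 s so generated bouts are "
                "recoverable by the >=10 s segmentation rule"
            )
        if self.bout_duration_mean_s <= 0 or self.bout_duration_sd_s < 0:
            raise LickwaveError("bout duration mean must be > 0 and SD >= 0")


@dataclass(frozen=True)
class HistamineKernel:
    """Event-locked response shape, in nominal z units.

    During a bout the signal relaxes toward ``suppression_depth`` (<= 0)
    with time constant ``onset_tau_s`` after ``onset_delay_s``. After the
    bout the suppression decays with ``post_recovery_tau_s`` and, in
    ``rebound`` mode, an alpha-shaped overshoot of ``rebound_amplitude``
    peaks ``rebound_delay_s + rebound_decay_tau_s`` seconds after bout
    end; ``sustained`` mode keeps the suppression (long recovery, no
    rebound). The response is truncated ``post_support_s`` after bout end.
    """

    onset_delay_s: float = 0.0
    onset_tau_s: float = 0.3
    suppression_depth: float = -1.0
    recovery_mode: str = "rebound"
    rebound_amplitude: float = 0.6
    rebound_delay_s: float = 3.0
    rebound_decay_tau_s: float = 2.5
    post_recovery_tau_s: float = 1.2
    post_support_s: float = 25.0

    def __post_init__(self) -> None:
        if self.suppression_depth > 0:
            raise LickwaveError("suppression_depth must be <= 0")
        if self.rebound_amplitude < 0:
            raise LickwaveError("rebound_amplitude must be >= 0")
        for name in ("onset_tau_s", "rebound_decay_tau_s", "post_recovery_tau_s"):
            if getattr(self, name) <= 0:
                raise LickwaveError(f"{name} must be > 0")
        if self.recovery_mode not in ("rebound", "sustained"):
            raise LickwaveError("recovery_mode must be 'rebound' or 'sustained'")

    @classmethod
    def pvh(cls) -> "HistamineKernel":
        """Rebound mode: suppression from ~1.5 s after lick onset, recovery
        within a few seconds of bout end, then an overshoot above baseline."""
        return cls(
            onset_delay_s=1.5,
            onset_tau_s=0.3,
            suppression_depth=-1.0,
            recovery_mode="rebound",
            rebound_amplitude=0.6,
            rebound_delay_s=3.0,
            rebound_decay_tau_s=2.5,
            post_recovery_tau_s=1.2,
        )

    @classmethod
    def vmh(cls) -> "HistamineKernel":
        """Sustained mode: fast-onset suppression that outlasts the bout by
        well over 10 s, with no rebound."""
        return cls(
            onset_delay_s=0.2,
            onset_tau_s=0.3,
            suppression_depth=-1.2,
            recovery_mode="sustained",
            rebound_amplitude=0.0,
            post_recovery_tau_s=40.0,
        )

    @classmethod
    def null(cls) -> "HistamineKernel":
        """No event-locked response at all (type-I calibration)."""
        return cls(suppression_depth=0.0, rebound_amplitude=0.0)


@dataclass(frozen=True)
class PhotometryParams:
    """Forward-model parameters for the dual-channel recording.

    ``kernel_scale`` converts kernel units to dF/F; the default channel
    noise (``noise_sd_465``/``noise_sd_405``, raw fluorescence units) is
    set so that after correction, low-pass and binning the baseline bin SD
    is about one ``kernel_scale``, i.e. kernel depth ~ z-score depth.
    """

    fs_hz: float = 100.0
    baseline_f: float = 1.0
    bleach_amplitudes: tuple[float, float] = (0.5, 0.2)
    bleach_taus_s: tuple[float, float] = (900.0, 120.0)
    motion_event_rate_hz: float = 0.02
    motion_amplitude: float = 0.05
    motion_rise_tau_s: float = 0.05
    motion_decay_tau_s: float = 0.5
    noise_sd_465: float = 0.035
    noise_sd_405: float = 0.035
    control_gain: float = 1.0
    kernel_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.fs_hz < 20:
            raise LickwaveError("fs_hz must be >= 20 to support 0.1 s bins")
        if any(t <= 0 for t in self.bleach_taus_s):
            raise LickwaveError("bleach taus must be > 0")
        if self.noise_sd_465 < 0 or self.noise_sd_405 < 0:
            raise LickwaveError("noise SDs must be >= 0")
        if self.motion_rise_tau_s <= 0 or self.motion_decay_tau_s <= 0:
            raise LickwaveError("motion taus must be > 0")


@dataclass
class SimulatedSession:
    """A generated session plus its noiseless ground truth."""

    session: Session
    truth: np.ndarray  # noiseless kernel trace, dF/F units, raw time grid
    kernel: HistamineKernel
    lick_params: LickTrainParams
    phot_params: PhotometryParams
    seed: int


# ---------------------------------------------------------------------------
# lick trains
# ---------------------------------------------------------------------------

def generate_lick_train(params: LickTrainParams, seed) -> np.ndarray:
    """Generate ascending lick timestamps with recoverable bout structure.

    Bouts are laid out left to right; the slack left in the session is
    split randomly (Dirichlet) over the gaps, so every inter-bout gap is
    ``inter_bout_gap_min_s`` plus a positive jitter. Raises
    :class:`SessionTooShortError` when the requested bouts cannot fit.
    """
    rng = np.random.default_rng(seed)
    if params.n_bouts == 0:
        return np.empty(0, dtype=np.float64)
    m, s = params.bout_duration_mean_s, params.bout_duration_sd_s
    if s > 0:
        sigma2 = np.log(1.0 + (s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        durations = rng.lognormal(mu, np.sqrt(sigma2), size=params.n_bouts)
    else:
        durations = np.full(params.n_bouts, m)
    scale = 1.0 / (params.intra_bout_rate_hz * ILI_GAMMA_SHAPE)
    ili_cap = params.inter_bout_gap_min_s / 2.0  # keep bouts unsplittable
    bouts_rel: list[np.ndarray] = []
    for dur in durations:
        ticks = [0.0]
        while ticks[-1] < dur or len(ticks) < 3:
            dt = min(float(rng.gamma(ILI_GAMMA_SHAPE, scale)), ili_cap)
            ticks.append(ticks[-1] + dt)
        bouts_rel.append(np.asarray(ticks))
    actual = np.array([b[-1] for b in bouts_rel])
    required = actual.sum() + (params.n_bouts - 1) * params.inter_bout_gap_min_s
    slack = params.session_length_s - required
    if slack < 0:
        raise SessionTooShortError(
            f"{params.n_bouts} bouts need {required:.1f} s but the session is "
            f"{params.session_length_s:.1f} s"
        )
    extras = rng.dirichlet(np.ones(params.n_bouts + 1)) * slack
    licks = []
    t = float(extras[0])
    for i, bout in enumerate(bouts_rel):
        licks.append(t + bout)
        t += actual[i] + params.inter_bout_gap_min_s + float(extras[i + 1])
    return np.concatenate(licks)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def kernel_trace(
    licks, kernel: HistamineKernel, t: np.ndarray
) -> np.ndarray:
    """Evaluate the event-locked kernel (in kernel units) on a time grid.

    One response per segmented bout; overlapping responses add.
    """
    k = np.zeros_like(t)
    depth = kernel.suppression_depth
    for bout in segment_bouts(licks, BoutParams()):
        tau = t - (bout.start_s + kernel.onset_delay_s)
        in_bout = (t >= bout.start_s) & (t <= bout.end_s)
        ramp = np.where(tau > 0, 1.0 - np.exp(-np.maximum(tau, 0) / kernel.onset_tau_s), 0.0)
        k[in_bout] += depth * ramp[in_bout]
        held = bout.end_s - bout.start_s - kernel.onset_delay_s
        s_end = depth * (1.0 - np.exp(-held / kernel.onset_tau_s)) if held > 0 else 0.0
        te = t - bout.end_s
        post = (te > 0) & (te <= kernel.post_support_s)
        if not np.any(post):
            continue
        resp = s_end * np.exp(-te[post] / kernel.post_recovery_tau_s)
        if kernel.recovery_mode == "rebound" and kernel.rebound_amplitude > 0:
            x = te[post] - kernel.rebound_delay_s
            alpha = np.where(
                x > 0,
                (x / kernel.rebound_decay_tau_s)
                * np.exp(1.0 - x / kernel.rebound_decay_tau_s),
                0.0,
            )
            resp = resp + kernel.rebound_amplitude * alpha
        k[post] += resp
    return k


def _motion_trace(t: np.ndarray, params: PhotometryParams, rng) -> np.ndarray:
    """Sparse biexponential transients, shared by both channels."""
    length = t[-1] if len(t) else 0.0
    n_events = rng.poisson(params.motion_event_rate_hz * length)
    m = np.zeros_like(t)
    if params.motion_amplitude == 0:
        # draw anyway so downstream streams stay aligned across settings
        rng.uniform(0, 1, size=2 * n_events)
        return m
    times = rng.uniform(0.0, length, size=n_events)
    amps = params.motion_amplitude * rng.normal(1.0, 0.3, size=n_events)
    signs = rng.choice([-1.0, 1.0], size=n_events)
    for t0, amp, sgn in zip(times, amps, signs):
        tau = t - t0
        win = (tau > 0) & (tau < 10 * params.motion_decay_tau_s)
        m[win] += (
            sgn
            * amp
            * (
                np.exp(-tau[win] / params.motion_decay_tau_s)
                - np.exp(-tau[win] / params.motion_rise_tau_s)
            )
        )
    return m


def generate_photometry(
    licks,
    kernel: HistamineKernel,
    pparams: PhotometryParams = PhotometryParams(),
    seed=None,
    session_length_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the two channels; returns ``(f465, f405, truth)``.

    ``truth`` is the noiseless kernel trace in dF/F units
    (``kernel_scale * k(t)``) on the raw time grid. The 405 channel shares
    bleach (scaled by ``control_gain``) and motion but carries no kernel.
    """
    licks = np.asarray(licks, dtype=np.float64)
    if len(licks) > 1 and np.any(np.diff(licks) < 0):
        raise LickwaveError("licks must be ascending")
    if session_length_s is None:
        session_length_s = (licks[-1] if len(licks) else 0.0) + 15.0
    rng = np.random.default_rng(seed)
    n = int(round(session_length_s * pparams.fs_hz))
    t = np.arange(n) / pparams.fs_hz
    a1, a2 = pparams.bleach_amplitudes
    t1, t2 = pparams.bleach_taus_s
    bleach = pparams.baseline_f + a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)
    truth = pparams.kernel_scale * kernel_trace(licks, kernel, t)
    motion = _motion_trace(t, pparams, rng)
    noise465 = (
        rng.normal(0.0, pparams.noise_sd_465, n) if pparams.noise_sd_465 else 0.0
    )
    noise405 = (
        rng.normal(0.0, pparams.noise_sd_405, n) if pparams.noise_sd_405 else 0.0
    )
    f465 = bleach * (1.0 + truth) + motion + noise465
    f405 = pparams.control_gain * bleach + motion + noise405
    return f465, f405, truth


def baseline_fit_mask(
    licks,
    n_samples: int,
    fs_hz: float,
    pre_margin_s: float = 5.0,
    post_support_s: float = 25.0,
) -> np.ndarray:
    """Boolean mask of samples outside every peri-bout kernel window.

    Useful as ``fit_mask`` for the control fit when event-locked transients
    should not bias the control gain.
    """
    t = np.arange(n_samples) / fs_hz
    mask = np.ones(n_samples, dtype=bool)
    for bout in segment_bouts(licks, BoutParams()):
        mask &= ~(
            (t >= bout.start_s - pre_margin_s)
            & (t <= bout.end_s + post_support_s)
        )
    return mask


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    n_sessions: int,
    region_kernel_map: dict[str, HistamineKernel],
    seeds: Sequence[int],
    lick_params: LickTrainParams = LickTrainParams(),
    phot_params: PhotometryParams = PhotometryParams(),
    condition: str = "Restricted",
    regions: Sequence[str] | None = None,
) -> list[SimulatedSession]:
    """Generate a reproducible cohort, one session per seed.

    Regions cycle through ``region_kernel_map`` keys unless given
    explicitly; each session's lick-train and photometry streams are
    derived from its seed. Duplicate seeds are allowed but logged.
    """
    if len(seeds) != n_sessions:
        raise LickwaveError("need exactly one seed per session")
    if len(set(seeds)) != len(seeds):
        logger.warning("duplicate seeds in cohort: %s", list(seeds))
    keys = list(region_kernel_map)
    if regions is None:
        regions = [keys[i % len(keys)] for i in range(n_sessions)]
    sessions = []
    for i, (seed, region) in enumerate(zip(seeds, regions)):
        kernel = region_kernel_map[region]
        ss = np.random.SeedSequence(int(seed))
        lick_ss, phot_ss = ss.spawn(2)
        licks = generate_lick_train(lick_params, lick_ss)
        f465, f405, truth = generate_photometry(
            licks,
            kernel,
            phot_params,
            seed=phot_ss,
            session_length_s=lick_params.session_length_s,
        )
        session = Session(
            mouse_id=f"sim{i:03d}",
            region=region,
            condition=condition,
            licks=licks,
            f465=f465,
            f405=f405,
            fs_hz=phot_params.fs_hz,
        )
        sessions.append(
            SimulatedSession(
                session=session,
                truth=truth,
                kernel=kernel,
                lick_params=lick_params,
                phot_params=phot_params,
                seed=int(seed),
            )
        )
    return sessions
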