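"""End-to-end orchestration: sessions -> tidy tables, figures, manifest.

`run_condition_analysis` drives the full analysis over a collection of
sessions: per-session correction/binning/segmentation/snips, pooled
bootstrap waveforms per (region, condition), significance runs and
onset/offset readouts, epoch AUCs, behavioral summaries with the
four-condition repeated-measures ANOVA, and the Restricted PVH-vs-VMH
region comparison. All outputs are tidy CSVs plus optional figures and a
machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import LickwaveError
from .licking import (
    BoutParams,
    rm_anova_oneway,
    segment_bouts,
    session_behavior,
)
from .preprocess import DEFAULT_LOWPASS_HZ, bin_trace, correct_signal
from .session import Session, write_table
from .snips import ARTIFACT_THRESHOLD, Snip, SnipGrid, build_snips
from .waveform import (
    BootstrapResult,
    auc_epochs,
    bootstrap_mean,
    compare_groups,
    onset_offset,
    significant_runs,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable analysis parameters, with the standard defaults.

    Defaults: bouts need >= 3 licks and >= 10 s separation; snips need
    bouts >= 4 s (condition analysis) or >= 8 s (region comparison);
    bootstrap uses 1000 resamples at 95% confidence with a 6-bin
    consecutive threshold; the artifact threshold is 12 baseline SDs.
    """

    input_paths: list[str] = field(default_factory=list)
    output_dir: str | None = None
    min_licks: int = 3
    min_inter_bout_gap_s: float = 10.0
    min_bout_duration_s: float = 4.0
    region_min_bout_duration_s: float = 8.0
    lowpass_cut_hz: float = DEFAULT_LOWPASS_HZ
    bin_width_s: float = 0.1
    n_boot: int = 1000
    alpha: float = 0.05
    min_consecutive: int = 6
    artifact_threshold: float = ARTIFACT_THRESHOLD
    short_bout_mode: str = "warp"
    make_figures: bool = True
    seed: int = 0

    @property
    def bout_params(self) -> BoutParams:
        return BoutParams(
            min_licks=self.min_licks,
            min_inter_bout_gap_s=self.min_inter_bout_gap_s,
        )

    @property
    def grid(self) -> SnipGrid:
        return SnipGrid(bin_width_s=self.bin_width_s)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise LickwaveError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def process_session(session: Session, config: RunConfig, min_bout_duration_s=None):
    """Correct, bin, segment and snip one session.

    Returns ``(bouts, behavior, snips, status_log, binned)``.
    """
    min_dur = (
        config.min_bout_duration_s
        if min_bout_duration_s is None
        else min_bout_duration_s
    )
    corrected = correct_signal(
        session.f465, session.f405, session.fs_hz, config.lowpass_cut_hz
    )
    binned = bin_trace(
        corrected.values, session.fs_hz, config.bin_width_s, session.t0_s
    )
    bouts = segment_bouts(session.licks, config.bout_params)
    behavior = session_behavior(session.licks, bouts)
    snips, log = build_snips(
        session.licks,
        binned,
        config.grid,
        config.bout_params,
        min_dur,
        config.artifact_threshold,
        config.short_bout_mode,
        bouts=bouts,
    )
    return bouts, behavior, snips, log, binned


def _group_key(session: Session) -> tuple[str, str]:
    return (session.region, session.condition)


def run_condition_analysis(
    sessions: Sequence[Session], config: RunConfig
) -> dict:
    """Run the full analysis over sessions; returns the results bundle.

    The bundle maps table names to DataFrames plus, under ``"bootstrap"``,
    the per-(region, condition) :class:`BootstrapResult` objects. When
    ``config.output_dir`` is set, tables, figures and a JSON manifest are
    written there.
    """
    if not sessions:
        raise LickwaveError("need at least one session")
    bout_rows, behavior_rows, status_rows = [], [], []
    group_snips: dict[tuple[str, str], list[Snip]] = {}
    per_session = {}
    for i, session in enumerate(sessions):
        key = f"{session.mouse_id}/{session.region}/{session.condition}/{i}"
        try:
            bouts, behavior, snips, log, binned = process_session(session, config)
        except LickwaveError as err:
            raise LickwaveError(f"session {key}: {err}") from err
        per_session[key] = (bouts, behavior, snips)
        for j, bout in enumerate(bouts):
            bout_rows.append(
                {
                    "session": key,
                    "mouse_id": session.mouse_id,
                    "region": session.region,
                    "condition": session.condition,
                    "bout_index": j,
                    "start_s": bout.start_s,
                    "end_s": bout.end_s,
                    "n_licks": bout.n_licks,
                    "duration_s": bout.duration_s,
                }
            )
        behavior_rows.append(
            {
                "session": key,
                "mouse_id": session.mouse_id,
                "region": session.region,
                "condition": session.condition,
                "total_licks": behavior.total_licks,
                "n_bouts": behavior.n_bouts,
                "mean_bout_length_s": behavior.mean_bout_length_s,
                "lick_frequency_hz": behavior.lick_frequency_hz,
            }
        )
        for snip in snips:
            status_rows.append(
                {
                    "session": key,
                    "region": session.region,
                    "condition": session.condition,
                    "bout_index": snip.bout_index,
                    "status": snip.status,
                    "warped": snip.warped,
                }
            )
        group_snips.setdefault(_group_key(session), []).extend(
            s for s in snips if s.included
        )

    wave_rows, run_rows, time_rows, auc_rows = [], [], [], []
    bootstraps: dict[tuple[str, str], BootstrapResult] = {}
    grid = config.grid
    for gi, (key, snips) in enumerate(sorted(group_snips.items())):
        region, condition = key
        if not snips:
            continue
        result = bootstrap_mean(
            snips, config.n_boot, config.alpha, seed=config.seed + gi
        )
        bootstraps[key] = result
        for b in range(len(result)):
            t_s, anchor = grid.bin_time(b, "left")
            wave_rows.append(
                {
                    "region": region,
                    "condition": condition,
                    "bin": b,
                    "t_s": t_s,
                    "anchor": anchor,
                    "mean": result.mean_wave[b],
                    "ci_lower": result.ci_lower[b],
                    "ci_upper": result.ci_upper[b],
                }
            )
        runs = significant_runs(result, config.min_consecutive, grid)
        for run in runs:
            run_rows.append(
                {
                    "region": region,
                    "condition": condition,
                    "comparison": "vs_zero",
                    "sign": run.sign,
                    "start_bin": run.start_bin,
                    "end_bin": run.end_bin,
                    "start_s": run.start_s,
                    "start_anchor": run.start_anchor,
                    "end_s": run.end_s,
                    "end_anchor": run.end_anchor,
                }
            )
        times = onset_offset(runs, grid)
        time_rows.append(
            {
                "region": region,
                "condition": condition,
                "n_snips": result.n_snips,
                "suppression_onset_s": times.suppression_onset_s,
                "suppression_offset_s": times.suppression_offset_s,
                "rebound_onset_s": times.rebound_onset_s,
            }
        )
        for snip in snips:
            for ea in auc_epochs(snip, grid):
                auc_rows.append(
                    {
                        "region": region,
                        "condition": condition,
                        "bout_id": ea.bout_id,
                        "epoch": ea.epoch,
                        "auc": ea.auc,
                    }
                )

    # Restricted PVH-vs-VMH comparison on >= 8 s bouts
    comparison_rows = []
    region_results: dict[str, BootstrapResult] = {}
    for region in ("PVH", "VMH"):
        pool: list[Snip] = []
        for session in sessions:
            if session.region == region and session.condition == "Restricted":
                _, _, snips, _, _ = process_session(
                    session, config, config.region_min_bout_duration_s
                )
                pool.extend(s for s in snips if s.included)
        if pool:
            region_results[region] = bootstrap_mean(
                pool, config.n_boot, config.alpha, seed=config.seed + 1000
            )
    if len(region_results) == 2:
        for run in compare_groups(
            region_results["PVH"],
            region_results["VMH"],
            config.min_consecutive,
            grid,
        ):
            comparison_rows.append(
                {
                    "comparison": "PVH_vs_VMH_Restricted",
                    "sign": run.sign,
                    "start_bin": run.start_bin,
                    "end_bin": run.end_bin,
                    "start_s": run.start_s,
                    "start_anchor": run.start_anchor,
                    "end_s": run.end_s,
                    "end_anchor": run.end_anchor,
                }
            )

    behavior_df = pd.DataFrame(behavior_rows)
    anova_rows = []
    if not behavior_df.empty:
        conditions = set(behavior_df["condition"])
        if {"Restricted", "Light", "Dark", "Sucralose"} <= conditions:
            per_mouse = (
                behavior_df.groupby(["mouse_id", "condition"], as_index=False)
                .mean(numeric_only=True)
            )
            complete = (
                per_mouse.groupby("mouse_id")["condition"].nunique() >= 4
            )
            keep = complete[complete].index
            per_mouse = per_mouse[per_mouse["mouse_id"].isin(keep)]
            if per_mouse["mouse_id"].nunique() >= 2:
                for measure in ("total_licks", "n_bouts", "mean_bout_length_s"):
                    res = rm_anova_oneway(
                        per_mouse, "mouse_id", "condition", measure
                    )
                    anova_rows.append(
                        {
                            "measure": measure,
                            "F": res.F,
                            "df1": res.df1,
                            "df2": res.df2,
                            "p_value": res.p_value,
                        }
                    )

    bundle = {
        "bouts": pd.DataFrame(bout_rows),
        "behavior": behavior_df,
        "snip_status": pd.DataFrame(status_rows),
        "waveform_bins": pd.DataFrame(wave_rows),
        "runs": pd.DataFrame(run_rows),
        "onset_offset": pd.DataFrame(time_rows),
        "auc": pd.DataFrame(auc_rows),
        "region_comparison": pd.DataFrame(comparison_rows),
        "anova": pd.DataFrame(anova_rows),
        "bootstrap": bootstraps,
        "region_bootstrap": region_results,
        "group_snips": group_snips,
    }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            if isinstance(df, pd.DataFrame):
                write_table(df, outdir / f"{name}.csv")
        manifest = {
            "package": "lickwave",
            "version": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "n_sessions": len(sessions),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if config.make_figures:
            _write_figures(bundle, grid, outdir)
    return bundle


def _write_figures(bundle: dict, grid: SnipGrid, outdir: Path) -> None:
    """Mean +/- CI traces and heatmaps of snips sorted by post-lick z."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(grid.total_bins)
    for key, result in bundle["bootstrap"].items():
        region, condition = key
        fig, (ax_hm, ax_tr) = plt.subplots(
            2, 1, figsize=(7, 6), sharex=True,
            gridspec_kw={"height_ratios": [2, 1]},
        )
        snips = [s for s in bundle["group_snips"][key] if s.included]
        if snips:
            M = np.asarray([s.values for s in snips])
            order = np.argsort(-M[:, grid.post_start_bin :].mean(axis=1))
            im = ax_hm.imshow(
                M[order], aspect="auto", cmap="RdBu_r",
                vmin=-3, vmax=3, interpolation="nearest",
            )
            fig.colorbar(im, ax=ax_hm, label="z")
        ax_hm.set_ylabel("bout (sorted by post-lick z)")
        ax_tr.fill_between(x, result.ci_lower, result.ci_upper, alpha=0.3)
        ax_tr.plot(x, result.mean_wave)
        ax_tr.axhline(0.0, color="k", lw=0.5)
        for edge in (grid.pre_bins, grid.end_anchor_bin, grid.post_start_bin):
            ax_tr.axvline(edge, color="grey", lw=0.5, ls="--")
        ax_tr.set_xlabel("bin (0.1 s)")
        ax_tr.set_ylabel("z")
        ax_tr.set_title(f"{region} / {condition} (n={result.n_snips})")
        fig.tight_layout()
        fig.savefig(outdir / f"waveform_{region}_{condition}.png", dpi=120)
        plt.close(fig)
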