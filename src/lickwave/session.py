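"""Session container and on-disk formats.

A :class:`Session` is the pipeline's atomic input: a list of lick
timestamps (seconds from recording start) plus the two continuous
fluorescence channels — 465 nm sensor signal and 405 nm isosbestic
control — sampled at ``fs_hz``, with animal/region/condition metadata.

Two interchangeable on-disk dialects are supported and auto-detected:

* HDF5 (single file, ``.h5``/``.hdf5``): groups ``/meta`` (attributes
  ``mouse_id``, ``region``, ``condition``, ``fs_hz``, ``t0_s``),
  ``/licks`` (1-D float64) and ``/signals/f465``, ``/signals/f405``.
* CSV directory: ``licks.csv`` (one column ``time_s``), ``signals.csv``
  (columns ``t_s``, ``f465``, ``f405``) and ``meta.json``.

Both round-trip losslessly (float64 bit-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import (
    LengthMismatchError,
    LickwaveError,
    MissingChannelError,
    NonMonotonicTimeError,
    SessionFormatError,
)

logger = logging.getLogger(__name__)

REGIONS = ("PVH", "VMH", "other")
CONDITIONS = ("Restricted", "Light", "Dark", "Sucralose", "other")


@dataclass
class Session:
    """One recording session: licks + dual-channel photometry + metadata."""

    mouse_id: str
    region: str
    condition: str
    licks: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.licks = np.asarray(self.licks, dtype=np.float64)
        self.f465 = np.asarray(self.f465, dtype=np.float64)
        self.f405 = np.asarray(self.f405, dtype=np.float64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.f465)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        """Sample timestamps, seconds from recording start."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise SessionFormatError(f"fs_hz must be > 0, got {self.fs_hz}")
        if len(self.f465) != len(self.f405):
            raise LengthMismatchError(
                f"f465 has {len(self.f465)} samples but f405 has {len(self.f405)}"
            )
        if self.licks.ndim != 1:
            raise SessionFormatError("licks must be a 1-D array of seconds")
        if len(self.licks) and np.any(np.diff(self.licks) <= 0):
            raise NonMonotonicTimeError(
                "lick timestamps must be strictly ascending "
                "(use read_session / clean_licks to sort and deduplicate)"
            )
        if len(self.licks):
            t_end = self.t0_s + self.n_samples / self.fs_hz
            if self.licks[0] < self.t0_s or self.licks[-1] > t_end:
                raise SessionFormatError(
                    f"licks must lie within the recorded span "
                    f"[{self.t0_s}, {t_end:.3f}] s; got "
                    f"[{self.licks[0]}, {self.licks[-1]}]"
                )


def clean_licks(raw: np.ndarray) -> np.ndarray:
    """Sort lick timestamps and drop exact duplicates, warning if anything changed.

    Lickometer glitches commonly produce duplicated or out-of-order
    timestamps; the repair is logged, never silent.
    """
    raw = np.asarray(raw, dtype=np.float64)
    cleaned = np.unique(raw)
    if len(cleaned) != len(raw) or not np.array_equal(cleaned, raw):
        logger.warning(
            "lick timestamps were not strictly ascending: sorted and dropped "
            "%d duplicate(s)", len(raw) - len(cleaned)
        )
    return cleaned


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def _is_hdf5_path(path: Path) -> bool:
    if path.is_dir():
        return False
    if path.suffix.lower() in (".h5", ".hdf5"):
        return True
    return path.is_file() and h5py.is_hdf5(str(path))


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session; HDF5 for ``.h5``/``.hdf5`` paths, CSV directory otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _write_hdf5(session, path)
    return _write_csvdir(session, path)


def read_session(path: str | Path) -> Session:
    """Read a session, auto-detecting the HDF5 or CSV-directory dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5_path(path):
        return _read_hdf5(path)
    if path.is_dir():
        return _read_csvdir(path)
    raise SessionFormatError(f"{path} is neither an HDF5 file nor a session directory")


def _write_hdf5(session: Session, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["mouse_id"] = session.mouse_id
        meta.attrs["region"] = session.region
        meta.attrs["condition"] = session.condition
        meta.attrs["fs_hz"] = float(session.fs_hz)
        meta.attrs["t0_s"] = float(session.t0_s)
        f.create_dataset("licks", data=session.licks)
        sig = f.create_group("signals")
        sig.create_dataset("f465", data=session.f465)
        sig.create_dataset("f405", data=session.f405)
    return path


def _read_hdf5(path: Path) -> Session:
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise MissingChannelError(f"{path}: missing /signals group")
        for name in ("f465", "f405"):
            if name not in f["signals"]:
                raise MissingChannelError(f"{path}: missing /signals/{name}")
        if "licks" not in f:
            raise MissingChannelError(f"{path}: missing /licks dataset")
        meta = f["meta"].attrs if "meta" in f else {}
        licks = clean_licks(f["licks"][()])
        return Session(
            mouse_id=str(meta.get("mouse_id", "unknown")),
            region=str(meta.get("region", "other")),
            condition=str(meta.get("condition", "other")),
            licks=licks,
            f465=f["signals/f465"][()],
            f405=f["signals/f405"][()],
            fs_hz=float(meta.get("fs_hz", 0.0)),
            t0_s=float(meta.get("t0_s", 0.0)),
        )


def _write_csvdir(session: Session, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": session.licks}).to_csv(
        path / "licks.csv", index=False
    )
    pd.DataFrame(
        {"t_s": session.time_s, "f465": session.f465, "f405": session.f405}
    ).to_csv(path / "signals.csv", index=False)
    meta = {
        "mouse_id": session.mouse_id,
        "region": session.region,
        "condition": session.condition,
        "fs_hz": session.fs_hz,
        "t0_s": session.t0_s,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def _read_csvdir(path: Path) -> Session:
    signals_path = path / "signals.csv"
    licks_path = path / "licks.csv"
    if not signals_path.exists():
        raise MissingChannelError(f"{path}: missing signals.csv")
    if not licks_path.exists():
        raise MissingChannelError(f"{path}: missing licks.csv")
    signals = pd.read_csv(signals_path, float_precision="round_trip")
    for col in ("t_s", "f465", "f405"):
        if col not in signals.columns:
            raise MissingChannelError(f"{signals_path}: missing column {col!r}")
        if signals[col].isna().any():
            raise LengthMismatchError(
                f"{signals_path}: column {col!r} is shorter than the others "
                "(missing values found)"
            )
    t = signals["t_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise NonMonotonicTimeError(f"{signals_path}: t_s is not strictly increasing")
    meta_path = path / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fs_hz = float(meta.get("fs_hz", 0.0))
    if fs_hz <= 0.0 and len(t) > 1:
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    licks_df = pd.read_csv(licks_path, float_precision="round_trip")
    if "time_s" not in licks_df.columns:
        raise MissingChannelError(f"{licks_path}: missing column 'time_s'")
    licks = clean_licks(licks_df["time_s"].to_numpy())
    return Session(
        mouse_id=str(meta.get("mouse_id", "unknown")),
        region=str(meta.get("region", "other")),
        condition=str(meta.get("condition", "other")),
        licks=licks,
        f465=signals["f465"].to_numpy(),
        f405=signals["f405"].to_numpy(),
        fs_hz=fs_hz,
        t0_s=float(meta.get("t0_s", t[0] if len(t) else 0.0)),
    )


# ---------------------------------------------------------------------------
# tidy result tables
# ---------------------------------------------------------------------------

def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write tidy rows as an RFC-4180 CSV with header, floats at full precision.

    ``rows`` is a homogeneous sequence of mappings (identical key sets) or a
    DataFrame. ``columns`` supplies the header when ``rows`` is empty.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            keys = [tuple(r.keys()) for r in rows]
            if len(set(keys)) != 1:
                raise LickwaveError(
                    "heterogeneous rows: all rows must share the same keys"
                )
            df = pd.DataFrame(rows, columns=list(keys[0]))
        else:
            df = pd.DataFrame(columns=list(columns or []))
    # str(float) is shortest-round-trip; re-read with float_precision="round_trip"
    df.to_csv(path, index=False)
    return path
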