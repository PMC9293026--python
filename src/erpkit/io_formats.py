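"""Readers and writers for the external data representations.

Three kinds of input are handled: continuous multichannel EEG (EDF+ or a
documented delimited-text dialect), a stimulus event table, and an
eye-tracker gaze-sample table.  Feature and reliability tables are written
as CSV/TSV and round-trip through :func:`read_table`.

No science happens here: units are microvolts and seconds in, microvolts
and seconds out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of stimulus condition labels.
CONDITIONS = (
    "checkerboard",
    "face_upright",
    "face_inverted",
    "animal_upright",
    "animal_inverted",
)

#: The 8-channel montage used throughout (dry-electrode low-density cap).
DEFAULT_CHANNELS = ("FPz", "Fz", "Cz", "Oz", "C3", "C4", "P7", "P8")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Ordered channel labels; one per data row.
    t0 : float
        Acquisition start time in seconds (arbitrary origin).
    """

    data: np.ndarray
    fs: float
    channels: tuple
    t0: float = 0.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if data.ndim != 2 or data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {data.shape} inconsistent with "
                f"{len(self.channels)} channel labels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass(frozen=True)
class EventList:
    """Stimulus onsets as sample indices into a Recording."""

    onsets: np.ndarray
    conditions: tuple
    trial_ids: tuple

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=int)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "trial_ids", tuple(self.trial_ids))
        if not (len(onsets) == len(self.conditions) == len(self.trial_ids)):
            raise ValueError("onsets, conditions and trial_ids must align")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        bad = [c for c in self.conditions if c not in CONDITIONS]
        if bad:
            raise FormatError(
                f"condition(s) {sorted(set(bad))} outside vocabulary {CONDITIONS}"
            )
        if len(set(self.trial_ids)) != len(self.trial_ids):
            raise ValueError("trial_ids must be unique")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass(frozen=True)
class GazeStream:
    """Eye-tracker samples: time (s), screen coordinates, validity flag.

    Invalid samples are retained (``valid=False``) because gap interpolation
    needs to see them.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        for name, arr in (("times", times), ("x", x), ("y", y), ("valid", valid)):
            object.__setattr__(self, name, arr)
        n = len(times)
        if not (len(x) == len(y) == len(valid) == n):
            raise ValueError("gaze arrays must have equal length")
        if n > 1 and np.any(np.diff(times) < 0):
            raise FormatError("gaze times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# continuous EEG


def read_continuous_eeg(path, dialect: str | None = None) -> Recording:
    """Read continuous EEG from EDF+ or the delimited-text dialect.

    The text dialect is a comma- or tab-separated table whose first column
    is ``time`` in seconds and whose remaining columns are channel traces
    in µV; the sampling rate is inferred from the time column, which must
    be uniform.

    Parameters
    ----------
    path : path-like
    dialect : {"edf", "tsv"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if dialect == "edf":
        return _read_edf(path)
    if dialect == "tsv":
        return _read_eeg_text(path)
    raise FormatError(f"unknown EEG dialect {dialect!r}")


def _read_edf(path: Path) -> Recording:
    import mne  # heavy import; only needed on the EDF path

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        t0=0.0,
    )


def _read_eeg_text(path: Path) -> Recording:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"{path}: cannot parse delimited EEG table: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0].lower() != "time":
        raise FormatError(
            f"{path}: first column must be 'time', got {list(df.columns)[:3]}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = next(zip(*np.nonzero(numeric.isna().to_numpy())))
        raise FormatError(
            f"{path}: non-numeric value {df.iat[row, col]!r} in column "
            f"{df.columns[col]!r}, data row {row + 1}"
        )
    t = numeric.iloc[:, 0].to_numpy()
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise FormatError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / float(np.median(dt))
    return Recording(
        data=numeric.iloc[:, 1:].to_numpy().T,
        fs=fs,
        channels=tuple(df.columns[1:]),
        t0=float(t[0]),
    )


def write_continuous_eeg(rec: Recording, path, sep: str = "\t") -> None:
    """Write a Recording in the delimited-text dialect read back by
    :func:`read_continuous_eeg`."""
    t = rec.t0 + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for i, ch in enumerate(rec.channels):
        df[ch] = rec.data[i]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# events


def read_events(path, fs: float | None = None) -> EventList:
    """Read the event table (columns trial_id, onset_sample or onset_time_s,
    condition).

    Onset times are converted to samples as ``floor(t*fs + 0.5)`` (round
    half up) and require ``fs``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = set(df.columns)
    if "trial_id" not in cols or "condition" not in cols:
        raise FormatError(f"{path}: need columns trial_id and condition, got {sorted(cols)}")
    if "onset_sample" in cols:
        onsets = df["onset_sample"].to_numpy(dtype=int)
    elif "onset_time_s" in cols:
        if fs is None:
            raise FormatError(f"{path}: onset_time_s given but no sampling rate supplied")
        onsets = np.floor(df["onset_time_s"].to_numpy(dtype=float) * fs + 0.5).astype(int)
    else:
        raise FormatError(f"{path}: need onset_sample or onset_time_s column")
    if df["trial_id"].duplicated().any():
        dup = df.loc[df["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise FormatError(f"{path}: duplicate trial_id {dup!r}")
    order = np.argsort(onsets, kind="stable")
    return EventList(
        onsets=onsets[order],
        conditions=tuple(df["condition"].iloc[order]),
        trial_ids=tuple(int(i) for i in df["trial_id"].iloc[order]),
    )


def write_events(ev: EventList, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"trial_id": ev.trial_ids, "onset_sample": ev.onsets, "condition": ev.conditions}
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# gaze


def read_gaze(path) -> GazeStream:
    """Read the gaze table (columns time_s, x, y, valid)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time_s", "x", "y", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gaze column(s) {sorted(missing)}")
    valid = df["valid"]
    if valid.dtype == object:
        valid = valid.astype(str).str.lower().isin(("true", "1", "yes"))
    return GazeStream(
        times=df["time_s"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        valid=valid.to_numpy(dtype=bool),
    )


def write_gaze(gs: GazeStream, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"time_s": gs.times, "x": gs.x, "y": gs.y, "valid": gs.valid.astype(int)}
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# generic record tables


def write_table(rows: Iterable[Mapping] | pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write homogeneous records as a delimited table (full float precision)."""
    if dialect not in ("csv", "tsv"):
        raise FormatError(f"unknown table dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty and df.columns.empty:
        # header-only files still need columns; an empty record list with no
        # known schema writes nothing but the newline-terminated header line
        Path(path).write_text("\n")
        return
    df.to_csv(path, sep=sep, index=False)


def read_table(path, dialect: str = "csv") -> pd.DataFrame:
    sep = "," if dialect == "csv" else "\t"
    return pd.read_csv(path, sep=sep)
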