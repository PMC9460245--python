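"""Reading, denoising and windowing of multi-channel inertial recordings.

A :class:`Recording` is one subject's labelled sensor stream (accelerometer,
gyroscope, magnetometer channels at a fixed sample rate).  Recordings are
denoised with a running median filter — the standard defence against the
saw-tooth/spike artefacts of MEMS inertial sensors — and then cut into
fixed-length, possibly overlapping :class:`Window` segments, each carrying
the majority per-sample activity label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "Recording",
    "Window",
    "SchemaError",
    "read_recordings",
    "write_recordings_csv",
    "median_denoise",
    "segment",
    "write_windows",
    "read_windows",
]


class SchemaError(ValueError):
    """The CSV column mapping does not match the file contents."""


@dataclass
class Recording:
    """A labelled multi-channel inertial time series for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the person wearing the sensors.
    sample_rate_hz : float
        Sampling frequency, strictly positive.
    channel_names : list of str
        One name per column of ``samples``, in column order.
    samples : ndarray, shape (T, C)
        Sensor readings; must be finite.
    labels : ndarray, shape (T,)
        Per-sample activity-class identifier.
    """

    subject_id: str
    sample_rate_hz: float
    channel_names: list[str]
    samples: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (T, C) matrix")
        t, c = self.samples.shape
        if t < 1 or c < 1:
            raise ValueError("recording needs at least one sample and one channel")
        if c != len(self.channel_names):
            raise ValueError("channel_names length must match sample columns")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (t,):
            raise ValueError("labels must have one entry per sample")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class Window:
    """A fixed-duration segment of one recording with a single label.

    ``label`` is the modal per-sample label of the segment and
    ``label_purity`` the fraction of samples carrying it.  Sample indexing is
    0-based and the window covers the half-open interval
    ``[start_index, start_index + n)`` of the source recording.
    """

    subject_id: str
    label: str
    samples: np.ndarray
    sample_rate_hz: float
    start_index: int
    label_purity: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("window samples must be (n, C)")
        if not 0.0 <= self.label_purity <= 1.0:
            raise ValueError("label_purity must lie in [0, 1]")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def _interpolate_gaps(values: np.ndarray, max_gap: int, column: str) -> np.ndarray:
    """Fill NaN runs of length <= max_gap linearly; longer runs are an error.

    Runs touching the first/last sample are filled with the nearest value.
    """
    isnan = np.isnan(values)
    if not isnan.any():
        return values
    # locate runs of consecutive NaNs
    padded = np.concatenate([[False], isnan, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    for s, e in zip(starts, ends):
        if e - s > max_gap:
            raise ValueError(
                f"channel {column!r}: {e - s} consecutive missing samples at row {s}"
                f" exceed the gap limit of {max_gap}"
            )
    ser = pd.Series(values)
    ser = ser.interpolate(method="linear", limit_direction="both")
    return ser.to_numpy()


def read_recordings(path: str | os.PathLike, schema: dict) -> list[Recording]:
    """Read a labelled multi-subject CSV into one :class:`Recording` per subject.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    schema : dict
        Column mapping with keys:

        ``subject`` : name of the subject-id column (required)
        ``label`` : name of the activity-label column (required)
        ``sample_rate_hz`` : sampling frequency of the file (required)
        ``channels`` : list of channel columns (wide layout)
        ``timestamp`` : optional time column used to sort samples
        ``layout`` : ``"wide"`` (default) or ``"long"``; a long layout needs
        ``channel_column`` and ``value_column`` plus ``timestamp``
        ``max_gap`` : largest run of missing samples to interpolate (default 5)

    Returns
    -------
    list of Recording
        One per subject, in order of first appearance in the file.
    """
    for key in ("subject", "label", "sample_rate_hz"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    layout = schema.get("layout", "wide")
    max_gap = int(schema.get("max_gap", 5))
    df = pd.read_csv(path)

    def _require(col: str) -> None:
        if col not in df.columns:
            raise SchemaError(f"mapped column {col!r} not present in {path}")

    _require(schema["subject"])
    _require(schema["label"])
    ts_col = schema.get("timestamp")
    if ts_col is not None:
        _require(ts_col)

    if layout == "long":
        for key in ("channel_column", "value_column"):
            if key not in schema:
                raise SchemaError(f"long layout requires schema key {key!r}")
        _require(schema["channel_column"])
        _require(schema["value_column"])
        if ts_col is None:
            raise SchemaError("long layout requires a timestamp column")
        wide = df.pivot_table(
            index=[schema["subject"], ts_col],
            columns=schema["channel_column"],
            values=schema["value_column"],
            aggfunc="first",
        ).reset_index()
        label_map = df.groupby([schema["subject"], ts_col])[schema["label"]].first()
        wide[schema["label"]] = label_map.loc[
            list(zip(wide[schema["subject"]], wide[ts_col]))
        ].to_numpy()
        channels = sorted(df[schema["channel_column"]].unique())
        df = wide
    else:
        channels = list(schema.get("channels", []))
        if not channels:
            raise SchemaError("wide layout requires a non-empty 'channels' list")
        for col in channels:
            _require(col)

    recordings: list[Recording] = []
    for subject in pd.unique(df[schema["subject"]]):
        sub = df[df[schema["subject"]] == subject]
        if ts_col is not None:
            sub = sub.sort_values(ts_col, kind="stable")
        mat = np.empty((len(sub), len(channels)), dtype=float)
        for j, col in enumerate(channels):
            raw = pd.to_numeric(sub[col], errors="coerce")
            bad = raw.isna() & sub[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric value in channel {col!r} at row {sub.index[row]}"
                )
            mat[:, j] = _interpolate_gaps(raw.to_numpy(dtype=float), max_gap, col)
        recordings.append(
            Recording(
                subject_id=str(subject),
                sample_rate_hz=float(schema["sample_rate_hz"]),
                channel_names=[str(c) for c in channels],
                samples=mat,
                labels=sub[schema["label"]].astype(str).to_numpy(),
            )
        )
    return recordings


def write_recordings_csv(recordings: list[Recording], path: str | os.PathLike) -> dict:
    """Write recordings to a single wide CSV; returns the matching schema."""
    if not recordings:
        raise ValueError("no recordings to write")
    channels = recordings[0].channel_names
    rate = recordings[0].sample_rate_hz
    frames = []
    for rec in recordings:
        if rec.channel_names != channels:
            raise ValueError("all recordings must share channel names")
        frame = pd.DataFrame(rec.samples, columns=channels)
        frame.insert(0, "subject", rec.subject_id)
        frame.insert(1, "label", rec.labels)
        frame.insert(2, "t", np.arange(rec.n_samples) / rec.sample_rate_hz)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return {
        "subject": "subject",
        "label": "label",
        "timestamp": None,
        "channels": channels,
        "sample_rate_hz": rate,
    }


def median_denoise(recording: Recording, kernel: int = 3) -> Recording:
    """Replace each channel by its running median over a centred window.

    The sensor stream is vulnerable to isolated spike/saw-tooth noise from
    abrupt displacement of the unit; a short median filter removes such
    single-sample outliers without smearing step edges the way a moving
    average would.  Boundaries are handled by edge replication, so the output
    has the same length as the input.  Labels and metadata are unchanged.
    """
    if kernel % 2 != 1:
        raise ValueError("median filter kernel must be odd")
    if kernel < 1 or kernel > recording.n_samples:
        raise ValueError("kernel must lie in [1, T]")
    filtered = median_filter(recording.samples, size=(kernel, 1), mode="nearest")
    return replace(recording, samples=filtered, labels=recording.labels.copy())


def _modal_label(labels: np.ndarray) -> tuple[str, float]:
    """Majority label with lexicographically-smallest tie-break, and purity."""
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    i = order[0]
    return str(uniq[i]), counts[i] / labels.size


def segment(
    recording: Recording,
    window_seconds: float,
    overlap_fraction: float = 0.5,
    purity_threshold: float = 0.75,
) -> list[Window]:
    """Cut a recording into fixed-length windows with majority labels.

    Windows of ``n = round(window_seconds * sample_rate_hz)`` samples start
    every ``round(n * (1 - overlap_fraction))`` samples.  A window's label is
    the modal per-sample label (ties broken by the lexicographically smallest
    label); windows whose modal-label fraction falls below
    ``purity_threshold`` are dropped, as is any trailing partial window.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    if not 0.0 < purity_threshold <= 1.0:
        raise ValueError("purity_threshold must lie in (0, 1]")
    n = int(round(window_seconds * recording.sample_rate_hz))
    if n < 8:
        raise ValueError(f"window of {n} samples is too short (minimum 8)")
    stride = max(1, int(round(n * (1.0 - overlap_fraction))))
    windows: list[Window] = []
    for start in range(0, recording.n_samples - n + 1, stride):
        seg_labels = recording.labels[start : start + n]
        label, purity = _modal_label(seg_labels)
        if purity < purity_threshold:
            continue
        windows.append(
            Window(
                subject_id=recording.subject_id,
                label=label,
                samples=recording.samples[start : start + n].copy(),
                sample_rate_hz=recording.sample_rate_hz,
                start_index=start,
                label_purity=purity,
            )
        )
    return windows


def write_windows(
    windows: list[Window], outdir: str | os.PathLike, channel_names: list[str] | None = None
) -> str:
    """Persist windows as per-segment CSVs plus a manifest CSV.

    Returns the manifest path.  Segment files are named ``segment_<i>.csv``
    in manifest row order.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, win in enumerate(windows):
        names = channel_names or [f"ch_{j}" for j in range(win.n_channels)]
        fname = f"segment_{i:05d}.csv"
        pd.DataFrame(win.samples, columns=names).to_csv(
            os.path.join(outdir, fname), index=False, float_format="%.17g"
        )
        rows.append(
            {
                "file": fname,
                "subject_id": win.subject_id,
                "label": win.label,
                "start_index": win.start_index,
                "label_purity": win.label_purity,
                "sample_rate_hz": win.sample_rate_hz,
            }
        )
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.17g")
    return manifest


def read_windows(outdir: str | os.PathLike) -> list[Window]:
    """Load windows written by :func:`write_windows`."""
    manifest = pd.read_csv(os.path.join(outdir, "manifest.csv"))
    windows = []
    for row in manifest.itertuples(index=False):
        samples = pd.read_csv(
            os.path.join(outdir, row.file), float_precision="round_trip"
        ).to_numpy(dtype=float)
        windows.append(
            Window(
                subject_id=str(row.subject_id),
                label=str(row.label),
                samples=samples,
                sample_rate_hz=float(row.sample_rate_hz),
                start_index=int(row.start_index),
                label_purity=float(row.label_purity),
            )
        )
    return windows
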