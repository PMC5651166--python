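"""Multichannel EEG recording I/O, channel statistics and reference selection.

A recording is a plain samples-by-channels matrix with a sampling rate and
channel labels.  Three on-disk formats are supported:

* **EDF** (European Data Format), the format PhysioNet distributes scalp EEG
  in.  Header sampling rate and physical scaling are honoured; EEG channels
  are returned in microvolts.
* **CSV** — one column per channel, optional header row of labels.
* **MAT** — a MATLAB file holding a single 2-D numeric array; orientation is
  auto-detected (the longer axis is taken as time).

Channel indices are 1-based everywhere user-facing, matching the convention
of clinical EEG channel numbering.  The *reference* channel — the channel
assumed closest to artifact-free — is the one with the smallest sample
standard deviation.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MultichannelRecording",
    "ChannelStats",
    "load_recording",
    "write_csv",
    "channel_statistics",
    "select_reference",
]


@dataclass
class MultichannelRecording:
    """A block of multichannel signal data.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_samples, n_channels)`` in recording
        amplitude units (microvolts for EDF input).
    fs
        Sampling rate in Hz; must be positive.
    labels
        One identifier per channel.
    t0
        Start offset of the block in seconds.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int) -> np.ndarray:
        """Return one channel by 1-based index."""
        if not 1 <= index <= self.n_channels:
            raise IndexError(
                f"channel {index} out of range 1..{self.n_channels}"
            )
        return self.data[:, index - 1]


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel summary statistics (amplitude units of the recording)."""

    channel: int  # 1-based
    mean: float
    abs_mean: float
    std: float  # sample (n-1) standard deviation


def load_recording(
    path: str | Path,
    format: str | None = None,
    duration_s: float | None = None,
    fs: float = 256.0,
) -> MultichannelRecording:
    """Load a multichannel recording from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``"edf"``, ``"csv"``, ``"mat"``; inferred from the file
        extension when omitted.
    duration_s
        If given, keep only the first ``round(duration_s * fs)`` samples.
    fs
        Sampling rate assumed for CSV and MAT input (EDF carries its own).

    Raises
    ------
    OSError
        Unreadable or missing file.
    ValueError
        Malformed content (e.g. ragged CSV rows) or an unknown format tag.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "edf":
        rec = _load_edf(path)
    elif format == "csv":
        rec = _load_csv(path, fs)
    elif format == "mat":
        rec = _load_mat(path, fs)
    else:
        raise ValueError(f"unknown format {format!r}; expected edf, csv or mat")
    if duration_s is not None:
        n = int(round(duration_s * rec.fs))
        if n > rec.n_samples:
            raise ValueError(
                f"requested {duration_s} s = {n} samples but the record has "
                f"only {rec.n_samples}"
            )
        rec = MultichannelRecording(rec.data[:n], rec.fs, rec.labels, rec.t0)
    return rec


def _load_edf(path: Path) -> MultichannelRecording:
    if not path.exists():
        raise OSError(f"no such file: {path}")
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # MNE rescales to SI units (volts for EEG); undo to the microvolt scale
    # the EDF header's physical dimension uses for scalp EEG.
    data = raw.get_data().T * 1e6
    return MultichannelRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _load_csv(path: Path, fs: float) -> MultichannelRecording:
    if not path.exists():
        raise OSError(f"no such file: {path}")
    with open(path, newline="") as fh:
        rows = [row for row in _csv.reader(fh) if row]
    if not rows:
        raise ValueError(f"empty CSV file: {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged CSV rows in {path}: widths {sorted(widths)}")

    def _numeric(row: list[str]) -> bool:
        try:
            [float(v) for v in row]
            return True
        except ValueError:
            return False

    if _numeric(rows[0]):
        labels = [f"ch{i + 1}" for i in range(len(rows[0]))]
        body = rows
    else:
        labels = [v.strip() for v in rows[0]]
        body = rows[1:]
        if not body:
            raise ValueError(f"CSV file {path} has a header but no data rows")
    try:
        data = np.array([[float(v) for v in row] for row in body])
    except ValueError as exc:
        raise ValueError(f"non-numeric value in {path}: {exc}") from exc
    return MultichannelRecording(data, fs, labels)


def _load_mat(path: Path, fs: float) -> MultichannelRecording:
    if not path.exists():
        raise OSError(f"no such file: {path}")
    arrays: dict[str, np.ndarray] = {}
    try:
        from scipy.io import loadmat

        for key, val in loadmat(path).items():
            if key.startswith("__"):
                continue
            arr = np.asarray(val)
            if arr.ndim == 2 and np.issubdtype(arr.dtype, np.number):
                arrays[key] = arr.astype(float)
    except NotImplementedError:  # MAT v7.3 is HDF5
        import h5py

        with h5py.File(path, "r") as fh:
            for key in fh:
                arr = np.asarray(fh[key])
                if arr.ndim == 2 and np.issubdtype(arr.dtype, np.number):
                    arrays[key] = arr.astype(float)
    if len(arrays) != 1:
        raise ValueError(
            f"expected exactly one 2-D numeric array in {path}, "
            f"found {sorted(arrays)}"
        )
    data = next(iter(arrays.values()))
    if data.shape[0] < data.shape[1]:  # longer axis is time
        data = data.T
    labels = [f"ch{i + 1}" for i in range(data.shape[1])]
    return MultichannelRecording(data, fs, labels)


def write_csv(rec: MultichannelRecording, path: str | Path) -> None:
    """Write a recording as CSV (header row of labels, one column/channel).

    Values are written with 17 significant digits so that a CSV round trip
    reproduces the double-precision samples bit-exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(rec.labels)
        for row in rec.data:
            writer.writerow([f"{v:.17g}" for v in row])


def channel_statistics(rec: MultichannelRecording) -> list[ChannelStats]:
    """Mean, absolute mean and sample standard deviation per channel.

    Requires at least two samples (the n-1 denominator of the sample
    standard deviation is undefined otherwise).
    """
    if rec.n_channels < 1:
        raise ValueError("recording has no channels")
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to compute a standard deviation")
    means = rec.data.mean(axis=0)
    stds = rec.data.std(axis=0, ddof=1)
    return [
        ChannelStats(channel=i + 1, mean=float(m), abs_mean=float(abs(m)), std=float(s))
        for i, (m, s) in enumerate(zip(means, stds))
    ]


def select_reference(stats: list[ChannelStats]) -> int:
    """1-based index of the reference channel: smallest standard deviation.

    Ties are broken toward the lowest channel index.  The selected channel is
    the one presumed least affected by motion artifacts and serves as the
    correlation reference for artifact recognition.
    """
    if not stats:
        raise ValueError("empty statistics list")
    return min(stats, key=lambda s: (s.std, s.channel)).channel
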