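"""EEG containers, CSV/EDF readers, epoch segmentation and normalization.

Recordings are channels x samples matrices with an ordered channel-label
list.  The canonical interchange format is a plain CSV whose single header
row holds the channel labels and whose data rows are channels (one row per
electrode).  EDF import is optional and delegated to :mod:`mne` when it is
installed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Default 16-electrode montage of the international 10-20 system used for
#: bipolar resting-state recordings (bilateral earlobe reference).
MONTAGE_16 = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)


class DegenerateChannelError(ValueError):
    """A channel has zero variance where nonzero variance is required."""


class MontageMismatchError(ValueError):
    """Channel count or labels disagree with the expected montage."""


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts or arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_labels : sequence of str
        Ordered electrode names, one per data row.
    subject_id : str
        Identifier of the subject the recording belongs to.
    group : str
        Diagnostic group label, conventionally ``"AD"``, ``"CN"`` or
        ``"unknown"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_16
    subject_id: str = "unknown"
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise MontageMismatchError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels were given"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or infinite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs cut from one or more recordings.

    ``provenance`` carries one ``(subject_id, group, epoch_index)`` triple
    per epoch; epoch indices are consecutive in source time.
    """

    epochs: list[np.ndarray]
    fs: float
    epoch_seconds: float
    channel_labels: tuple[str, ...]
    provenance: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            shape = self.epochs[0].shape
            for e in self.epochs:
                if e.shape != shape:
                    raise ValueError("all epochs must share an identical shape")
        if len(self.provenance) != len(self.epochs):
            raise ValueError("provenance must align with epochs")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[0] if self.epochs else 0


def read_recording(
    path: str | Path,
    fs: float,
    format: str = "csv",
    montage: tuple[str, ...] | None = None,
    subject_id: str = "unknown",
    group: str = "unknown",
) -> EEGRecording:
    """Read a recording from disk and validate it.

    CSV files must carry one header row of channel labels and one numeric
    row per channel.  When ``montage`` is given, the file's channel count
    and labels are checked against it (case-insensitive).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        labels, data = _read_csv_matrix(path)
    elif format == "edf":
        labels, data, fs = _read_edf(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if montage is not None:
        want = [m.upper() for m in montage]
        got = [l.upper() for l in labels]
        if got != want:
            raise MontageMismatchError(
                f"{path.name}: channels {got} do not match expected montage {want}"
            )
    return EEGRecording(data=data, fs=fs, channel_labels=labels,
                        subject_id=subject_id, group=group)


def _read_csv_matrix(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        labels = tuple(h.strip() for h in header)
        rows = []
        for i, row in enumerate(reader):
            if not row:
                continue
            try:
                rows.append([float(v) for v in row])
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell in channel row {i}"
                ) from None
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        raise ValueError(f"{path}: no data rows")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: NaN or infinite value present")
    return labels, data


def _read_edf(path: Path):  # pragma: no cover - optional dependency path
    try:
        import mne
    except ImportError as exc:
        raise ImportError(
            "EDF support requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return tuple(raw.ch_names), raw.get_data(), float(raw.info["sfreq"])


def write_recording(rec: EEGRecording, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a recording as the canonical CSV matrix (rows = channels)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(rec.channel_labels)
        for row in rec.data:
            writer.writerow([fmt % v for v in row])


def segment_epochs(
    rec: EEGRecording,
    epoch_seconds: float,
    start_s: float = 0.0,
    duration_s: float | None = None,
) -> EpochSet:
    """Cut ``floor(duration/epoch_seconds)`` non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded; each epoch
    has ``round(epoch_seconds * fs)`` samples.  ``start_s`` selects the
    analysis span within the recording (e.g. a stable eyes-closed window).
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    if duration_s is None:
        duration_s = rec.duration_s - start_s
    if duration_s < epoch_seconds:
        raise ValueError(
            f"span of {duration_s} s cannot hold a {epoch_seconds} s epoch"
        )
    start = int(round(start_s * rec.fs))
    span = int(round(duration_s * rec.fs))
    if start + span > rec.n_samples:
        raise ValueError("requested span exceeds the recording length")
    window = int(round(epoch_seconds * rec.fs))
    n_epochs = span // window
    epochs, provenance = [], []
    for k in range(n_epochs):
        seg = rec.data[:, start + k * window: start + (k + 1) * window]
        epochs.append(np.array(seg))
        provenance.append((rec.subject_id, rec.group, k))
    return EpochSet(epochs=epochs, fs=rec.fs, epoch_seconds=epoch_seconds,
                    channel_labels=rec.channel_labels, provenance=provenance)


def segment_cohort(
    recordings: list[EEGRecording],
    epoch_seconds: float,
    start_s: float = 0.0,
    duration_s: float | None = None,
) -> EpochSet:
    """Segment several recordings into one pooled :class:`EpochSet`."""
    all_epochs: list[np.ndarray] = []
    provenance: list[tuple[str, str, int]] = []
    fs = recordings[0].fs
    labels = recordings[0].channel_labels
    for rec in recordings:
        if rec.fs != fs or rec.channel_labels != labels:
            raise ValueError("recordings must share fs and montage")
        es = segment_epochs(rec, epoch_seconds, start_s, duration_s)
        all_epochs.extend(es.epochs)
        provenance.extend(es.provenance)
    return EpochSet(epochs=all_epochs, fs=fs, epoch_seconds=epoch_seconds,
                    channel_labels=labels, provenance=provenance)


def zscore_epoch(epoch: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization per channel.

    Uses the population (1/N) standard deviation.  A constant channel is a
    hard error rather than silent zeros: downstream complexity features are
    undefined on flat signals.
    """
    epoch = np.asarray(epoch, dtype=float)
    mean = epoch.mean(axis=-1, keepdims=True)
    sd = epoch.std(axis=-1, keepdims=True)
    # relative tolerance so channels constant up to float rounding are caught
    tiny = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(tiny):
        flat = np.nonzero(tiny.ravel())[0].tolist()
        raise DegenerateChannelError(
            f"constant channel(s) {flat}: z-scoring undefined"
        )
    return (epoch - mean) / sd
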