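"""Recording / annotation containers and file I/O.

All intervals are 0-based, half-open ``[start, end)`` in sample indices;
seconds appear only at I/O boundaries. The canonical on-disk format for a
recording is a single self-describing HDF5 file (matrix + sampling rate +
channel labels); EDF is supported read-only for scalp EEG. Annotations
travel as CSV (``onset_sample, offset_sample, label``) or an equivalent
JSON list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

SEIZURE = "seizure"
NONSEIZURE = "nonseizure"
_LABELS = (SEIZURE, NONSEIZURE)

#: sampling-rate conversions demonstrated on the EEG path (input Hz -> target Hz)
SUPPORTED_UPSAMPLING = {256: 25_600, 250: 20_000, 1000: 20_000}


class FormatError(ValueError):
    """A file could not be parsed in the declared format."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


@dataclass
class Recording:
    """Multichannel time series: ``data`` is channels x samples.

    Amplitude units are arbitrary but consistent across channels; the
    synthetic generator uses background-SD units (SD of the non-seizure
    baseline == 1), the EEG path uses microvolts.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: Sequence[str] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("recording needs >= 1 channel and >= 1 sample")
        if not self.fs_hz > 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        self.channel_labels = [str(x) for x in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def subset_channels(self, idx: Sequence[int]) -> "Recording":
        idx = list(idx)
        return Recording(
            data=self.data[idx],
            fs_hz=self.fs_hz,
            channel_labels=[self.channel_labels[i] for i in idx],
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class Interval:
    """Half-open annotated span ``[start, end)`` in sample indices."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValidationError(f"label must be one of {_LABELS}, got {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Ordered, non-overlapping labeled intervals on one recording."""

    intervals: list[Interval]
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"intervals overlap: [{a.start},{a.end}) and [{b.start},{b.end})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def with_label(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    @property
    def seizure_intervals(self) -> list[Interval]:
        return self.with_label(SEIZURE)

    def validate_against(self, rec: Recording) -> None:
        if self.intervals and self.intervals[-1].end > rec.n_samples:
            raise ValidationError(
                f"annotation ends at {self.intervals[-1].end} but recording has "
                f"{rec.n_samples} samples"
            )


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to the canonical HDF5 container (lossless)."""
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.attrs["fs_hz"] = float(rec.fs_hz)
            f.attrs["source_id"] = rec.source_id
            f.create_dataset(
                "channel_labels",
                data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
            )
    except OSError as e:  # unwritable path
        raise OSError(f"cannot write recording to {path}: {e}") from e
    return path


def load_recording(path: str | Path, format: str = "container") -> Recording:
    """Load a recording from the HDF5 container or an EDF file.

    EDF signals are returned in microvolts (the conventional scalp-EEG unit),
    with the sampling rate declared in the EDF header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container":
        return _load_container(path)
    if format == "edf":
        return _load_edf(path)
    raise FormatError(f"unknown format {format!r}; expected 'container' or 'edf'")


def _load_container(path: Path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            for key in ("data", "channel_labels"):
                if key not in f:
                    raise FormatError(f"{path}: container missing field '{key}'")
            if "fs_hz" not in f.attrs:
                raise FormatError(f"{path}: container missing field 'fs_hz'")
            data = f["data"][()]
            labels = [x.decode() if isinstance(x, bytes) else str(x) for x in f["channel_labels"][()]]
            return Recording(
                data=data,
                fs_hz=float(f.attrs["fs_hz"]),
                channel_labels=labels,
                source_id=str(f.attrs.get("source_id", "")),
            )
    except OSError as e:
        raise FormatError(f"{path}: not a readable HDF5 container ({e})") from e


def _load_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as e:  # mne raises a mix of OSError/ValueError subtypes
        raise FormatError(f"{path}: not a readable EDF file ({e})") from e
    data = raw.get_data() * 1e6  # mne loads volts; report microvolts
    return Recording(
        data=data,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        source_id=path.stem,
    )


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path, recording_id: str = "") -> AnnotationSet:
    """Read annotations from CSV (onset_sample, offset_sample, label) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text() or "[]")
        records = [(int(r["onset_sample"]), int(r["offset_sample"]), r["label"]) for r in rows]
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["onset_sample", "offset_sample", "label"])
        missing = {"onset_sample", "offset_sample", "label"} - set(df.columns)
        if missing and len(df):
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        records = [
            (int(r.onset_sample), int(r.offset_sample), str(r.label))
            for r in df.itertuples(index=False)
        ]
    intervals = []
    for onset, offset, label in records:
        if offset <= onset:
            raise ValidationError(f"{path}: offset {offset} <= onset {onset}")
        intervals.append(Interval(onset, offset, label))
    return AnnotationSet(intervals=intervals, recording_id=recording_id)


def save_annotations(ann: AnnotationSet, path: str | Path, fs_hz: float | None = None) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = [
            {"onset_sample": iv.start, "offset_sample": iv.end, "label": iv.label}
            for iv in ann
        ]
        path.write_text(json.dumps(rows, indent=1))
    else:
        df = pd.DataFrame(
            {
                "onset_sample": [iv.start for iv in ann],
                "offset_sample": [iv.end for iv in ann],
                "label": [iv.label for iv in ann],
            }
        )
        if fs_hz:
            df["onset_s"] = df["onset_sample"] / fs_hz
            df["offset_s"] = df["offset_sample"] / fs_hz
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# cross-modal resampling / normalization (the EEG adaptation path)
# ---------------------------------------------------------------------------

def upsample_linear(rec: Recording, target_fs_hz: float, factor: int | None = None) -> Recording:
    """Linearly interpolate a low-rate recording up to an invasive-style rate.

    Only integer upsampling factors are supported; the demonstrated map is
    256 Hz -> 25 600 Hz (x100), 250 Hz -> 20 000 Hz (x80) and
    1000 Hz -> 20 000 Hz (x20). ``factor`` overrides the ratio check for
    other integer factors. Output length is ``(n - 1) * factor + 1`` and the
    original samples reappear unchanged at stride ``factor``.
    """
    if factor is None:
        ratio = target_fs_hz / rec.fs_hz
        factor = int(round(ratio))
        if not np.isclose(ratio, factor) or factor < 1:
            raise ValidationError(
                f"target {target_fs_hz} Hz is not an integer multiple of {rec.fs_hz} Hz; "
                f"supported map: {SUPPORTED_UPSAMPLING} (or pass an explicit integer factor)"
            )
    if factor == 1:
        return replace(rec, data=rec.data.copy(), fs_hz=float(target_fs_hz))

    x = rec.data
    n = x.shape[1]
    out = np.empty((x.shape[0], (n - 1) * factor + 1), dtype=np.float64)
    out[:, ::factor] = x
    lo, hi = x[:, :-1], x[:, 1:]
    seg_min, seg_max = np.minimum(lo, hi), np.maximum(lo, hi)
    for j in range(1, factor):
        t = j / factor
        # clip guards the no-overshoot guarantee against float rounding
        out[:, j::factor] = np.clip(lo + (hi - lo) * t, seg_min, seg_max)
    return replace(rec, data=out, fs_hz=float(target_fs_hz))


def scale_amplitude(rec: Recording, divisor: float) -> Recording:
    """Divide every sample by ``divisor`` (the EEG path uses 500)."""
    if not divisor > 0:
        raise ValidationError(f"divisor must be positive, got {divisor}")
    return replace(rec, data=rec.data / divisor)
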