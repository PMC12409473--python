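"""Sliding-window inference and conversion of positive flags into events.

The classifier scores windows started every ``step`` samples (5-20 points,
i.e. 0.25-1 ms at 20 kHz). Positive flags appear as clusters of consecutive
ones over ongoing discharges; clusters separated by a silent stretch no
longer than the merge gap (400 samples = 20 ms at 20 kHz, the minimum
in-vivo inter-seizure interval) are merged into a single event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording
from .model import TrainedModel

DEFAULT_MERGE_GAP = 400
DEFAULT_STEP = 20


@dataclass
class FlagSeries:
    """Starts of positively classified windows over one recording."""

    positions: np.ndarray
    step: int
    window_len: int
    n_samples: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions):
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("flag positions must be strictly increasing")
            if self.positions[-1] + self.window_len > self.n_samples:
                raise ValueError("a flagged window extends past the recording end")
            if np.any(self.positions % self.step):
                raise ValueError("positions must be multiples of the inference step")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class EventList:
    """Sorted, non-overlapping detected intervals [start, end)."""

    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [(int(s), int(e)) for s, e in self.events]
        for (s, e), (s2, _) in zip(self.events, self.events[1:]):
            if s2 < e:
                raise ValueError("events must be sorted and non-overlapping")
        if any(e <= s for s, e in self.events):
            raise ValueError("events must satisfy start < end")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_dataframe(self, fs_hz: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=["onset_sample", "offset_sample"])
        if fs_hz:
            df["onset_s"] = df["onset_sample"] / fs_hz
            df["offset_s"] = df["offset_sample"] / fs_hz
        return df

    def save_csv(self, path: str | Path, fs_hz: float | None = None) -> Path:
        path = Path(path)
        self.to_dataframe(fs_hz).to_csv(path, index=False)
        return path

    @staticmethod
    def load_csv(path: str | Path) -> "EventList":
        df = pd.read_csv(path)
        if df.empty:
            return EventList([])
        return EventList(list(zip(df["onset_sample"].astype(int), df["offset_sample"].astype(int))))


def sliding_infer(
    model: TrainedModel,
    rec: Recording,
    step: int = DEFAULT_STEP,
    threshold: float = 0.5,
    batch_size: int = 1024,
) -> FlagSeries:
    """Classify every step-spaced window; flag starts with p_seizure > threshold.

    Windows are materialized batch by batch from a strided view, so memory
    stays bounded even for minutes of 20 kHz data.
    """
    L = model.config.window_len
    if rec.n_samples < L:
        raise ValueError(f"recording has {rec.n_samples} samples but windows need {L}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(0, rec.n_samples - L + 1, step)
    view = np.lib.stride_tricks.sliding_window_view(rec.data, L, axis=1)  # C x starts x L
    flagged = []
    for i in range(0, len(starts), batch_size):
        chunk = starts[i : i + batch_size]
        windows = np.ascontiguousarray(view[:, chunk].transpose(1, 0, 2))
        p = model.predict_proba(windows, batch_size=batch_size)[:, 1]
        flagged.append(chunk[p > threshold])
    positions = np.concatenate(flagged) if flagged else np.empty(0, np.int64)
    return FlagSeries(positions=positions, step=step, window_len=L, n_samples=rec.n_samples)


def merge_intervals(intervals: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    """Merge sorted intervals whose gap (next start - previous end) <= merge_gap."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def flags_to_events(flags: FlagSeries, merge_gap: int = DEFAULT_MERGE_GAP) -> EventList:
    """Cluster flagged windows into events.

    Each flagged start s spans [s, s + L); spans whose silent gap is at most
    ``merge_gap`` samples are reported as one event. Consecutive flags
    (step < L apart) overlap and always fuse.
    """
    spans = [(int(s), int(s) + flags.window_len) for s in flags.positions]
    return EventList(merge_intervals(spans, merge_gap))
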