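"""Window augmentation: annotated recordings -> balanced labeled window sets.

Three strategies turn scarce, imbalanced seizure annotations into training
windows of shape channels x L (L = 100 samples = 5 ms at 20 kHz):

* **sequential** — a sliding window traverses every segment, stride 1 inside
  seizure segments and stride 50 inside non-seizure segments;
* **random contiguous** — a predefined number of windows drawn uniformly
  over all valid start positions of the matching class;
* **random non-contiguous** — hybrid positive windows splicing ``m`` non-
  seizure columns (``m`` uniform on ``[1, m_max]``, ``m_max < 40`` for
  L=100) in front of ``L - m`` seizure columns, the same time columns taken
  across all channels so cross-channel alignment is preserved.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .io import NONSEIZURE, SEIZURE, AnnotationSet, Recording, ValidationError

POSITIVE, NEGATIVE = 1, 0


@dataclass
class AugmentationConfig:
    window_len: int = 100
    stride_seizure: int = 1
    stride_nonseizure: int = 50
    m_max: int = 39
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValidationError("window_len must be >= 1")
        if not (1 <= self.m_max < self.window_len):
            raise ValidationError(f"need 1 <= m_max < window_len, got m_max={self.m_max}")
        if self.stride_seizure < 1 or self.stride_nonseizure < 1:
            raise ValidationError("strides must be >= 1")


@dataclass
class Segment:
    """Channel-complete sub-matrix of one annotated interval."""

    data: np.ndarray  # channels x length
    label: str
    segment_id: int
    start: int  # position in the source recording

    def __len__(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowSet:
    """Labeled windows plus per-window provenance and the config snapshot.

    ``data`` is (n, channels, L) float32; ``labels`` is (n,) with 1 =
    positive (seizure) and 0 = negative.
    """

    data: np.ndarray
    labels: np.ndarray
    provenance: list[dict] = field(default_factory=list)
    config: AugmentationConfig | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.data) != len(self.labels):
            raise ValidationError("data/labels length mismatch")
        if self.provenance and len(self.provenance) != len(self.labels):
            raise ValidationError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == POSITIVE))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == NEGATIVE))

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        prov = [self.provenance[i] for i in idx] if self.provenance else []
        return WindowSet(self.data[idx], self.labels[idx], prov, self.config)

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValidationError("nothing to concatenate")
        prov = sum((s.provenance for s in sets), [])
        return WindowSet(
            np.concatenate([s.data for s in sets]),
            np.concatenate([s.labels for s in sets]),
            prov,
            sets[0].config,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            f.create_dataset("labels", data=self.labels)
            f.attrs["provenance"] = json.dumps(self.provenance)
            if self.config is not None:
                f.attrs["config"] = json.dumps(asdict(self.config))
        return path

    @staticmethod
    def load(path: str | Path) -> "WindowSet":
        with h5py.File(path, "r") as f:
            cfg = (
                AugmentationConfig(**json.loads(f.attrs["config"]))
                if "config" in f.attrs
                else None
            )
            return WindowSet(
                f["data"][()],
                f["labels"][()],
                json.loads(f.attrs.get("provenance", "[]")),
                cfg,
            )


# ---------------------------------------------------------------------------

def extract_segments(rec: Recording, ann: AnnotationSet) -> tuple[list[Segment], list[Segment]]:
    """Split a recording into (seizure segments, non-seizure segments)."""
    ann.validate_against(rec)
    seiz, nonseiz = [], []
    for i, iv in enumerate(ann):
        seg = Segment(rec.data[:, iv.start : iv.end], iv.label, i, iv.start)
        (seiz if iv.label == SEIZURE else nonseiz).append(seg)
    return seiz, nonseiz


def expected_window_count(segment_len: int, window_len: int, stride: int) -> int:
    """Number of stride-spaced windows that fit in a segment."""
    if segment_len < window_len:
        return 0
    return (segment_len - window_len) // stride + 1


def _slide(seg: Segment, L: int, stride: int) -> np.ndarray:
    """All stride-spaced windows of one segment, shape (n, C, L)."""
    n = expected_window_count(len(seg), L, stride)
    if n == 0:
        return np.empty((0, seg.data.shape[0], L), dtype=np.float32)
    view = np.lib.stride_tricks.sliding_window_view(seg.data, L, axis=1)  # C x starts x L
    return view[:, ::stride][:, :n].transpose(1, 0, 2).astype(np.float32)


def sequential_windows(
    seizure_segments: Sequence[Segment],
    nonseizure_segments: Sequence[Segment],
    cfg: AugmentationConfig,
) -> WindowSet:
    """Stride-1 traversal of seizure segments, stride-50 of non-seizure ones
    (defaults; both configurable). Segments shorter than L yield nothing."""
    chunks, labels, prov = [], [], []
    for segs, stride, lab in (
        (seizure_segments, cfg.stride_seizure, POSITIVE),
        (nonseizure_segments, cfg.stride_nonseizure, NEGATIVE),
    ):
        for seg in segs:
            w = _slide(seg, cfg.window_len, stride)
            if not len(w):
                continue
            chunks.append(w)
            labels.append(np.full(len(w), lab, dtype=np.int8))
            prov.extend(
                {"strategy": "sequential", "segment": seg.segment_id, "start": int(s)}
                for s in range(0, len(w) * stride, stride)
            )
    if not chunks:
        c = seizure_segments[0].data.shape[0] if seizure_segments else 1
        return WindowSet(np.empty((0, c, cfg.window_len), np.float32), np.empty(0, np.int8), [], cfg)
    return WindowSet(np.concatenate(chunks), np.concatenate(labels), prov, cfg)


def _uniform_starts(
    segments: Sequence[Segment], n: int, L: int, rng: np.random.Generator, cls: str
) -> list[tuple[Segment, int]]:
    """n (segment, start) pairs uniform over the union of valid positions."""
    eligible = [s for s in segments if len(s) >= L]
    if not eligible:
        raise ValidationError(f"no {cls} segment is at least {L} samples long")
    counts = np.array([len(s) - L + 1 for s in eligible])
    seg_idx = rng.choice(len(eligible), size=n, p=counts / counts.sum()) if n else np.empty(0, int)
    return [(eligible[i], int(rng.integers(counts[i]))) for i in seg_idx]


def random_contiguous_windows(
    seizure_segments: Sequence[Segment],
    nonseizure_segments: Sequence[Segment],
    n_pos: int,
    n_neg: int,
    cfg: AugmentationConfig,
) -> WindowSet:
    """Exactly ``n_pos`` positive and ``n_neg`` negative windows, start
    offsets uniform over all valid positions of the matching class."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.window_len
    data, labels, prov = [], [], []
    for segs, n, lab, cls in (
        (seizure_segments, n_pos, POSITIVE, SEIZURE),
        (nonseizure_segments, n_neg, NEGATIVE, NONSEIZURE),
    ):
        if n == 0:
            continue
        for seg, start in _uniform_starts(segs, n, L, rng, cls):
            data.append(seg.data[:, start : start + L])
            labels.append(lab)
            prov.append({"strategy": "contiguous", "segment": seg.segment_id, "start": start})
    if not data:
        c = seizure_segments[0].data.shape[0] if seizure_segments else 1
        return WindowSet(np.empty((0, c, L), np.float32), np.empty(0, np.int8), [], cfg)
    return WindowSet(np.stack(data), np.array(labels, np.int8), prov, cfg)


def random_noncontiguous_windows(
    seizure_segments: Sequence[Segment],
    nonseizure_segments: Sequence[Segment],
    n: int,
    cfg: AugmentationConfig,
) -> WindowSet:
    """``n`` hybrid positive windows: m ~ U{1..m_max} non-seizure columns
    followed by L - m seizure columns; both blocks are contiguous runs from
    a randomly chosen segment, time-aligned across channels."""
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.window_len
    if not any(len(s) >= L - cfg.m_max for s in seizure_segments):
        raise ValidationError("seizure pool has no segment long enough for the seizure block")
    if not any(len(s) >= 1 for s in nonseizure_segments):
        raise ValidationError("non-seizure pool is empty")
    data, prov = [], []
    for _ in range(n):
        m = int(rng.integers(1, cfg.m_max + 1))
        (nseg, nstart), = _uniform_starts(nonseizure_segments, 1, m, rng, NONSEIZURE)
        (sseg, sstart), = _uniform_starts(seizure_segments, 1, L - m, rng, SEIZURE)
        w = np.concatenate(
            [nseg.data[:, nstart : nstart + m], sseg.data[:, sstart : sstart + L - m]], axis=1
        )
        data.append(w)
        prov.append(
            {
                "strategy": "noncontiguous",
                "m": m,
                "nonseizure_segment": nseg.segment_id,
                "nonseizure_start": nstart,
                "seizure_segment": sseg.segment_id,
                "seizure_start": sstart,
            }
        )
    if not data:
        c = seizure_segments[0].data.shape[0] if seizure_segments else 1
        return WindowSet(np.empty((0, c, L), np.float32), np.empty(0, np.int8), [], cfg)
    return WindowSet(np.stack(data), np.full(n, POSITIVE, np.int8), prov, cfg)


def boundary_windows(
    rec: Recording,
    ann: AnnotationSet,
    cfg: AugmentationConfig,
    stride: int = 1,
) -> WindowSet:
    """Optional pass over non-seizure -> seizure transitions.

    Windows straddling a seizure onset are labeled positive only when they
    contain at least ``L - m_max`` seizure columns (>= 61 of 100 at the
    defaults), mirroring the hybrid-composition rule; otherwise negative.
    """
    L = cfg.window_len
    data, labels, prov = [], [], []
    for iv in ann.seizure_intervals:
        first = max(iv.start - L + 1, 0)
        for start in range(first, iv.start, stride):
            if start + L > rec.n_samples:
                break
            seiz_cols = min(start + L, iv.end) - iv.start
            data.append(rec.data[:, start : start + L])
            labels.append(POSITIVE if seiz_cols >= L - cfg.m_max else NEGATIVE)
            prov.append({"strategy": "boundary", "start": start, "seizure_cols": int(seiz_cols)})
    if not data:
        return WindowSet(np.empty((0, rec.n_channels, L), np.float32), np.empty(0, np.int8), [], cfg)
    return WindowSet(np.stack(data), np.array(labels, np.int8), prov, cfg)
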