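"""Event-level scoring of detections against annotated ground truth.

Detections are matched to true seizure intervals by any overlap of the
half-open intervals. From the resulting counts:

    recall    = 100 * TP / (TP + FN)          (sensitivity)
    precision = 100 * TP / (TP + FP)
    F1        = 2 * P * R / (P + R)
    accuracy  = 100 * TP / (TP + FP + FN)

"Accuracy" here is the event-level positive-predict accuracy — a
threat-score-like quantity with no true-negative term — and is labeled
``event_accuracy`` in outputs to avoid confusion with sample accuracy.
Undefined ratios (zero denominators) are reported as NaN, never silently 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detect import EventList
from .io import AnnotationSet


@dataclass(frozen=True)
class EventMetrics:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    accuracy: float

    def rounded(self, ndigits: int = 1) -> dict:
        """Report form: percentages to one decimal, as in published tables."""
        d = asdict(self)
        for k in ("recall", "precision", "f1", "accuracy"):
            d[k] = round(d[k], ndigits) if math.isfinite(d[k]) else None
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["event_accuracy"] = d.pop("accuracy")
        path.write_text(json.dumps({k: (None if isinstance(v, float) and not math.isfinite(v) else v)
                                    for k, v in d.items()}, indent=1))
        return path


@dataclass(frozen=True)
class AggregateStats:
    """Per-metric mean and SD over subjects (population SD by default)."""

    mean: dict
    sd_population: dict
    sd_sample: dict
    n: int


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_events(detected: EventList, truth: AnnotationSet) -> tuple[int, int, int]:
    """Any-overlap matching at event level.

    TP = true seizure intervals touched by >= 1 detection; FN = those
    touched by none; FP = detections touching no true seizure interval.
    One detection spanning two true events credits both; two detections
    inside one true event credit it once.
    """
    seiz = [(iv.start, iv.end) for iv in truth.seizure_intervals]
    det = list(detected)
    tp = sum(any(_overlaps(t, d) for d in det) for t in seiz)
    fp = sum(not any(_overlaps(d, t) for t in seiz) for d in det)
    fn = len(seiz) - tp
    return tp, fp, fn


def compute_metrics(tp: int, fp: int, fn: int) -> EventMetrics:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    recall = 100.0 * tp / (tp + fn) if tp + fn else math.nan
    precision = 100.0 * tp / (tp + fp) if tp + fp else math.nan
    if math.isfinite(recall) and math.isfinite(precision) and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    elif tp + fp + fn == 0:
        f1 = math.nan
    else:
        f1 = 0.0
    accuracy = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else math.nan
    return EventMetrics(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
                        f1=f1, accuracy=accuracy)


def evaluate_events(detected: EventList, truth: AnnotationSet) -> EventMetrics:
    """match_events + compute_metrics in one call."""
    return compute_metrics(*match_events(detected, truth))


def aggregate_metrics(per_subject: Sequence[EventMetrics]) -> AggregateStats:
    """Arithmetic mean and SD per metric over subjects ("Average" rows)."""
    if not per_subject:
        raise ValueError("aggregate_metrics needs at least one subject")
    out_mean, out_pop, out_samp = {}, {}, {}
    for key in ("recall", "precision", "f1", "accuracy"):
        vals = np.array([getattr(m, key) for m in per_subject], dtype=float)
        out_mean[key] = float(np.mean(vals))
        out_pop[key] = float(np.std(vals))
        out_samp[key] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return AggregateStats(mean=out_mean, sd_population=out_pop, sd_sample=out_samp,
                          n=len(per_subject))
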