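"""End-to-end synthetic-recovery pipeline.

Wires the whole framework together on generated data: simulate an annotated
multichannel recording, build a labeled window set with all three
augmentation strategies, train the CPU-scale classifier, run sliding-window
detection on a held-out recording from the same scenario, and score the
detected events against ground truth — including reduced-channel detection
(1/2/4/8 of 16 channels) to exercise the channel-agnostic property.

One global seed fans out to per-stage seeds through a fixed derivation, so
every stage is individually reproducible and the whole run is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augment import (
    AugmentationConfig,
    WindowSet,
    extract_segments,
    random_contiguous_windows,
    random_noncontiguous_windows,
    sequential_windows,
)
from .detect import DEFAULT_MERGE_GAP, DEFAULT_STEP, flags_to_events, sliding_infer
from .io import Recording
from .metrics import EventMetrics, evaluate_events
from .model import ModelConfig, TrainedModel, tiny_config
from .synth import ScenarioConfig, generate_recording
from .train import HyperParams, split_dataset, train_model

_STAGES = ("scenario_train", "scenario_test", "augment", "train", "channels")


def derive_stage_seeds(global_seed: int) -> dict[str, int]:
    """Fixed fan-out of one global seed into per-stage seeds (< 2**31)."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(_STAGES, children)}


@dataclass
class E2EConfig:
    """Study conditions for the synthetic recovery run.

    Defaults: 16-channel 20 kHz 60 s recordings with 20 embedded
    large-amplitude burst events at snr 6, ~20 000 training windows split
    across the three augmentation strategies, the tiny model preset, and
    step-20 inference with the 400-sample merge gap.
    """

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    model: ModelConfig = field(default_factory=tiny_config)
    n_sequential_per_class: int = 6000
    n_contiguous_per_class: int = 3000
    n_noncontiguous: int = 2000
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 3e-4
    val_fraction: float = 0.1
    channel_subsample_prob: float = 0.5
    step: int = DEFAULT_STEP
    merge_gap: int = DEFAULT_MERGE_GAP
    channel_subsets: tuple[int, ...] = (1, 2, 4, 8)


def build_window_set(rec, ann, cfg: E2EConfig, seed: int) -> WindowSet:
    """All three augmentation strategies under one window budget.

    Sequential strides are chosen so each class contributes about
    ``n_sequential_per_class`` windows; the random strategies contribute
    fixed counts on top.
    """
    seiz, nonseiz = extract_segments(rec, ann)
    L = cfg.model.window_len

    def stride_for(segments, target):
        total = sum(max(len(s) - L + 1, 0) for s in segments)
        return max(1, int(np.ceil(total / target)))

    aug = AugmentationConfig(
        window_len=L,
        stride_seizure=stride_for(seiz, cfg.n_sequential_per_class),
        stride_nonseizure=stride_for(nonseiz, cfg.n_sequential_per_class),
        seed=seed,
    )
    parts = [sequential_windows(seiz, nonseiz, aug)]
    if cfg.n_contiguous_per_class:
        parts.append(
            random_contiguous_windows(
                seiz, nonseiz, cfg.n_contiguous_per_class, cfg.n_contiguous_per_class, aug
            )
        )
    if cfg.n_noncontiguous:
        parts.append(random_noncontiguous_windows(seiz, nonseiz, cfg.n_noncontiguous, aug))
    return WindowSet.concatenate(parts)


def detect_and_score(
    model: TrainedModel, rec: Recording, ann, step: int, merge_gap: int
) -> tuple[EventMetrics, int]:
    flags = sliding_infer(model, rec, step=step)
    events = flags_to_events(flags, merge_gap=merge_gap)
    return evaluate_events(events, ann), len(events)


def run_e2e(seed: int, cfg: E2EConfig | None = None, verbose: bool = False) -> dict:
    """Full simulate -> augment -> train -> detect -> evaluate run.

    Returns a dict with the trained model, held-out detection metrics, and
    per-channel-subset metrics keyed by channel count.
    """
    cfg = cfg or E2EConfig()
    seeds = derive_stage_seeds(seed)

    rec_train, ann_train = generate_recording(
        replace(cfg.scenario, seed=seeds["scenario_train"])
    )
    rec_test, ann_test = generate_recording(replace(cfg.scenario, seed=seeds["scenario_test"]))

    windows = build_window_set(rec_train, ann_train, cfg, seeds["augment"])
    train_ws, val_ws = split_dataset(windows, cfg.val_fraction, seeds["train"])
    hyper = HyperParams(
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        val_fraction=cfg.val_fraction,
        channel_subsample_prob=cfg.channel_subsample_prob,
        seed=seeds["train"],
    )
    model = train_model(cfg.model, hyper, train_ws, val_ws, verbose=verbose)

    metrics, n_events = detect_and_score(model, rec_test, ann_test, cfg.step, cfg.merge_gap)

    ch_rng = np.random.default_rng(seeds["channels"])
    by_channels: dict[int, EventMetrics] = {}
    for k in cfg.channel_subsets:
        if k > rec_test.n_channels:
            continue
        idx = np.sort(ch_rng.choice(rec_test.n_channels, size=k, replace=False))
        sub = rec_test.subset_channels(idx)
        by_channels[k], _ = detect_and_score(model, sub, ann_test, cfg.step, cfg.merge_gap)

    return {
        "seed": seed,
        "stage_seeds": seeds,
        "n_windows": len(windows),
        "n_positive": windows.n_positive,
        "n_negative": windows.n_negative,
        "model": model,
        "metrics": metrics,
        "n_detected_events": n_events,
        "n_true_events": len(ann_test.seizure_intervals),
        "by_channels": by_channels,
    }


def smoke_config() -> E2EConfig:
    """Very small configuration for fast smoke/determinism checks."""
    return E2EConfig(
        scenario=ScenarioConfig(
            n_channels=4, duration_s=6.0, n_seizures=3,
            seizure_duration_range_s=(0.05, 0.3), gap_range_s=(0.3, 1.0),
        ),
        model=ModelConfig(d_model=32, n_layers=1, n_heads=2, d_ff=32, mlp2_hidden=16),
        n_sequential_per_class=200,
        n_contiguous_per_class=100,
        n_noncontiguous=100,
        epochs=3,
        step=40,
        channel_subsets=(),
    )
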