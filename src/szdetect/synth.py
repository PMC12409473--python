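"""Synthetic multichannel recordings with ground-truth seizure annotations.

Emulates the statistical structure of acute rodent hippocampal LFP and
low-rate scalp-EEG recordings: a 1/f-colored background at unit SD per
channel, plus embedded epileptiform events of three morphologies —

``ptx_burst``
    Large-amplitude burst discharges (GABA_A-antagonist-like): a
    Hann-enveloped train of biphasic sharp transients.
``fourap_spiking``
    Potassium-channel-blocker-like activity: an initial dense spike train
    followed by regularly spaced pseudo-periodic spikes.
``eeg_like``
    Low-rate rhythmic ~3 Hz spike-and-wave discharge for scalp-style
    signals; the scenario also sprinkles isolated single-channel artifact
    transients through the background to mimic muscle/non-epileptiform
    contamination.

Amplitudes are expressed in background-SD units: ``snr`` is the peak event
amplitude relative to the per-channel background SD (== 1). A per-channel
depth profile (smooth gain gradient with a polarity flip mid-array,
mimicking the dendrite-soma-dendrite laminar layout of a linear probe)
gives channels correlated but distinguishable views of each event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NONSEIZURE, SEIZURE, AnnotationSet, Interval, Recording, ValidationError

SEIZURE_KINDS = ("ptx_burst", "fourap_spiking", "eeg_like")


class ConfigError(ValueError):
    """Scenario parameters are inconsistent (e.g. events do not fit)."""


@dataclass
class ScenarioConfig:
    """Full description of one synthetic recording scenario."""

    n_channels: int = 16
    fs_hz: float = 20_000.0
    duration_s: float = 60.0
    seizure_kind: str = "ptx_burst"
    n_seizures: int = 20
    seizure_duration_range_s: tuple[float, float] = (0.05, 1.5)
    gap_range_s: tuple[float, float] = (0.5, 2.0)
    snr: float = 6.0
    depth_profile: np.ndarray | None = None
    artifact_rate_hz: float = 0.0  # eeg_like scenarios use ~1/30 Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seizure_kind not in SEIZURE_KINDS:
            raise ConfigError(f"unknown seizure_kind {self.seizure_kind!r}; choose from {SEIZURE_KINDS}")
        if self.duration_s <= 0 or self.n_channels < 1 or self.fs_hz <= 0:
            raise ConfigError("duration, channel count and sampling rate must be positive")
        if self.n_seizures < 0:
            raise ConfigError("n_seizures must be >= 0")
        lo, hi = self.seizure_duration_range_s
        if not (0 < lo <= hi):
            raise ConfigError("seizure_duration_range_s must satisfy 0 < min <= max")
        glo, ghi = self.gap_range_s
        if not (0 < glo <= ghi):
            raise ConfigError("gap_range_s must satisfy 0 < min <= max")


def default_depth_profile(n_channels: int) -> np.ndarray:
    """Smooth gain gradient with a polarity flip at the middle of the array.

    Magnitudes run from 1.2 at the array ends to 0.4 near the reversal
    point, so every contact still sees the event.
    """
    if n_channels == 1:
        return np.array([1.0])
    x = np.linspace(-1.0, 1.0, n_channels)
    sign = np.where(x >= 0, 1.0, -1.0)
    return sign * (0.4 + 0.8 * np.abs(x))


def generate_background(
    n_channels: int, n_samples: int, fs_hz: float, seed: int
) -> np.ndarray:
    """1/f-weighted colored noise, zero mean and unit SD per channel."""
    if n_channels < 1 or n_samples < 1:
        raise ValidationError("n_channels and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    if n_samples < 4:
        out = white
    else:
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
        weight = np.ones_like(freqs)
        weight[1:] = 1.0 / np.sqrt(freqs[1:])
        weight[0] = 0.0  # no DC offset
        out = np.fft.irfft(spec * weight, n=n_samples, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _biphasic_spike(width_samples: int) -> np.ndarray:
    """Sharp biphasic transient (positive peak then undershoot), unit peak."""
    width_samples = max(width_samples, 3)
    t = np.linspace(-1.0, 1.0, width_samples)
    w = np.exp(-(t**2) / 0.08) - 0.6 * np.exp(-((t - 0.45) ** 2) / 0.18)
    return w / np.max(np.abs(w))


def _add_spikes(template: np.ndarray, centers: np.ndarray, spike: np.ndarray) -> None:
    half = len(spike) // 2
    n = len(template)
    for c in centers:
        a, b = int(c) - half, int(c) - half + len(spike)
        sa, sb = max(0, -a), len(spike) - max(0, b - n)
        a, b = max(a, 0), min(b, n)
        if a < b:
            template[a:b] += spike[sa:sb]


def generate_seizure_waveform(
    kind: str, duration_s: float, fs_hz: float, snr: float, seed: int
) -> np.ndarray:
    """One event template, shape ``(1, round(duration_s * fs_hz))``.

    Peak absolute amplitude equals ``snr`` (background-SD units);
    ``snr=0`` degenerates to an all-zero template.
    """
    if kind not in SEIZURE_KINDS:
        raise ConfigError(f"unknown seizure kind {kind!r}")
    n = int(round(duration_s * fs_hz))
    if n < 1:
        raise ConfigError(f"duration {duration_s}s at {fs_hz}Hz yields an empty template")
    rng = np.random.default_rng(seed)
    w = np.zeros(n)

    if kind == "ptx_burst":
        # dense burst of sharp biphasic deflections with abrupt onset and
        # offset. The inter-spike period (~4 ms) is below the 5 ms analysis
        # window so every window inside the annotated interval contains
        # discharge activity: annotations stay faithful at window scale.
        spike = _biphasic_spike(int(round(0.003 * fs_hz)))
        period = max(int(round(0.004 * fs_hz)), 2)
        centers = np.arange(period // 2, n, period, dtype=float)
        centers += rng.uniform(-0.15, 0.15, size=centers.shape) * period
        _add_spikes(w, np.clip(centers, 0, n - 1), spike)
    elif kind == "fourap_spiking":
        # dense (tonic-like) spiking phase, then pseudo-periodic spikes
        spike = _biphasic_spike(int(round(0.002 * fs_hz)))
        n_dense = max(n // 2, 1)
        dense_period = max(int(round(0.003 * fs_hz)), 2)
        dense = np.arange(dense_period // 2, n_dense, dense_period, dtype=float)
        dense += rng.uniform(-0.3, 0.3, size=dense.shape) * dense_period
        sparse_period = max(int(round(0.040 * fs_hz)), 4)
        sparse = np.arange(n_dense + sparse_period // 2, n, sparse_period, dtype=float)
        _add_spikes(w, np.clip(np.concatenate([dense, sparse]), 0, n - 1), spike)
    else:  # eeg_like: rhythmic ~3 Hz spike-and-wave
        t = np.arange(n) / fs_hz
        f = 3.0
        slow = np.sin(2 * np.pi * f * t)
        sharp = np.clip(np.sin(2 * np.pi * f * t + 0.6), 0, None) ** 6
        w = slow * 0.5 + sharp
        w *= np.hanning(n) if n > 2 else 1.0

    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak * snr
    else:
        w = w * snr
    return w[np.newaxis, :]


def generate_recording(cfg: ScenarioConfig) -> tuple[Recording, AnnotationSet]:
    """Background plus embedded events; annotations tile the whole recording.

    Events are placed left to right separated by gaps drawn uniformly from
    ``gap_range_s``; any slack becomes a trailing non-seizure interval. Each
    event template is scaled per channel by the depth profile. Fully
    deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.fs_hz))
    data = generate_background(
        cfg.n_channels, n_samples, cfg.fs_hz, seed=int(rng.integers(2**31))
    )
    profile = (
        np.asarray(cfg.depth_profile, dtype=float)
        if cfg.depth_profile is not None
        else default_depth_profile(cfg.n_channels)
    )
    if profile.shape != (cfg.n_channels,):
        raise ConfigError(f"depth_profile must have shape ({cfg.n_channels},)")

    durations = rng.uniform(*cfg.seizure_duration_range_s, size=cfg.n_seizures)
    gaps = rng.uniform(*cfg.gap_range_s, size=cfg.n_seizures + 1)
    lengths = np.round(durations * cfg.fs_hz).astype(int)
    gap_lengths = np.round(gaps * cfg.fs_hz).astype(int)
    needed = int(lengths.sum() + gap_lengths[: cfg.n_seizures + 1].sum())
    if cfg.n_seizures > 0 and needed > n_samples:
        raise ConfigError(
            f"{cfg.n_seizures} events need {needed} samples but the recording has {n_samples}; "
            "shorten events/gaps or lengthen the recording"
        )

    intervals: list[Interval] = []
    cursor = 0
    for i in range(cfg.n_seizures):
        start = cursor + gap_lengths[i]
        end = start + lengths[i]
        template = generate_seizure_waveform(
            cfg.seizure_kind,
            lengths[i] / cfg.fs_hz,
            cfg.fs_hz,
            cfg.snr,
            seed=int(rng.integers(2**31)),
        )
        data[:, start:end] += profile[:, np.newaxis] * template[0, : end - start]
        if start > cursor:
            intervals.append(Interval(cursor, start, NONSEIZURE))
        intervals.append(Interval(start, end, SEIZURE))
        cursor = end
    if cursor < n_samples:
        intervals.append(Interval(cursor, n_samples, NONSEIZURE))

    if cfg.artifact_rate_hz > 0:
        _add_artifacts(data, intervals, cfg, rng)

    rec = Recording(
        data=data,
        fs_hz=cfg.fs_hz,
        channel_labels=[f"ch{i}" for i in range(cfg.n_channels)],
        source_id=f"synthetic-{cfg.seizure_kind}-seed{cfg.seed}",
    )
    ann = AnnotationSet(intervals=intervals, recording_id=rec.source_id)
    ann.validate_against(rec)
    return rec, ann


def _add_artifacts(
    data: np.ndarray, intervals: list[Interval], cfg: ScenarioConfig, rng: np.random.Generator
) -> None:
    """Isolated high-amplitude single-channel transients inside non-seizure spans."""
    nonseiz = [iv for iv in intervals if iv.label == NONSEIZURE]
    n_art = rng.poisson(cfg.artifact_rate_hz * cfg.duration_s)
    width = max(int(round(0.1 * cfg.fs_hz)), 5)
    shape = _biphasic_spike(width)
    for _ in range(n_art):
        iv = nonseiz[rng.integers(len(nonseiz))]
        if len(iv) <= width:
            continue
        start = int(rng.integers(iv.start, iv.end - width))
        ch = int(rng.integers(data.shape[0]))
        data[ch, start : start + width] += shape * rng.uniform(3.0, 5.0) * rng.choice([-1, 1])


def eeg_like_scenario(**overrides) -> ScenarioConfig:
    """Convenience preset for a noisy low-rate scalp-style scenario."""
    base = dict(
        n_channels=20,
        fs_hz=256.0,
        duration_s=120.0,
        seizure_kind="eeg_like",
        n_seizures=10,
        seizure_duration_range_s=(1.0, 5.0),
        gap_range_s=(2.0, 8.0),
        snr=4.0,
        artifact_rate_hz=1.0 / 30.0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)
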