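"""Synthetic 9-channel gait/FoG accelerometer simulator.

Generates two-class recordings with the statistical structure the detection
method assumes: informative channels switch from a locomotor-band oscillation
(~0.5-3 Hz, normal stepping) to a freeze-band oscillation (~3-8 Hz, the
classical trembling-in-place signature) with a larger amplitude and a
postural-tilt mean offset during FoG episodes, while non-informative channels
carry class-independent locomotor signal.  Everything is reproducible from
(seed, recording_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import (
    ANNOT_FOG,
    ANNOT_NORMAL,
    CHANNELS,
    N_CHANNELS,
    ChannelId,
    GaitRecording,
    LabeledDataset,
    ValidationError,
    channel_by_index,
    to_labeled_dataset,
)

#: default planted channels: vertical upper-leg (5) and vertical trunk (8),
#: the two axes that dominate real FoG recordings.
DEFAULT_INFORMATIVE = (5, 8)


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults define the standard study conditions.

    ``amplitude_ratio`` scales the freeze-band oscillation on informative
    channels during episodes, and ``fog_offset`` adds a constant shift there
    (gravity-projection change when stepping stops) so informative channels
    are separable at the single-timestep level.  ``channel_expression`` is
    the probability that a given episode is expressed on a given informative
    channel — freezing manifests heterogeneously across sensor sites, so no
    single channel sees every episode; every episode is expressed on at
    least one informative channel (an annotated episode is by construction
    visible in some sensor).  ``episode_rate`` is the expected
    fraction of time spent frozen; episodes alternate with normal gait using
    exponentially distributed segment lengths.
    """

    n_recordings: int = 4
    duration_s: float = 240.0
    sample_rate_hz: float = 64.0
    locomotor_band_hz: tuple[float, float] = (0.5, 3.0)
    freeze_band_hz: tuple[float, float] = (3.0, 8.0)
    informative_channels: tuple[int, ...] = DEFAULT_INFORMATIVE
    episode_rate: float = 0.3
    amplitude_ratio: float = 2.0
    fog_offset: float = 2.0
    channel_expression: float = 0.8
    noise_sd: float = 0.1
    mean_episode_s: float = 5.0
    n_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for band in (self.locomotor_band_hz, self.freeze_band_hz):
            if not band[0] < band[1]:
                raise ValidationError(f"band must satisfy low < high, got {band}")
        if not 0.0 <= self.episode_rate < 1.0:
            raise ValidationError("episode_rate must be in [0, 1)")
        if self.amplitude_ratio <= 0:
            raise ValidationError("amplitude_ratio must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 < self.channel_expression <= 1.0:
            raise ValidationError("channel_expression must be in (0, 1]")
        if self.n_recordings < 1 or self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValidationError("n_recordings, duration_s, sample_rate_hz must be positive")

    @property
    def informative_ids(self) -> tuple[ChannelId, ...]:
        return tuple(channel_by_index(i) for i in self.informative_channels)


@dataclass
class GroundTruth:
    """Planted truth for one recording: episode bounds and informative set."""

    episodes: list[tuple[int, int]] = field(default_factory=list)  # [start, end) rows
    informative_channels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.episodes:
            if s < 0 or e <= s or s < prev_end:
                raise ValidationError("episodes must be ordered, non-overlapping")
            prev_end = e


def _segment_annotations(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Alternating normal/FoG segments with exponential lengths."""
    ann = np.full(n, ANNOT_NORMAL, dtype=np.int64)
    if cfg.episode_rate == 0.0:
        return ann
    fs = cfg.sample_rate_hz
    mean_fog = cfg.mean_episode_s * fs
    mean_normal = mean_fog * (1.0 - cfg.episode_rate) / cfg.episode_rate
    pos = 0
    state_fog = rng.random() < cfg.episode_rate  # stationary start state
    while pos < n:
        mean_len = mean_fog if state_fog else mean_normal
        seg = max(1, int(round(rng.exponential(mean_len))))
        if state_fog:
            ann[pos : pos + seg] = ANNOT_FOG
        pos += seg
        state_fog = not state_fog
    return ann


def _sinusoid_mixture(
    t: np.ndarray, band: tuple[float, float], n_components: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-amplitude-budget mixture of random sinusoids within a band."""
    freqs = rng.uniform(band[0], band[1], size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    weights = rng.uniform(0.5, 1.0, size=n_components)
    weights /= weights.sum()
    sig = np.zeros_like(t)
    for f, p, w in zip(freqs, phases, weights):
        sig += w * np.sin(2.0 * np.pi * f * t + p)
    return sig


def simulate_recording(
    config: SyntheticConfig, recording_index: int = 0
) -> tuple[GaitRecording, GroundTruth]:
    """Simulate one recording; identical (config, index) gives identical output.

    Annotations are 1 outside episodes and 2 inside.  Informative channels
    carry a locomotor-band mixture during normal gait and, on expressed
    episodes, a freeze-band mixture scaled by ``amplitude_ratio`` plus
    ``fog_offset``; unexpressed episodes and non-informative channels carry
    class-independent locomotor signal.
    """
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, recording_index])
    ann = _segment_annotations(config, n, rng)
    t = np.arange(n) / fs

    informative = tuple(sorted(set(config.informative_channels)))
    samples = np.empty((n, N_CHANNELS))
    # segment boundaries (constant annotation)
    bounds = np.flatnonzero(np.diff(ann)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [n]))

    # per-episode expression mask over informative channels; every episode is
    # expressed on at least one of them
    expression: dict[int, dict[int, bool]] = {}
    for s, e in zip(starts, ends):
        if ann[s] == ANNOT_FOG and informative:
            while True:
                mask = rng.random(len(informative)) < config.channel_expression
                if mask.any():
                    break
            expression[int(s)] = dict(zip(informative, mask))

    for ch in CHANNELS:
        c = ch.index - 1
        if ch.index in informative:
            sig = np.empty(n)
            for s, e in zip(starts, ends):
                if ann[s] == ANNOT_FOG and expression[int(s)][ch.index]:
                    seg = config.amplitude_ratio * _sinusoid_mixture(
                        t[s:e], config.freeze_band_hz, config.n_components, rng
                    )
                    seg = seg + config.fog_offset
                else:
                    seg = _sinusoid_mixture(
                        t[s:e], config.locomotor_band_hz, config.n_components, rng
                    )
                sig[s:e] = seg
        else:
            # class-independent carrier spanning the whole recording
            sig = _sinusoid_mixture(t, config.locomotor_band_hz, config.n_components, rng)
        if config.noise_sd > 0:
            sig = sig + rng.normal(0.0, config.noise_sd, size=n)
        samples[:, c] = sig

    episodes = [
        (int(s), int(e)) for s, e in zip(starts, ends) if ann[s] == ANNOT_FOG
    ]
    rec = GaitRecording(
        subject_id=f"synthetic{recording_index:03d}",
        timestamps=np.round(t * 1000.0).astype(np.int64) + 1,  # strictly increasing @64 Hz
        samples=samples,
        annotations=ann,
        sample_rate_hz=fs,
    )
    truth = GroundTruth(episodes=episodes, informative_channels=tuple(sorted(informative)))
    return rec, truth


def make_dataset(
    config: SyntheticConfig,
    sequence_length: int = 128,
    stride: int | None = None,
) -> tuple[LabeledDataset, list[GroundTruth]]:
    """Simulate ``n_recordings`` recordings and cut them into labelled sequences."""
    parts, truths = [], []
    for i in range(config.n_recordings):
        rec, truth = simulate_recording(config, i)
        parts.append(to_labeled_dataset(rec, sequence_length=sequence_length, stride=stride))
        truths.append(truth)
    return LabeledDataset.concat(parts), truths


def train_test_datasets(
    config: SyntheticConfig,
    sequence_length: int = 128,
    stride: int | None = None,
    test_fraction: float = 0.25,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Convenience split: later recordings are held out, never mixed windows.

    The last ``ceil(test_fraction * n_recordings)`` recordings form the test
    set so that train and test windows never come from the same recording.
    """
    n_test = max(1, int(np.ceil(test_fraction * config.n_recordings)))
    if n_test >= config.n_recordings:
        raise ValidationError("test_fraction leaves no training recordings")
    train_parts, test_parts = [], []
    for i in range(config.n_recordings):
        rec, _ = simulate_recording(config, i)
        ds = to_labeled_dataset(rec, sequence_length=sequence_length, stride=stride)
        (test_parts if i >= config.n_recordings - n_test else train_parts).append(ds)
    return LabeledDataset.concat(train_parts), LabeledDataset.concat(test_parts)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different random seed."""
    return replace(config, seed=seed)
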