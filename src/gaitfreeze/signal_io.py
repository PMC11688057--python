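"""Reading, validation, labelling and normalization of Daphnet-style recordings.

A recording is a whitespace-delimited text file with 11 columns per row:
a timestamp in milliseconds, nine tri-axial accelerometer channels (ankle,
upper leg, trunk, each with horizontal-forward, vertical and
horizontal-lateral axes) and an integer annotation in {0, 1, 2} where
0 = outside the experiment, 1 = normal gait and 2 = freezing of gait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("gaitfreeze")

N_CHANNELS = 9

#: annotation codes
ANNOT_EXCLUDED = 0
ANNOT_NORMAL = 1
ANNOT_FOG = 2

#: binary class labels after mapping
LABEL_NORMAL = 0
LABEL_FOG = 1

#: default label map: annotation -> class label (None = excluded)
DEFAULT_LABEL_MAP = {0: None, 1: LABEL_NORMAL, 2: LABEL_FOG}

DEFAULT_SAMPLE_RATE_HZ = 64.0


class ValidationError(ValueError):
    """Input violates a structural contract (shape, annotation range, ...)."""


class ParseError(ValueError):
    """A recording file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class ChannelId:
    """One of the nine sensor-axis streams.

    ``index`` is the 1-based column position used throughout; ``site`` is
    the body placement and ``axis`` the acceleration direction.
    """

    index: int
    site: str
    axis: str

    def __str__(self) -> str:  # e.g. "5:upper_leg/vertical"
        return f"{self.index}:{self.site}/{self.axis}"


_SITES = ("ankle", "upper_leg", "trunk")
_AXES = ("horizontal_forward", "vertical", "horizontal_lateral")

#: fixed index -> (site, axis) mapping; index 1 is ankle/horizontal-forward,
#: index 5 upper-leg/vertical, index 8 trunk/vertical, etc.
CHANNELS: tuple[ChannelId, ...] = tuple(
    ChannelId(index=3 * i + j + 1, site=_SITES[i], axis=_AXES[j])
    for i in range(3)
    for j in range(3)
)


def channel_by_index(index: int) -> ChannelId:
    if not 1 <= index <= N_CHANNELS:
        raise ValidationError(f"channel index must be in 1..{N_CHANNELS}, got {index}")
    return CHANNELS[index - 1]


@dataclass
class GaitRecording:
    """One subject's multichannel accelerometer session with annotations."""

    subject_id: str
    timestamps: np.ndarray  # (T,) int64 milliseconds, strictly increasing
    samples: np.ndarray  # (T, 9) float
    annotations: np.ndarray  # (T,) int in {0, 1, 2}
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.annotations = np.asarray(self.annotations, dtype=np.int64)
        t = self.timestamps.shape[0]
        if self.samples.ndim != 2 or self.samples.shape != (t, N_CHANNELS):
            raise ValidationError(
                f"samples must have shape ({t}, {N_CHANNELS}), got {self.samples.shape}"
            )
        if self.annotations.shape != (t,):
            raise ValidationError("annotations length must equal number of timestamps")
        bad = ~np.isin(self.annotations, (0, 1, 2))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"annotation out of {{0,1,2}} at row {i}: {self.annotations[i]}"
            )
        if t > 1 and not (np.diff(self.timestamps) > 0).all():
            raise ValidationError("timestamps must be strictly increasing")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class NormalizationParams:
    """Per-channel min/max fitted on training data; reused for held-out data."""

    minimum: np.ndarray  # (9,)
    maximum: np.ndarray  # (9,)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=np.float64)
        self.maximum = np.asarray(self.maximum, dtype=np.float64)
        if self.minimum.shape != (N_CHANNELS,) or self.maximum.shape != (N_CHANNELS,):
            raise ValidationError(f"min/max must each have {N_CHANNELS} entries")
        if (self.maximum < self.minimum).any():
            raise ValidationError("maximum[c] must be >= minimum[c]")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of channels with max == min (constant in training)."""
        return self.maximum == self.minimum


@dataclass
class LabeledDataset:
    """Fixed-length sequences with binary labels, ready for scoring/training.

    ``X`` has shape (n, L, C) with channels in ``channel_ids`` order; ``y``
    holds 0 (normal) / 1 (FoG); ``provenance`` records, per example, the
    originating subject and the start row in its recording.
    """

    X: np.ndarray
    y: np.ndarray
    channel_ids: tuple[ChannelId, ...]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3:
            raise ValidationError("X must be (n_examples, length, n_channels)")
        if self.X.shape[2] != len(self.channel_ids):
            raise ValidationError("X channel axis must match channel_ids")
        if self.y.shape != (self.X.shape[0],):
            raise ValidationError("y length must match number of examples")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError("labels must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def sequence_length(self) -> int:
        return self.X.shape[1]

    def subset_channels(self, channels: Sequence[ChannelId]) -> "LabeledDataset":
        """Restrict feature sequences to ``channels`` (order preserved)."""
        idx = [self.channel_ids.index(c) for c in channels]
        return LabeledDataset(
            X=self.X[:, :, idx],
            y=self.y.copy(),
            channel_ids=tuple(channels),
            provenance=list(self.provenance),
        )

    @staticmethod
    def concat(parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValidationError("cannot concatenate zero non-empty datasets")
        ids = parts[0].channel_ids
        if any(p.channel_ids != ids for p in parts):
            raise ValidationError("all parts must share channel_ids")
        return LabeledDataset(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            channel_ids=ids,
            provenance=[pr for p in parts for pr in p.provenance],
        )


# ---------------------------------------------------------------------------
# Reading / writing the plain-text dialect
# ---------------------------------------------------------------------------

def read_daphnet(path: str | Path, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> GaitRecording:
    """Parse a Daphnet-dialect text file into a :class:`GaitRecording`.

    Each row is ``timestamp_ms ch1 ... ch9 annotation`` separated by
    whitespace.  Row order is preserved and no resampling is done.
    Raises :class:`ParseError` naming the offending line for malformed rows
    and :class:`ValidationError` for annotations outside {0, 1, 2}.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue  # blank line
            if len(fields) != 11:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 11 columns, got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from None
    if not rows:
        raise ParseError(f"{path.name}: empty file")
    data = np.asarray(rows, dtype=np.float64)
    ann = data[:, 10]
    if not np.array_equal(ann, np.round(ann)):
        raise ValidationError(f"{path.name}: annotations must be integers")
    return GaitRecording(
        subject_id=path.stem,
        timestamps=data[:, 0].astype(np.int64),
        samples=data[:, 1:10],
        annotations=ann.astype(np.int64),
        sample_rate_hz=sample_rate_hz,
    )


def write_daphnet(recording: GaitRecording, path: str | Path) -> None:
    """Write ``recording`` in the same text dialect :func:`read_daphnet` reads.

    Sample values are written with full double precision so that a
    write/read round trip is exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for t, row, a in zip(recording.timestamps, recording.samples, recording.annotations):
            vals = " ".join(repr(float(v)) for v in row)
            fh.write(f"{int(t)} {vals} {int(a)}\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_minmax(
    recording: GaitRecording, params: NormalizationParams | None = None
) -> tuple[GaitRecording, NormalizationParams]:
    """Min-max scale each channel into [0, 1].

    When ``params`` is None the per-channel minima/maxima are fitted on this
    recording (training data — the caller's contract); otherwise the supplied
    training-fit parameters are applied and out-of-range values are clipped
    into [0, 1].  Channels that were constant in training are mapped to 0
    with a logged warning.
    """
    if params is None:
        params = NormalizationParams(
            minimum=recording.samples.min(axis=0),
            maximum=recording.samples.max(axis=0),
        )
    scaled = normalize_array(recording.samples, params)
    out = GaitRecording(
        subject_id=recording.subject_id,
        timestamps=recording.timestamps.copy(),
        samples=scaled,
        annotations=recording.annotations.copy(),
        sample_rate_hz=recording.sample_rate_hz,
    )
    return out, params


def normalize_array(samples: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply fitted min-max parameters to an (..., 9) array with clipping."""
    span = params.maximum - params.minimum
    degen = params.degenerate
    if degen.any():
        names = [str(CHANNELS[i]) for i in np.flatnonzero(degen)]
        logger.warning("degenerate (constant) channels mapped to 0: %s", ", ".join(names))
    safe_span = np.where(degen, 1.0, span)
    scaled = (samples - params.minimum) / safe_span
    scaled = np.where(degen, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0)


def fit_sequence_norm(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel min/max over all training sequences; x is (n, L, C)."""
    return x.min(axis=(0, 1)), x.max(axis=(0, 1))


def apply_sequence_norm(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Min-max scale sequences with training-fit bounds, clipping to [0, 1]."""
    span = np.where(hi > lo, hi - lo, 1.0)
    out = np.clip((x - lo) / span, 0.0, 1.0)
    return np.where(hi > lo, out, 0.0)


# ---------------------------------------------------------------------------
# Sequence formation
# ---------------------------------------------------------------------------

def to_labeled_dataset(
    recording: GaitRecording,
    sequence_length: int = 128,
    stride: int | None = None,
    channels: Sequence[ChannelId] | None = None,
    label_map: dict[int, int | None] | None = None,
) -> LabeledDataset:
    """Cut a recording into fixed-length, single-annotation sequences.

    Rows annotated 0 are excluded outright.  Each example is a contiguous
    run of ``sequence_length`` timesteps whose annotations are all 1 or all
    2; windows never span a change of annotation, so mixed runs are simply
    skipped.  ``stride`` defaults to ``sequence_length`` (non-overlapping).
    A recording too short to yield any window returns an empty dataset with
    a logged warning rather than an error.
    """
    if sequence_length < 1:
        raise ValidationError("sequence_length must be >= 1")
    if stride is None:
        stride = sequence_length
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    channels = tuple(channels) if channels is not None else CHANNELS
    if not channels:
        raise ValidationError("channels must be nonempty")
    label_map = dict(DEFAULT_LABEL_MAP) if label_map is None else label_map
    col = [c.index - 1 for c in channels]

    ann = recording.annotations
    X, y, prov = [], [], []
    # maximal runs of constant annotation
    t = len(ann)
    boundaries = np.flatnonzero(np.diff(ann)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [t]))
    for s, e in zip(starts, ends):
        label = label_map.get(int(ann[s]))
        if label is None:
            continue
        for w in range(s, e - sequence_length + 1, stride):
            X.append(recording.samples[w : w + sequence_length, col])
            y.append(label)
            prov.append((recording.subject_id, int(w)))
    if not X:
        logger.warning(
            "recording %s yielded no examples (too short after exclusion)",
            recording.subject_id,
        )
        return LabeledDataset(
            X=np.empty((0, sequence_length, len(channels))),
            y=np.empty((0,), dtype=np.int64),
            channel_ids=channels,
        )
    return LabeledDataset(
        X=np.stack(X), y=np.asarray(y), channel_ids=channels, provenance=prov
    )
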