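"""Core domain types: stage labels, hypnograms, and polysomnogram containers.

Sleep staging follows the AASM convention: a night is tiled by 30-second
epochs, each assigned one of five stages — W (wake), N1, N2, N3 (non-REM
depths), R (REM). All matrices and vectors in this package index stages in
that fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StageLabel",
    "STAGE_ORDER",
    "Hypnogram",
    "ChannelSignal",
    "PolysomnogramRecord",
    "ConfigurationError",
    "DegenerateSignalError",
    "EPOCH_LEN_S",
]

#: AASM scoring epoch length in seconds.
EPOCH_LEN_S = 30.0


class ConfigurationError(ValueError):
    """Raised when inputs cannot be wired together (missing channels, bad maps)."""


class DegenerateSignalError(ValueError):
    """Raised for signals that defeat a computation (zero variance, zero power)."""


class StageLabel(str, Enum):
    """The five AASM sleep stages, in the fixed matrix row/column order."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    R = "R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def index(self) -> int:
        return STAGE_ORDER.index(self)


#: Fixed total order of stages used for every matrix and argmax tie-break.
STAGE_ORDER: tuple[StageLabel, ...] = (
    StageLabel.W,
    StageLabel.N1,
    StageLabel.N2,
    StageLabel.N3,
    StageLabel.R,
)

_LABEL_TO_INDEX = {s: i for i, s in enumerate(STAGE_ORDER)}
_NAME_TO_LABEL = {s.value: s for s in STAGE_ORDER}


def parse_stage(token: str) -> StageLabel:
    """Parse a stage token; raises ValueError for anything outside {W,N1,N2,N3,R}."""
    try:
        return _NAME_TO_LABEL[token]
    except KeyError:
        raise ValueError(f"unknown stage label {token!r}") from None


@dataclass(frozen=True)
class Hypnogram:
    """A sequence of stage labels on a fixed epoch grid (default 30 s)."""

    labels: tuple[StageLabel, ...]
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def to_indices(self) -> np.ndarray:
        """Stage indices in the fixed order, shape (n_epochs,)."""
        return np.array([_LABEL_TO_INDEX[s] for s in self.labels], dtype=np.int64)

    @classmethod
    def from_indices(cls, idx: Iterable[int], epoch_len_s: float = EPOCH_LEN_S) -> "Hypnogram":
        return cls(tuple(STAGE_ORDER[int(i)] for i in idx), epoch_len_s)

    def stage_fractions(self) -> dict[StageLabel, float]:
        idx = self.to_indices()
        counts = np.bincount(idx, minlength=len(STAGE_ORDER))
        return {s: counts[i] / len(self) for i, s in enumerate(STAGE_ORDER)}


@dataclass
class ChannelSignal:
    """One recorded channel: montage (or raw electrode) label, samples in µV, rate in Hz."""

    label: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.label:
            raise ValueError("channel label must be non-empty")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("channel must contain samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def epoch_slice(self, epoch: int, epoch_len_s: float = EPOCH_LEN_S) -> np.ndarray:
        """Samples of the half-open epoch window [epoch*L, (epoch+1)*L) seconds."""
        start = math.floor(epoch * epoch_len_s * self.fs)
        stop = math.floor((epoch + 1) * epoch_len_s * self.fs)
        return self.samples[start:stop]


@dataclass
class PolysomnogramRecord:
    """A multichannel polysomnogram; channels may carry different sampling rates."""

    subject_id: str
    channels: list[ChannelSignal]
    start_time: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("record must contain at least one channel")
        durations = [c.duration_s for c in self.channels]
        ref = durations[0]
        for c, d in zip(self.channels, durations):
            # channels must tile the same span, within one sample at that rate
            if abs(d - ref) > 1.0 / c.fs + 1e-9:
                raise ValueError(
                    f"channel {c.label!r} covers {d:.3f}s but record spans {ref:.3f}s"
                )

    @property
    def duration_s(self) -> float:
        return min(c.duration_s for c in self.channels)

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel(self, label: str) -> ChannelSignal:
        for c in self.channels:
            if c.label == label:
                return c
        raise ConfigurationError(f"record has no channel {label!r}")

    def has_channel(self, label: str) -> bool:
        return any(c.label == label for c in self.channels)


def epoch_count(record_or_duration, epoch_len_s: float = EPOCH_LEN_S) -> int:
    """Number of whole epochs in a record; a trailing partial epoch is discarded."""
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    if isinstance(record_or_duration, PolysomnogramRecord):
        duration = record_or_duration.duration_s
    else:
        duration = float(record_or_duration)
    return int(math.floor(duration / epoch_len_s + 1e-9))
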