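"""Core domain containers for P300 speller sessions.

Everything downstream (preprocessing, phase statistics, ranking,
decoding) consumes these types.  Channel order is montage order
everywhere: every matrix whose axes are channels is indexed
consistently with ``Montage.labels``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Input violates a structural invariant (shapes, ranges, pairing)."""


class FormatError(ValueError):
    """A file could not be parsed as the expected on-disk format."""


class ParameterError(ValueError):
    """A parameter value is outside its admissible range."""


#: Default 6x6 Farwell-Donchin character matrix, row-major.
DEFAULT_MATRIX: tuple[str, ...] = (
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
)

#: 32-channel 10-20 montage used for full-cap simulations.
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

#: Reduced 16-channel montage (default simulator cap): fronto-central,
#: temporal, parietal and occipital coverage.
MONTAGE_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "FC5", "FC1", "C3",
    "Cz", "C4", "T8", "P7", "P3", "Pz", "P8", "Oz",
)

# Approximate 2-D scalp coordinates (x: left-right, y: back-front) for
# topography export; not used by any numerical routine.
_POSITIONS_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95), "AF3": (-0.35, 0.80),
    "AF4": (0.35, 0.80), "F7": (-0.81, 0.59), "F3": (-0.45, 0.55),
    "Fz": (0.0, 0.50), "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.70, 0.30), "FC1": (-0.25, 0.27), "FC2": (0.25, 0.27),
    "FC6": (0.70, 0.30), "T7": (-1.0, 0.0), "C3": (-0.50, 0.0),
    "Cz": (0.0, 0.0), "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.70, -0.30), "CP1": (-0.25, -0.27), "CP2": (0.25, -0.27),
    "CP6": (0.70, -0.30), "P7": (-0.81, -0.59), "P3": (-0.45, -0.55),
    "Pz": (0.0, -0.50), "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.80), "PO4": (0.35, -0.80), "O1": (-0.31, -0.95),
    "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}


@dataclass(frozen=True)
class Montage:
    """Ordered set of channel names, optionally with 2-D scalp positions."""

    labels: tuple[str, ...]
    positions: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValidationError("montage needs at least 2 channels")
        if len(set(labels)) != len(labels):
            raise ValidationError("montage labels must be unique")

    @classmethod
    def standard(cls, n_channels: int) -> "Montage":
        """A 10-20 montage with ``n_channels`` electrodes (2..32)."""
        if n_channels == 32:
            labels = MONTAGE_32
        elif n_channels <= 16:
            labels = MONTAGE_16[:n_channels]
        elif n_channels < 32:
            labels = MONTAGE_32[:n_channels]
        else:
            raise ParameterError("standard montages cover at most 32 channels")
        pos = {lb: _POSITIONS_1020[lb] for lb in labels if lb in _POSITIONS_1020}
        return cls(labels=tuple(labels), positions=pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"channel {label!r} not in montage") from None


@dataclass(frozen=True)
class StimulusEvent:
    """One row/column intensification.

    Codes 1-6 are rows, 7-12 are columns of the 6x6 matrix.
    """

    code: int
    onset_time: float
    is_target: bool
    block_index: int
    repetition_index: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.code) <= 12:
            raise ValidationError(f"stimulus code must be 1..12, got {self.code}")
        if self.block_index < 0 or self.repetition_index < 0:
            raise ValidationError("block and repetition indices must be >= 0")


@dataclass
class EpochSet:
    """Labeled trials x channels x samples tensor (microvolts)."""

    data: np.ndarray
    fs: float
    events: list[StimulusEvent]
    montage: Montage
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be 3-D (trials, channels, samples)")
        if self.data.shape[0] != len(self.events):
            raise ValidationError(
                f"{self.data.shape[0]} trials but {len(self.events)} events"
            )
        if self.data.shape[1] != len(self.montage):
            raise ValidationError(
                f"{self.data.shape[1]} channels but montage has {len(self.montage)}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def target_mask(self) -> np.ndarray:
        return np.array([e.is_target for e in self.events], dtype=bool)

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return EpochSet(
            data=self.data[idx],
            fs=self.fs,
            events=[self.events[i] for i in idx],
            montage=self.montage,
            t0=self.t0,
        )

    def select_channels(self, channels: Sequence[str] | Sequence[int]) -> "EpochSet":
        """Restrict to a channel subset (labels or indices), keeping order given."""
        idx = [
            c if isinstance(c, (int, np.integer)) else self.montage.index(c)
            for c in channels
        ]
        labels = tuple(self.montage.labels[i] for i in idx)
        pos = None
        if self.montage.positions is not None:
            pos = {lb: self.montage.positions[lb]
                   for lb in labels if lb in self.montage.positions}
        return EpochSet(
            data=self.data[:, idx, :],
            fs=self.fs,
            events=list(self.events),
            montage=Montage(labels=labels, positions=pos),
            t0=self.t0,
        )


@dataclass
class SpellerSession:
    """Full record of one spelling run.

    Holds either a continuous multichannel signal or an already-epoched
    tensor, plus the stimulus schedule and (for simulated sessions)
    ground-truth annotations.
    """

    fs: float
    schedule: list[StimulusEvent]
    montage: Montage
    signals: Optional[np.ndarray] = None
    epochs: Optional[EpochSet] = None
    matrix: tuple[str, ...] = DEFAULT_MATRIX
    target_characters: Optional[str] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.signals is None and self.epochs is None:
            raise ValidationError("session needs continuous signals or epochs")
        if self.signals is not None:
            self.signals = np.asarray(self.signals, dtype=float)
            if self.signals.ndim != 2:
                raise ValidationError("continuous signals must be 2-D (channels, samples)")
            if self.signals.shape[0] != len(self.montage):
                raise ValidationError("signal channel count does not match montage")
            dur = self.signals.shape[1] / self.fs
            for i, ev in enumerate(self.schedule):
                if not 0 <= ev.onset_time <= dur:
                    raise ValidationError(
                        f"event {i} onset {ev.onset_time:.3f}s outside recording"
                        f" duration {dur:.3f}s"
                    )

    @property
    def duration_s(self) -> float:
        if self.signals is None:
            raise ValidationError("session has no continuous signals")
        return self.signals.shape[1] / self.fs

    @property
    def n_blocks(self) -> int:
        return 1 + max(e.block_index for e in self.schedule)


def char_for_codes(row_code: int, col_code: int,
                   matrix: tuple[str, ...] = DEFAULT_MATRIX) -> str:
    """Character at the intersection of a row code (1-6) and column code (7-12)."""
    if not (1 <= row_code <= 6 and 7 <= col_code <= 12):
        raise ValidationError("need a row code 1..6 and a column code 7..12")
    return matrix[row_code - 1][col_code - 7]


def codes_for_char(char: str, matrix: tuple[str, ...] = DEFAULT_MATRIX) -> tuple[int, int]:
    """(row_code, col_code) for a character in the matrix."""
    for r, row in enumerate(matrix):
        c = row.find(char)
        if c >= 0:
            return r + 1, c + 7
    raise ValidationError(f"character {char!r} not in matrix")


def validate_schedule(schedule: Sequence[StimulusEvent]) -> None:
    """Check paradigm invariants of a stimulus schedule.

    Within every (block, repetition) cell each of the 12 codes appears
    exactly once and exactly 2 of them are targets; onsets strictly
    increase within each block.
    """
    by_cell: dict[tuple[int, int], list[StimulusEvent]] = {}
    by_block: dict[int, list[StimulusEvent]] = {}
    for ev in schedule:
        by_cell.setdefault((ev.block_index, ev.repetition_index), []).append(ev)
        by_block.setdefault(ev.block_index, []).append(ev)
    for (b, r), evs in by_cell.items():
        codes = sorted(e.code for e in evs)
        if codes != list(range(1, 13)):
            raise ValidationError(
                f"block {b} repetition {r}: codes are not a permutation of 1..12"
            )
        n_tgt = sum(e.is_target for e in evs)
        if n_tgt != 2:
            raise ValidationError(
                f"block {b} repetition {r}: {n_tgt} target codes, expected 2"
            )
    for b, evs in by_block.items():
        onsets = [e.onset_time for e in sorted(evs, key=lambda e: e.onset_time)]
        if any(t1 <= t0 for t0, t1 in zip(onsets, onsets[1:])):
            raise ValidationError(f"block {b}: onsets not strictly increasing")
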