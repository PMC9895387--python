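"""Core data carriers shared by every analysis stage.

The package deliberately keeps EEG in a plain ``channels x samples`` numpy
matrix (microvolts) plus an electrode montage, rather than wrapping a
heavier Raw-style object: every stage here is a pure function on that
matrix, and provenance (filters applied, reference) travels as lightweight
tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Default 32-electrode subset of the extended 10-10 system used by the
#: synthetic generator (a typical 32-channel cap layout).
CHANNELS_32 = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8", "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]


@dataclass(frozen=True)
class Montage:
    """Electrode names and unit-sphere 3-D positions (x right, y anterior,
    z superior)."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 3), unit norm rows

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if pos.shape[0] != len(self.names):
            raise ValueError("positions/names length mismatch")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms <= 0):
            raise ValueError("zero-norm electrode position")
        object.__setattr__(self, "positions", pos / norms[:, None])

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def standard_32(cls) -> "Montage":
        """32-channel 10-10 montage, positions projected on the unit sphere.

        Uses the mne ``standard_1005`` template positions, re-centred on the
        head origin and radially normalized so electrodes lie on the outer
        shell of the spherical head model.
        """
        import mne

        try:
            std = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:
            std = mne.channels.make_standard_montage("standard_1005")
        lookup = std.get_positions()["ch_pos"]
        pos = np.array([lookup[name] for name in CHANNELS_32])
        return cls(tuple(CHANNELS_32), pos)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]
    montage: Montage
    reference: str = "recorded"  # "recorded" | "average"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length != channel count")
        if len(self.montage) != self.data.shape[0]:
            raise ValueError("montage size != channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def with_data(self, data: np.ndarray, reference: str | None = None) -> "EEGRecording":
        return EEGRecording(
            data=data,
            fs_hz=self.fs_hz,
            channel_names=self.channel_names,
            montage=self.montage,
            reference=self.reference if reference is None else reference,
        )

    def copy(self) -> "EEGRecording":
        return self.with_data(self.data.copy())


@dataclass
class EpochSet:
    """Fixed-length consecutive epochs cut from one recording.

    ``epochs`` has shape (n_epochs, channels, samples_per_epoch); ``kept_mask``
    marks epochs surviving artifact rejection.  Rejection never mutates the
    data, it only clears mask bits.
    """

    epochs: np.ndarray
    fs_hz: float
    epoch_length_s: float
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, channels, samples)")
        expected = int(round(self.fs_hz * self.epoch_length_s))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != fs*epoch_length_s={expected}"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.epochs.shape[0],):
            raise ValueError("kept_mask length != epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept(self) -> np.ndarray:
        """Epochs surviving rejection, shape (n_kept, channels, samples)."""
        return self.epochs[self.kept_mask]

    def concatenate_kept(self) -> np.ndarray:
        """Kept epochs glued back into one channels x samples matrix."""
        k = self.kept()
        if k.shape[0] == 0:
            return np.empty((self.epochs.shape[1], 0))
        return np.concatenate(list(k), axis=1)
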