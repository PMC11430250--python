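"""Core containers shared across the pipeline.

The two central objects are :class:`EEGRecording` (a raw multichannel time
series plus its stimulus schedule) and :class:`EpochSet` (labelled fixed-length
epochs, the unit of everything downstream: graph construction, training,
evaluation).

Label convention used throughout the package: positive valence = 1,
negative valence = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: stimulus-schedule tags
TAG_MUSIC_POSITIVE = "music_positive"
TAG_MUSIC_NEGATIVE = "music_negative"
TAG_SILENCE = "silence"

MUSIC_TAGS = {TAG_MUSIC_POSITIVE: 1, TAG_MUSIC_NEGATIVE: 0}

LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0


@dataclass
class EEGRecording:
    """A multichannel EEG recording with its stimulus schedule.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitude in arbitrary (microvolt-like) units.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        Ordered channel labels, one per data row.
    schedule : list of (float, float, str)
        Stimulus intervals ``(start_s, end_s, tag)`` with tags in
        {``music_positive``, ``music_negative``, ``silence``}.
    subject_id : str
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    schedule: list = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.n_samples / self.fs
        for start, end, tag in self.schedule:
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"schedule interval ({start}, {end}, {tag!r}) outside [0, {dur}]"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Same metadata, new sample array (used by the filter stages)."""
        return EEGRecording(
            data=data,
            fs=self.fs,
            channel_names=list(self.channel_names),
            schedule=list(self.schedule),
            subject_id=self.subject_id,
        )


@dataclass
class EpochSet:
    """Labelled fixed-length epochs ready for learning.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch);
    ``labels`` holds 0 (negative) / 1 (positive); ``provenance`` carries one
    dict per epoch with at least ``subject_id`` and ``block`` keys.
    """

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: Sequence[str] = ()
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal number of epochs")
        if self.n_epochs and not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 (negative) or 1 (positive)")
        if self.provenance and len(self.provenance) != self.n_epochs:
            raise ValueError("provenance length must equal number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            epochs=self.epochs[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            provenance=[self.provenance[i] for i in idx] if self.provenance else [],
        )

    @staticmethod
    def concatenate(parts: Sequence["EpochSet"]) -> "EpochSet":
        parts = [p for p in parts if p.n_epochs]
        if not parts:
            raise ValueError("nothing to concatenate")
        fs = parts[0].fs
        if any(p.fs != fs for p in parts):
            raise ValueError("sampling rates differ")
        prov = []
        for p in parts:
            prov.extend(p.provenance)
        return EpochSet(
            epochs=np.concatenate([p.epochs for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            fs=fs,
            channel_names=list(parts[0].channel_names),
            provenance=prov,
        )
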