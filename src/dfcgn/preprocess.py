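"""Preprocessing: channel selection, notch and band-pass filtering, epoching.

The emulated pipeline keeps three channels (FP1, Pz, Fz), removes 50 Hz mains
with an IIR notch, band-passes to 0.5–60 Hz with a 2nd-order Butterworth, and
cuts one 15 s epoch per music block — five blocks per class, i.e. 76,800
samples per channel per class at 1024 Hz.

Filters are applied zero-phase (forward–backward) by default so epoch timing
is preserved; effective attenuation in dB doubles relative to a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import EEGRecording, EpochSet, MUSIC_TAGS


@dataclass
class FilterSpec:
    """Notch + band-pass parameters.

    ``order`` is the Butterworth design order per band edge; ``notch_q`` is
    the notch quality factor (centre frequency / −3 dB bandwidth).
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    band_lo_hz: float = 0.5
    band_hi_hz: float = 60.0
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("band edges must satisfy 0 < lo < hi")
        if self.band_hi_hz >= nyq:
            raise ValueError(
                f"band_hi_hz {self.band_hi_hz} must be below Nyquist {nyq}"
            )
        if self.notch_hz >= nyq:
            raise ValueError(f"notch_hz {self.notch_hz} must be below Nyquist {nyq}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def select_channels(rec: EEGRecording, wanted: Sequence[str]) -> EEGRecording:
    """Restrict a recording to ``wanted`` channels, in the order given."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [w for w in wanted if w not in index]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not present; available: {list(rec.channel_names)}"
        )
    rows = [index[w] for w in wanted]
    return EEGRecording(
        data=rec.data[rows],
        fs=rec.fs,
        channel_names=list(wanted),
        schedule=list(rec.schedule),
        subject_id=rec.subject_id,
    )


def _apply(rec: EEGRecording, b, a, zero_phase: bool) -> EEGRecording:
    if zero_phase:
        # odd-reflection padding suppresses edge transients
        filtered = signal.filtfilt(b, a, rec.data, axis=1, padtype="odd")
    else:
        filtered = signal.lfilter(b, a, rec.data, axis=1)
    return rec.copy_with(filtered)


def apply_notch(rec: EEGRecording, spec: Optional[FilterSpec] = None) -> EEGRecording:
    """Remove the mains frequency with an IIR notch."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
    return _apply(rec, b, a, spec.zero_phase)


def apply_bandpass(rec: EEGRecording, spec: Optional[FilterSpec] = None) -> EEGRecording:
    """Butterworth band-pass keeping the informative 0.5–60 Hz range."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    b, a = signal.butter(
        spec.order, [spec.band_lo_hz, spec.band_hi_hz], btype="band", fs=rec.fs
    )
    return _apply(rec, b, a, spec.zero_phase)


def preprocess_recording(
    rec: EEGRecording,
    channels: Optional[Sequence[str]] = None,
    spec: Optional[FilterSpec] = None,
) -> EEGRecording:
    """Channel selection -> notch -> band-pass, the standard chain."""
    if channels is not None:
        rec = select_channels(rec, channels)
    rec = apply_notch(rec, spec)
    return apply_bandpass(rec, spec)


def extract_emotion_epochs(
    rec: EEGRecording,
    epoch_s: float = 15.0,
    window_s: Optional[float] = None,
) -> EpochSet:
    """Cut one labelled epoch per music block; silence blocks are discarded.

    Each music block must be at least ``epoch_s`` long; the first
    ``epoch_s`` seconds are taken.  When ``window_s`` is given, every epoch is
    further split into non-overlapping ``window_s`` windows that inherit the
    block label — an optional way to multiply training examples.

    Returns an :class:`EpochSet`; with no music blocks in the schedule the
    set is empty (not an error).
    """
    n_epoch = epoch_s * rec.fs
    if abs(n_epoch - round(n_epoch)) > 1e-9:
        raise ValueError(f"epoch_s x fs must be integer, got {n_epoch}")
    n_epoch = int(round(n_epoch))
    if window_s is not None:
        n_win = window_s * rec.fs
        if abs(n_win - round(n_win)) > 1e-9:
            raise ValueError(f"window_s x fs must be integer, got {n_win}")
        n_win = int(round(n_win))
        if n_win < 1 or n_win > n_epoch:
            raise ValueError("window_s must lie in (0, epoch_s]")
    else:
        n_win = n_epoch

    epochs, labels, prov = [], [], []
    block_idx = -1
    for start_s, end_s, tag in rec.schedule:
        if tag not in MUSIC_TAGS:
            continue
        block_idx += 1
        if end_s - start_s < epoch_s - 1e-9:
            raise ValueError(
                f"music block {block_idx} ({start_s}-{end_s} s) shorter than "
                f"epoch_s={epoch_s}"
            )
        i0 = int(round(start_s * rec.fs))
        label = MUSIC_TAGS[tag]
        for w in range(n_epoch // n_win):
            a = i0 + w * n_win
            epochs.append(rec.data[:, a:a + n_win])
            labels.append(label)
            prov.append({"subject_id": rec.subject_id, "block": block_idx, "window": w})

    if not epochs:
        arr = np.zeros((0, rec.n_channels, n_win))
        return EpochSet(arr, np.zeros(0, dtype=int), rec.fs,
                        channel_names=list(rec.channel_names))
    return EpochSet(
        np.stack(epochs), np.asarray(labels), rec.fs,
        channel_names=list(rec.channel_names), provenance=prov,
    )


def epochs_from_recordings(
    recs: Sequence[EEGRecording],
    channels: Optional[Sequence[str]] = None,
    spec: Optional[FilterSpec] = None,
    epoch_s: float = 15.0,
    window_s: Optional[float] = None,
) -> EpochSet:
    """Full preprocessing over a dataset: filter each recording and pool epochs."""
    parts = [
        extract_emotion_epochs(preprocess_recording(r, channels, spec), epoch_s, window_s)
        for r in recs
    ]
    return EpochSet.concatenate(parts)
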