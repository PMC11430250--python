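"""Synthetic EEG generator emulating the music-stimulus recording protocol.

The generator reproduces the *protocol*, not the physiology: each subject
hears alternating 15 s music / 15 s silence blocks (five music blocks per
valence class), recorded on three channels (FP1, Pz, Fz) at 1024 Hz.  A music
block of a given class carries a class-dependent mixture of band-limited
stochastic oscillations in the canonical EEG bands; silence blocks carry a
neutral mixture.  A 50 Hz mains sinusoid and broadband Gaussian noise at a
configurable SNR are added on top.

Oscillations are synthesised as 4th-order Butterworth band-pass filtered
white noise, scaled to the target relative band power — simple, controllable
and stationary within a block.  Band sources are shared across channels with
per-channel gains near 1, so that channel correlations (the basis of the
functional-connectivity graph downstream) are high but not degenerate.

Class signatures are a modelling choice: the positive class has elevated
alpha+beta relative power, the negative class elevated theta.  They are test
fixtures, not scientific claims about valence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import signal

from .core import (
    EEGRecording,
    TAG_MUSIC_NEGATIVE,
    TAG_MUSIC_POSITIVE,
    TAG_SILENCE,
)

#: canonical EEG bands, Hz
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
}

CLASSES = ("positive", "negative")

#: default class band-power signatures (relative power per band)
DEFAULT_CLASS_BAND_POWER: Dict[str, Dict[str, float]] = {
    "positive": {"delta": 0.20, "theta": 0.10, "alpha": 0.35, "beta": 0.25, "gamma": 0.10},
    "negative": {"delta": 0.25, "theta": 0.35, "alpha": 0.10, "beta": 0.10, "gamma": 0.20},
}

#: easy, strongly separated variant of the class signatures, used by
#: demonstrations and end-to-end sanity checks (large alpha/theta contrast)
HIGH_CONTRAST_CLASS_BAND_POWER: Dict[str, Dict[str, float]] = {
    "positive": {"delta": 0.15, "theta": 0.05, "alpha": 0.45, "beta": 0.30, "gamma": 0.05},
    "negative": {"delta": 0.25, "theta": 0.45, "alpha": 0.05, "beta": 0.05, "gamma": 0.20},
}

#: neutral signature used for silence blocks
NEUTRAL_BAND_POWER: Dict[str, float] = {
    "delta": 0.25, "theta": 0.20, "alpha": 0.20, "beta": 0.20, "gamma": 0.15,
}


def _default_class_band_power():
    return {c: dict(v) for c, v in DEFAULT_CLASS_BAND_POWER.items()}


@dataclass
class SynthConfig:
    """Configuration of the synthetic recording protocol.

    Defaults mirror the emulated study: 20 subjects, 1024 Hz, channels
    FP1/Pz/Fz, five 15 s music blocks per class each followed by 15 s of
    silence.  ``amplitude`` sets the overall RMS scale of the oscillatory
    signal in microvolt-like arbitrary units.
    """

    n_subjects: int = 20
    fs: float = 1024.0
    channels: Sequence[str] = ("FP1", "Pz", "Fz")
    n_music_blocks_per_class: int = 5
    block_s: float = 15.0
    silence_s: float = 15.0
    class_band_power: Dict[str, Dict[str, float]] = field(
        default_factory=_default_class_band_power
    )
    mains_hz: float = 50.0
    mains_amp: float = 2.0
    noise_snr_db: float = 20.0
    amplitude: float = 30.0
    channel_gain_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        top = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * top:
            raise ValueError(f"fs must exceed twice the highest band edge ({top} Hz)")
        for name in ("block_s", "silence_s"):
            n = getattr(self, name) * self.fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} x fs must be an integer sample count, got {n}")
        for cls, powers in self.class_band_power.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            for band, p in powers.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r}")
                if p <= 0:
                    raise ValueError(f"band power for {cls}/{band} must be positive")

    @property
    def block_samples(self) -> int:
        return int(round(self.block_s * self.fs))

    @property
    def silence_samples(self) -> int:
        return int(round(self.silence_s * self.fs))

    @property
    def samples_per_recording(self) -> int:
        return self.n_music_blocks_per_class * (self.block_samples + self.silence_samples)

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


_SYNTH_FILTER_ORDER = 8


def _band_sos(lo: float, hi: float, fs: float):
    return signal.butter(_SYNTH_FILTER_ORDER, [lo, hi], btype="band", fs=fs,
                         output="sos")


@lru_cache(maxsize=8)
def _band_mix_matrix(fs: float, grid: int = 8192) -> np.ndarray:
    """M[i, j] = fraction of band-j source power landing inside band i.

    Band-pass filters leak energy outside their nominal edges; the configured
    class signatures are *measured* in-band ratios, so source powers are
    obtained by solving M p = target rather than used directly.
    """
    freqs = np.linspace(0.0, fs / 2.0, grid)
    names = list(BANDS)
    M = np.zeros((len(names), len(names)))
    for j, band in enumerate(names):
        lo, hi = BANDS[band]
        _, h = signal.sosfreqz(_band_sos(lo, hi, fs), worN=freqs, fs=fs)
        psd = np.abs(h) ** 2
        total = np.trapezoid(psd, freqs)
        for i, tgt in enumerate(names):
            tlo, thi = BANDS[tgt]
            m = (freqs >= tlo) & (freqs < thi)
            M[i, j] = np.trapezoid(psd[m], freqs[m]) / total
    return M


def _source_powers(band_power: Dict[str, float], fs: float) -> Dict[str, float]:
    """Solve the leakage system so measured in-band ratios match the config."""
    from scipy.optimize import nnls

    names = list(BANDS)
    target = np.array([band_power.get(b, 0.0) for b in names], dtype=float)
    target = target / target.sum()
    p, _ = nnls(_band_mix_matrix(fs), target)
    p = np.maximum(p, 0.0)
    p = p / p.sum()
    return dict(zip(names, p))


def _block_signals(
    rng: np.random.Generator,
    band_power: Dict[str, float],
    n_samples: int,
    n_channels: int,
    cfg: SynthConfig,
) -> np.ndarray:
    """Oscillatory part of one block: shared band sources, per-channel gains."""
    powers = _source_powers(band_power, cfg.fs)
    pad = int(round(2 * cfg.fs))  # discard filter warm-up
    out = np.zeros((n_channels, n_samples))
    for band, rel in powers.items():
        if rel <= 0:
            continue
        lo, hi = BANDS[band]
        white = rng.standard_normal(n_samples + 2 * pad)
        src = signal.sosfilt(_band_sos(lo, hi, cfg.fs), white)[pad:pad + n_samples]
        src = src / (np.std(src) + 1e-30)
        scale = cfg.amplitude * np.sqrt(rel)
        gains = 1.0 + cfg.channel_gain_sd * rng.standard_normal(n_channels)
        out += np.outer(gains, src) * scale
    return out


def generate_recording(cfg: SynthConfig, subject: int, class_label: str) -> EEGRecording:
    """Generate one subject's recording for one valence class.

    The recording alternates ``n_music_blocks_per_class`` music blocks (all of
    ``class_label``) with silence blocks, per the emulated protocol, and
    carries a machine-readable stimulus schedule.  Bit-reproducible for a
    given config, subject and class.
    """
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}, got {class_label!r}")
    if not (0 <= subject < cfg.n_subjects):
        raise ValueError(f"subject {subject} out of range [0, {cfg.n_subjects})")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(subject), CLASSES.index(class_label)])
    )
    n_ch = len(cfg.channels)
    tag = TAG_MUSIC_POSITIVE if class_label == "positive" else TAG_MUSIC_NEGATIVE

    chunks, schedule, t = [], [], 0.0
    music_mask = np.zeros(cfg.samples_per_recording, dtype=bool)
    pos = 0
    for _ in range(cfg.n_music_blocks_per_class):
        block = _block_signals(
            rng, cfg.class_band_power[class_label], cfg.block_samples, n_ch, cfg
        )
        chunks.append(block)
        schedule.append((t, t + cfg.block_s, tag))
        music_mask[pos:pos + cfg.block_samples] = True
        t += cfg.block_s
        pos += cfg.block_samples

        sil = _block_signals(rng, NEUTRAL_BAND_POWER, cfg.silence_samples, n_ch, cfg)
        chunks.append(sil)
        schedule.append((t, t + cfg.silence_s, TAG_SILENCE))
        t += cfg.silence_s
        pos += cfg.silence_samples

    data = np.concatenate(chunks, axis=1)

    # 50 Hz mains over the whole recording
    if cfg.mains_amp != 0.0:
        tt = np.arange(data.shape[1]) / cfg.fs
        phase = rng.uniform(0, 2 * np.pi, size=n_ch)
        data += cfg.mains_amp * np.sin(
            2 * np.pi * cfg.mains_hz * tt[None, :] + phase[:, None]
        )

    # broadband noise scaled so SNR on the music portion hits noise_snr_db
    if np.isfinite(cfg.noise_snr_db):
        p_sig = float(np.mean(data[:, music_mask] ** 2))
        p_noise = p_sig / 10.0 ** (cfg.noise_snr_db / 10.0)
        data += np.sqrt(p_noise) * rng.standard_normal(data.shape)

    return EEGRecording(
        data=data,
        fs=cfg.fs,
        channel_names=list(cfg.channels),
        schedule=schedule,
        subject_id=f"S{subject:02d}_{class_label}",
    )


def generate_dataset(cfg: SynthConfig) -> list:
    """One positive and one negative recording per subject (2 x n_subjects)."""
    return [
        generate_recording(cfg, subject, cls)
        for subject in range(cfg.n_subjects)
        for cls in CLASSES
    ]


def band_power_ratios(x: np.ndarray, fs: float) -> Dict[str, float]:
    """Relative power per canonical band from a Welch spectrum (diagnostics).

    ``x`` is a 1-D signal; returns powers normalised to sum to 1 over BANDS.
    """
    nper = min(len(x), int(4 * fs))
    f, pxx = signal.welch(x, fs=fs, nperseg=nper)
    out = {}
    for band, (lo, hi) in BANDS.items():
        m = (f >= lo) & (f < hi)
        out[band] = float(np.trapezoid(pxx[m], f[m]))
    total = sum(out.values())
    return {b: p / total for b, p in out.items()}
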