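"""Recording and epoch-set readers/writers.

Two interchange dialects:

* **delimited + sidecar** — a UTF-8 CSV of samples × channels with a header
  row of channel labels, plus a JSON sidecar (``<file>.json``) carrying the
  sampling rate, stimulus schedule and subject id.  Lossless round trip; the
  native format of the synthetic generator.
* **EDF** (European Data Format) — the field's standard container for real
  recordings.  Reading goes through MNE; writing uses a minimal EDF writer
  (16-bit samples, 1-second data records) since sample values quantise to
  the 16-bit digital range anyway.  The stimulus schedule travels in the same
  JSON sidecar next to the ``.edf`` file.

Epoch sets persist as ``.npz`` (arrays) plus a JSON manifest.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .core import EEGRecording, EpochSet


# ---------------------------------------------------------------------------
# sidecar


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(rec: EEGRecording, path) -> None:
    payload = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "schedule": [[s, e, t] for s, e, t in rec.schedule],
        "subject_id": rec.subject_id,
    }
    _sidecar_path(path).write_text(json.dumps(payload, indent=1))


def _read_sidecar(path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc}")
    return json.loads(sc.read_text())


# ---------------------------------------------------------------------------
# delimited matrix


def write_delimited(rec: EEGRecording, path) -> None:
    """Samples × channels CSV with channel-label header + JSON sidecar."""
    header = ",".join(rec.channel_names)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="",
               fmt="%.10g")
    _write_sidecar(rec, path)


def read_delimited(path) -> EEGRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
    return EEGRecording(
        data=data,
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        schedule=[tuple(iv) for iv in meta["schedule"]],
        subject_id=meta.get("subject_id", ""),
    )


# ---------------------------------------------------------------------------
# EDF


def write_edf(rec: EEGRecording, path) -> None:
    """Write an EDF file (16-bit, one data record per second) + sidecar.

    The sampling rate must be an integer; amplitudes are scaled to the full
    digital range per channel, so the round trip is exact to the 16-bit
    quantisation step.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, : rec.n_samples] = rec.data

    ph_min = padded.min(axis=1)
    ph_max = padded.max(axis=1)
    same = ph_max - ph_min < 1e-12
    ph_max = np.where(same, ph_min + 1.0, ph_max)
    dig_min, dig_max = -32768, 32767

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(256 + n_ch * 256, 8),
        f("EDF", 44), f(n_rec, 8), f("1", 8), f(n_ch, 4),
    ])
    labels = [f(name, 16) for name in rec.channel_names]
    hdr += b"".join(labels)
    hdr += b"".join(f("", 80) for _ in range(n_ch))          # transducer
    hdr += b"".join(f("uV", 8) for _ in range(n_ch))         # physical dim
    hdr += b"".join(f(f"{v:.6g}", 8) for v in ph_min)
    hdr += b"".join(f(f"{v:.6g}", 8) for v in ph_max)
    hdr += b"".join(f(dig_min, 8) for _ in range(n_ch))
    hdr += b"".join(f(dig_max, 8) for _ in range(n_ch))
    hdr += b"".join(f("", 80) for _ in range(n_ch))          # prefiltering
    hdr += b"".join(f(fs, 8) for _ in range(n_ch))
    hdr += b"".join(f("", 32) for _ in range(n_ch))          # reserved

    # physical -> digital, per EDF spec (re-parse the printed physical range
    # so the round trip is bit-faithful to the header)
    ph_min_r = np.array([float(f"{v:.6g}") for v in ph_min])
    ph_max_r = np.array([float(f"{v:.6g}") for v in ph_max])
    gain = (dig_max - dig_min) / (ph_max_r - ph_min_r)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            seg = padded[:, r * fs:(r + 1) * fs]
            dig = np.round((seg - ph_min_r[:, None]) * gain[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())
    _write_sidecar(rec, path)


def read_edf(path, schedule_sidecar: bool = True) -> EEGRecording:
    """Read an EDF recording via MNE; schedule from the JSON sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # MNE converts EEG channels to volts
    schedule, subject = [], ""
    if schedule_sidecar and _sidecar_path(path).exists():
        meta = _read_sidecar(path)
        if abs(meta["fs"] - fs) > 1e-6:
            raise ValueError(f"sidecar fs {meta['fs']} != EDF header fs {fs}")
        schedule = [tuple(iv) for iv in meta["schedule"]]
        subject = meta.get("subject_id", "")
    return EEGRecording(
        data=data, fs=fs, channel_names=list(raw.ch_names),
        schedule=schedule, subject_id=subject,
    )


def read_recording(path, format: Optional[str] = None) -> EEGRecording:
    """Dispatch on format ('edf' or 'delimited'); inferred from the suffix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return read_edf(path)
    if format == "delimited":
        return read_delimited(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: EEGRecording, path, format: Optional[str] = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        write_edf(rec, path)
    elif format == "delimited":
        write_delimited(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# epoch sets


def save_epochs(eset: EpochSet, path) -> None:
    """Compressed array container + JSON manifest (labels, fs, provenance)."""
    np.savez_compressed(path, epochs=eset.epochs, labels=eset.labels)
    manifest = {
        "fs": eset.fs,
        "channel_names": list(eset.channel_names),
        "provenance": eset.provenance,
        "n_epochs": eset.n_epochs,
    }
    _sidecar_path(path).write_text(json.dumps(manifest, indent=1))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    npz = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    if not npz.exists():
        npz = path
    meta = _read_sidecar(path if _sidecar_path(path).exists() else npz)
    with np.load(npz) as z:
        return EpochSet(
            epochs=z["epochs"], labels=z["labels"], fs=meta["fs"],
            channel_names=meta["channel_names"],
            provenance=meta.get("provenance", []),
        )
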