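"""Minimal European Data Format (EDF) reader/writer for EEG recordings.

Implements the plain EDF layout: a 256-byte ASCII global header, 256 bytes
of ASCII header per signal, then little-endian int16 samples grouped into
fixed-duration data records.  Physical scaling follows the header's
physical/digital min/max fields, so a write/read round-trip preserves
samples to the 16-bit quantisation step.

Subject label and id do not fit EDF's patient field reliably, so cohorts
are written with a JSON sidecar per recording and a CSV manifest
(``subject_id, label, file``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Recording

__all__ = ["write_edf", "read_edf", "write_cohort", "read_cohort", "EdfFormatError"]

DIG_MIN, DIG_MAX = -32768, 32767


class EdfFormatError(ValueError):
    """Raised for malformed or truncated EDF files."""


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def quantization_step(physical_min: float, physical_max: float) -> float:
    """Microvolts per digital unit for a signal's header ranges."""
    return (physical_max - physical_min) / (DIG_MAX - DIG_MIN)


def write_edf(rec: Recording, path) -> None:
    """Write a recording as EDF with a JSON sidecar carrying id and label.

    The recording duration must be a whole number of seconds (one-second
    data records are used).
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise EdfFormatError("sampling rate must be an integer for EDF export")
    if rec.n_samples % spr != 0:
        raise EdfFormatError("recording length must be a whole number of seconds")
    n_records = rec.n_samples // spr
    n_sig = rec.n_channels

    pmins = np.empty(n_sig)
    pmaxs = np.empty(n_sig)
    digital = np.empty((n_sig, rec.n_samples), dtype=np.int16)
    for c in range(n_sig):
        x = rec.signal[c]
        amp = max(float(np.max(np.abs(x))), 1e-6)
        # EDF stores phys min/max as 8-char ASCII; round up so the printed
        # value still covers the data.
        amp = float(np.ceil(amp * 1e3) / 1e3)
        pmins[c], pmaxs[c] = -amp, amp
        gain = (DIG_MAX - DIG_MIN) / (2 * amp)
        digital[c] = np.clip(
            np.round((x - (-amp)) * gain + DIG_MIN), DIG_MIN, DIG_MAX
        ).astype(np.int16)

    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii(rec.subject_id, 80)
    header += _ascii("synthetic EEG", 80)
    header += _ascii("01.01.20", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_sig), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)
    header += _ascii(n_sig, 4)
    for c in range(n_sig):
        header += _ascii(rec.channel_names[c], 16)
    header += b"".join(_ascii("", 80) for _ in range(n_sig))
    header += b"".join(_ascii("uV", 8) for _ in range(n_sig))
    header += b"".join(_ascii(f"{pmins[c]:.3f}"[:8], 8) for c in range(n_sig))
    header += b"".join(_ascii(f"{pmaxs[c]:.3f}"[:8], 8) for c in range(n_sig))
    header += b"".join(_ascii(DIG_MIN, 8) for _ in range(n_sig))
    header += b"".join(_ascii(DIG_MAX, 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 80) for _ in range(n_sig))
    header += b"".join(_ascii(spr, 8) for _ in range(n_sig))
    header += b"".join(_ascii("", 32) for _ in range(n_sig))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        rec3 = digital.reshape(n_sig, n_records, spr)
        for r in range(n_records):
            fh.write(rec3[:, r, :].astype("<i2").tobytes())

    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "sampling_rate": fs,
            }
        )
    )


def _field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path) -> Recording:
    """Read an EDF file (with optional JSON sidecar) back into a Recording."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: file shorter than EDF global header")
    try:
        header_bytes = int(_field(raw, 184, 8))
        n_records = int(_field(raw, 236, 8))
        record_dur = float(_field(raw, 244, 8))
        n_sig = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed EDF global header") from exc
    if len(raw) < header_bytes or header_bytes != 256 * (1 + n_sig):
        raise EdfFormatError(f"{path}: truncated or inconsistent EDF header")

    sig = raw[256:header_bytes]

    def sig_fields(block: int, width: int) -> list[str]:
        base = block
        return [
            sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(n_sig)
        ]

    off = 0
    labels = sig_fields(off, 16); off += 16 * n_sig
    off += 80 * n_sig  # transducer
    off += 8 * n_sig   # dimension
    pmin = [float(v) for v in sig_fields(off, 8)]; off += 8 * n_sig
    pmax = [float(v) for v in sig_fields(off, 8)]; off += 8 * n_sig
    dmin = [int(v) for v in sig_fields(off, 8)]; off += 8 * n_sig
    dmax = [int(v) for v in sig_fields(off, 8)]; off += 8 * n_sig
    off += 80 * n_sig  # prefiltering
    spr = [int(v) for v in sig_fields(off, 8)]; off += 8 * n_sig

    if len(set(spr)) != 1:
        raise EdfFormatError(f"{path}: mixed per-signal sampling rates unsupported")
    spr0 = spr[0]
    expected = header_bytes + n_records * n_sig * spr0 * 2
    if len(raw) < expected:
        raise EdfFormatError(
            f"{path}: truncated data section ({len(raw)} bytes, expected {expected})"
        )

    data = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    data = data.reshape(n_records, n_sig, spr0).transpose(1, 0, 2).reshape(n_sig, -1)
    signal = np.empty(data.shape, dtype=np.float64)
    for c in range(n_sig):
        gain = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
        signal[c] = (data[c].astype(np.float64) - dmin[c]) * gain + pmin[c]

    fs = spr0 / record_dur
    subject_id, label = path.stem, "CONTROL"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        subject_id = meta.get("subject_id", subject_id)
        label = meta.get("label", label)
    return Recording(
        subject_id=subject_id,
        label=label,
        sampling_rate=fs,
        channel_names=tuple(labels),
        signal=signal,
    )


def write_cohort(recordings: list[Recording], out_dir) -> Path:
    """Write a cohort as EDF files plus a ``manifest.csv``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.edf"
        write_edf(rec, out_dir / fname)
        rows.append({"subject_id": rec.subject_id, "label": rec.label, "file": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[Recording]:
    """Load every recording listed in a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    recs = []
    for _, row in df.iterrows():
        rec = read_edf(manifest_path.parent / row["file"])
        rec.subject_id = str(row["subject_id"])
        rec.label = str(row["label"])
        recs.append(rec)
    return recs
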