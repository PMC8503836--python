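"""Minimal EDF writing and reading for single-channel PPG.

The writer emits a plain EDF file (one signal, 16-bit samples, 1-s data
records) sufficient for round-tripping simulated PPG through standard
readers; reading goes through MNE's native EDF reader.  Durations are
truncated to whole seconds and amplitudes quantized to the 16-bit digital
range, so round trips agree to the quantization step.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .preprocess import PPGRecording

__all__ = ["write_edf", "read_edf"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: PPGRecording, channel: str = "PPG") -> None:
    """Write one PPG channel as EDF (16-bit, 1-s records)."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    fs = int(round(fs))
    n_records = len(rec.samples) // fs
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s data record")
    x = np.asarray(rec.samples[: n_records * fs], dtype=float)
    pmin, pmax = float(x.min()), float(x.max())
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((x - pmin) * scale) + dmin, dmin, dmax
                      ).astype("<i2")

    start = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(rec.patient_id or "X", 80),
        _field("Startdate 01-JAN-2000", 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(str(256 * 2), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field("1", 4),
        # per-signal fields
        _field(channel, 16),
        _field("", 80),
        _field("au", 8),
        _field(f"{pmin:.6g}"[:8], 8),
        _field(f"{pmax:.6g}"[:8], 8),
        _field(str(dmin), 8),
        _field(str(dmax), 8),
        _field("", 80),
        _field(str(fs), 8),
        _field("", 32),
    ])
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path, channel: str | None = None,
             patient_id: str = "") -> PPGRecording:
    """Load one channel from an EDF/EDF+ file via MNE."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    name = channel or raw.ch_names[0]
    if name not in raw.ch_names:
        raise KeyError(f"channel {name!r} not in {raw.ch_names}")
    data = raw.get_data(picks=[name])[0]
    return PPGRecording(data, raw.info["sfreq"], patient_id=patient_id)
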