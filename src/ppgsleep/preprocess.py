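"""Raw PPG to model input: anti-aliased downsampling, z-scoring, windowing.

The model consumes 30-s windows of PPG resampled to 32 Hz (960 samples) and
z-score normalized over the whole recording.  Downsampling applies an order-8
Chebyshev type I low-pass (0.05 dB passband ripple, cutoff at 0.8x the output
Nyquist) forward-backward before decimating by the integer factor, which is
scipy's standard IIR decimator.  Windows may overlap: a step ``d`` < 30 s
yields a densified epoch grid with window ``i`` covering ``[i*d, i*d + 30)``
seconds; the trailing remainder shorter than one step is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PPGRecording",
    "EpochTensor",
    "antialias_downsample",
    "zscore",
    "segment_epochs",
    "MODEL_FS",
    "EPOCH_LEN_S",
    "SAMPLES_PER_EPOCH",
    "VALID_INTERVALS",
    "n_epochs_for",
    "prepare_epochs",
]

MODEL_FS = 32
EPOCH_LEN_S = 30
SAMPLES_PER_EPOCH = MODEL_FS * EPOCH_LEN_S  # 960
VALID_INTERVALS = (30, 15, 5, 1)


@dataclass
class PPGRecording:
    """Single-channel pulse waveform with its sampling rate."""

    samples: np.ndarray
    fs: float
    patient_id: str = ""
    start_offset_s: float = 0.0
    zero_variance: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class EpochTensor:
    """Stack of (possibly overlapping) 960-sample epoch windows."""

    windows: np.ndarray  # (n_epochs, 960)
    interval_s: int
    epoch_len_s: int = EPOCH_LEN_S
    patient_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.windows.shape[0]

    @property
    def window_starts_s(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.interval_s


def n_epochs_for(duration_s: float, interval_s: int,
                 epoch_len_s: int = EPOCH_LEN_S) -> int:
    """Number of epoch windows: floor((T - 30) / d) + 1."""
    if duration_s < epoch_len_s:
        raise ValueError(
            f"recording of {duration_s} s shorter than one {epoch_len_s}-s epoch")
    return int((duration_s - epoch_len_s) // interval_s) + 1


def antialias_downsample(rec: PPGRecording, target_fs: int = MODEL_FS) -> PPGRecording:
    """Low-pass filter and decimate to ``target_fs``.

    The source rate must be an integer multiple of the target rate.  The
    anti-aliasing filter is an order-8 Chebyshev type I design applied
    forward-backward (zero phase), so pulse landmarks are not shifted.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs {rec.fs} is not an integer multiple of target {target_fs}")
    factor = int(round(factor))
    if factor == 1:
        return PPGRecording(rec.samples.copy(), target_fs, rec.patient_id,
                            rec.start_offset_s)
    # filtfilt needs ~3x the filter order of padding on each side
    if len(rec.samples) < 8 * 3 * 2:
        raise ValueError("signal shorter than the filter warm-up")
    out = signal.decimate(rec.samples, factor, n=8, ftype="iir", zero_phase=True)
    return PPGRecording(out, target_fs, rec.patient_id, rec.start_offset_s)


def zscore(rec: PPGRecording) -> PPGRecording:
    """Whole-recording z-score normalization (population SD).

    A zero-variance input yields an all-zero signal with the
    ``zero_variance`` flag set (and a warning).
    """
    x = rec.samples
    if len(x) == 0:
        raise ValueError("empty signal")
    sd = x.std()
    if sd == 0.0:
        warnings.warn("zero-variance signal; z-score output is all zeros")
        return PPGRecording(np.zeros_like(x), rec.fs, rec.patient_id,
                            rec.start_offset_s, zero_variance=True)
    return PPGRecording((x - x.mean()) / sd, rec.fs, rec.patient_id,
                        rec.start_offset_s)


def segment_epochs(rec: PPGRecording, interval_s: int) -> EpochTensor:
    """Cut a 32-Hz recording into 30-s windows every ``interval_s`` seconds."""
    if interval_s not in VALID_INTERVALS:
        raise ValueError(f"interval must be one of {VALID_INTERVALS}")
    if rec.fs != MODEL_FS:
        raise ValueError(f"expected a {MODEL_FS}-Hz recording, got fs={rec.fs}")
    n = n_epochs_for(rec.duration_s, interval_s)
    step = interval_s * MODEL_FS
    idx = np.arange(n)[:, None] * step + np.arange(SAMPLES_PER_EPOCH)[None, :]
    return EpochTensor(rec.samples[idx], interval_s, patient_id=rec.patient_id)


def prepare_epochs(rec: PPGRecording, interval_s: int = 30) -> EpochTensor:
    """Full input pipeline: downsample to 32 Hz, z-score, segment."""
    return segment_epochs(zscore(antialias_downsample(rec)), interval_s)
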