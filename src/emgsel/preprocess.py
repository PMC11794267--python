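"""Denoising and overlapping-window segmentation of raw EMG.

Standard myoelectric preprocessing: a narrow 50 Hz notch against powerline
interference, a 20-500 Hz Butterworth bandpass, then fixed-duration
overlapping windows (250 ms, 50% overlap by default) cut strictly inside
annotated movement intervals.  Filters are applied forward-backward
(zero phase) so zero-crossing and slope-sign counts are not shifted by phase
distortion.  Sample coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth import Recording

__all__ = ["SegmentSet", "notch_filter", "bandpass_filter", "segment", "window_count"]


class ParameterError(ValueError):
    pass


@dataclass
class SegmentSet:
    """Labeled fixed-length windows: ``windows[n_windows, n_channels, W]``."""

    windows: np.ndarray
    labels: np.ndarray                  # movement label per window
    window_ms: float
    overlap_fraction: float
    fs: float
    provenance: list = field(default_factory=list)  # (subject, repetition) per window

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_samples(self) -> int:
        return self.windows.shape[2]


def _as_channel_matrix(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def notch_filter(signal: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` Hz with quality factor ``q``."""
    if not 0 < f0 < fs / 2:
        raise ParameterError(f"notch frequency {f0} outside (0, fs/2)")
    x = _as_channel_matrix(signal)
    b, a = sps.iirnotch(f0, q, fs=fs)
    # a high-Q notch has a long impulse response; extend the reflection
    # padding so filtfilt start-up transients stay outside the data
    padlen = min(x.shape[-1] - 1, int(fs))
    out = sps.filtfilt(b, a, x, axis=-1, padlen=padlen)
    return out if np.asarray(signal).ndim > 1 else out[0]


def bandpass_filter(signal: np.ndarray, fs: float, low: float = 20.0,
                    high: float = 500.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass; removes DC and out-of-band content."""
    if not 0 < low < high < fs / 2:
        raise ParameterError(f"invalid band ({low}, {high}) for fs={fs}")
    x = _as_channel_matrix(signal)
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, x, axis=-1)
    return out if np.asarray(signal).ndim > 1 else out[0]


def window_count(interval_samples: int, window_samples: int, overlap_fraction: float) -> int:
    """Number of overlapping windows that fit in an interval (0 if too short)."""
    step = int(round(window_samples * (1.0 - overlap_fraction)))
    if step < 1:
        raise ParameterError("overlap too large: step would be < 1 sample")
    if interval_samples < window_samples:
        return 0
    return (interval_samples - window_samples) // step + 1


def segment(rec: Recording, window_ms: float = 250.0,
            overlap_fraction: float = 0.5) -> SegmentSet:
    """Cut labeled overlapping windows from each annotated movement interval.

    Windows never cross interval boundaries; intervals shorter than one window
    are skipped with a warning.  Empty annotations give an empty SegmentSet.
    """
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must be in [0, 1)")
    W = int(round(window_ms * rec.fs / 1000.0))
    step = int(round(W * (1.0 - overlap_fraction)))
    windows, labels, prov = [], [], []
    for onset, offset, label, rep in rec.annotations:
        T = offset - onset
        n_win = window_count(T, W, overlap_fraction)
        if n_win == 0:
            warnings.warn(
                f"interval [{onset}, {offset}) of movement {label!r} shorter than "
                f"one {W}-sample window; skipped"
            )
            continue
        for i in range(n_win):
            s = onset + i * step
            windows.append(rec.signal[:, s:s + W])
            labels.append(label)
            prov.append((rec.subject_id, rep))
    if windows:
        arr = np.stack(windows)
    else:
        arr = np.empty((0, rec.n_channels, W))
    return SegmentSet(windows=arr, labels=np.asarray(labels, dtype=object),
                      window_ms=window_ms, overlap_fraction=overlap_fraction,
                      fs=rec.fs, provenance=prov)
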