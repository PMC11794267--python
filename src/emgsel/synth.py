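"""Seeded synthetic multi-channel surface EMG.

Emulates a standard myoelectric-control acquisition protocol: a small set of
hand/wrist movements, each repeated several times with rest in between,
recorded at 2 kHz from 10-12 forearm channels.  The carrier is Gaussian white
noise bandpassed to the sEMG band (20-450 Hz by default) and variance
normalized, so the amplitude- and spectrum-sensitive window features
downstream respond to it the way they respond to real sEMG.  Each movement
modulates the carrier with a per-channel activation gain under a trapezoidal
onset/offset envelope; baseline noise and optional 50 Hz powerline
interference are added throughout.

Amplitude units are arbitrary: every threshold downstream is defined relative
to window statistics, never absolute volts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "SynthConfig",
    "Recording",
    "default_gain_matrix",
    "generate_recording",
    "write_recording",
    "read_recording",
    "planted_feature_matrix",
]

DEFAULT_MOVEMENTS = ("AF", "FF", "WE", "WRD", "WUD", "WEC")


class ConfigurationError(ValueError):
    """Raised when a SynthConfig is internally inconsistent."""


def default_gain_matrix(n_movements: int, n_channels: int) -> np.ndarray:
    """Activation amplitude per (movement, channel).

    Each movement gets two dominant channels at gain 3 (cyclically assigned)
    and the remaining channels get supporting gains cycled through
    0.5/0.75/1.0, mimicking dominant and co-activated muscles.
    """
    gain = np.empty((n_movements, n_channels))
    support = (0.5, 0.75, 1.0)
    pair_period = max(1, n_channels // 2)
    k = 2 if pair_period % 3 == 2 else 1
    for m in range(n_movements):
        # movements spaced pair_period apart share a dominant-channel pair;
        # the extra phase keeps their support patterns (hence rows) distinct
        phase = m + k * (m // pair_period)
        for c in range(n_channels):
            gain[m, c] = support[(phase + c) % 3]
        gain[m, (2 * m) % n_channels] = 3.0
        gain[m, (2 * m + 1) % n_channels] = 3.0
    return gain


@dataclass
class SynthConfig:
    n_channels: int = 12
    fs: float = 2000.0
    movements: tuple = DEFAULT_MOVEMENTS
    n_reps: int = 6
    rep_duration: float = 5.0
    rest_duration: float = 3.0
    gain: np.ndarray | None = None          # [n_movements x n_channels]
    baseline_sd: float = 0.3
    powerline_amp: float = 0.0
    carrier_band: tuple = (20.0, 450.0)
    envelope_ramp: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.rep_duration <= 0 or self.rest_duration <= 0:
            raise ConfigurationError("rep_duration and rest_duration must be > 0")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if not (0 < self.carrier_band[0] < self.carrier_band[1] < self.fs / 2):
            raise ConfigurationError("carrier_band must satisfy 0 < low < high < fs/2")
        if self.gain is None:
            self.gain = default_gain_matrix(len(self.movements), self.n_channels)
        else:
            self.gain = np.asarray(self.gain, dtype=float)
            if self.gain.shape != (len(self.movements), self.n_channels):
                raise ConfigurationError(
                    f"gain must have shape ({len(self.movements)}, {self.n_channels}), "
                    f"got {self.gain.shape}"
                )
            if np.any(self.gain < 0):
                raise ConfigurationError("gain entries must be >= 0")


@dataclass
class Recording:
    """Raw multi-channel signal with movement/repetition annotations.

    ``annotations`` is a list of ``(onset, offset, movement, repetition)``
    with 0-based half-open sample intervals, sorted and non-overlapping.
    """

    signal: np.ndarray            # [n_channels x n_samples]
    fs: float
    annotations: list = field(default_factory=list)
    subject_id: str = "synthetic"

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _bandlimited_noise(rng: np.random.Generator, n: int, band, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise bandpassed to ``band``."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _trapezoid(n: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n)
    r = min(ramp_samples, n // 2)
    if r > 0:
        env[:r] = np.linspace(0.0, 1.0, r, endpoint=False)
        env[n - r:] = np.linspace(1.0, 0.0, r + 1)[1:]
    return env


def generate_recording(config: SynthConfig, subject_id: str = "synthetic") -> Recording:
    """Generate one seeded recording following the movement/rest protocol.

    Layout: movements in catalog order; for each movement, ``n_reps`` blocks of
    ``rep_duration`` s activity followed by ``rest_duration`` s rest.  The same
    config and seed produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_mov = len(config.movements)
    rep_n = int(round(config.rep_duration * fs))
    rest_n = int(round(config.rest_duration * fs))
    block = rep_n + rest_n
    n_samples = n_mov * config.n_reps * block

    sig = np.empty((config.n_channels, n_samples))
    for c in range(config.n_channels):
        sig[c] = config.baseline_sd * _bandlimited_noise(
            rng, n_samples, config.carrier_band, fs
        )

    ramp = int(round(config.envelope_ramp * fs))
    env = _trapezoid(rep_n, ramp)
    annotations = []
    idx = 0
    for m, label in enumerate(config.movements):
        for rep in range(config.n_reps):
            onset, offset = idx, idx + rep_n
            for c in range(config.n_channels):
                g = config.gain[m, c]
                carrier = _bandlimited_noise(rng, rep_n, config.carrier_band, fs)
                if g > 0:
                    sig[c, onset:offset] += g * env * carrier
            annotations.append((onset, offset, label, rep))
            idx += block

    if config.powerline_amp:
        t = np.arange(n_samples) / fs
        sig += config.powerline_amp * np.sin(2 * np.pi * 50.0 * t)

    return Recording(signal=sig, fs=fs, annotations=annotations, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Text serialization: TSV sample matrix + JSON sidecar
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    """Raised on malformed or inconsistent on-disk recordings."""


def write_recording(rec: Recording, path) -> None:
    """Write ``<path>.tsv`` (samples x channels, header row) and ``<path>.json``."""
    path = Path(path)
    header = "\t".join(f"ch{c}" for c in range(rec.n_channels))
    np.savetxt(path.with_suffix(".tsv"), rec.signal.T, fmt="%.17e",
               delimiter="\t", header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "annotations": [list(a) for a in rec.annotations],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "subject_id", "n_channels", "n_samples", "annotations"):
        if key not in meta:
            raise FormatError(f"sidecar missing required key {key!r}")
    sig = np.loadtxt(path.with_suffix(".tsv"), delimiter="\t", skiprows=1, ndmin=2).T
    if sig.shape != (meta["n_channels"], meta["n_samples"]):
        raise FormatError(
            f"signal shape {sig.shape} does not match sidecar "
            f"({meta['n_channels']}, {meta['n_samples']})"
        )
    annotations = [(int(a[0]), int(a[1]), str(a[2]), int(a[3]))
                   for a in meta["annotations"]]
    return Recording(signal=sig, fs=float(meta["fs"]),
                     annotations=annotations, subject_id=meta["subject_id"])


def read_ninapro_mat(path, enabled: bool = False) -> Recording:
    """Stub interface for Ninapro-style MAT recordings (feature-flagged).

    Real-dataset ingestion is optional and intentionally not implemented
    here; pass ``enabled=True`` once an implementation is wired in.
    """
    if not enabled:
        raise NotImplementedError(
            "Ninapro MAT ingestion is a stub interface; generate synthetic "
            "recordings with generate_recording() or load the TSV+JSON format"
        )
    raise NotImplementedError("MAT layout reader not implemented")


# ---------------------------------------------------------------------------
# Planted feature matrices (small classification problems with known answers)
# ---------------------------------------------------------------------------

def planted_feature_matrix(
    n_classes: int = 6,
    n_per_class: int = 20,
    n_features: int = 8,
    informative: tuple = (0, 1),
    separation: float = 3.0,
    graded: bool = False,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Gaussian class-conditional features with planted structure.

    Two regimes:

    * ``graded=False`` -- only ``informative`` features carry signal: class
      means lie on a well separated 2-D grid (scaled by ``separation``) so the
      informative *pair* is jointly, but not individually, discriminative.
      Everything else is pure noise.  Used to test planted-subset recovery.
    * ``graded=True`` -- every feature carries signal of per-feature strength
      decaying from ``separation`` down to ``0.25*separation``, with random
      class-mean patterns, so accuracy grows as features are added.  Used to
      test the accuracy-vs-set-size trend.

    Returns ``(X, y, feature_names)`` with ``X`` shaped
    ``[n_classes*n_per_class, n_features]``.
    """
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    y = np.repeat(np.arange(n_classes), n_per_class)
    X = rng.normal(0.0, noise_sd, size=(n, n_features))
    if graded:
        strengths = np.linspace(1.0, 0.25, n_features) * separation
        means = rng.normal(size=(n_classes, n_features))
        means -= means.mean(axis=0)
        means /= np.maximum(means.std(axis=0), 1e-12)
        for j in range(n_features):
            X[:, j] += strengths[j] * means[y, j]
    else:
        # classes on a 2-column grid in the informative pair
        grid = np.array([(i // 2, i % 2) for i in range(n_classes)], dtype=float)
        grid -= grid.mean(axis=0)
        f0, f1 = informative
        X[:, f0] += separation * grid[y, 0]
        X[:, f1] += separation * grid[y, 1]
    names = [f"F{j}" for j in range(n_features)]
    return X, y, names
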