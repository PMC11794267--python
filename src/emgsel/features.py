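"""The sEMG window-feature catalog and feature-table assembly.

34 time-domain and 6 frequency-domain features commonly used in myoelectric
control, plus the plain mean absolute value (MAV), computed per window and
per channel.  The literature names these features but conventions vary; the
exact formula used for each is pinned below (``x`` a window of N samples,
``d`` the first difference, central moments ``m_k``, one-sided periodogram
``P(f)`` restricted to the 20-500 Hz analysis band):

==========  ==============================================================
IEMG/IAV    sum |x|
MAV         sum |x| / N
RMS         sqrt(sum x^2 / N)
VAR         sum (x - mean)^2 / (N - 1)        (sample variance)
WL          sum |d|
ZC          #{i : x_i * x_{i+1} < 0 and |x_i - x_{i+1}| >= eps_zc}
SSC         #{i : (x_i - x_{i-1}) (x_i - x_{i+1}) > eps_ssc}
MAD         sum |x - mean| / N
SSI         sum x^2
AE          SSI / N                           (average energy)
SKEW        m3 / m2^1.5                       (Fisher, biased moments)
MMAV1       weighted MAV, w = 1 in [0.25N, 0.75N], 0.5 outside
MMAV2       weighted MAV, w ramps 4i/N and 4(N-i)/N outside the middle half
TM3/TM5     |sum x^k / N|  for k = 3, 5
TM4         sum x^4 / N
STD         sqrt(VAR)
VO          (sum |x|^v / N)^(1/v),  v = 3
LD          exp(mean log(|x| + eps))          (log detector)
DAMV/AAC    sum |d| / (N - 1)
DASDV       sqrt(sum d^2 / (N - 1))
MFL         log10(sqrt(sum d^2))              (maximum fractal length)
LDAMV       ln(DAMV)
LCOV        ln(CV)
WAMP        #{|d| > theta},  theta = 0.1 * window SD
CV          STD / |mean|
HMOB        sqrt(var(d) / var(x))             (Hjorth mobility, population var)
ASS         |sum sqrt(|x|)|
APEN        approximate entropy, m = 2, r = 0.2 * SD, Chebyshev distance,
            self-matches included
CARD        # distinct values after quantizing to steps of 0.01 * SD
IQR         Q3 - Q1 (linear-interpolation quantiles)
KURT        m4 / m2^2 - 3                     (excess kurtosis)
ME          max x^2
PF          argmax_f P(f)
MP          mean_f P(f)
MNF         sum f P / sum P                   (mean frequency)
FR          sum_{20..split} P / sum_{split..500} P,  split = 250 Hz
TP          sum P
MMF         sum f A / sum A,  A = sqrt(P)     (modified mean frequency)
==========  ==============================================================

Logs and divisions are floored at ``log_eps`` so no feature ever returns
NaN/Inf; a constant window yields 0 for all difference- and crossing-based
features.  Several catalog entries are intentional duplicates (IAV = IEMG,
AAC = DAMV, STD = sqrt(VAR), AE = SSI/N): the catalog mirrors common usage,
and downstream redundancy analysis is expected to find them.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import SegmentSet

__all__ = [
    "CATALOG",
    "FeatureParams",
    "FeatureMatrix",
    "Scaler",
    "compute_feature",
    "extract_features",
    "zscore_fit",
    "zscore_apply",
]


class CatalogError(KeyError):
    pass


class InputError(ValueError):
    pass


# Table-1 order, plus MAV (appears throughout the ranked/selected sets).
CATALOG = (
    "IEMG", "RMS", "VAR", "WL", "ZC", "SSC", "MAD", "SSI", "AE", "SKEW",
    "MMAV1", "MMAV2", "TM3", "TM4", "TM5", "STD", "VO", "LD", "DAMV", "DASDV",
    "MFL", "LDAMV", "LCOV", "WAMP", "AAC", "CV", "HMOB", "ASS", "APEN", "CARD",
    "IQR", "IAV", "KURT", "ME", "PF", "MP", "MNF", "FR", "TP", "MMF", "MAV",
)

SPECTRAL = frozenset({"PF", "MP", "MNF", "FR", "TP", "MMF"})

# analysis band for all spectral features
_BAND_LOW, _BAND_HIGH = 20.0, 500.0


@dataclass
class FeatureParams:
    eps_zc: float = 0.0
    eps_ssc: float = 0.0
    theta_wamp_frac: float = 0.1     # threshold as fraction of window SD
    v_order: int = 3
    apen_m: int = 2
    apen_r_frac: float = 0.2         # tolerance as fraction of window SD
    card_tau: float = 0.01           # quantization step as fraction of window SD
    fr_split: float = 250.0
    log_eps: float = 1e-12

    def __post_init__(self):
        for name in ("eps_zc", "eps_ssc", "theta_wamp_frac", "apen_r_frac", "card_tau"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not _BAND_LOW < self.fr_split < _BAND_HIGH:
            raise InputError("fr_split must lie inside the 20-500 Hz band")


def _apen(x: np.ndarray, m: int, r: float) -> float:
    """Approximate entropy (Pincus), self-matches included."""
    N = len(x)
    if N <= m + 1:
        return 0.0

    def phi(mm: int) -> float:
        tpl = np.lib.stride_tricks.sliding_window_view(x, mm)
        dist = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
        c = np.mean(dist <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def _periodogram_band(x: np.ndarray, fs: float):
    f, p = sps.periodogram(x, fs=fs)
    mask = (f >= _BAND_LOW) & (f <= _BAND_HIGH)
    return f[mask], p[mask]


def _compute_all(window: np.ndarray, fs: float, names, params: FeatureParams) -> dict:
    """Compute the requested features for one window, sharing intermediates."""
    x = np.asarray(window, dtype=float)
    N = len(x)
    if N < 3:
        raise InputError(f"window length {N} < 3")
    eps = params.log_eps
    absx = np.abs(x)
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev ** 2)
    d = np.diff(x)
    sd = x.std()
    var_s = np.sum(dev ** 2) / (N - 1)
    std_s = np.sqrt(var_s)
    damv = np.sum(np.abs(d)) / (N - 1)
    sum_d2 = np.sum(d ** 2)
    cv = std_s / max(abs(mean), eps)
    out = {}
    need = set(names)
    f = p = None
    if need & SPECTRAL:
        f, p = _periodogram_band(x, fs)
    for name in names:
        if name in ("IEMG", "IAV"):
            v = np.sum(absx)
        elif name == "MAV":
            v = np.mean(absx)
        elif name == "RMS":
            v = np.sqrt(np.mean(x ** 2))
        elif name == "VAR":
            v = var_s
        elif name == "STD":
            v = std_s
        elif name == "WL":
            v = np.sum(np.abs(d))
        elif name == "ZC":
            v = np.count_nonzero((x[:-1] * x[1:] < 0)
                                 & (np.abs(x[:-1] - x[1:]) >= params.eps_zc))
        elif name == "SSC":
            v = np.count_nonzero((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > params.eps_ssc)
        elif name == "MAD":
            v = np.mean(np.abs(dev))
        elif name == "SSI":
            v = np.sum(x ** 2)
        elif name == "AE":
            v = np.mean(x ** 2)
        elif name == "SKEW":
            v = np.mean(dev ** 3) / max(m2, eps) ** 1.5
        elif name == "KURT":
            v = np.mean(dev ** 4) / max(m2, eps) ** 2 - 3.0
        elif name in ("MMAV1", "MMAV2"):
            i = np.arange(1, N + 1, dtype=float)
            if name == "MMAV1":
                w = np.where((i >= 0.25 * N) & (i <= 0.75 * N), 1.0, 0.5)
            else:
                w = np.ones(N)
                lo = i < 0.25 * N
                hi = i > 0.75 * N
                w[lo] = 4 * i[lo] / N
                w[hi] = 4 * (N - i[hi]) / N
            v = np.sum(w * absx) / N
        elif name == "TM3":
            v = abs(np.mean(x ** 3))
        elif name == "TM4":
            v = np.mean(x ** 4)
        elif name == "TM5":
            v = abs(np.mean(x ** 5))
        elif name == "VO":
            v = np.mean(absx ** params.v_order) ** (1.0 / params.v_order)
        elif name == "LD":
            v = np.exp(np.mean(np.log(absx + eps)))
        elif name in ("DAMV", "AAC"):
            v = damv
        elif name == "DASDV":
            v = np.sqrt(sum_d2 / (N - 1))
        elif name == "MFL":
            v = np.log10(max(np.sqrt(sum_d2), eps))
        elif name == "LDAMV":
            v = np.log(max(damv, eps))
        elif name == "LCOV":
            v = np.log(max(cv, eps))
        elif name == "WAMP":
            theta = params.theta_wamp_frac * sd
            v = np.count_nonzero(np.abs(d) > theta)
        elif name == "CV":
            v = cv
        elif name == "HMOB":
            v = np.sqrt(d.var() / max(x.var(), eps)) if x.var() > eps else 0.0
        elif name == "ASS":
            v = abs(np.sum(np.sqrt(absx)))
        elif name == "APEN":
            r = params.apen_r_frac * sd
            v = _apen(x, params.apen_m, r) if sd > 0 else 0.0
        elif name == "CARD":
            tau = params.card_tau * sd
            if tau <= 0:
                v = 1.0
            else:
                v = len(np.unique(np.round(x / tau)))
        elif name == "IQR":
            q1, q3 = np.percentile(x, [25, 75])
            v = q3 - q1
        elif name == "ME":
            v = np.max(x ** 2)
        elif name == "PF":
            v = f[int(np.argmax(p))]
        elif name == "MP":
            v = np.mean(p)
        elif name == "MNF":
            v = np.sum(f * p) / max(np.sum(p), eps)
        elif name == "FR":
            low = p[f <= params.fr_split].sum()
            high = p[f > params.fr_split].sum()
            v = low / max(high, eps)
        elif name == "TP":
            v = np.sum(p)
        elif name == "MMF":
            a = np.sqrt(p)
            v = np.sum(f * a) / max(np.sum(a), eps)
        else:
            raise CatalogError(f"unknown feature {name!r}")
        out[name] = float(v)
    return out


def compute_feature(name: str, window: np.ndarray, fs: float,
                    params: FeatureParams | None = None) -> float:
    """One catalog feature on one single-channel window."""
    if name not in CATALOG:
        raise CatalogError(f"unknown feature {name!r}")
    return _compute_all(window, fs, [name], params or FeatureParams())[name]


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Windows x (channel, feature) table with labels.

    Column order is channel-major: all features for channel 0, then channel 1,
    and so on, with features in catalog-subset order within each channel.
    """

    values: np.ndarray                  # [n_windows x (n_channels * n_features)]
    column_meta: list                   # (channel_id, feature_name) per column
    labels: np.ndarray
    feature_names: tuple
    n_channels: int
    subjects: np.ndarray | None = None  # optional subject id per row

    def columns_for(self, feature_names) -> np.ndarray:
        """Indices of all channels' columns for the given features."""
        wanted = set([feature_names] if isinstance(feature_names, str) else feature_names)
        return np.array([i for i, (_, f) in enumerate(self.column_meta) if f in wanted],
                        dtype=int)

    def subset(self, feature_names) -> "FeatureMatrix":
        names = tuple(f for f in self.feature_names if f in set(feature_names))
        idx = self.columns_for(names)
        return FeatureMatrix(
            values=self.values[:, idx],
            column_meta=[self.column_meta[i] for i in idx],
            labels=self.labels,
            feature_names=names,
            n_channels=self.n_channels,
            subjects=self.subjects,
        )

    def to_csv(self, path) -> None:
        cols = [f"ch{c}_{f}" for c, f in self.column_meta]
        df = pd.DataFrame(self.values, columns=cols)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        meta = []
        for col in df.columns:
            ch, feat = col.split("_", 1)
            meta.append((int(ch[2:]), feat))
        channels = sorted({c for c, _ in meta})
        names = tuple(dict.fromkeys(f for _, f in meta))
        return cls(values=df.to_numpy(float), column_meta=meta,
                   labels=labels, feature_names=names, n_channels=len(channels))


def extract_features(segs: SegmentSet, names=CATALOG,
                     params: FeatureParams | None = None) -> FeatureMatrix:
    """Assemble the per-window, per-channel feature table."""
    params = params or FeatureParams()
    names = tuple(names)
    for n in names:
        if n not in CATALOG:
            raise CatalogError(f"unknown feature {n!r}")
    if segs.n_windows == 0:
        raise InputError("empty SegmentSet")
    n_ch = segs.n_channels
    values = np.empty((segs.n_windows, n_ch * len(names)))
    meta = [(c, f) for c in range(n_ch) for f in names]
    for w in range(segs.n_windows):
        for c in range(n_ch):
            feats = _compute_all(segs.windows[w, c], segs.fs, names, params)
            base = c * len(names)
            for j, f in enumerate(names):
                values[w, base + j] = feats[f]
    subjects = np.asarray([s for s, _ in segs.provenance], dtype=object) \
        if segs.provenance else None
    return FeatureMatrix(values=values, column_meta=meta, labels=segs.labels,
                         feature_names=names, n_channels=n_ch, subjects=subjects)


# ---------------------------------------------------------------------------
# Column z-scoring (fit on training rows only)
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    means: np.ndarray
    sds: np.ndarray


def zscore_fit(X: np.ndarray, rows=None, log_eps: float = 1e-12) -> Scaler:
    """Column means/SDs from the given training rows (all rows if None)."""
    X = np.asarray(X, dtype=float)
    sub = X if rows is None else X[np.asarray(rows)]
    if sub.shape[0] == 0:
        raise InputError("no training rows to fit scaler on")
    means = sub.mean(axis=0)
    sds = sub.std(axis=0)
    n_const = int(np.sum(sds < log_eps))
    if n_const:
        warnings.warn(f"{n_const} constant column(s); scaled to zero")
    sds = np.maximum(sds, log_eps)
    return Scaler(means=means, sds=sds)


def zscore_apply(X: np.ndarray, scaler: Scaler) -> np.ndarray:
    return (np.asarray(X, dtype=float) - scaler.means) / scaler.sds
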