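"""Time- and frequency-domain window descriptors.

Each 3-second window yields 86 named features over the four channels
x, y, z and magnitude:

* time domain (42): per channel mean (M), standard deviation (SD),
  variance (V), maximum (Max), minimum (Min), range (R), number of peaks
  (NOP, strict local maxima above the window mean), skewness (SK) and
  kurtosis (KS); plus the Pearson correlation (CORR) of all six unordered
  channel pairs;
* frequency domain (28): per channel, from the Welch PSD: mean, maximum,
  SD, NOP (local PSD maxima above the PSD mean), average band power (ABP),
  normalized ABP (NABP) and the frequency of maximum PSD (Fmax);
* hand-tremor frequency range, HTFR (16): per channel mean, maximum, SD
  and ABP of the PSD restricted to 4-14 Hz — the band in which
  hypoglycemic hand tremor concentrates its power.

Numerical conventions (the field offers no single standard; these are
documented and fixed): variance/SD use the population (n) estimator;
kurtosis is excess kurtosis; ABP is the trapezoidal band integral divided
by the bandwidth; NABP is the band-integrated power as a fraction of total
integrated power; the general ABP/NABP band excludes the DC bin (the Welch
estimate is mean-detrended per segment, so DC carries no information).
Degenerate cases (constant channels, zero total power) emit 0 with a log
message rather than NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import Window

log = logging.getLogger(__name__)

CHANNELS = ("x", "y", "z", "mag")

TIME_STATS = ("mean", "sd", "var", "max", "min", "range", "nop", "skew", "kurt")
FREQ_STATS = ("psd_mean", "psd_max", "psd_sd", "psd_nop", "abp", "nabp", "fmax")
HTFR_STATS = ("htfr_mean", "htfr_max", "htfr_sd", "htfr_abp")

CORR_PAIRS = tuple(combinations(CHANNELS, 2))  # 6 unordered pairs


@dataclass(frozen=True)
class BandSpec:
    """Frequency band of interest; default is the 4-14 Hz tremor band."""

    low: float = 4.0
    high: float = 14.0

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError("need 0 <= low < high")


@dataclass(frozen=True)
class FeatureCatalog:
    """The ordered, named feature set; 86 features by construction."""

    band: BandSpec = BandSpec()

    @property
    def time_names(self) -> list[str]:
        names = [f"{ch}_{st}" for st in TIME_STATS for ch in CHANNELS]
        names += [f"corr_{a}_{b}" for a, b in CORR_PAIRS]
        return names

    @property
    def freq_names(self) -> list[str]:
        names = [f"{ch}_{st}" for st in FREQ_STATS for ch in CHANNELS]
        names += [f"{ch}_{st}" for st in HTFR_STATS for ch in CHANNELS]
        return names

    @property
    def names(self) -> list[str]:
        return self.time_names + self.freq_names

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self) -> str:
        import json
        return json.dumps({"band": [self.band.low, self.band.high],
                           "names": self.names})


DEFAULT_CATALOG = FeatureCatalog()

#: features dropped by the default impurity-guided selection: the whole
#: skewness, minimum, range, maximum, kurtosis and correlation families
#: (26 features), leaving 60.
DEFAULT_DROP: tuple[str, ...] = tuple(
    [f"{ch}_{st}" for st in ("skew", "min", "range", "max", "kurt")
     for ch in CHANNELS]
    + [f"corr_{a}_{b}" for a, b in CORR_PAIRS]
)


@dataclass
class PsdEstimate:
    """One-sided Welch PSD on a uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        if np.any(self.frequencies < 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be non-negative and ascending")


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def _count_peaks(x: np.ndarray) -> np.ndarray:
    """Strict local maxima above the signal mean, endpoints excluded.

    Vectorised over leading axes; the scan runs along the last axis.
    """
    if x.shape[-1] < 3:
        return np.zeros(x.shape[:-1], dtype=int)
    interior = x[..., 1:-1]
    mean = x.mean(axis=-1, keepdims=True)
    peaks = (interior > x[..., :-2]) & (interior > x[..., 2:]) & (interior > mean)
    return peaks.sum(axis=-1)


def _time_feature_arrays(samples: np.ndarray) -> dict[str, np.ndarray]:
    """Time-domain features for a batch, samples shape (k, n, 4)."""
    x = np.moveaxis(samples, 1, 2)  # (k, 4, n)
    out: dict[str, np.ndarray] = {}
    mean = x.mean(axis=-1)
    sd = x.std(axis=-1)           # population convention
    mx = x.max(axis=-1)
    mn = x.min(axis=-1)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant channels trigger scipy's precision-loss warning; their
        # moments are mapped to 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        sk = stats.skew(x, axis=-1)
        ku = stats.kurtosis(x, axis=-1)  # excess kurtosis
    stat_values = {
        "mean": mean, "sd": sd, "var": sd ** 2, "max": mx, "min": mn,
        "range": mx - mn, "nop": _count_peaks(x).astype(float),
        "skew": np.nan_to_num(sk), "kurt": np.nan_to_num(ku),
    }
    for st in TIME_STATS:
        for c, ch in enumerate(CHANNELS):
            out[f"{ch}_{st}"] = stat_values[st][:, c]

    centered = x - mean[..., None]
    for a, b in CORR_PAIRS:
        ia, ib = CHANNELS.index(a), CHANNELS.index(b)
        denom = sd[:, ia] * sd[:, ib]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (centered[:, ia] * centered[:, ib]).mean(axis=-1) / denom
        bad = ~np.isfinite(r)
        if bad.any():
            log.debug("constant channel: %d undefined correlation(s) set to 0",
                      int(bad.sum()))
        out[f"corr_{a}_{b}"] = np.where(bad, 0.0, r)
    return out


def time_features(window: Window) -> dict[str, float]:
    """The 42 time-domain features of one window, in catalog order."""
    arrs = _time_feature_arrays(window.samples[None])
    return {k: float(v[0]) for k, v in arrs.items()}


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def _welch(samples_1d_or_nd: np.ndarray, rate: float,
           nperseg: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD: 1-second Hann segments, 50% overlap, mean-detrended."""
    nperseg = nperseg or int(round(rate))
    if samples_1d_or_nd.shape[-1] < nperseg:
        raise ValueError("window shorter than the Welch segment length")
    return signal.welch(samples_1d_or_nd, fs=rate, window="hann",
                        nperseg=nperseg, noverlap=nperseg // 2,
                        detrend="constant", axis=-1)


def welch_psd(window: Window, channel: str = "mag",
              nperseg: int | None = None) -> PsdEstimate:
    """Welch PSD estimate of one channel of a window.

    With the defaults (64 Hz rate, 192-sample window) this averages three
    Hann-tapered 1-second segments at 50% overlap, for a 1 Hz grid.
    """
    f, p = _welch(window.channel(channel), window.rate, nperseg)
    return PsdEstimate(f, p, float(f[1] - f[0]) if f.size > 1 else 0.0)


def _band_integrals(f: np.ndarray, p: np.ndarray,
                    lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of the PSD over [lo, hi]; p shape (..., nf)."""
    mask = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    if mask.sum() < 2:
        return np.zeros(p.shape[:-1])
    return np.trapezoid(p[..., mask], f[mask], axis=-1)


def _freq_feature_arrays(f: np.ndarray, p: np.ndarray,
                         band: BandSpec) -> dict[str, np.ndarray]:
    """Frequency features for a batch; p shape (k, 4, nf)."""
    out: dict[str, np.ndarray] = {}
    total = np.trapezoid(p, f, axis=-1)
    lo_edge = f[1] if f.size > 1 else f[0]   # general band excludes DC
    band_full = _band_integrals(f, p, lo_edge, f[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        nabp = band_full / total
    bad = ~np.isfinite(nabp)
    if bad.any():
        log.debug("zero total power: %d NABP value(s) set to 0", int(bad.sum()))
    stat_values = {
        "psd_mean": p.mean(axis=-1),
        "psd_max": p.max(axis=-1),
        "psd_sd": p.std(axis=-1),
        "psd_nop": _count_peaks(p).astype(float),
        "abp": band_full / max(f[-1] - lo_edge, 1e-12),
        "nabp": np.where(bad, 0.0, nabp),
        "fmax": f[np.argmax(p, axis=-1)],
    }
    for st in FREQ_STATS:
        for c, ch in enumerate(CHANNELS):
            out[f"{ch}_{st}"] = stat_values[st][:, c]

    hmask = (f >= band.low - 1e-9) & (f <= band.high + 1e-9)
    ph = p[..., hmask]
    htfr_values = {
        "htfr_mean": ph.mean(axis=-1),
        "htfr_max": ph.max(axis=-1),
        "htfr_sd": ph.std(axis=-1),
        "htfr_abp": _band_integrals(f, p, band.low, band.high)
                    / max(band.high - band.low, 1e-12),
    }
    for st in HTFR_STATS:
        for c, ch in enumerate(CHANNELS):
            out[f"{ch}_{st}"] = htfr_values[st][:, c]
    return out


def freq_features(psds: dict[str, PsdEstimate] | list[PsdEstimate],
                  band: BandSpec | None = None) -> dict[str, float]:
    """The 44 frequency-domain features from the four per-channel PSDs."""
    band = band or BandSpec()
    if isinstance(psds, dict):
        psds = [psds[ch] for ch in CHANNELS]
    f = psds[0].frequencies
    p = np.stack([e.power for e in psds])[None]  # (1, 4, nf)
    arrs = _freq_feature_arrays(f, p, band)
    return {k: float(v[0]) for k, v in arrs.items()}


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract(window: Window, catalog: FeatureCatalog | None = None) -> pd.Series:
    """All 86 features of one window, as a named series in catalog order."""
    catalog = catalog or DEFAULT_CATALOG
    return extract_matrix(window.samples[None], window.rate, catalog).iloc[0]


def extract_matrix(samples: np.ndarray, rate: float,
                   catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Feature matrix for a batch of windows, samples shape (k, n, 4)."""
    catalog = catalog or DEFAULT_CATALOG
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[2] != len(CHANNELS):
        raise ValueError("samples must have shape (k, n_samples, 4)")
    arrs = _time_feature_arrays(samples)
    f, p = _welch(np.moveaxis(samples, 1, 2), rate)
    arrs.update(_freq_feature_arrays(f, p, catalog.band))
    df = pd.DataFrame({name: arrs[name] for name in catalog.names})
    return df


def select_features(vectors: pd.DataFrame | pd.Series,
                    drop: tuple[str, ...] | list[str] | None = None):
    """Drop a named feature subset, preserving order.

    The default drop list removes the 26 features found least informative
    by impurity-based ranking (skewness, minimum, range, maximum, kurtosis
    and all correlations), leaving 60.  Unknown names raise ``KeyError``.
    """
    drop = DEFAULT_DROP if drop is None else tuple(drop)
    have = set(vectors.columns) if isinstance(vectors, pd.DataFrame) else set(vectors.index)
    unknown = [d for d in drop if d not in have]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    if isinstance(vectors, pd.DataFrame):
        return vectors.drop(columns=list(drop))
    return vectors.drop(index=list(drop))
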