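"""Time-frequency statistical (TF-ST) feature extraction.

Every dynamic channel is summarised by a fixed catalogue of descriptors
drawn from five groups:

* basic statistics (14): max, min, quartiles, percentiles and ranges,
  centre and dispersion measures;
* distribution (15): kurtosis, skewness, a 10-bin histogram, and the 20th
  and 80th value percentiles of the empirical distribution plus the ECDF
  slope between them;
* temporal (27): lag-1 autocorrelation, summary statistics of peak and
  valley values, extremum and direction-change counts, peak-to-peak range,
  signal path length, trapezoidal area under the curve, histogram entropy
  and multiscale sample entropy, zero crossings;
* differenced signal (6): median, mean and sum of the first difference and
  of its absolute value;
* spectral (262): a fixed-length FFT mean-coefficient vector (FMC) from a
  short-time spectrogram, spectral distance, fundamental and centroid
  frequency, the frequency of the maximum spectral peak, the 95%-power
  maximum frequency, and the maximum power value;
* wavelet & cepstral (49): per-scale absolute mean / variance / standard
  deviation / energy of a Mexican-hat continuous wavelet transform at
  integer scales 1..9, one overall wavelet entropy, and 12 MFCCs.

The layout (names and count) is a function of the configuration only,
never of the signal content, and every value is finite for finite input:
degenerate signals (constant, no peaks, zero variance) map to 0 by
convention so feature tables stay rectangular.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pywt
import scipy.fft
import scipy.signal
import scipy.stats

from ._fast import sample_entropy
from .dynamics import ChannelSet

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureTable",
    "extract_basic_stats",
    "extract_distribution",
    "extract_temporal",
    "extract_difference",
    "extract_spectral",
    "extract_wavelet_mfcc",
    "extract_channel",
    "extract_all",
    "feature_catalogue",
    "COMMON_FEATURES",
]

#: the widely used baseline feature set of the ablation comparison
COMMON_FEATURES = (
    "mean", "median", "max", "min", "standard_deviation",
    "quartile_1", "quartile_3", "interquartile_range",
    "percentile_1", "percentile_99", "percentile_range",
    "number_of_peaks", "number_of_valleys",
    "number_of_changes", "relative_number_of_changes",
)


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Catalogue configuration (fixed layout).

    n_fmc:
        Length of the FFT mean-coefficient vector.
    n_histogram:
        Histogram bin count (bins span [min, max] of the signal).
    wavelet_scales:
        Integer scales of the Mexican-hat CWT.
    n_mfcc / n_mel_filters / mfcc_frame:
        MFCC settings; the frame length is capped at the signal length.
    mse_scales:
        Coarse-graining scales of the multiscale sample entropy (m=2,
        tolerance 0.2 * signal standard deviation).
    """

    n_fmc: int = 256
    n_histogram: int = 10
    wavelet_scales: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    n_mfcc: int = 12
    n_mel_filters: int = 40
    mfcc_frame: int = 256
    mse_scales: tuple[int, ...] = (1, 2, 3)


DEFAULT_CONFIG = FeatureConfig()

_PEAK_STATS = ("mean", "median", "quartile_1", "quartile_3",
               "percentile_5", "percentile_95")


def _check_signal(signal: np.ndarray, min_len: int = 1) -> np.ndarray:
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or len(s) < min_len:
        raise ValueError(f"need a 1-D signal of length >= {min_len}")
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    return s


def extract_basic_stats(signal: np.ndarray) -> dict[str, float]:
    """The 14 essential statistics of a signal."""
    s = _check_signal(signal)
    q1, q3, p1, p99, med = np.percentile(s, [25, 75, 1, 99, 50])
    mean = float(s.mean())
    return {
        "max": float(s.max()),
        "min": float(s.min()),
        "quartile_1": float(q1),
        "quartile_3": float(q3),
        "interquartile_range": float(q3 - q1),
        "percentile_1": float(p1),
        "percentile_99": float(p99),
        "percentile_range": float(p99 - p1),
        "median": float(med),
        "mean": mean,
        "standard_deviation": float(s.std()),
        "variance": float(s.var()),
        "mean_absolute_deviation": float(np.mean(np.abs(s - mean))),
        "median_absolute_deviation": float(np.median(np.abs(s - med))),
    }


def extract_distribution(
    signal: np.ndarray, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Shape descriptors: kurtosis, skewness, histogram, ECDF anchors."""
    s = _check_signal(signal)
    out: dict[str, float] = {}
    if s.std() == 0:
        out["kurtosis"] = 0.0
        out["skewness"] = 0.0
    else:
        # nearly-constant data can make these non-finite; map to 0 so the
        # feature table stays rectangular
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kur = float(scipy.stats.kurtosis(s))
            skw = float(scipy.stats.skew(s))
        out["kurtosis"] = kur if np.isfinite(kur) else 0.0
        out["skewness"] = skw if np.isfinite(skw) else 0.0
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        hi = lo + 1.0  # constant signal: all mass lands in one bin
    counts, _ = np.histogram(s, bins=config.n_histogram, range=(lo, hi))
    for k, c in enumerate(counts):
        out[f"histogram_{k}"] = float(c)
    p20, p80 = np.percentile(s, [20, 80])
    out["ecdf_percentile_20"] = float(p20)
    out["ecdf_percentile_80"] = float(p80)
    gap = p80 - p20
    out["ecdf_slope"] = float(0.6 / gap) if gap > 0 else 0.0
    return out


def _strict_peaks(s: np.ndarray) -> np.ndarray:
    """Indices of strict 3-point local maxima (plateaus excluded)."""
    if len(s) < 3:
        return np.empty(0, dtype=int)
    core = (s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])
    return np.flatnonzero(core) + 1


def _extremum_stats(values: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    if len(values) == 0:
        for stat in _PEAK_STATS:
            out[f"{prefix}_values_{stat}"] = 0.0
        return out
    q1, q3, p5, p95, med = np.percentile(values, [25, 75, 5, 95, 50])
    out[f"{prefix}_values_mean"] = float(values.mean())
    out[f"{prefix}_values_median"] = float(med)
    out[f"{prefix}_values_quartile_1"] = float(q1)
    out[f"{prefix}_values_quartile_3"] = float(q3)
    out[f"{prefix}_values_percentile_5"] = float(p5)
    out[f"{prefix}_values_percentile_95"] = float(p95)
    return out


def _direction_changes(s: np.ndarray) -> int:
    d = np.diff(s)
    signs = np.sign(d)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def extract_temporal(
    signal: np.ndarray,
    t: np.ndarray | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Temporal-domain descriptors; ``t`` is the time axis for the AUC."""
    s = _check_signal(signal)
    n = len(s)
    if t is None:
        t = np.arange(n, dtype=float)
    out: dict[str, float] = {}
    if n > 1 and s[:-1].std() > 0 and s[1:].std() > 0:
        out["autocorrelation"] = float(np.corrcoef(s[:-1], s[1:])[0, 1])
    else:
        out["autocorrelation"] = 0.0
    peaks = _strict_peaks(s)
    valleys = _strict_peaks(-s)
    out.update(_extremum_stats(s[peaks], "peaks"))
    out.update(_extremum_stats(s[valleys], "valleys"))
    out["number_of_peaks"] = float(len(peaks))
    out["number_of_valleys"] = float(len(valleys))
    out["peak_to_peak_value"] = float(s.max() - s.min())
    ds = np.diff(s)
    out["signal_distance"] = float(np.sum(np.sqrt(1.0 + ds**2)))
    out["area_under_curve"] = float(np.trapezoid(np.abs(s), t))
    # Shannon entropy of the normalised histogram
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        hi = lo + 1.0
    counts, _ = np.histogram(s, bins=config.n_histogram, range=(lo, hi))
    p = counts[counts > 0] / n
    out["entropy"] = float(-np.sum(p * np.log(p)))
    r = 0.2 * float(s.std())
    for scale in config.mse_scales:
        if r <= 0:
            out[f"multiscale_entropy_{scale}"] = 0.0
            continue
        m = n // scale
        coarse = s[: m * scale].reshape(m, scale).mean(axis=1) if m else s[:0]
        out[f"multiscale_entropy_{scale}"] = float(sample_entropy(coarse, 2, r))
    sb = np.signbit(s)
    out["zero_crossing_rate"] = float(np.sum(sb[1:] != sb[:-1]))
    out["number_of_maximums"] = float(len(peaks))
    out["number_of_minimums"] = float(len(valleys))
    ndc = _direction_changes(s)
    out["number_of_changes"] = float(ndc)
    out["relative_number_of_changes"] = float(ndc) / n
    return out


def extract_difference(signal: np.ndarray) -> dict[str, float]:
    """Median, mean and sum of the differenced signal and its absolute value."""
    s = _check_signal(signal)
    if len(s) < 2:
        return {k: 0.0 for k in ("diff_median", "diff_mean", "diff_sum",
                                 "abs_diff_median", "abs_diff_mean",
                                 "sum_absolute_diff")}
    d = np.diff(s)
    ad = np.abs(d)
    return {
        "diff_median": float(np.median(d)),
        "diff_mean": float(d.mean()),
        "diff_sum": float(d.sum()),
        "abs_diff_median": float(np.median(ad)),
        "abs_diff_mean": float(ad.mean()),
        "sum_absolute_diff": float(ad.sum()),
    }


def extract_spectral(
    signal: np.ndarray,
    fs: float,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Frequency-domain descriptors from the FFT and a short-time spectrogram."""
    s = _check_signal(signal, min_len=8)
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = len(s)
    out: dict[str, float] = {}
    # FMC: time-mean of the short-time power spectrogram, resampled onto a
    # fixed number of bins so the layout is independent of signal length.
    nperseg = min(n, 256)
    f_spec, _, sxx = scipy.signal.spectrogram(s, fs=fs, nperseg=nperseg,
                                              noverlap=nperseg // 2)
    mean_coef = sxx.mean(axis=1)
    src = np.linspace(0.0, 1.0, len(mean_coef))
    dst = np.linspace(0.0, 1.0, config.n_fmc)
    fmc = np.interp(dst, src, mean_coef)
    for k in range(config.n_fmc):
        out[f"FMC_{k}"] = float(fmc[k])
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(s))
    power = mag**2
    # spectral distance: cumulative magnitude spectrum vs its straight line
    cum = np.cumsum(mag)
    line = np.linspace(0.0, cum[-1], len(cum))
    out["spectral_distance"] = float(np.sum(line - cum))
    floor = 1e-4 * mag[1:].max() if len(mag) > 1 else 0.0
    peak_idx, _ = scipy.signal.find_peaks(mag[1:], height=floor)
    out["fundamental_frequency"] = (
        float(freqs[1:][peak_idx[0]]) if len(peak_idx) else 0.0
    )
    out["maximum_peak_frequency"] = (
        float(freqs[1:][np.argmax(power[1:])]) if power[1:].max() > 0 else 0.0
    )
    ptot = power.sum()
    out["spectral_centroid"] = float((freqs * power).sum() / ptot) if ptot > 0 else 0.0
    if ptot > 0:
        cumpow = np.cumsum(power)
        out["maximum_frequency"] = float(freqs[np.searchsorted(cumpow, 0.95 * ptot)])
    else:
        out["maximum_frequency"] = 0.0
    out["maximum_power_spectrum"] = float(power[1:].max()) if len(power) > 1 else 0.0
    return out


def _mel_filterbank(n_filters: int, n_fft: int, fs: float) -> np.ndarray:
    def mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def invmel(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    points = invmel(np.linspace(mel(0.0), mel(fs / 2.0), n_filters + 2))
    bins = np.floor((n_fft + 1) * points / fs).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        for j in range(a, b):
            if b > a:
                fb[i, j] = (j - a) / (b - a)
        for j in range(b, c):
            if c > b:
                fb[i, j] = (c - j) / (c - b)
    return fb


def _mfcc(s: np.ndarray, fs: float, config: FeatureConfig) -> np.ndarray:
    frame = min(len(s), config.mfcc_frame)
    hop = max(frame // 2, 1)
    starts = range(0, len(s) - frame + 1, hop)
    win = np.hamming(frame)
    fb = _mel_filterbank(config.n_mel_filters, frame, fs)
    coeffs = np.zeros(config.n_mfcc)
    count = 0
    for st in starts:
        seg = s[st:st + frame] * win
        pow_spec = np.abs(np.fft.rfft(seg)) ** 2 / frame
        energies = fb @ pow_spec
        logE = np.log(energies + 1e-12)
        c = scipy.fft.dct(logE, type=2, norm="ortho")[: config.n_mfcc]
        coeffs += c
        count += 1
    return coeffs / max(count, 1)


def extract_wavelet_mfcc(
    signal: np.ndarray,
    fs: float,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Mexican-hat CWT descriptors per scale, wavelet entropy, and MFCCs."""
    s = _check_signal(signal, min_len=16)
    coef, _ = pywt.cwt(s, np.asarray(config.wavelet_scales, dtype=float), "mexh")
    out: dict[str, float] = {}
    energies = []
    for k, row in enumerate(coef):
        e = float(np.mean(row**2))
        out[f"WAM_{k}"] = float(np.mean(np.abs(row)))
        out[f"wavelet_variance_{k}"] = float(row.var())
        out[f"wavelet_standard_deviation_{k}"] = float(row.std())
        out[f"wavelet_energy_{k}"] = e
        energies.append(e)
    energies = np.asarray(energies)
    etot = energies.sum()
    if etot > 0:
        p = energies[energies > 0] / etot
        out["wavelet_entropy"] = float(-np.sum(p * np.log(p)))
    else:
        out["wavelet_entropy"] = 0.0
    mfcc = _mfcc(s, fs, config)
    for k in range(config.n_mfcc):
        out[f"MFCC_{k}"] = float(mfcc[k])
    return out


def extract_channel(
    signal: np.ndarray,
    fs: float,
    t: np.ndarray | None = None,
    feature_set: str = "tfst",
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """All features of one channel, as an ordered name -> value mapping."""
    if feature_set == "common":
        basic = extract_basic_stats(signal)
        temporal = extract_temporal(signal, t, config)
        return {name: (basic[name] if name in basic else temporal[name])
                for name in COMMON_FEATURES}
    if feature_set != "tfst":
        raise ValueError(f"unknown feature set {feature_set!r}")
    out = extract_basic_stats(signal)
    out.update(extract_distribution(signal, config))
    out.update(extract_temporal(signal, t, config))
    out.update(extract_difference(signal))
    out.update(extract_spectral(signal, fs, config))
    out.update(extract_wavelet_mfcc(signal, fs, config))
    return out


@dataclasses.dataclass
class FeatureVector:
    """Flat, ordered feature layout for one recording.

    ``names`` are ``<channel>__<feature>``; ``families`` tags each entry
    with its channel's family.
    """

    names: list[str]
    channels: list[str]
    families: list[str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def extract_all(
    channels: ChannelSet,
    fs: float | None = None,
    feature_set: str = "tfst",
    config: FeatureConfig = DEFAULT_CONFIG,
    t: np.ndarray | None = None,
) -> FeatureVector:
    """Extract the configured catalogue from every channel of a recording."""
    fs = channels.fs if fs is None else fs
    if t is None:
        t = np.arange(len(channels)) / fs
    names: list[str] = []
    chans: list[str] = []
    fams: list[str] = []
    values: list[float] = []
    for cname, sig in channels.signals.items():
        feats = extract_channel(sig, fs, t, feature_set, config)
        for fname, v in feats.items():
            names.append(f"{cname}__{fname}")
            chans.append(cname)
            fams.append(channels.families[cname])
            values.append(v)
    vec = FeatureVector(names, chans, fams, np.asarray(values))
    if not np.all(np.isfinite(vec.values)):
        bad = [n for n, v in zip(names, vec.values) if not np.isfinite(v)]
        raise AssertionError(f"non-finite features produced: {bad[:5]}")
    return vec


def feature_catalogue(
    feature_set: str = "tfst", config: FeatureConfig = DEFAULT_CONFIG
) -> list[tuple[str, str]]:
    """(feature name, group) pairs of the per-channel catalogue."""
    probe = np.sin(np.linspace(0.0, 20.0, 64)) + 0.1
    groups = {
        "basic": extract_basic_stats(probe),
        "distribution": extract_distribution(probe, config),
        "temporal": extract_temporal(probe, None, config),
        "difference": extract_difference(probe),
        "spectral": extract_spectral(probe, 200.0, config),
        "wavelet_mfcc": extract_wavelet_mfcc(probe, 200.0, config),
    }
    if feature_set == "common":
        return [(n, "common") for n in COMMON_FEATURES]
    return [(name, group) for group, feats in groups.items() for name in feats]


@dataclasses.dataclass
class FeatureTable:
    """Rectangular per-recording feature matrix with labels and family tags."""

    data: pd.DataFrame  # rows: recordings, columns: feature names
    families: dict[str, str]  # feature name -> family tag
    labels: pd.Series  # row label per recording (may hold None)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels index must match table index")

    @classmethod
    def from_vectors(
        cls,
        vectors: dict[str, FeatureVector],
        labels: dict[str, str | None] | None = None,
    ) -> "FeatureTable":
        first = next(iter(vectors.values()))
        families = dict(zip(first.names, first.families))
        rows = {}
        for rid, vec in vectors.items():
            if vec.names != first.names:
                raise ValueError("inconsistent feature layout across recordings")
            rows[rid] = vec.values
        df = pd.DataFrame.from_dict(rows, orient="index", columns=first.names)
        lab = pd.Series(
            {rid: (labels or {}).get(rid) for rid in df.index}, index=df.index
        )
        return cls(df, families, lab)

    def without_family(self, family: str) -> "FeatureTable":
        """Drop one family's columns (e.g. the moment-ablation table)."""
        keep = [c for c in self.data.columns if self.families[c] != family]
        return FeatureTable(self.data[keep],
                            {c: self.families[c] for c in keep},
                            self.labels)

    def family_columns(self, family: str) -> list[str]:
        return [c for c in self.data.columns if self.families[c] == family]

    @property
    def family_tags(self) -> list[str]:
        seen: list[str] = []
        for c in self.data.columns:
            f = self.families[c]
            if f not in seen:
                seen.append(f)
        return seen
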