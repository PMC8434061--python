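"""Per-window time- and frequency-domain feature extraction.

Each window slice of each behavior signal yields 14 time-domain values
(10 scalar statistics plus 4 Burg autoregression coefficients) and 16
frequency-domain values (13 scalar statistics on the magnitude spectrum plus
3 band energies), i.e. 30 per channel; the default two channels (head pitch
and lip aperture) give a 60-dimensional feature vector.

Conventions, fixed so the vector is a pure function of the spec:

* standard deviation, skewness and kurtosis use population (1/N) moments;
* entropy is computed on the normalized absolute signal,
  ``sum(c * ln(c))`` with ``c_i = |s_i| / sum|s|`` and ``0 * ln 0 = 0``
  (values are therefore <= 0);
* quartiles interpolate linearly between order statistics at ``p * (N - 1)``;
* the spectrum is the magnitude of the DFT of the mean-subtracted slice,
  bins 1..width/2 (DC excluded, Nyquist included) so spectral features
  describe oscillation rate rather than offset;
* degenerate inputs (constant slices, all-zero spectra) return 0 for the
  moment ratios, AR coefficients and weighted averages instead of raising,
  so silent stretches of a meeting do not abort extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windowing import WindowSample

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "time_features",
    "freq_features",
    "burg_ar",
    "spectrum",
    "cross_features",
    "feature_vector",
    "feature_names",
    "feature_fields",
    "extract_features",
    "default_bands",
    "METADATA_COLUMNS",
]

#: Metadata columns preceding the features in an extracted table.
METADATA_COLUMNS = ("participant", "start", "end", "label")


def default_bands(n_bins: int) -> tuple[tuple[int, int], ...]:
    """Three contiguous 1-based bands covering ``1..n_bins``.

    Bins split as evenly as possible with remainder bins assigned to the
    trailing bands; 16 bins give (1,5), (6,10), (11,16).
    """
    if n_bins < 3:
        raise ValueError("need at least 3 spectral bins for 3 bands")
    base, rem = divmod(n_bins, 3)
    sizes = [base + (1 if i >= 3 - rem else 0) for i in range(3)]
    bands, lo = [], 1
    for size in sizes:
        bands.append((lo, lo + size - 1))
        lo += size
    return tuple(bands)


@dataclass(frozen=True)
class FeatureSpec:
    """Recipe turning a window into a fixed-length feature vector.

    Attributes
    ----------
    channels
        Ordered signal names; each contributes 14 + 16 values.
    ar_order
        Burg autoregression order (must be < window width).
    exclude_dc
        Drop the DC bin from the magnitude spectrum (default True).
    bands
        1-based inclusive spectral band ranges for the band-energy features;
        ``None`` derives three near-equal bands from the bin count.
    angle_ref
        Reference vector for the (cross-signal) angle feature.
    sample_rate
        Frames per second; divides the spectral power sum in the PSD feature.
    """

    channels: tuple[str, ...] = ("pose_Rx", "lip_62_66")
    ar_order: int = 4
    exclude_dc: bool = True
    bands: tuple[tuple[int, int], ...] | None = None
    angle_ref: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sample_rate: float = 29.97

    def __post_init__(self) -> None:
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.bands is not None:
            for a, b in self.bands:
                if not (1 <= a <= b):
                    raise ValueError(f"invalid band ({a}, {b}): need 1 <= a <= b")

    def bands_for(self, n_bins: int) -> tuple[tuple[int, int], ...]:
        bands = self.bands if self.bands is not None else default_bands(n_bins)
        for a, b in bands:
            if b > n_bins:
                raise ValueError(
                    f"band ({a}, {b}) exceeds the {n_bins} available spectral bins"
                )
        return bands

    def n_features(self, width: int) -> int:
        return len(feature_names(self, width))


@dataclass
class FeatureVector:
    """Ordered (name, value) pairs for one window."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values must have equal length")


# ---------------------------------------------------------------------------
# scalar statistics shared by both domains
# ---------------------------------------------------------------------------

def _std(s: np.ndarray) -> float:
    return float(np.sqrt(np.mean((s - s.mean()) ** 2)))


def _mad(s: np.ndarray) -> float:
    return float(np.median(np.abs(s - np.median(s))))


def _energy(s: np.ndarray) -> float:
    return float(np.mean(s ** 2))


def _entropy(s: np.ndarray) -> float:
    a = np.abs(s)
    total = a.sum()
    if total == 0:
        return 0.0
    c = a / total
    nz = c > 0
    return float(np.sum(c[nz] * np.log(c[nz])))


def _iqr(s: np.ndarray) -> float:
    q1, q3 = np.percentile(s, [25, 75])  # linear interpolation at p*(N-1)
    return float(q3 - q1)


def _scalar_stats(s: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(s.mean()),
        "std": _std(s),
        "mad": _mad(s),
        "max": float(s.max()),
        "min": float(s.min()),
        "energy": _energy(s),
        "entropy": _entropy(s),
        "iqr": _iqr(s),
    }


# ---------------------------------------------------------------------------
# Burg autoregression
# ---------------------------------------------------------------------------

def burg_ar(s: np.ndarray, order: int = 4) -> np.ndarray:
    """Burg-method AR coefficients of the prediction polynomial.

    Returns ``a_1..a_order`` with ``a_0 = 1`` implied, i.e. the model
    ``s_t + a_1 s_{t-1} + ... + a_p s_{t-p} = e_t``.  The lattice recursion
    minimizes the summed forward and backward prediction error; the input is
    not demeaned.  A constant slice returns all zeros (documented degenerate
    case).
    """
    x = np.asarray(s, dtype=float)
    n = x.shape[0]
    if n <= order:
        raise ValueError(f"need more than {order} samples for order-{order} Burg AR")
    coeffs = np.zeros(order)
    if np.ptp(x) == 0:
        return coeffs
    f = x[1:].copy()   # forward prediction error
    b = x[:-1].copy()  # backward prediction error
    a = np.array([1.0])
    for _ in range(order):
        denom = f @ f + b @ b
        if denom == 0:
            break
        k = -2.0 * (f @ b) / denom
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    coeffs[: a.shape[0] - 1] = a[1:]
    return coeffs


def time_features(s: np.ndarray, ar_order: int = 4) -> dict[str, float]:
    """The 14 time-domain values of one window slice.

    Ten scalar statistics (mean, std, mad, max, min, energy, entropy, iqr,
    range, rms) followed by ``ar_order`` Burg coefficients.
    """
    s = np.asarray(s, dtype=float)
    if s.shape[0] < ar_order + 1:
        raise ValueError(
            f"slice of length {s.shape[0]} too short for ar_order={ar_order}"
        )
    out = _scalar_stats(s)
    out["range"] = float(s.max() - s.min())
    out["rms"] = float(np.sqrt(np.mean(s ** 2)))
    for i, coef in enumerate(burg_ar(s, ar_order), start=1):
        out[f"arcoeff{i}"] = float(coef)
    return out


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def spectrum(s: np.ndarray, exclude_dc: bool = True) -> np.ndarray:
    """Magnitude spectrum of the mean-subtracted slice.

    For a slice of even length ``W`` returns bins ``1..W/2`` (16 bins for the
    default 32-frame window); a constant slice maps to all-zero bins.
    """
    s = np.asarray(s, dtype=float)
    mags = np.abs(np.fft.rfft(s - s.mean()))
    return mags[1:] if exclude_dc else mags


def freq_features(
    bins: np.ndarray,
    bands: tuple[tuple[int, int], ...],
    sample_rate: float,
) -> dict[str, float]:
    """The 16 frequency-domain values computed from magnitude bins.

    Eight shared scalar statistics, population skewness and kurtosis,
    the 1-based index of the largest bin (lowest on ties), the
    frequency-weighted average ``sum(i * s_i) / sum(s_j)``, one mean squared
    magnitude per band, and the power sum divided by the sampling rate.
    """
    s = np.asarray(bins, dtype=float)
    out = _scalar_stats(s)
    m = s.mean()
    var = np.mean((s - m) ** 2)
    if var == 0:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["skewness"] = float(np.mean(((s - m) / np.sqrt(var)) ** 3))
        out["kurtosis"] = float(np.mean((s - m) ** 4) / var ** 2)
    out["maxfreqind"] = float(np.argmax(s) + 1)
    total = s.sum()
    idx = np.arange(1, s.shape[0] + 1)
    out["meanfreq"] = float((idx * s).sum() / total) if total != 0 else 0.0
    for a, b in bands:
        if not (1 <= a <= b <= s.shape[0]):
            raise ValueError(f"band ({a}, {b}) out of range for {s.shape[0]} bins")
        out[f"energyband_{a}_{b}"] = float(np.sum(s[a - 1 : b] ** 2) / (b - a + 1))
    out["psd"] = float(np.sum(s ** 2) / sample_rate)
    return out


# ---------------------------------------------------------------------------
# cross-signal functions (not part of the default vector)
# ---------------------------------------------------------------------------

def cross_features(
    s1: np.ndarray,
    s2: np.ndarray,
    s3: np.ndarray,
    v: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> dict[str, float]:
    """Signal magnitude area, Pearson correlation of (s1, s2), and the angle
    between the per-signal mean vector and a reference vector.

    These need a signal triple and are excluded from the default per-channel
    vector; they are provided for multi-signal configurations.
    """
    s1, s2, s3 = (np.asarray(s, dtype=float) for s in (s1, s2, s3))
    if not (s1.shape == s2.shape == s3.shape):
        raise ValueError("cross_features requires equal-length slices")
    sma = float((np.abs(s1).sum() + np.abs(s2).sum() + np.abs(s3).sum()) / 3.0)
    d1, d2 = s1 - s1.mean(), s2 - s2.mean()
    denom = np.sqrt((d1 @ d1) * (d2 @ d2))
    corr = float((d1 @ d2) / denom) if denom > 0 else 0.0
    m = np.array([s1.mean(), s2.mean(), s3.mean()])
    vv = np.asarray(v, dtype=float)
    angle = float(np.arctan2(np.linalg.norm(np.cross(m, vv)), m @ vv))
    return {"sma": sma, "correlation": corr, "angle": angle}


# ---------------------------------------------------------------------------
# vector assembly
# ---------------------------------------------------------------------------

_TIME_ORDER = ("mean", "std", "mad", "max", "min", "energy", "entropy", "iqr",
               "range", "rms")
_FREQ_ORDER = ("mean", "std", "mad", "max", "min", "energy", "entropy", "iqr",
               "skewness", "kurtosis", "maxfreqind", "meanfreq")


def _channel_keys(spec: FeatureSpec, width: int) -> tuple[list[str], list[str]]:
    time_keys = list(_TIME_ORDER) + [f"arcoeff{i}" for i in range(1, spec.ar_order + 1)]
    n_bins = width // 2 if spec.exclude_dc else width // 2 + 1
    freq_keys = list(_FREQ_ORDER) + [
        f"energyband_{a}_{b}" for a, b in spec.bands_for(n_bins)
    ] + ["psd"]
    return time_keys, freq_keys


def feature_fields(spec: FeatureSpec, width: int) -> list[tuple[str, str, str]]:
    """Ordered (function, component, domain) triples for the full vector."""
    time_keys, freq_keys = _channel_keys(spec, width)
    fields = []
    for ch in spec.channels:
        fields += [(k, ch, "time") for k in time_keys]
        fields += [(k, ch, "freq") for k in freq_keys]
    return fields


def feature_names(spec: FeatureSpec, width: int) -> tuple[str, ...]:
    """Stable ``function_channel_domain`` identifiers for the full vector."""
    return tuple(f"{fn}_{ch}_{dom}" for fn, ch, dom in feature_fields(spec, width))


def feature_vector(w: WindowSample, spec: FeatureSpec) -> FeatureVector:
    """Assemble the per-window feature vector (60 values for the defaults)."""
    width = w.end - w.start
    names = feature_names(spec, width)
    values = []
    for ch in spec.channels:
        if ch not in w.channels:
            raise KeyError(f"window is missing channel {ch!r}")
        s = w.channels[ch]
        tf = time_features(s, spec.ar_order)
        n_bins = width // 2 if spec.exclude_dc else width // 2 + 1
        ff = freq_features(
            spectrum(s, spec.exclude_dc), spec.bands_for(n_bins), spec.sample_rate
        )
        time_keys, freq_keys = _channel_keys(spec, width)
        values += [tf[k] for k in time_keys]
        values += [ff[k] for k in freq_keys]
    return FeatureVector(names=names, values=np.array(values))


def extract_features(samples: list[WindowSample], spec: FeatureSpec) -> pd.DataFrame:
    """One row per window: participant, start, end, label, then all features."""
    if not samples:
        raise ValueError("no window samples to extract features from")
    width = samples[0].end - samples[0].start
    names = feature_names(spec, width)
    rows = []
    for w in samples:
        vec = feature_vector(w, spec)
        rows.append(
            [w.participant_id, w.start, w.end, w.label] + vec.values.tolist()
        )
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(names))
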