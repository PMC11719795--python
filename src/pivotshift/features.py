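"""Segment-wise features of the pivot-shift X-axis trace.

Four data representations are analysed: original values, min-max normalized
values, and the Fourier magnitude spectrum of each.  Two named feature sets
are registered:

* class set (maneuver execution class, computed on the *normalized*
  representation of segment 3): ``S3n-STD``, ``S3n-R``, ``S3n-Rx``,
  ``S3n-O``, ``S3TF-P``;
* grade set (injury grade, computed on the *original* representation):
  ``S1-Max``, ``S3-Max``, ``S2-R``, ``S3-R``, ``S3-STD``, ``S3-We``,
  ``S3TF-P``.

Naming: the ``n`` suffix marks the normalized representation; ``R`` is the
range max-min; ``Rx`` is range plus segment mean; ``O`` and ``P`` are the
intercept (ordinate) and slope of an ordinary least-squares line; ``TF``
marks the Fourier-magnitude domain (slope of magnitude vs frequency, DC bin
excluded); ``We`` is the Shannon entropy (bits) of the sample energy
distribution.  Standard deviations are population-normalized (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GyroRecording
from .preprocessing import SegmentedSignal, Signal, normalize, segment_signal, select_axis

__all__ = [
    "Spectrum",
    "FeatureVector",
    "CLASS_FEATURES",
    "GRADE_FEATURES",
    "ALL_FEATURES",
    "fourier_magnitude",
    "segment_stats",
    "linreg_features",
    "shannon_entropy",
    "extract_class_features",
    "extract_grade_features",
    "extract_all_features",
]

CLASS_FEATURES = ("S3n-STD", "S3n-R", "S3n-Rx", "S3n-O", "S3TF-P")
GRADE_FEATURES = ("S1-Max", "S3-Max", "S2-R", "S3-R", "S3-STD", "S3-We", "S3TF-P")
ALL_FEATURES = CLASS_FEATURES + tuple(f for f in GRADE_FEATURES if f not in CLASS_FEATURES)


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum: bins 0..floor(n/2), freqs k*fs/n."""

    freqs_hz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))
        object.__setattr__(self, "magnitude", np.asarray(self.magnitude, dtype=float))
        if len(self.freqs_hz) != len(self.magnitude):
            raise ValueError("freqs and magnitude length mismatch")
        if len(self.freqs_hz) and (self.freqs_hz[0] != 0 or np.any(np.diff(self.freqs_hz) <= 0)):
            raise ValueError("freqs must start at 0 and be strictly increasing")


@dataclass(frozen=True)
class FeatureVector:
    """Named scalar features for one test."""

    values: dict

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unregistered feature names: {sorted(unknown)}")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_array(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


def fourier_magnitude(sig: Signal) -> Spectrum:
    """One-sided DFT magnitude of a signal.

    Bin k carries ``|sum_j x_j exp(-2*pi*i*j*k/n)|`` at frequency k*fs/n,
    for k = 0..floor(n/2).
    """
    n = len(sig)
    if n < 4:
        raise ValueError(f"need >= 4 samples for a spectrum, got {n}")
    mag = np.abs(np.fft.rfft(sig.values))
    freqs = np.fft.rfftfreq(n, d=sig.dt_s)
    return Spectrum(freqs_hz=freqs, magnitude=mag)


def segment_stats(values: np.ndarray) -> dict:
    """Basic amplitude statistics of one segment.

    ``range`` = max - min; ``rx`` = range + mean; ``std`` is population
    (ddof=0).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty segment")
    rng = float(np.max(v) - np.min(v))
    mean = float(np.mean(v))
    return {
        "max": float(np.max(v)),
        "min": float(np.min(v)),
        "mean": mean,
        "range": rng,
        "std": float(np.std(v)),
        "rx": rng + mean,
    }


def linreg_features(values: np.ndarray, dt_s: float) -> dict:
    """OLS line through (elapsed time, value) pairs.

    Abscissa is 0, dt, 2*dt, ...; ``ordinate`` is the intercept at segment
    start, ``slope`` the fitted gradient.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 samples for a regression")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    x = np.arange(v.size) * dt_s
    slope, ordinate = np.polyfit(x, v, 1)
    return {"slope": float(slope), "ordinate": float(ordinate)}


def shannon_entropy(values: np.ndarray) -> float:
    """Shannon entropy (bits) of the sample energy distribution.

    p_i = x_i^2 / sum_j x_j^2; H = -sum p_i log2 p_i, with 0*log(0) = 0.
    An all-zero segment has zero energy and returns 0 by convention.  This
    estimator is binning-free and deterministic.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty segment")
    energy = v * v
    total = energy.sum()
    if total == 0:
        return 0.0
    p = energy / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _spectral_slope(spec: Spectrum) -> float:
    """Slope of OLS fit of magnitude vs frequency (Hz), DC bin excluded."""
    if len(spec.freqs_hz) < 3:
        raise ValueError("spectrum too short for a slope")
    slope, _ = np.polyfit(spec.freqs_hz[1:], spec.magnitude[1:], 1)
    return float(slope)


def extract_class_features(
    seg_normalized: SegmentedSignal, spectrum_s3n: Spectrum | None = None
) -> FeatureVector:
    """Class feature set from the normalized segmentation.

    Time-domain statistics of normalized S3 plus the spectral slope of its
    Fourier magnitude.  ``spectrum_s3n`` may be passed in to reuse a
    precomputed spectrum; otherwise it is computed here.
    """
    s3 = seg_normalized.S3
    if s3.representation != "normalized":
        raise ValueError("class features require the normalized representation")
    stats = segment_stats(s3.values)
    reg = linreg_features(s3.values, s3.dt_s)
    spec = spectrum_s3n if spectrum_s3n is not None else fourier_magnitude(s3)
    return FeatureVector(
        {
            "S3n-STD": stats["std"],
            "S3n-R": stats["range"],
            "S3n-Rx": stats["rx"],
            "S3n-O": reg["ordinate"],
            "S3TF-P": _spectral_slope(spec),
        }
    )


def extract_grade_features(
    seg_original: SegmentedSignal, spectrum_s3n: Spectrum
) -> FeatureVector:
    """Grade feature set from the original segmentation.

    Amplitude features (max, range, std) of the raw deg/s segments, the
    energy entropy of S3, and the same normalized-S3 spectral slope used in
    the class set.
    """
    if seg_original.S1.representation != "original":
        raise ValueError("grade features require the original representation")
    s1 = segment_stats(seg_original.S1.values)
    s2 = segment_stats(seg_original.S2.values)
    s3 = segment_stats(seg_original.S3.values)
    return FeatureVector(
        {
            "S1-Max": s1["max"],
            "S3-Max": s3["max"],
            "S2-R": s2["range"],
            "S3-R": s3["range"],
            "S3-STD": s3["std"],
            "S3-We": shannon_entropy(seg_original.S3.values),
            "S3TF-P": _spectral_slope(spectrum_s3n),
        }
    )


def extract_all_features(rec: GyroRecording, strategy: str = "equal_thirds") -> FeatureVector:
    """Full feature row (class set + grade set) for one recording.

    The X axis is selected, min-max normalized over the whole test, and both
    representations are segmented with identical boundaries so that class
    and grade features describe the same time windows.
    """
    x = select_axis(rec, "X")
    xn = normalize(x)
    seg = segment_signal(x, strategy)
    seg_n = segment_signal(xn, "explicit", boundaries=seg.boundaries)
    spec_n = fourier_magnitude(seg_n.S3)
    cls = extract_class_features(seg_n, spec_n)
    grd = extract_grade_features(seg, spec_n)
    return FeatureVector({**cls.values, **grd.values})
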