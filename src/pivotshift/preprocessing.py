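"""Axis selection, quality control, normalization and 3-segment split.

The maneuver signal analysed is the gyroscope X axis, which tracks knee
flexion/extension during the pivot shift.  Each trace is divided into three
contiguous segments S1, S2, S3; the shift event (tibial reduction) lands in
the final segment, which carries most of the diagnostic information.

Normalization is min-max to [0, 1] computed over the whole test signal
*before* segmentation, so inter-segment amplitude ratios survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GyroRecording

__all__ = [
    "Signal",
    "SegmentedSignal",
    "QCConfig",
    "QCReport",
    "DegenerateSignalError",
    "select_axis",
    "run_qc",
    "normalize",
    "segment_signal",
]


class DegenerateSignalError(ValueError):
    """Signal has no amplitude information (constant)."""


@dataclass(frozen=True)
class Signal:
    """A single-axis series, either raw deg/s or min-max normalized."""

    values: np.ndarray
    sample_rate_hz: float
    representation: str = "original"  # original | normalized

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.representation not in ("original", "normalized"):
            raise ValueError(f"unknown representation {self.representation!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sample_rate_hz


@dataclass(frozen=True)
class SegmentedSignal:
    """The trace split into contiguous segments S1 | S2 | S3."""

    S1: Signal
    S2: Signal
    S3: Signal
    boundaries: tuple[int, int]

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not (0 < b1 < b2):
            raise ValueError(f"boundaries must satisfy 0 < b1 < b2, got {self.boundaries}")
        if len(self.S1) != b1 or len(self.S2) != b2 - b1 or len(self.S3) == 0:
            raise ValueError("segment lengths inconsistent with boundaries")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.S1.values, self.S2.values, self.S3.values])


def select_axis(rec: GyroRecording, axis: str = "X") -> Signal:
    """Project one gyroscope axis out of a recording.

    The X axis is the default analysis target: it reflects the
    flexion/extension component of the maneuver.
    """
    key = {"X": "omega_x", "Y": "omega_y", "Z": "omega_z"}.get(axis.upper())
    if key is None:
        raise ValueError(f"axis must be X, Y or Z, got {axis!r}")
    return Signal(values=getattr(rec, key), sample_rate_hz=rec.sample_rate_hz)


@dataclass(frozen=True)
class QCConfig:
    """Quality-control rule thresholds.

    Defaults bound a plausible pivot-shift capture: 1-10 s duration, at
    least 50 samples, no NaNs, below gyroscope saturation, and a minimum
    peak X-axis amplitude so that flat or detached captures are rejected.
    """

    min_duration_s: float = 1.0
    max_duration_s: float = 10.0
    min_samples: int = 50
    saturation_deg_s: float = 2000.0
    max_saturated_fraction: float = 0.05
    min_peak_abs_x: float = 5.0
    flatline_eps: float = 1e-9


@dataclass(frozen=True)
class QCReport:
    test_id: str
    passed: bool
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to empty reasons")


def run_qc(rec: GyroRecording, rules: QCConfig | None = None) -> QCReport:
    """Deterministic pass/fail screen with machine-readable reason codes.

    Codes: ``DURATION_OUT_OF_RANGE``, ``SATURATION``, ``FLATLINE``,
    ``NAN_SAMPLES``, ``AMPLITUDE_FLOOR``.  QC failures are report content,
    never exceptions — discarded tests mirror real-world exclusions for
    technical failures or incorrect execution.
    """
    rules = rules or QCConfig()
    reasons: list[str] = []

    if not (rules.min_duration_s <= rec.duration_s <= rules.max_duration_s) or (
        rec.n_samples < rules.min_samples
    ):
        reasons.append("DURATION_OUT_OF_RANGE")

    stacked = np.concatenate([rec.omega_x, rec.omega_y, rec.omega_z])
    if np.isnan(stacked).any():
        reasons.append("NAN_SAMPLES")
    else:
        sat = np.abs(stacked) >= rules.saturation_deg_s
        if sat.mean() > rules.max_saturated_fraction:
            reasons.append("SATURATION")
        x = rec.omega_x
        if np.ptp(x) <= rules.flatline_eps:
            reasons.append("FLATLINE")
        if np.max(np.abs(x)) < rules.min_peak_abs_x:
            reasons.append("AMPLITUDE_FLOOR")

    return QCReport(test_id=rec.test_id, passed=not reasons, reasons=tuple(reasons))


def normalize(sig: Signal) -> Signal:
    """Min-max map onto [0, 1]; min -> 0 and max -> 1 exactly.

    Idempotent, and invariant to positive affine rescaling of the input.
    Raises :class:`DegenerateSignalError` on a constant signal.
    """
    v = sig.values
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi <= lo:
        raise DegenerateSignalError("cannot normalize a constant signal")
    out = (v - lo) / (hi - lo)
    # pin the extrema exactly despite rounding
    out[np.argmin(v)] = 0.0
    out[np.argmax(v)] = 1.0
    return Signal(values=out, sample_rate_hz=sig.sample_rate_hz, representation="normalized")


def segment_signal(
    sig: Signal,
    strategy: str = "equal_thirds",
    boundaries: tuple[int, int] | None = None,
) -> SegmentedSignal:
    """Split a signal into S1 | S2 | S3.

    ``equal_thirds`` (default): |S1| = |S2| = floor(n/3), S3 takes the
    remainder — the final segment is the analysis target, so it absorbs the
    extra samples.  ``explicit`` uses the given cut indices, for
    event-aligned analyses.
    """
    n = len(sig)
    if n < 3:
        raise ValueError(f"need >= 3 samples to segment, got {n}")
    if strategy == "equal_thirds":
        k = n // 3
        b1, b2 = k, 2 * k
    elif strategy == "explicit":
        if boundaries is None:
            raise ValueError("explicit strategy requires boundaries=(b1, b2)")
        b1, b2 = boundaries
        if not (0 < b1 < b2 < n):
            raise ValueError(f"boundaries must satisfy 0 < b1 < b2 < {n}, got {boundaries}")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    mk = lambda v: Signal(v, sig.sample_rate_hz, sig.representation)  # noqa: E731
    return SegmentedSignal(
        S1=mk(sig.values[:b1]),
        S2=mk(sig.values[b1:b2]),
        S3=mk(sig.values[b2:]),
        boundaries=(b1, b2),
    )
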