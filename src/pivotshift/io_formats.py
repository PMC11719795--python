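"""Reading and writing gyroscope recordings and dataset manifests.

A recording is one pivot-shift test: a time base plus three-axis angular
velocity in deg/s, as captured by a smartphone gyroscope strapped to the
tibial tuberosity.  Signal payload (CSV: ``t, omega_x, omega_y, omega_z``)
is kept separate from clinical metadata, which travels in a manifest CSV
(one row per test: side, clinical context, IKDC grade, maneuver class).

Units are fixed: seconds and deg/s.  No unit auto-detection is attempted —
phone gyroscope APIs disagree on conventions, and a single convention keeps
features comparable across evaluators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GyroRecording",
    "DatasetManifest",
    "FormatError",
    "IntegrityError",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "CONTEXTS",
    "SIDES",
]

CONTEXTS = ("office", "preop", "postop", "followup")
SIDES = ("L", "R")

SIGNAL_COLUMNS = ("t", "omega_x", "omega_y", "omega_z")
MANIFEST_COLUMNS = (
    "test_id",
    "path",
    "side",
    "context",
    "ikdc_grade",
    "class_label",
    "include_flag",
)


class FormatError(ValueError):
    """A file does not conform to the expected CSV schema."""


class IntegrityError(ValueError):
    """Parsed content violates a domain invariant (e.g. non-monotone time)."""


@dataclass(frozen=True)
class GyroRecording:
    """One pivot-shift test: time base + 3-axis angular velocity (deg/s).

    Parameters
    ----------
    test_id : str
        Unique identifier of the test.
    sample_rate_hz : float
        Nominal sampling rate; must agree with ``median(diff(t))`` within 5%.
    t : ndarray
        Strictly increasing sample times in seconds.
    omega_x, omega_y, omega_z : ndarray
        Angular velocity per axis in deg/s.  The X axis reflects knee
        flexion/extension and is the axis analysed downstream.
    meta : dict
        Clinical metadata: ``side`` (L|R), ``context``
        (office|preop|postop|followup), ``evaluator_id``, ``ikdc_grade``
        (0..3 or None), ``class_label`` (1..8 or None).
    """

    test_id: str
    sample_rate_hz: float
    t: np.ndarray
    omega_x: np.ndarray
    omega_y: np.ndarray
    omega_z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t", "omega_x", "omega_y", "omega_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if n < 2:
            raise IntegrityError(f"{self.test_id}: need >= 2 samples, got {n}")
        for name in ("omega_x", "omega_y", "omega_z"):
            if len(getattr(self, name)) != n:
                raise IntegrityError(f"{self.test_id}: length mismatch in {name}")
        dt = np.diff(self.t)
        if not np.all(dt > 0):
            raise IntegrityError(f"{self.test_id}: time base not strictly increasing")
        if self.sample_rate_hz <= 0:
            raise IntegrityError(f"{self.test_id}: sample_rate_hz must be positive")
        implied = 1.0 / float(np.median(dt))
        if abs(implied - self.sample_rate_hz) > 0.05 * self.sample_rate_hz:
            raise IntegrityError(
                f"{self.test_id}: sample_rate_hz={self.sample_rate_hz} inconsistent "
                f"with median(diff(t)) -> {implied:.3f} Hz (>5% off)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def with_meta(self, **kwargs) -> "GyroRecording":
        return replace(self, meta={**self.meta, **kwargs})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GyroRecording):
            return NotImplemented
        return (
            self.test_id == other.test_id
            and self.sample_rate_hz == other.sample_rate_hz
            and all(
                np.array_equal(getattr(self, a), getattr(other, a))
                for a in ("t", "omega_x", "omega_y", "omega_z")
            )
        )


def read_recording(
    path: str | Path,
    *,
    sample_rate_hz: float | None = None,
    test_id: str | None = None,
    column_names: Mapping[str, str] | None = None,
) -> GyroRecording:
    """Read one signal CSV into a :class:`GyroRecording`.

    ``column_names`` maps the canonical names (``t``, ``omega_x``, ...) to
    the header names actually present, for files written by other tools.
    If ``sample_rate_hz`` is omitted it is inferred from ``median(diff(t))``.
    """
    path = Path(path)
    # round_trip parsing keeps write->read bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {v: k for k, v in (column_names or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2 and sample_rate_hz is None:
        dt = np.diff(t)
        if np.all(dt > 0):
            # snap to 6 significant digits: nominal device rates are round
            # numbers, and ulp-level jitter in parsed timestamps must not
            # perturb the frequency axis of downstream spectra
            sample_rate_hz = float(f"{1.0 / float(np.median(dt)):.6g}")
    return GyroRecording(
        test_id=test_id or path.stem,
        sample_rate_hz=float(sample_rate_hz) if sample_rate_hz else 0.0,
        t=t,
        omega_x=df["omega_x"].to_numpy(dtype=float),
        omega_y=df["omega_y"].to_numpy(dtype=float),
        omega_z=df["omega_z"].to_numpy(dtype=float),
    )


def write_recording(rec: GyroRecording, path: str | Path) -> Path:
    """Write a recording as CSV (one row per sample, full float precision).

    ``read_recording`` inverts this bit-exactly: values are serialized with
    Python's shortest round-trippable ``repr``.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": rec.t,
            "omega_x": rec.omega_x,
            "omega_y": rec.omega_y,
            "omega_z": rec.omega_z,
        }
    )
    # %.17g guarantees bit-exact float round-trips through text
    df.to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass
class DatasetManifest:
    """Per-test metadata table for a cohort of pivot-shift tests.

    Wraps a DataFrame with columns ``test_id, path, side, context,
    ikdc_grade, class_label, include_flag``.  Unknown grade/class are
    encoded as missing values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"manifest missing columns {missing}")
        ids = self.table["test_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise IntegrityError(f"duplicate test_id values: {dupes}")
        bad_ctx = set(self.table["context"].dropna()) - set(CONTEXTS)
        if bad_ctx:
            raise FormatError(f"invalid context values: {sorted(bad_ctx)}")
        bad_side = set(self.table["side"].dropna()) - set(SIDES)
        if bad_side:
            raise FormatError(f"invalid side values: {sorted(bad_side)}")
        for col, lo, hi in (("ikdc_grade", 0, 3), ("class_label", 1, 8)):
            vals = pd.to_numeric(self.table[col], errors="coerce").dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise FormatError(f"{col} values out of range [{lo},{hi}]")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "DatasetManifest":
        return cls(pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS)))


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read and validate a manifest CSV."""
    df = pd.read_csv(
        Path(path), dtype={"test_id": str, "path": str, "side": str, "context": str}
    )
    for col in ("ikdc_grade", "class_label"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return DatasetManifest(df)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, index=False)
    return path
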