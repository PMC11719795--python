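"""Synthetic pivot-shift gyroscope recordings with known labels.

No raw clinical traces are published for this maneuver, so a documented
stand-in generates X-axis angular-velocity waveforms whose structure tracks
the clinical picture: a positive flexion lobe as the knee is flexed to 90
degrees, and a negative "shift" lobe — the tibial reduction event — in the
final third of the trace, whose amplitude scales with injury grade:

    omega_x(t) = A_f * exp(-(t - t1)^2 / (2 s1^2))
               - grade * Delta * exp(-(t - t2)^2 / (2 s2^2)) + eps(t)

with eps ~ N(0, sigma^2) i.i.d.  (t1, s1, t2, s2) come from a per-class
morphology registry: classes 2..7 are standardized executions whose lobe
timings/widths differ (t2 always in the final third); class 1 is a
truncated capture (recording stopped early — it fails default duration QC
by construction); class 8 places the shift lobe in the middle third, a
mistimed maneuver.  Y and Z channels are leak-scaled copies of X plus
independent noise, mimicking cross-axis coupling of the phone mount.

Grade 0 (intact or reconstructed knee) has no shift lobe; classes then
differ through how far the flexion lobe's tail reaches into segment 3.

Defaults encode the cohort being emulated: class proportions follow the
standardized-test column of the observed 8-class frequency table; 60/33/7%
of injured knees are grades I/II/III; the grade-0 share matches the
postoperative and follow-up fraction of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import DatasetManifest, GyroRecording, write_manifest, write_recording

__all__ = [
    "ClassShape",
    "SimulationConfig",
    "LabeledDataset",
    "DEFAULT_CLASS_REGISTRY",
    "DEFAULT_CLASS_PROBS",
    "DEFAULT_GRADE_PROBS",
    "DEFAULT_CONTEXT_PROBS",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ClassShape:
    """Morphology of one maneuver class, as fractions of the recording.

    ``t1_frac``/``w1_frac``: center and width of the flexion lobe;
    ``t2_frac``/``w2_frac``: center and width of the shift lobe;
    ``duration_factor``: fraction of the nominal duration actually captured
    (< 1 models a truncated recording).
    """

    t1_frac: float
    w1_frac: float
    t2_frac: float
    w2_frac: float
    duration_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w1_frac", "w2_frac", "duration_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# Classes 2..7: unique flexion-lobe timing/width (progressively later and
# wider, so the tail reaching S3 is class-distinctive even at grade 0) and
# unique shift-lobe placement within the final third.  Class 1: capture
# stopped mid-flexion — a short recording that ends on the rising lobe.
# Class 8: shift lobe mistimed into the middle third.
DEFAULT_CLASS_REGISTRY: dict[int, ClassShape] = {
    1: ClassShape(0.90, 0.25, 0.80, 0.04, duration_factor=0.3),
    2: ClassShape(0.40, 0.070, 0.73, 0.027),
    3: ClassShape(0.46, 0.090, 0.83, 0.027),
    4: ClassShape(0.52, 0.110, 0.93, 0.027),
    5: ClassShape(0.58, 0.130, 0.78, 0.060),
    6: ClassShape(0.64, 0.150, 0.88, 0.060),
    7: ClassShape(0.70, 0.170, 0.83, 0.095),
    8: ClassShape(0.35, 0.085, 0.50, 0.040),
}

# Standardized-test class frequencies (11, 28, 81, 79, 90, 83, 21, 6) / 399.
DEFAULT_CLASS_PROBS = tuple(np.array([11, 28, 81, 79, 90, 83, 21, 6]) / 399.0)

# Grade 0 share = postop + follow-up fraction (83/399); the injured mass is
# split 60/33/7 across grades I-III as graded by the examiners.
_g0 = 83.0 / 399.0
DEFAULT_GRADE_PROBS = (_g0, 0.60 * (1 - _g0), 0.33 * (1 - _g0), 0.07 * (1 - _g0))

# office / preop / postop / followup = (136, 180, 63, 20) / 399
DEFAULT_CONTEXT_PROBS = tuple(np.array([136, 180, 63, 20]) / 399.0)
_CONTEXTS = ("office", "preop", "postop", "followup")

# right knee fraction 233/437
_P_RIGHT = 233.0 / 437.0


@dataclass(frozen=True)
class SimulationConfig:
    """Waveform, noise and cohort parameters for the generator.

    ``flexion_amplitude_deg_s`` (A_f) sets the flexion lobe peak; the shift
    lobe peak is ``grade * grade_step_deg_s`` (Delta).  ``noise_sd_deg_s``
    is the i.i.d. Gaussian sensor-noise sd; ``leak_gain_y``/``_z`` couple
    the X waveform into the other axes.
    """

    duration_s: float = 3.0
    sample_rate_hz: float = 100.0
    flexion_amplitude_deg_s: float = 60.0
    grade_step_deg_s: float = 30.0
    noise_sd_deg_s: float = 3.0
    leak_gain_y: float = 0.35
    leak_gain_z: float = 0.20
    class_registry: dict[int, ClassShape] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_REGISTRY)
    )

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be positive")
        if self.noise_sd_deg_s < 0:
            raise ValueError("noise sd must be non-negative")
        missing = set(range(1, 9)) - set(self.class_registry)
        if missing:
            raise ValueError(f"class registry must cover classes 1..8, missing {missing}")


@dataclass
class LabeledDataset:
    """Simulated cohort: recordings plus a manifest of true labels."""

    recordings: list[GyroRecording]
    manifest: DatasetManifest

    def __len__(self) -> int:
        return len(self.recordings)

    def write(self, out_dir: str | Path) -> Path:
        """Write signal CSVs and the manifest CSV into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in self.recordings:
            write_recording(rec, out_dir / f"{rec.test_id}.csv")
        return write_manifest(self.manifest, out_dir / "manifest.csv")


def simulate_recording(
    grade: int,
    klass: int,
    cfg: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    test_id: str | None = None,
) -> GyroRecording:
    """Generate one labeled recording; deterministic given the seed."""
    cfg = cfg or SimulationConfig()
    if not 0 <= grade <= 3:
        raise ValueError(f"grade must be 0..3, got {grade}")
    if not 1 <= klass <= 8:
        raise ValueError(f"class must be 1..8, got {klass}")
    shape = cfg.class_registry[klass]
    rng = np.random.default_rng(seed)

    duration = cfg.duration_s * shape.duration_factor
    n = int(round(duration * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz
    t1, s1 = shape.t1_frac * duration, shape.w1_frac * duration
    t2, s2 = shape.t2_frac * duration, shape.w2_frac * duration

    flexion = cfg.flexion_amplitude_deg_s * np.exp(-((t - t1) ** 2) / (2 * s1**2))
    shift = grade * cfg.grade_step_deg_s * np.exp(-((t - t2) ** 2) / (2 * s2**2))
    x = flexion - shift + rng.normal(0.0, cfg.noise_sd_deg_s, n)
    y = cfg.leak_gain_y * x + rng.normal(0.0, cfg.noise_sd_deg_s, n)
    z = cfg.leak_gain_z * x + rng.normal(0.0, cfg.noise_sd_deg_s, n)

    return GyroRecording(
        test_id=test_id or f"sim_c{klass}_g{grade}",
        sample_rate_hz=cfg.sample_rate_hz,
        t=t,
        omega_x=x,
        omega_y=y,
        omega_z=z,
        meta={"ikdc_grade": grade, "class_label": klass},
    )


def simulate_cohort(
    n: int,
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS,
    grade_probs: tuple[float, ...] = DEFAULT_GRADE_PROBS,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Draw a labeled cohort of ``n`` tests.

    Class and grade labels are multinomial draws from the given simplices;
    context and knee side are drawn independently at the cohort's observed
    proportions.  Identical seeds give identical datasets.
    """
    cfg = cfg or SimulationConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, probs, k in (("class_probs", class_probs, 8), ("grade_probs", grade_probs, 4)):
        if len(probs) != k:
            raise ValueError(f"{name} must have {k} entries")
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError(f"{name} must be a probability simplex")

    rng = np.random.default_rng(seed)
    classes = rng.choice(np.arange(1, 9), size=n, p=np.asarray(class_probs))
    grades = rng.choice(np.arange(4), size=n, p=np.asarray(grade_probs))
    contexts = rng.choice(_CONTEXTS, size=n, p=np.asarray(DEFAULT_CONTEXT_PROBS))
    sides = rng.choice(["R", "L"], size=n, p=[_P_RIGHT, 1 - _P_RIGHT])

    recordings, rows = [], []
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        tid = f"sim_{i:05d}"
        rec = simulate_recording(
            int(grades[i]), int(classes[i]), cfg, seed=int(child_seeds[i]), test_id=tid
        )
        rec = rec.with_meta(side=str(sides[i]), context=str(contexts[i]))
        recordings.append(rec)
        rows.append(
            {
                "test_id": tid,
                "path": f"{tid}.csv",
                "side": str(sides[i]),
                "context": str(contexts[i]),
                "ikdc_grade": int(grades[i]),
                "class_label": int(classes[i]),
                "include_flag": True,
            }
        )
    return LabeledDataset(recordings=recordings, manifest=DatasetManifest.from_rows(rows))
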