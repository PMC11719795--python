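import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from pivotshift import (
    Signal,
    SimulationConfig,
    extract_all_features,
    extract_class_features,
    extract_grade_features,
    fourier_magnitude,
    linreg_features,
    normalize,
    segment_signal,
    segment_stats,
    shannon_entropy,
    simulate_recording,
)
from pivotshift.features import CLASS_FEATURES, GRADE_FEATURES


# ---------------------------------------------------------------- oracles
def naive_dft_magnitude(x):
    """Brute-force O(n^2) DFT magnitude, one-sided bins 0..floor(n/2)."""
    x = np.asarray(x, float)
    n = len(x)
    out = []
    for k in range(n // 2 + 1):
        re = sum(x[j] * np.cos(-2 * np.pi * j * k / n) for j in range(n))
        im = sum(x[j] * np.sin(-2 * np.pi * j * k / n) for j in range(n))
        out.append(np.hypot(re, im))
    return np.array(out)


def two_pass_stats(x):
    """Textbook two-pass mean/std plus range."""
    x = np.asarray(x, float)
    mean = sum(x) / len(x)
    var = sum((v - mean) ** 2 for v in x) / len(x)
    return {"mean": mean, "std": np.sqrt(var), "range": max(x) - min(x)}


def normal_equation_line(t, y):
    """OLS slope/intercept from the closed-form normal equations."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    n = len(t)
    sx, sy, sxx, sxy = t.sum(), y.sum(), (t * t).sum(), (t * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return slope, (sy - slope * sx) / n


# ------------------------------------------------------------------ tests
class TestFourierMagnitude:
    def test_pure_sinusoid_peaks_at_its_bin(self):
        n, fs, k0 = 64, 64.0, 5
        t = np.arange(n) / fs
        sig = Signal(np.sin(2 * np.pi * k0 * t), fs)
        spec = fourier_magnitude(sig)
        assert np.argmax(spec.magnitude[1:]) + 1 == k0

    def test_constant_signal_has_zero_ac_bins(self):
        spec = fourier_magnitude(Signal(np.full(32, 3.0), 100.0))
        np.testing.assert_allclose(spec.magnitude[1:], 0, atol=1e-9)

    def test_matches_naive_dft_oracle(self, rng):
        for n in (8, 17, 32, 64):
            x = rng.normal(size=n)
            spec = fourier_magnitude(Signal(x, 100.0))
            np.testing.assert_allclose(spec.magnitude, naive_dft_magnitude(x), atol=1e-9)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=64)
        full = np.abs(np.fft.fft(x))
        assert abs((full**2).sum() / 64 - (x**2).sum()) < 1e-9

    def test_frequency_axis(self):
        spec = fourier_magnitude(Signal(np.arange(10, dtype=float), 100.0))
        np.testing.assert_allclose(spec.freqs_hz, np.arange(6) * 10.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            fourier_magnitude(Signal(np.ones(3), 100.0))


class TestSegmentStats:
    def test_hand_computed_example(self):
        s = segment_stats([1, 2, 3])
        assert s["max"] == 3 and s["range"] == 2 and s["mean"] == 2 and s["rx"] == 4
        assert abs(s["std"] - np.sqrt(2.0 / 3.0)) < 1e-12

    def test_constant_segment(self):
        s = segment_stats([7.0, 7.0, 7.0])
        assert s["range"] == 0 and s["std"] == 0 and s["rx"] == 7.0

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(3.0, 2.0, size=100)
        got = segment_stats(x)
        want = two_pass_stats(x)
        for key in ("mean", "std", "range"):
            assert abs(got[key] - want[key]) < 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            segment_stats([])

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50),
        st.floats(-1e3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_range_and_std_translation_invariant_but_max_rx_not(self, values, shift):
        base = segment_stats(values)
        moved = segment_stats(np.asarray(values) + shift)
        assert abs(moved["range"] - base["range"]) < 1e-6
        assert abs(moved["std"] - base["std"]) < 1e-6
        if abs(shift) > 1e-6:
            assert abs(moved["max"] - base["max"]) > 0
            assert abs(moved["rx"] - base["rx"]) > 0


class TestLinregFeatures:
    def test_exact_line_recovered(self):
        t = np.arange(50) * 0.01
        out = linreg_features(2 * t + 1, dt_s=0.01)
        assert abs(out["slope"] - 2) < 1e-9 and abs(out["ordinate"] - 1) < 1e-9

    def test_constant_signal(self):
        out = linreg_features(np.full(10, 4.2), dt_s=0.1)
        assert abs(out["slope"]) < 1e-12 and abs(out["ordinate"] - 4.2) < 1e-12

    def test_matches_normal_equation_oracle(self, rng):
        y = rng.normal(size=50)
        dt = 0.02
        got = linreg_features(y, dt)
        slope, intercept = normal_equation_line(np.arange(50) * dt, y)
        assert abs(got["slope"] - slope) < 1e-9
        assert abs(got["ordinate"] - intercept) < 1e-9

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            linreg_features([1.0], 0.01)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 0, 0, 0], 0.0), ([1, 1, 1, 1], 2.0), ([1, 1, 0, 0], 1.0), ([0, 0, 0], 0.0)],
    )
    def test_energy_distribution_entropy(self, values, expected):
        assert abs(shannon_entropy(values) - expected) < 1e-12

    def test_sign_invariant(self, rng):
        x = rng.normal(size=30)
        assert abs(shannon_entropy(x) - shannon_entropy(-x)) < 1e-12


class TestFeatureVectors:
    def _segments(self, rec):
        from pivotshift import select_axis

        x = select_axis(rec, "X")
        xn = normalize(x)
        seg = segment_signal(x)
        seg_n = segment_signal(xn, "explicit", boundaries=seg.boundaries)
        return seg, seg_n

    def test_constant_normalized_s3(self):
        # construct a normalized signal whose S3 is constant at 0.5
        v = np.concatenate([[0.0, 1.0], np.full(8, 0.5)])
        sig = Signal(v, 100.0, representation="normalized")
        seg = segment_signal(sig, "explicit", boundaries=(1, 2))
        fv = extract_class_features(seg)
        assert fv["S3n-STD"] == 0 and fv["S3n-R"] == 0 and abs(fv["S3n-Rx"] - 0.5) < 1e-12

    def test_grade_features_from_explicit_segments(self):
        v = np.array([1, 4, 2, 5, 1, 3, 0, 6, 3, 1], dtype=float)
        sig = Signal(v, 100.0)
        seg = segment_signal(sig, "explicit", boundaries=(3, 6))
        spec = fourier_magnitude(seg.S3)
        fv = extract_grade_features(seg, spec)
        assert fv["S1-Max"] == 4 and fv["S3-Max"] == 6 and fv["S3-R"] == 6
        assert fv["S2-R"] == 4  # S2 = [5,1,3]

    def test_feature_extraction_deterministic(self):
        rec = simulate_recording(2, 5, seed=21)
        a = extract_all_features(rec)
        b = extract_all_features(rec)
        assert a.values == b.values

    def test_registered_names_cover_both_sets(self):
        rec = simulate_recording(1, 4, seed=3)
        fv = extract_all_features(rec)
        assert set(CLASS_FEATURES) | set(GRADE_FEATURES) <= set(fv.values)

    def test_class_features_invariant_to_raw_rescaling(self):
        rec = simulate_recording(2, 3, seed=13)
        fv1 = extract_all_features(rec)
        scaled = type(rec)(
            rec.test_id, rec.sample_rate_hz, rec.t,
            3.0 * rec.omega_x + 10.0, rec.omega_y, rec.omega_z,
        )
        fv2 = extract_all_features(scaled)
        for name in CLASS_FEATURES:
            assert abs(fv1[name] - fv2[name]) < 1e-6, name


class TestGradeMonotonicity:
    def test_higher_grade_increases_normalized_s3_range(self):
        """Grade-3 vs grade-0 cohorts: the shift lobe widens normalized S3."""
        vals = {g: [] for g in (0, 3)}
        cfg = SimulationConfig(noise_sd_deg_s=1.0)
        for g in vals:
            for i in range(100):
                rec = simulate_recording(g, 3, cfg, seed=11000 + 7 * i + g)
                vals[g].append(extract_all_features(rec)["S3n-R"])
        assert np.mean(vals[3]) > np.mean(vals[0])

    def test_s3_range_correlates_with_grade(self):
        """Across grades 0..3 the original-representation S3 range is
        grade-monotone (Spearman > 0.8)."""
        rng = np.random.default_rng(5)
        grades, s3r = [], []
        for i in range(200):
            g = int(rng.integers(0, 4))
            rec = simulate_recording(g, 3, seed=50000 + i)
            grades.append(g)
            s3r.append(extract_all_features(rec)["S3-R"])
        rho, _ = spearmanr(grades, s3r)
        assert rho > 0.8
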