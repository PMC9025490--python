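import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimsmark.peak_processing import (
    ConsensusIonTable,
    PeakDetectionParams,
    ProfileTrace,
    detect_peaks,
    multi_replicate_consensus,
    normalize,
    recalibrate,
    replicate_consensus,
)
from dimsmark.spectra_io import PeakList
from dimsmark.synthetic_data import generate_profile_spectrum


def _peaklist(mz, intensity=None, sample="s", rep="r1"):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.full(mz.size, 1000.0)
    return PeakList(sample, rep, mz, np.asarray(intensity, dtype=float))


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------


class TestDetectPeaks:
    def test_all_zero_trace_gives_no_peaks(self):
        trace = ProfileTrace(np.linspace(100, 110, 2000), np.zeros(2000))
        assert len(detect_peaks(trace)) == 0

    def test_single_gaussian_located_within_grid_step(self):
        center, step = 400.1234, 0.002
        grid = np.arange(399, 401, step)
        trace = ProfileTrace(grid, 5e4 * np.exp(-0.5 * ((grid - center) / 0.01) ** 2))
        peaks = detect_peaks(trace)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - center) < step

    def test_planted_peaks_below_relative_cutoff_excluded(self):
        """10 peaks above the cutoffs and 5 below the 0.01% relative cutoff."""
        rng = np.random.default_rng(11)
        grid = np.arange(100, 900, 0.01)
        big_centers = np.linspace(150, 850, 10)
        small_centers = np.linspace(200, 800, 5) + 13.0
        trace = np.zeros_like(grid)
        base = 1e7
        for c in big_centers:
            trace += rng.uniform(0.01, 1.0) * base * np.exp(-0.5 * ((grid - c) / 0.05) ** 2)
        for c in small_centers:
            # above absolute cutoff (100) but below 0.01% of the base peak
            trace += 0.5e-4 * base * np.exp(-0.5 * ((grid - c) / 0.05) ** 2)
        peaks = detect_peaks(ProfileTrace(grid, trace))
        assert len(peaks) == 10
        for c in big_centers:
            assert np.min(np.abs(peaks.mz - c)) < 0.05

    def test_trace_shorter_than_min_points_is_empty(self, caplog):
        trace = ProfileTrace(np.array([100.0]), np.array([1e6]))
        with caplog.at_level("WARNING"):
            assert len(detect_peaks(trace)) == 0

    def test_outputs_respect_intensity_cutoffs(self):
        rng = np.random.default_rng(3)
        grid = np.arange(50, 450, 0.01)
        trace = np.abs(rng.normal(0, 50, grid.size))
        for c in rng.uniform(60, 440, 25):
            trace += rng.lognormal(10, 2) * np.exp(-0.5 * ((grid - c) / 0.03) ** 2)
        params = PeakDetectionParams()
        peaks = detect_peaks(ProfileTrace(grid, trace), params)
        floor = max(params.absolute_intensity_cutoff,
                    params.relative_intensity_cutoff * trace.max())
        assert np.all(peaks.intensity >= floor)

    def test_roundtrip_with_profile_renderer(self):
        """Rendering 10 separated centroids and re-detecting recovers all 10."""
        rng = np.random.default_rng(5)
        mz = np.sort(rng.uniform(100, 900, 10))
        while np.min(np.diff(mz)) < 2.0:
            mz = np.sort(rng.uniform(100, 900, 10))
        planted = _peaklist(mz, rng.uniform(1e5, 1e6, 10))
        trace = generate_profile_spectrum(
            planted, peak_width=0.02, baseline_noise_sd=20.0, grid_step=0.004, seed=2
        )
        detected = detect_peaks(trace)
        assert len(detected) == 10
        for m in planted.mz:
            assert np.min(np.abs(detected.mz - m)) < 0.02


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------


class TestRecalibrate:
    references = [150.0, 423.169, 750.0]

    def test_exact_peaks_unchanged(self):
        peaks = _peaklist(self.references)
        out = recalibrate(peaks, self.references)
        np.testing.assert_allclose(out.mz, peaks.mz, rtol=1e-12)

    def test_constant_drift_removed(self):
        drifted = _peaklist([m * (1 + 5e-6) for m in self.references])
        out = recalibrate(drifted, self.references)
        residual = np.abs(out.mz - self.references) / self.references * 1e6
        assert residual.max() <= 0.1

    def test_linear_drift_removed(self):
        refs = np.array([100.0, 300.0, 500.0, 700.0, 900.0])
        drift_ppm = (refs - 50.0) / 950.0 * 6.0  # 0 ppm at m/z 50 -> 6 ppm at 1000
        drifted = _peaklist(refs * (1 + drift_ppm * 1e-6))
        out = recalibrate(drifted, refs.tolist())
        residual = np.abs(out.mz - refs) / refs * 1e6
        assert residual.max() <= 0.2

    def test_no_matching_reference_warns_and_passes_through(self, caplog):
        peaks = _peaklist([200.0, 300.0])
        with caplog.at_level("WARNING"):
            out = recalibrate(peaks, [600.0])
        np.testing.assert_array_equal(out.mz, peaks.mz)
        assert "no reference" in caplog.text

    @given(
        st.floats(min_value=-4.0, max_value=4.0),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_never_increases_mean_reference_error(self, intercept_ppm, slope_span_ppm):
        refs = np.array([120.0, 320.0, 520.0, 720.0, 920.0])
        drift = intercept_ppm + slope_span_ppm * (refs - 120.0) / 800.0
        noisy = refs * (1 + drift * 1e-6)
        before = np.mean(np.abs((noisy - refs) / refs * 1e6))
        out = recalibrate(_peaklist(noisy), refs.tolist())
        matched = np.array([out.mz[np.argmin(np.abs(out.mz - r))] for r in refs])
        after = np.mean(np.abs((matched - refs) / refs * 1e6))
        assert after <= before + 1e-9


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class TestNormalize:
    def test_internal_standard_division(self):
        peaks = _peaklist([423.169, 500.0], [2.0, 4.0])
        out = normalize(peaks, "internal_standard", is_mz=423.169)
        assert out.intensity[1] == pytest.approx(2.0)

    def test_tic_normalized_sums_to_one(self):
        rng = np.random.default_rng(1)
        peaks = _peaklist(np.sort(rng.uniform(50, 1000, 30)), rng.lognormal(8, 1, 30))
        out = normalize(peaks, "total_ion_current")
        assert out.intensity.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["internal_standard", "total_ion_current"])
    def test_scale_invariance(self, method):
        rng = np.random.default_rng(2)
        mz = np.sort(np.append(rng.uniform(50, 1000, 20), 423.169))
        inten = rng.lognormal(8, 1, 21)
        a = normalize(_peaklist(mz, inten), method, is_mz=423.169)
        b = normalize(_peaklist(mz, inten * 10.0), method, is_mz=423.169)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_missing_internal_standard_raises_or_falls_back(self):
        peaks = _peaklist([200.0], [5.0])
        with pytest.raises(ValueError, match="not found"):
            normalize(peaks, "internal_standard", is_mz=423.169)
        out = normalize(peaks, "internal_standard", is_mz=423.169, fallback_to_tic=True)
        assert out.intensity.sum() == pytest.approx(1.0)

    def test_mz_untouched(self):
        peaks = _peaklist([100.0, 423.169], [1.0, 2.0])
        out = normalize(peaks, "internal_standard", is_mz=423.169)
        np.testing.assert_array_equal(out.mz, peaks.mz)


# ---------------------------------------------------------------------------
# Replicate consensus
# ---------------------------------------------------------------------------


def _optimal_pairing(mz_a, mz_b, tol_ppm):
    """Independent oracle: maximum-cardinality min-cost matching by assignment."""
    from scipy.optimize import linear_sum_assignment

    n, m = len(mz_a), len(mz_b)
    big = 1e9
    cost = np.full((n, m), big)
    for i in range(n):
        for j in range(m):
            dev = abs(mz_a[i] - mz_b[j]) / (0.5 * (mz_a[i] + mz_b[j])) * 1e6
            if dev <= tol_ppm:
                cost[i, j] = dev
    rows, cols = linear_sum_assignment(cost)
    return sorted((i, j) for i, j in zip(rows, cols) if cost[i, j] < big)


class TestReplicateConsensus:
    def test_identical_lists_fully_retained(self):
        mz = np.array([100.0, 250.0, 600.0])
        table = replicate_consensus(_peaklist(mz), _peaklist(mz, rep="r2"))
        assert len(table) == 3
        np.testing.assert_allclose(table.consensus_mz, mz, rtol=1e-12)

    def test_ion_in_single_replicate_discarded(self):
        a = _peaklist([100.0, 250.0])
        b = _peaklist([100.0], rep="r2")
        table = replicate_consensus(a, b)
        assert table.consensus_mz.tolist() == [100.0]

    def test_consensus_mz_between_contributors(self):
        a = _peaklist([400.000], [100.0])
        b = _peaklist([400.001], [300.0], rep="r2")
        table = replicate_consensus(a, b, match_tol_ppm=5)
        assert 400.000 <= table.consensus_mz[0] <= 400.001
        # intensity-weighted: closer to the more intense replicate
        assert table.consensus_mz[0] == pytest.approx(400.00075, abs=1e-6)

    def test_empty_inputs(self):
        table = replicate_consensus(_peaklist([]), _peaklist([], rep="r2"))
        assert len(table) == 0

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_symmetric_in_replicate_order(self, seed):
        rng = np.random.default_rng(seed)
        a = _peaklist(np.sort(rng.uniform(50, 1000, 15)), rng.lognormal(8, 1, 15))
        b = _peaklist(
            np.sort(rng.uniform(50, 1000, 12)), rng.lognormal(8, 1, 12), rep="r2"
        )
        ab = replicate_consensus(a, b)
        ba = replicate_consensus(b, a)
        np.testing.assert_allclose(np.sort(ab.consensus_mz), np.sort(ba.consensus_mz))

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_matches_optimal_assignment_on_separated_ions(self, seed):
        """Pairs at ~3 ppm offsets, clusters well separated: greedy == optimal."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 10)
        centers = np.sort(rng.uniform(100, 900, n))
        while n > 1 and np.min(np.diff(centers)) < 1.0:
            centers = np.sort(rng.uniform(100, 900, n))
        mz_a = centers * (1 + rng.normal(0, 1.0, n) * 1e-6)
        mz_b = centers * (1 + rng.normal(0, 1.0, n) * 1e-6)
        a = _peaklist(np.sort(mz_a))
        b = _peaklist(np.sort(mz_b), rep="r2")
        table = replicate_consensus(a, b, match_tol_ppm=5)
        assert table.source_indices == _optimal_pairing(a.mz, b.mz, 5)

    def test_three_replicates_require_presence_in_all(self):
        a = _peaklist([100.0, 250.0, 600.0])
        b = _peaklist([100.0, 250.0], rep="r2")
        c = _peaklist([100.0, 600.0], rep="r3")
        table = multi_replicate_consensus([a, b, c])
        assert table.consensus_mz.tolist() == [100.0]
        assert table.intensities.shape == (1, 3)
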