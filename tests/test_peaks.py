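"""Peak caller: width estimation, kernel properties, detection, merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpr import (
    CoverageSimConfig,
    CoverageTrack,
    DEFAULT_OPERATOR_CONSENSUS,
    PeakCallConfig,
    RickerPeakCaller,
    build_kernel,
    call_peaks,
    convolve_track,
    estimate_expected_width,
    gen_genome,
    normalize_and_merge,
    plant_sites,
    simulate_coverage,
)
from mrpr.exceptions import (
    DegenerateBackgroundError,
    InputError,
    NoCandidatePeakError,
)


def rect_track(length=1000, background=2.0, bumps=((100, 20, 30.0), (500, 30, 30.0))):
    v = np.full(length, background)
    for start, span, height in bumps:
        v[start : start + span] = height
    return CoverageTrack(contig="c", values=v)


class TestExpectedWidth:
    def test_two_rectangular_bumps_median(self):
        # mean = (2*950 + 30*50)/1000 = 3.4, threshold 10.2; widths 20, 30
        track = rect_track()
        assert track.values.mean() == pytest.approx(3.4)
        assert estimate_expected_width(track, 3.0) == 25

    def test_exact_rectangle_width_single_bump(self):
        for span in (7, 20, 111):
            track = rect_track(bumps=((300, span, 40.0),))
            assert estimate_expected_width(track, 3.0) == span

    def test_constant_track_raises(self):
        with pytest.raises(NoCandidatePeakError):
            estimate_expected_width(CoverageTrack("c", np.full(500, 5.0)), 3.0)

    def test_triangular_bump_matches_brute_force(self):
        v = np.full(2000, 1.0)
        apex, half_span, height = 1000, 60, 80.0
        for i in range(-half_span, half_span + 1):
            v[apex + i] = max(1.0, height * (1 - abs(i) / half_span))
        track = CoverageTrack("c", v)

        # independent linear scan oracle
        half = v[apex] / 2.0
        left = apex
        while v[left] >= half:
            left -= 1
        right = apex
        while v[right] >= half:
            right += 1
        assert estimate_expected_width(track, 3.0) == right - left - 1


class TestKernel:
    def test_support_and_sigma(self):
        k = build_kernel(10)
        assert k.sigma == 5.0
        assert k.support == 2 * int(np.ceil(4 * 5.0)) + 1 == 41

    @given(st.integers(min_value=2, max_value=400))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_zero_sum_and_symmetry(self, width):
        k = build_kernel(width)
        assert abs(k.weights.sum()) < 1e-12
        assert np.allclose(k.weights, k.weights[::-1])
        assert k.weights.argmax() == k.half_width  # positive at center

    def test_ricker_zero_crossings_at_sigma(self):
        width = 50
        k = build_kernel(width)
        sigma = width / 2
        x = np.arange(-k.half_width, k.half_width + 1)
        raw = (1 - (x / sigma) ** 2) * np.exp(-(x**2) / (2 * sigma**2))
        sign_changes = x[np.flatnonzero(np.diff(np.sign(raw)))]
        assert np.all(np.abs(np.abs(sign_changes) - sigma) <= 1.0)

    def test_too_narrow_raises(self):
        with pytest.raises(InputError):
            build_kernel(1)


class TestConvolution:
    def test_constant_track_zero_response(self):
        k = build_kernel(30)
        track = CoverageTrack("c", np.full(5000, 123.0))
        resp = convolve_track(track, k)
        assert np.max(np.abs(resp)) < 1e-9

    def test_unit_impulse_response(self):
        k = build_kernel(20)
        v = np.zeros(2001)
        v[1000] = 1.0
        resp = convolve_track(CoverageTrack("c", v), k)
        assert resp.argmax() == 1000
        assert resp[1000] == pytest.approx(k.weights[k.half_width])

    def test_linearity(self, rng):
        k = build_kernel(16)
        a = rng.poisson(5.0, 1500).astype(float)
        b = rng.poisson(9.0, 1500).astype(float)
        ra = convolve_track(CoverageTrack("c", a), k)
        rb = convolve_track(CoverageTrack("c", b), k)
        rab = convolve_track(CoverageTrack("c", a + b), k)
        assert np.allclose(rab, ra + rb)

    def test_kernel_longer_than_track_raises(self):
        with pytest.raises(InputError):
            convolve_track(CoverageTrack("c", np.ones(10)), build_kernel(30))


def gaussian_bump_track(length=20_000, center=10_000, depth=50.0, enr=20.0, sd=75.0):
    x = np.arange(length, dtype=float)
    v = depth * (1 + enr * np.exp(-((x - center) ** 2) / (2 * sd**2)))
    return CoverageTrack("c", v)


class TestCallPeaks:
    def test_flat_track_no_peaks(self):
        k = build_kernel(50)
        assert call_peaks(CoverageTrack("c", np.full(3000, 8.0)), k) == []

    def test_single_gaussian_bump_summit_accuracy(self):
        track = gaussian_bump_track()
        width = estimate_expected_width(track, 3.0)
        kernel = build_kernel(width)
        peaks = call_peaks(track, kernel)
        assert len(peaks) == 1
        # brute-force argmax oracle on the noise-free track
        assert abs(peaks[0].summit - track.values.argmax()) <= 2
        assert peaks[0].conv_score > 0
        assert peaks[0].start <= peaks[0].summit < peaks[0].end

    def test_ten_planted_sites_noise_free(self):
        g = gen_genome(130_000, 0.44, seed=1)
        positions = [5000 + 12_500 * i for i in range(10)]
        g = plant_sites(g, DEFAULT_OPERATOR_CONSENSUS, positions)
        cfg = CoverageSimConfig(mean_depth=50.0, enrichment=20.0, noise="none", seed=0)
        (track,) = simulate_coverage(g, cfg)
        caller = RickerPeakCaller().fit(track)
        peaks = caller.predict(track)
        assert len(peaks) == 10
        centers = np.array([s.center for s in g.planted_sites])
        for p in peaks:
            assert np.min(np.abs(centers - p.summit)) <= 2
        # no peak farther than 4 sigma from any planted site
        sigma = caller.expected_width_ / 2
        for p in peaks:
            assert np.min(np.abs(centers - p.summit)) <= 4 * sigma

    def test_determinism(self):
        track = gaussian_bump_track()
        k = build_kernel(150)
        p1 = call_peaks(track, k)
        p2 = call_peaks(track, k)
        assert [(p.summit, p.start, p.end) for p in p1] == [
            (p.summit, p.start, p.end) for p in p2
        ]

    def test_constant_offset_invariance(self):
        """Adding constant background changes no summit position."""
        track = gaussian_bump_track(depth=50.0)
        k = build_kernel(150)
        shifted = CoverageTrack("c", track.values + 500.0)
        s1 = [p.summit for p in call_peaks(track, k, PeakCallConfig(threshold_mult=0.1))]
        s2 = [p.summit for p in call_peaks(shifted, k, PeakCallConfig(threshold_mult=0.1))]
        assert s1 == s2

    def test_min_score_filter(self):
        track = gaussian_bump_track()
        k = build_kernel(150)
        (peak,) = call_peaks(track, k)
        assert call_peaks(track, k, PeakCallConfig(min_score=peak.conv_score * 2)) == []


class TestNormalizeAndMerge:
    def test_hand_computed_normalization(self):
        # one peak with raw intensity 1000 on a track totalling 101,000:
        # C = 100,000 and the normalized intensity is 1000/C * 1e6 = 10,000
        from mrpr.peaks import Peak

        track2 = CoverageTrack("c", np.full(2000, 50.0))
        peak = Peak("c", 480, 500, 490, raw_intensity=1000.0, conv_score=5.0)
        track2.values[0] += 101_000 - track2.values.sum()
        merged = normalize_and_merge([[peak]], [track2], overlap_tol=10)
        assert merged[0].normalized_intensity == pytest.approx(1000 / 100_000 * 1e6)

    def test_scale_invariance(self):
        track = gaussian_bump_track()
        k = build_kernel(150)
        peaks = call_peaks(track, k)
        doubled = CoverageTrack("c", track.values * 2)
        peaks2 = call_peaks(doubled, k)
        m1 = normalize_and_merge([peaks], [track], overlap_tol=75)
        m2 = normalize_and_merge([peaks2], [doubled], overlap_tol=75)
        assert m1[0].normalized_intensity == pytest.approx(
            m2[0].normalized_intensity, rel=1e-9
        )

    def test_two_identical_replicates_support(self):
        track = gaussian_bump_track()
        k = build_kernel(150)
        t1 = CoverageTrack("c", track.values, replicate=1)
        t2 = CoverageTrack("c", track.values, replicate=2)
        merged = normalize_and_merge(
            [call_peaks(t1, k), call_peaks(t2, k)], [t1, t2], overlap_tol=75
        )
        assert all(p.n_replicates == 2 for p in merged)

    def test_literal_normalization_mode(self):
        from mrpr.peaks import Peak

        track = CoverageTrack("c", np.full(1000, 101.0))
        peak = Peak("c", 10, 20, 15, raw_intensity=1000.0, conv_score=1.0)
        (m,) = normalize_and_merge([[peak]], [track], 10, normalization="literal")
        assert m.normalized_intensity == pytest.approx((101_000 - 1000) / 1000)

    def test_degenerate_background_raises(self):
        from mrpr.peaks import Peak

        track = CoverageTrack("c", np.full(100, 1.0))
        peak = Peak("c", 0, 100, 50, raw_intensity=100.0, conv_score=1.0)
        with pytest.raises(DegenerateBackgroundError):
            normalize_and_merge([[peak]], [track], 10)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        caller = RickerPeakCaller(threshold_mult=2.5, fixed_width=99)
        params = caller.get_params()
        clone = RickerPeakCaller().set_params(**params)
        assert clone.threshold_mult == 2.5 and clone.fixed_width == 99

    def test_fixed_width_bypasses_estimation(self):
        track = CoverageTrack("c", np.full(1000, 3.0))  # no candidates
        caller = RickerPeakCaller(fixed_width=40).fit(track)
        assert caller.expected_width_ == 40
        assert caller.predict(track) == []
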