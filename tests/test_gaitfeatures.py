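"""Gait events, stride timing and the five signal features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import detrend as scipy_detrend

from frontgait.exceptions import (
    DegenerateSignalError,
    InputError,
    InsufficientEventsError,
)
from frontgait.gaitfeatures import (
    GaitEventSeries,
    GaitFeatureExtractor,
    avg_stride_time,
    centroid_variability,
    detect_events,
    dfa_alpha,
    entropy,
    extract_features,
    spectral_centroids,
    stride_phases,
    valley_peak_time,
)
from frontgait.heightsignal import WalkSegments
from frontgait.synthetic import GaitProfile, simulate_height_signal

from conftest import make_signal


def quantized_staircase(plateaus, partition_size=5, fps=25.0):
    """Piecewise-constant signal with one plateau per partition."""
    return make_signal(np.repeat(plateaus, partition_size), stage="quantized", fps=fps)


# ---------------------------------------------------------------------------
# reference DFA used as an independent oracle (distinct implementation path:
# scipy linear detrend per box, explicit loops, per-size sqrt of pooled MSE)
# ---------------------------------------------------------------------------

def reference_dfa(x, box_size=5):
    x = np.asarray(x, float)
    n = len(x)
    y = np.cumsum(x - np.mean(x))
    sizes, flucts = [], []
    size = box_size
    while size <= n // 4:
        squares = []
        for start in range(0, n - size + 1, size):
            box = y[start : start + size]
            squares.extend(scipy_detrend(box, type="linear") ** 2)
        sizes.append(size)
        flucts.append(np.sqrt(np.mean(squares)))
        size += box_size
    coeffs = np.polyfit(np.log(sizes), np.log(flucts), 1)
    return coeffs[0]


def colored_noise(exponent, n, rng):
    """Gaussian noise with power spectrum ~ 1/f**exponent (0=white, 1=pink)."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    spectrum[1:] = spectrum[1:] * freqs[1:] ** (-exponent / 2)
    spectrum[0] = 0
    return np.fft.irfft(spectrum, n)


class TestDetectEvents:
    def test_rising_plateaus_produce_timestamps(self):
        events = detect_events(quantized_staircase([0.0, 0.1, 0.1, 0.2]))
        np.testing.assert_allclose(events.timestamps_s, [0.2, 0.6])

    def test_staircase_of_six_rises_gives_six_events(self):
        plateaus = []
        for level in np.linspace(0, 1, 7):
            plateaus.extend([level, level])  # hold each level for two partitions
        events = detect_events(quantized_staircase(plateaus))
        assert len(events) == 6

    def test_constant_signal_raises(self):
        with pytest.raises(InsufficientEventsError):
            detect_events(quantized_staircase([0.5] * 8))

    def test_decreasing_plateaus_emit_no_events(self):
        with pytest.raises(InsufficientEventsError):
            detect_events(quantized_staircase([1.0, 0.8, 0.6, 0.4]))

    def test_smeared_rise_counts_once(self):
        # one physical rise whose ramp straddles a partition: the intermediate
        # plateau must not create a second event
        events = detect_events(quantized_staircase([0.0, 0.0, 0.04, 0.2, 0.2, 0.5, 0.5]))
        np.testing.assert_allclose(events.timestamps_s, [0.6, 1.0])

    def test_sub_threshold_noise_ignored(self):
        events = detect_events(quantized_staircase([0.0, 0.004, 0.0, 0.3, 0.296, 0.3, 0.6]))
        np.testing.assert_allclose(events.timestamps_s, [0.6, 1.2])


class TestStridePhases:
    @pytest.mark.parametrize(
        "timestamps, stance, swing, strides",
        [
            ([0.0, 0.4, 0.88], [0.4], [0.48], [0.88]),
            ([0.0, 0.4, 0.9, 1.3, 1.8], [0.4, 0.4], [0.5, 0.5], [0.9, 0.9]),
            ([0.0, 0.4, 0.9, 1.3], [0.4], [0.5], [0.9]),  # unpaired tail dropped
        ],
    )
    def test_alternating_interval_pairing(self, timestamps, stance, swing, strides):
        phases = stride_phases(GaitEventSeries(np.array(timestamps)))
        np.testing.assert_allclose(phases.stance_times_s, stance)
        np.testing.assert_allclose(phases.swing_times_s, swing)
        np.testing.assert_allclose(phases.stride_times_s, strides)
        np.testing.assert_allclose(
            phases.stride_times_s, phases.stance_times_s + phases.swing_times_s
        )

    def test_too_few_events_raises(self):
        with pytest.raises(InsufficientEventsError):
            stride_phases(GaitEventSeries(np.array([0.0, 0.4])))

    def test_average_stride_time(self):
        phases = stride_phases(GaitEventSeries(np.array([0.0, 0.4, 1.0, 1.5, 2.2])))
        assert avg_stride_time(phases) == pytest.approx((1.0 + 1.2) / 2)


class TestDfa:
    def test_known_noise_classes(self, rng):
        assert 0.4 <= dfa_alpha(rng.standard_normal(2000)) <= 0.6
        assert 1.3 <= dfa_alpha(np.cumsum(rng.standard_normal(2000))) <= 1.7
        assert dfa_alpha(colored_noise(1.0, 2000, rng)) == pytest.approx(1.0, abs=0.15)

    def test_agrees_with_independent_reference(self, rng):
        """Implementation and the scipy-detrend reference oracle agree within
        0.05 on 21 series spanning the white / 1-over-f / Brownian regimes."""
        for exponent in (0.0, 1.0, 2.0):
            for _ in range(7):
                x = colored_noise(exponent, 2000, rng)
                assert dfa_alpha(x) == pytest.approx(reference_dfa(x), abs=0.05)

    def test_too_short_raises(self):
        with pytest.raises(InputError):
            dfa_alpha(np.arange(30.0))

    def test_constant_signal_raises(self):
        with pytest.raises(DegenerateSignalError):
            dfa_alpha(np.full(400, 2.0))


class TestEntropy:
    @pytest.mark.parametrize(
        "values, expected",
        [([0.5, 0.5], 1.0), ([1.0], 0.0), ([0.0, 1.0], 0.0)],
    )
    def test_closed_form_values(self, values, expected):
        assert entropy(np.array(values)) == pytest.approx(expected)

    @given(st.permutations(list(np.linspace(0.05, 1.0, 8))))
    def test_permutation_invariant(self, values):
        baseline = entropy(np.linspace(0.05, 1.0, 8))
        assert entropy(np.array(values)) == pytest.approx(baseline)

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(InputError):
            entropy(np.array([0.5, 1.2]))


class TestSpectralCentroids:
    def test_constant_box_has_zero_centroid(self):
        c = spectral_centroids(np.full(5, 3.3), box_n=5, fps=25.0)
        np.testing.assert_allclose(c, [0.0], atol=1e-12)

    def test_single_cycle_sinusoid_centroid(self):
        # one cycle at fps/box_n = 5 Hz; oracle: direct 5-point DFT by hand
        box = np.cos(2 * np.pi * np.arange(5) / 5)
        mags = np.abs([np.sum(box * np.exp(-2j * np.pi * k * np.arange(5) / 5)) for k in range(3)])
        freqs = np.array([0.0, 5.0, 10.0])
        expected = (mags * freqs).sum() / mags.sum()
        got = spectral_centroids(box, box_n=5, fps=25.0)[0]
        assert got == pytest.approx(expected)
        assert got == pytest.approx(5.0, abs=0.5)  # energy concentrated at 5 Hz

    def test_centroids_bounded_by_nyquist(self, rng):
        c = spectral_centroids(rng.random(100), box_n=5, fps=25.0)
        assert len(c) == 20
        assert (c >= 0).all() and (c <= 12.5).all()

    def test_small_box_raises(self):
        with pytest.raises(InputError):
            spectral_centroids(np.arange(10.0), box_n=1, fps=25.0)


class TestCentroidVariability:
    @pytest.mark.parametrize(
        "centroids, absolute, expected",
        [
            ([2.0, 2.0, 2.0], False, 0.0),
            ([1.0, 2.0, 3.0], False, 2 / 3),
            ([3.0, 2.0, 1.0], False, -2 / 3),
            ([3.0, 2.0, 1.0], True, 2 / 3),
        ],
    )
    def test_mean_consecutive_difference(self, centroids, absolute, expected):
        assert centroid_variability(centroids, absolute=absolute) == pytest.approx(expected)

    def test_single_centroid_raises(self):
        with pytest.raises(InputError):
            centroid_variability([1.0])


class TestValleyPeakTime:
    def test_frame_distance_in_seconds(self):
        values = np.zeros(251)
        values[250] = 1.0
        assert valley_peak_time(values, fps=25.0) == pytest.approx(10.0)

    def test_adjacent_extrema(self):
        assert valley_peak_time(np.array([1.0, 0.0, 0.5]), fps=25.0) == pytest.approx(0.04)

    def test_constant_raises(self):
        with pytest.raises(DegenerateSignalError):
            valley_peak_time(np.ones(10), fps=25.0)

    def test_slow_walk_has_larger_t_than_fast_walk(self):
        extractor = GaitFeatureExtractor()
        t = {}
        for name, dur, cad in (("fast", 5.5, 1.15), ("slow", 13.0, 0.55)):
            profile = GaitProfile(
                label=0, cadence_strides_per_s=cad, step_amplitude=1.0,
                forward_duration_s=dur, noise_sd=0.01,
            )
            walk = simulate_height_signal(profile, seed=2)
            t[name] = extractor.extract_one(walk.series).T
        assert t["slow"] > t["fast"]


class TestExtractFeatures:
    def test_healthy_profile_yields_complete_vector(self):
        profile = GaitProfile(label=0, cadence_strides_per_s=1.0, step_amplitude=1.0)
        walk = simulate_height_signal(profile, seed=0)
        fv = GaitFeatureExtractor().extract_one(walk.series, label=0)
        assert fv.is_complete
        assert fv.label == 0
        assert fv.S_avg > 0 and fv.T > 0 and fv.E > 0

    def test_constant_signal_yields_flagged_incomplete_vector(self):
        from conftest import make_series

        series = make_series([100.0] * 50, faces=[16.0] * 50)
        fv = GaitFeatureExtractor().extract_one(series)
        assert not fv.is_complete
        assert any("Degenerate" in f for f in fv.flags)

    def test_class_profiles_order_completion_time(self):
        extractor = GaitFeatureExtractor()
        from frontgait.synthetic import profile_for_label

        ts = []
        for label in (0, 1, 2):
            walk = simulate_height_signal(
                profile_for_label(label, np.random.default_rng(11)), seed=4
            )
            ts.append(extractor.extract_one(walk.series).T)
        assert ts[0] < ts[1] < ts[2]

    def test_event_timestamps_shift_invariant(self):
        """Adding a constant to the raw heights changes nothing downstream of
        normalization, so event timestamps are unchanged."""
        from conftest import make_series

        profile = GaitProfile(label=0, cadence_strides_per_s=0.9, step_amplitude=1.0)
        walk = simulate_height_signal(profile, seed=6)
        heights = walk.series.person_heights()
        faces = walk.series.face_heights()
        extractor = GaitFeatureExtractor()
        base = extractor.extract_one(make_series(list(heights), faces=list(faces)))
        shifted = extractor.extract_one(make_series(list(heights + 30.0), faces=list(faces)))
        # S_avg is a deterministic function of the event timestamps
        assert shifted.S_avg == pytest.approx(base.S_avg)
        assert shifted.T == pytest.approx(base.T)

    def test_cadence_recovery_within_ten_percent(self):
        """Mean recovered stride time matches 1/cadence within 10% across
        seeds for cadences spanning the clinical range."""
        extractor = GaitFeatureExtractor()
        for cadence in (0.5, 0.8, 1.2):
            errors = []
            for seed in range(10):
                profile = GaitProfile(
                    label=0, cadence_strides_per_s=cadence, step_amplitude=1.0,
                    amplitude_jitter=0.05, cadence_jitter=0.05, noise_sd=0.01,
                    forward_duration_s=max(8.0, 12.0 / cadence),
                )
                walk = simulate_height_signal(profile, seed=seed)
                fv = extractor.extract_one(walk.series)
                errors.append(abs(fv.S_avg - 1.0 / cadence) * cadence)
            assert np.mean(errors) <= 0.10

    def test_forward_segment_option(self):
        profile = GaitProfile(label=0, cadence_strides_per_s=1.0, step_amplitude=1.0)
        walk = simulate_height_signal(profile, seed=1)
        full = GaitFeatureExtractor(feature_segment="full").extract_one(walk.series)
        fwd = GaitFeatureExtractor(feature_segment="forward").extract_one(walk.series)
        assert fwd.is_complete
        assert fwd.E < full.E  # entropy sums over roughly half the frames
        assert fwd.S_avg == pytest.approx(full.S_avg)  # events always forward-only
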