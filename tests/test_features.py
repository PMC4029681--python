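"""Feature extraction: energies, tonality, peaks, entropy, crest models, tracking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheezekit.audio_io import frame_segments
from wheezekit.features import (
    CrestSet,
    PeakSet,
    EnergyHistory,
    EntropyPair,
    TonalityState,
    detect_crests_energy,
    detect_crests_moments,
    entropy_ratio,
    find_spectral_peaks,
    peak_entropy,
    segment_energy,
    tonal_index,
    update_crest_tracks,
)
from wheezekit.spectral import BandSelection, stft_frames

from conftest import make_frame


class TestEnergy:
    def test_zero_and_constant(self, band57):
        frame = make_frame(np.zeros(257))
        assert segment_energy(frame, band57) == 0.0
        frame = make_frame(np.ones(257))
        assert segment_energy(frame, band57) == 57.0

    def test_random_equals_direct_sum(self, band57, rng):
        p = rng.random(257)
        frame = make_frame(p)
        brute = sum(p[k] for k in range(band57.k_lo, band57.k_hi + 1))
        assert segment_energy(frame, band57) == pytest.approx(brute, rel=1e-12)

    def test_history_bounds(self):
        h = EnergyHistory(3)
        h.push(5); h.push(1); h.push(4)
        assert h.bounds() == (1, 5)
        h2 = EnergyHistory(10)
        h2.push(3)
        assert h2.bounds() == (3, 3)

    def test_history_sliding_window_oracle(self, rng):
        h = EnergyHistory(10)
        values = list(rng.random(100))
        for i, v in enumerate(values):
            h.push(v)
            window = values[max(0, i - 9) : i + 1]
            assert h.bounds() == (min(window), max(window))

    def test_empty_history_errors(self):
        with pytest.raises(RuntimeError):
            EnergyHistory(5).bounds()


class TestTonality:
    """T = log2(E_w / E): near the floor for predictable tones, near 0 for noise."""

    def _frames(self, rec, band):
        return stft_frames(rec, n=512, overlap=0.5, need_phase=True), band

    def test_exact_complex_tone_hits_floor(self):
        # constant amplitude, linear phase ramp: prediction error is exactly 0,
        # so T collapses to the clamp floor
        from wheezekit.features import T_FLOOR
        from wheezekit.spectral import SpectrumFrame

        band = BandSelection(0, 9)
        a = np.full(10, 2.0)

        def frame(m):
            phi = np.angle(np.exp(1j * (0.3 + 1.1 * m) * np.ones(10)))
            x = a * np.exp(1j * phi)
            return SpectrumFrame(m=m, X=x, P=a**2, A=a, Phi=phi, bin_hz=15.625)

        state = TonalityState()
        state.push(frame(0).A, frame(0).Phi)
        state.push(frame(1).A, frame(1).Phi)
        assert tonal_index(frame(2), state, band) == T_FLOOR

    def test_real_tone_deeply_tonal(self, tone_recording):
        # a real windowed tone carries twin-phasor leakage, so T does not reach
        # the floor, but stays far below anything noise produces
        band = BandSelection(4, 60)
        frames = stft_frames(tone_recording, need_phase=True)
        state = TonalityState()
        sl = band.sl
        state.push(frames[0].A[sl], frames[0].Phi[sl])
        state.push(frames[1].A[sl], frames[1].Phi[sl])
        t = tonal_index(frames[2], state, band)
        assert t < -5.0

    def test_all_zero_spectra_give_zero(self, band57):
        z = make_frame(np.zeros(257))
        state = TonalityState()
        state.push(z.A[band57.sl], z.Phi[band57.sl])
        state.push(z.A[band57.sl], z.Phi[band57.sl])
        assert tonal_index(z, state, band57) == 0.0

    def test_tone_more_tonal_than_noise(self, tone_recording, noise_recording):
        band = BandSelection(4, 60)

        def median_t(rec):
            frames = stft_frames(rec, need_phase=True)
            state = TonalityState()
            out = []
            for f in frames:
                if state.primed:
                    out.append(tonal_index(f, state, band))
                state.push(f.A[band.sl], f.Phi[band.sl])
            return float(np.median(out))

        t_tone, t_noise = median_t(tone_recording), median_t(noise_recording)
        assert t_tone < t_noise
        assert t_noise > -3.0  # noise is unpredictable: T stays near zero

    def test_unprimed_state_errors(self, band57):
        frame = make_frame(np.ones(257))
        with pytest.raises(RuntimeError):
            tonal_index(frame, TonalityState(), band57)


class TestPeaks:
    def test_hand_case(self):
        band = BandSelection(0, 4)
        frame = make_frame(np.array([1.0, 3.0, 2.0, 5.0, 4.0]))
        peaks = find_spectral_peaks(frame, band)
        np.testing.assert_array_equal(peaks.k_peak, [1, 3])
        np.testing.assert_array_equal(peaks.p_peak, [3.0, 5.0])

    @pytest.mark.parametrize("p", [np.arange(1.0, 6.0), np.full(5, 2.0)])
    def test_ramp_and_constant_have_no_peaks(self, p):
        assert find_spectral_peaks(make_frame(p), BandSelection(0, 4)).n_p == 0

    def test_matches_exhaustive_scan(self, band57, rng):
        for _ in range(20):
            p = rng.random(257)
            peaks = find_spectral_peaks(make_frame(p), band57)
            brute = [
                k
                for k in range(band57.k_lo + 1, band57.k_hi)
                if p[k] > p[k - 1] and p[k] > p[k + 1]
            ]
            np.testing.assert_array_equal(peaks.k_peak, brute)

    def test_narrow_band_rejected(self):
        with pytest.raises(ValueError):
            find_spectral_peaks(make_frame(np.ones(10)), BandSelection(0, 1))


class TestEntropy:
    def test_single_peak_is_zero(self):
        ps = PeakSet(k_peak=np.array([5]), p_peak=np.array([3.0]))
        assert peak_entropy(ps) == 0.0

    def test_equal_peaks_saturate_log2_n(self):
        for n in (2, 4, 8):
            ps = PeakSet(k_peak=np.arange(n), p_peak=np.full(n, 2.5))
            assert peak_entropy(ps) == pytest.approx(np.log2(n), abs=1e-12)

    def test_half_quarter_quarter(self):
        ps = PeakSet(k_peak=np.arange(3), p_peak=np.array([2.0, 1.0, 1.0]))
        assert peak_entropy(ps) == pytest.approx(1.5, abs=1e-12)

    def test_empty_or_massless_is_zero(self):
        assert peak_entropy(PeakSet(k_peak=np.array([]), p_peak=np.array([]))) == 0.0
        assert peak_entropy(PeakSet(k_peak=np.array([1]), p_peak=np.array([0.0]))) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=30))
    def test_bounded_by_log2_n(self, mags):
        ps = PeakSet(k_peak=np.arange(len(mags)), p_peak=np.array(mags))
        en = peak_entropy(ps)
        assert -1e-9 <= en <= np.log2(len(mags)) + 1e-9

    def test_ratio(self):
        assert entropy_ratio(EntropyPair(2.0, 2.0)) == 1.0
        assert entropy_ratio(EntropyPair(1.0, 2.0)) == 0.5
        assert np.isnan(entropy_ratio(EntropyPair(1.0, 0.0)))  # sentinel


class TestCrestMoments:
    def test_hand_arithmetic(self):
        # band values {1,1,1,10,1,1,1}: mean 15/7, population stdev ~3.248,
        # threshold 1.5*mean + 1.0*stdev ~ 6.46 < 10 -> crest accepted
        p = np.ones(64)
        p[10] = 10.0
        band = BandSelection(0, 63)
        frame = make_frame(p)
        peaks = find_spectral_peaks(frame, band)
        assert list(peaks.k_peak) == [10]
        crests = detect_crests_moments(frame, peaks, band, b_crest=6, c_m=1.5, c_s=1.0)
        assert list(crests.k_crest) == [10]
        # raise c_m so the threshold exceeds the peak -> rejected
        none = detect_crests_moments(frame, peaks, band, b_crest=6, c_m=4.0, c_s=1.0)
        assert none.n_c == 0

    def test_zero_thresholds_accept_all_peaks(self, band57, rng):
        p = rng.random(257) + 0.1
        frame = make_frame(p)
        peaks = find_spectral_peaks(frame, band57)
        crests = detect_crests_moments(frame, peaks, band57, b_crest=6, c_m=0.0, c_s=0.0)
        np.testing.assert_array_equal(crests.k_crest, peaks.k_peak)

    def test_subset_of_peaks(self, band57, rng):
        for _ in range(10):
            frame = make_frame(rng.random(257))
            peaks = find_spectral_peaks(frame, band57)
            crests = detect_crests_moments(frame, peaks, band57, 6, 1.5, 1.0)
            assert set(crests.k_crest).issubset(set(peaks.k_peak))

    def test_odd_width_rejected(self, band57):
        frame = make_frame(np.ones(257))
        with pytest.raises(ValueError):
            detect_crests_moments(frame, find_spectral_peaks(frame, band57), band57, b_crest=5)


class TestCrestEnergy:
    def test_hand_arithmetic(self):
        # crest (3 bins) energy 100; narrow annulus 10; wide annulus 40
        # ratios 10 and 2.5 exceed 1.2 and 1.5 -> accepted
        p = np.zeros(257)
        k = 30
        p[k - 1 : k + 2] = [30.0, 40.0, 30.0]
        p[[k - 3, k - 2, k + 2, k + 3]] = 2.5  # narrow annulus (half-width 3 bins)
        p[[k - 4, k + 4]] = 15.0  # remainder of the wide annulus (half-width 4)
        band = BandSelection(4, 60)
        frame = make_frame(p)  # bin_hz 15.625 -> half_n=3, half_w=4
        peaks = find_spectral_peaks(frame, band)
        crests = detect_crests_energy(
            frame, peaks, band, b_crest=2, b_narrow_hz=80, b_wide_hz=120,
            c_narrow=1.2, c_wide=1.5,
        )
        assert k in crests.k_crest
        # demand more dominance than the wide ratio 2.5 delivers -> rejected
        crests = detect_crests_energy(
            frame, peaks, band, b_crest=2, b_narrow_hz=80, b_wide_hz=120,
            c_narrow=1.2, c_wide=3.0,
        )
        assert k not in crests.k_crest

    def test_flat_spectrum_rejected(self, band57):
        # constant spectrum: crest/annulus energy ratio = bin-count ratio < 1
        p = np.full(257, 3.0)
        p[30] = 3.0001  # a barely-there peak so the peak finder fires
        frame = make_frame(p)
        peaks = find_spectral_peaks(frame, band57)
        assert peaks.n_p == 1
        crests = detect_crests_energy(frame, peaks, band57, c_narrow=1.0, c_wide=1.0)
        assert crests.n_c == 0

    def test_tone_on_silence_accepted(self, band57):
        p = np.zeros(257)
        p[30] = 5.0
        frame = make_frame(p)
        peaks = find_spectral_peaks(frame, band57)
        crests = detect_crests_energy(frame, peaks, band57)
        assert list(crests.k_crest) == [30]

    def test_band_ordering_precondition(self, band57):
        frame = make_frame(np.ones(257))
        peaks = find_spectral_peaks(frame, band57)
        with pytest.raises(ValueError):
            detect_crests_energy(frame, peaks, band57, b_crest=8, b_narrow_hz=80, b_wide_hz=120)


def _crests(*bins):
    k = np.asarray(bins, dtype=int)
    return CrestSet(k_crest=k, p_crest=np.ones(k.size))


class TestCrestTracking:
    C = [3.0, 3.0, 3.0, 3.0]

    def test_steady_crest_accumulates_duration(self):
        tracks = []
        for _ in range(5):
            tracks = update_crest_tracks(tracks, _crests(20), 4, self.C)
        assert len(tracks) == 1
        assert tracks[0].duration == 5
        assert tracks[0].deviations(4) == [0, 0, 0, 0]
        assert tracks[0].is_continuous(4, self.C)

    def test_jump_kills_and_respawns(self):
        tracks = update_crest_tracks([], _crests(20), 4, self.C)
        tracks = update_crest_tracks(tracks, _crests(20), 4, self.C)
        tracks = update_crest_tracks(tracks, _crests(30), 4, self.C)  # 10-bin jump
        assert len(tracks) == 1
        assert tracks[0].current_bin == 30 and tracks[0].duration == 1

    def test_equal_distance_tie_resolved_lowest_frequency_first(self):
        tracks = update_crest_tracks([], _crests(12), 4, self.C)
        tracks = update_crest_tracks(tracks, _crests(10, 14), 4, self.C)
        by_bin = {t.current_bin: t for t in tracks}
        assert by_bin[10].duration == 2  # lower-frequency crest won the track
        assert by_bin[14].duration == 1

    def test_slow_chirp_keeps_one_track(self):
        # drift of <= 1 bin per segment, within the 3-bin continuity threshold
        bins = [20 + i // 2 for i in range(12)]
        tracks = []
        for b in bins:
            tracks = update_crest_tracks(tracks, _crests(b), 4, self.C)
        assert len(tracks) == 1
        assert tracks[0].duration == len(bins)
        assert tracks[0].is_continuous(4, self.C)

    def test_empty_crests_kill_all(self):
        tracks = update_crest_tracks([], _crests(20, 40), 4, self.C)
        tracks = update_crest_tracks(tracks, _crests(), 4, self.C)
        assert tracks == []


def test_frames_pipeline_smoke(tone_recording):
    """frame -> analyze -> peaks finds the 400 Hz tone at the right bin."""
    frames = stft_frames(tone_recording)
    band = BandSelection(4, 60)
    peaks = find_spectral_peaks(frames[10], band)
    strongest = peaks.k_peak[int(np.argmax(peaks.p_peak))]
    assert abs(strongest * frames[10].bin_hz - 400.0) <= frames[10].bin_hz
    assert len(frames) == len(frame_segments(tone_recording, 512, 0.5))
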