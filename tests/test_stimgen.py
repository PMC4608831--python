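"""Stimulus synthesis and chirp quantification."""

import math

import numpy as np
import pytest

from chirpinv.stimgen import (
    ChirpSpec,
    beat_phase_at,
    chirp_attributes,
    instantaneous_frequency,
    phase_uniformity_test,
    similarity_metric,
    synthesize_dyad_signal,
)


def _small(onset=350.0, phase=None, exc=50.0, sigma=6.0):
    return ChirpSpec(kind="small", freq_excursion=exc, duration_sigma=sigma,
                     onset_time=onset, beat_phase_target=phase)


class TestChirpSpec:
    def test_small_chirp_excursion_bounds_enforced(self):
        with pytest.raises(ValueError):
            ChirpSpec(kind="small", freq_excursion=200.0, duration_sigma=6.0,
                      onset_time=100.0)
        with pytest.raises(ValueError):
            ChirpSpec(kind="big", freq_excursion=100.0, duration_sigma=3.0,
                      onset_time=100.0)

    def test_small_chirp_carries_no_amplitude_dip(self):
        with pytest.raises(ValueError):
            ChirpSpec(kind="small", freq_excursion=50.0, duration_sigma=6.0,
                      onset_time=100.0, amp_dip_fraction=0.5)


class TestSynthesizeDyadSignal:
    def test_envelope_oscillates_at_beat_frequency(self):
        tr = synthesize_dyad_signal(750.0, 10.0, [], duration=1000.0, dt=0.025)
        spec = np.abs(np.fft.rfft(tr.samples - tr.samples.mean()))
        freqs = np.fft.rfftfreq(tr.samples.size, d=tr.dt * 1e-3)
        assert abs(freqs[np.argmax(spec)] - 10.0) <= 1.0

    def test_big_chirp_collapses_beat_amplitude(self):
        from scipy.signal import hilbert

        big = ChirpSpec(kind="big", freq_excursion=260.0, duration_sigma=3.0,
                        onset_time=300.0, amp_dip_fraction=0.8)
        tr = synthesize_dyad_signal(750.0, 80.0, [big], duration=600.0, dt=0.025)
        beat_amp = np.abs(hilbert(tr.samples))  # instantaneous beat amplitude
        t = tr.times
        inside = np.abs(t - 300.0) < 6.0
        outside = (np.abs(t - 300.0) > 30.0) & (t > 50.0) & (t < 550.0)
        assert beat_amp[inside].min() < 0.5 * beat_amp[outside].min()

    @pytest.mark.parametrize("target", [0.0, 90.0, 180.0, 270.0])
    def test_beat_phase_round_trip(self, target):
        tr = synthesize_dyad_signal(750.0, 10.0, [_small(phase=target)],
                                    duration=600.0, dt=0.025)
        measured = beat_phase_at(tr, 350.0, before=325.0)
        delta = (measured - target + 180.0) % 360.0 - 180.0
        assert abs(delta) < 5.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            synthesize_dyad_signal(750.0, 10.0, [], duration=100.0, dt=-1.0)
        with pytest.raises(ValueError):
            synthesize_dyad_signal(750.0, 10.0, [_small(onset=500.0)],
                                   duration=400.0, dt=0.025)


class TestInstantaneousFrequency:
    def test_pure_tone_recovered(self):
        t = np.arange(0.0, 200.0, 0.025)
        x = np.sin(2 * np.pi * 700.0 * t * 1e-3)
        _, f = instantaneous_frequency(x, 0.025)
        assert np.all(np.abs(f - 700.0) < 1.0)

    def test_gaussian_excursion_peak_recovered(self):
        from scipy.integrate import cumulative_trapezoid

        t = np.arange(0.0, 600.0, 0.025)
        fins = 700.0 + 50.0 * np.exp(-0.5 * ((t - 300.0) / 6.0) ** 2)
        phase = 2 * np.pi * cumulative_trapezoid(fins, dx=0.025e-3, initial=0.0)
        _, f = instantaneous_frequency(np.sin(phase), 0.025)
        assert abs(f.max() - 750.0) < 2.0

    def test_constant_signal_yields_empty_result(self):
        t, f = instantaneous_frequency(np.ones(1000), 0.025)
        assert t.size == 0 and f.size == 0


class TestChirpAttributes:
    @pytest.fixture()
    def freq_series(self):
        from scipy.integrate import cumulative_trapezoid

        t = np.arange(0.0, 600.0, 0.025)
        fins = 750.0 + 50.0 * np.exp(-0.5 * ((t - 350.0) / 6.0) ** 2)
        phase = 2 * np.pi * cumulative_trapezoid(fins, dx=0.025e-3, initial=0.0)
        return instantaneous_frequency(np.sin(phase), 0.025)

    def test_fwhm_matches_gaussian_analytic(self, freq_series):
        tr = synthesize_dyad_signal(750.0, 10.0, [_small(phase=180.0)],
                                    duration=600.0, dt=0.025)
        attrs = chirp_attributes(*freq_series, tr, (320.0, 380.0))
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * 6.0  # ~14.13 ms
        assert abs(attrs.duration_fwhm - expected) < 0.3
        assert abs(attrs.peak_excursion - 50.0) < 2.0

    @pytest.mark.parametrize("target", [0.0, 180.0])
    def test_phase_matches_generation_target(self, freq_series, target):
        tr = synthesize_dyad_signal(750.0, 10.0, [_small(phase=target)],
                                    duration=600.0, dt=0.025)
        attrs = chirp_attributes(*freq_series, tr, (320.0, 380.0))
        delta = (attrs.phase - target + 180.0) % 360.0 - 180.0
        assert abs(delta) < 5.0

    def test_no_excursion_raises(self, freq_series):
        t, f = freq_series
        flat = np.full_like(f, 750.0)
        tr = synthesize_dyad_signal(750.0, 10.0, [], duration=600.0, dt=0.025)
        with pytest.raises(ValueError):
            chirp_attributes(t, flat, tr, (320.0, 380.0))


class TestSimilarityMetric:
    def test_identical_waveforms_score_one(self, rng):
        x = rng.normal(size=500)
        assert similarity_metric(x, x) == pytest.approx(1.0)

    def test_constant_offset_is_ignored(self, rng):
        x = rng.normal(size=500)
        assert similarity_metric(x, x + 3.7) == pytest.approx(1.0)

    def test_antiphase_sinusoids(self):
        t = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        sm = similarity_metric(np.sin(t), -np.sin(t))
        assert sm == pytest.approx(1.0 - math.sqrt(2.0), abs=1e-3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 200))
            sm_ab = similarity_metric(a, b)
            assert sm_ab == pytest.approx(similarity_metric(b, a))
            assert sm_ab <= 1.0

    def test_two_constant_waveforms_undefined(self):
        with pytest.raises(ValueError):
            similarity_metric(np.ones(10), np.full(10, 2.0))


class TestPhaseUniformity:
    def test_uniform_phases_pass_over_many_seeds(self, rng):
        passed = 0
        for seed in range(20):
            phases = rng.uniform(0.0, 360.0, size=500)
            if phase_uniformity_test(phases, seed=seed)["uniform"]:
                passed += 1
        assert passed >= 16  # the 3-SD band admits rare false alarms

    def test_clustered_phases_rejected(self, rng):
        phases = rng.uniform(0.0, 14.0, size=500)
        assert not phase_uniformity_test(phases, seed=0)["uniform"]

    def test_surrogate_count_contract(self, rng):
        out = phase_uniformity_test(rng.uniform(0, 360, 100), n_surrogate=1000,
                                    seed=0)
        assert out["n_surrogate"] == 1000

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            phase_uniformity_test(np.array([]))
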