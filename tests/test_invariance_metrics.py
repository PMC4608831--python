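"""PSTH construction, CSI, Victor-Purpura distance, FI, bimodality,
robustness."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpinv.invariance_metrics import (
    Psth,
    bimodality_index,
    compute_psth,
    csi,
    fi,
    fi_rmse,
    rmse_avg,
    robustness,
    vpd,
    vpd_avg,
)
from chirpinv.synthetic_ell import SpikeTrainSet, generate_spike_trains


def brute_force_vpd(a, b, q_per_s):
    """Exhaustive Victor-Purpura cost over all monotone spike matchings.

    Independent oracle: every subset matching between the two trains is
    enumerated (order-preserving by optimality of sorted matchings for this
    cost), each matched pair paying q|dt| (capped at 2 by delete+insert)
    and each unmatched spike paying 1.
    """
    a, b = list(a), list(b)
    best = [math.inf]

    def rec(i, j, cost):
        if cost >= best[0]:
            return
        if i == len(a):
            best[0] = min(best[0], cost + (len(b) - j))
            return
        if j == len(b):
            best[0] = min(best[0], cost + (len(a) - i))
            return
        rec(i + 1, j + 1, cost + q_per_s * abs(a[i] - b[j]) * 1e-3)  # match
        rec(i + 1, j, cost + 1.0)  # delete a[i]
        rec(i, j + 1, cost + 1.0)  # insert b[j]

    rec(0, 0, 0.0)
    return best[0]


def _train_set(trains_by_key, duration=1000.0):
    n_trials = max(k[1] for k in trains_by_key) + 1
    return SpikeTrainSet(
        trains={k: np.asarray(v, float) for k, v in trains_by_key.items()},
        n_trials=n_trials,
        duration=duration,
    )


class TestComputePsth:
    def test_single_spike_mass_conserved(self):
        ts = _train_set({("s", 0): [100.0]}, duration=300.0)
        p = compute_psth(ts, bin_ms=0.1, smooth_ms=10.8)
        integral = np.sum(p.rate) * p.bin_ms * 1e-3
        assert integral == pytest.approx(1.0, rel=1e-6)
        assert p.times[np.argmax(p.rate)] == pytest.approx(100.0, abs=6.0)

    def test_identical_trains_average_to_single_train(self):
        spk = [50.0, 120.0, 121.5]
        ts1 = _train_set({("s", 0): spk}, duration=300.0)
        ts20 = _train_set({("s", i): spk for i in range(20)}, duration=300.0)
        p1 = compute_psth(ts1)
        p20 = compute_psth(ts20)
        np.testing.assert_allclose(p1.rate, p20.rate)

    def test_poisson_rate_recovery(self):
        st_set = generate_spike_trains(np.full(4000, 40.0), 0.5, 50, seed=4)
        p = compute_psth(st_set, bin_ms=0.1, smooth_ms=10.8)
        # SE of the mean level: sqrt(40 / (2 s * 50 trials)) ~ 0.63 sp/s
        assert p.rate.mean() == pytest.approx(40.0, abs=3 * 0.7)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compute_psth(SpikeTrainSet(trains={}, n_trials=0, duration=0.0),
                         stimulus_id="nope")


class TestCsi:
    def _psth(self, rate):
        return Psth(rate=np.asarray(rate, float), bin_ms=1.0, smooth_ms=0.0)

    def test_pure_chirp_response(self):
        rate = np.zeros(400)
        rate[210] = 50.0
        assert csi(self._psth(rate), 200.0) == pytest.approx(1.0)

    def test_pure_beat_response(self):
        rate = np.zeros(400)
        rate[50] = 50.0
        assert csi(self._psth(rate), 200.0) == pytest.approx(-1.0)

    def test_worked_ratio(self):
        rate = np.zeros(400)
        rate[250] = 60.0
        rate[50] = 20.0
        assert csi(self._psth(rate), 200.0) == pytest.approx(0.5)

    def test_silent_psth_gives_zero(self):
        assert csi(self._psth(np.zeros(400)), 200.0) == 0.0

    def test_invariant_to_rate_scaling(self, rng):
        rate = rng.uniform(0, 50, 400)
        a = csi(self._psth(rate), 200.0)
        b = csi(self._psth(rate * 7.3), 200.0)
        assert a == pytest.approx(b)


class TestVpd:
    def test_identical_trains_zero(self):
        assert vpd([10.0, 20.0], [10.0, 20.0]) == 0.0

    def test_single_deletion(self):
        assert vpd([100.0], []) == 1.0

    def test_single_shift(self):
        assert vpd([100.0], [105.0], q=100.0) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 500, rng.integers(0, 6)))
            b = np.sort(rng.uniform(0, 500, rng.integers(0, 6)))
            assert vpd(a, b) == pytest.approx(brute_force_vpd(a, b, 100.0))

    def test_metric_axioms(self, rng):
        trains = [np.sort(rng.uniform(0, 300, rng.integers(0, 5)))
                  for _ in range(8)]
        for a, b in itertools.combinations(trains, 2):
            d = vpd(a, b)
            assert d >= 0.0
            assert d == pytest.approx(vpd(b, a))
            assert d <= len(a) + len(b) + 1e-12  # delete-all bound
        for a, b, c in itertools.combinations(trains, 3):
            assert vpd(a, c) <= vpd(a, b) + vpd(b, c) + 1e-9

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            vpd([20.0, 10.0], [5.0])


class TestVpdAvg:
    def test_identical_trains_zero(self):
        ts = _train_set({("a", 0): [10.0], ("a", 1): [10.0], ("b", 0): [10.0]})
        assert vpd_avg(ts) == 0.0

    def test_single_pair(self):
        ts = _train_set({("a", 0): [], ("b", 0): [100.0]})
        assert vpd_avg(ts) == 1.0

    def test_pools_within_and_between_stimuli(self):
        # 2 stimuli x 3 trials -> C(6,2) = 15 pairs; all trains empty but
        # one with a single spike -> 5 pairs at cost 1 -> mean = 5/15
        trains = {("a", i): [] for i in range(3)}
        trains.update({("b", i): [] for i in range(3)})
        trains[("b", 2)] = [50.0]
        assert vpd_avg(_train_set(trains)) == pytest.approx(5.0 / 15.0)

    def test_fewer_than_two_trains_rejected(self):
        with pytest.raises(ValueError):
            vpd_avg(_train_set({("a", 0): [1.0]}))


class TestRmseAvg:
    def test_identical_psths_zero(self, rng):
        r = rng.uniform(0, 50, 256)
        assert rmse_avg([Psth(rate=r), Psth(rate=r.copy())]) == 0.0

    def test_circular_shift_is_aligned_away(self, rng):
        r = rng.uniform(0, 50, 256)
        shifted = np.roll(r, 37)
        assert rmse_avg([Psth(rate=r), Psth(rate=shifted)]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_hand_computed_toy_case(self):
        # best circular alignment of b=[.5,.5,0,0] onto a=[1,0,0,0] leaves
        # residual [.5,-.5,0,0] -> rmse = sqrt(0.5/4)
        a = Psth(rate=np.array([1.0, 0.0, 0.0, 0.0]))
        b = Psth(rate=np.array([0.5, 0.5, 0.0, 0.0]))
        assert rmse_avg([a, b]) == pytest.approx(math.sqrt(0.125))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_avg([Psth(rate=np.zeros(4)), Psth(rate=np.zeros(5))])


class TestFi:
    def test_example_neuron(self):
        assert round(fi(1.0, 1.19), 2) == 0.99

    def test_on_population_rectified_to_zero(self):
        assert fi(-0.05, 53.3) == 0.0

    def test_ts_population_mean(self):
        assert fi(0.61, 7.4) == pytest.approx(0.536)

    def test_fi_rmse_examples(self):
        assert fi_rmse(0.5, 0.0) == 0.5
        assert fi_rmse(-0.1, 0.0) == 0.0
        assert fi_rmse(0.61, 18.0) == pytest.approx(0.5362, abs=1e-4)

    @given(
        csi_avg=st.floats(-1.0, 1.0),
        v1=st.floats(0.0, 100.0),
        v2=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_vpd(self, csi_avg, v1, v2):
        lo, hi = sorted((v1, v2))
        assert fi(csi_avg, lo) >= fi(csi_avg, hi)
        assert fi(csi_avg, lo) >= 0.0

    @given(
        c1=st.floats(-1.0, 1.0),
        c2=st.floats(-1.0, 1.0),
        v=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_csi(self, c1, c2, v):
        lo, hi = sorted((c1, c2))
        assert fi(lo, v) <= fi(hi, v)


class TestBimodality:
    def test_two_equal_bumps(self):
        t = np.linspace(0, 1, 500, endpoint=False)
        v = np.exp(-0.5 * ((t - 0.25) / 0.05) ** 2) + np.exp(
            -0.5 * ((t - 0.75) / 0.05) ** 2
        )
        assert bimodality_index(v) == pytest.approx(1.0, abs=0.01)

    def test_sinusoid_is_unimodal(self):
        t = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        assert bimodality_index(np.sin(t)) == pytest.approx(0.0, abs=1e-9)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            bimodality_index(np.ones(100))


class TestRobustness:
    def test_extremes(self):
        assert robustness(np.ones((3, 3))) == 100.0
        assert robustness(np.zeros((3, 3))) == 0.0

    def test_boundary_counts_as_robust(self):
        grid = np.array([[0.8, 0.6], [0.7, 0.1]])
        assert robustness(grid) == 50.0

    def test_nan_cells_excluded(self):
        grid = np.array([[0.8, np.nan], [0.7, 0.1]])
        assert robustness(grid) == pytest.approx(100.0 * 2 / 3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            robustness(np.full((2, 2), np.nan))
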