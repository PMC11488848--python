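import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterplay.config import AnalysisParams
from clusterplay.lifsim import SpikeRecord
from clusterplay.placefield import (
    central_third_fraction,
    compute_rate_map,
    compute_time_fields,
    field_center_of_mass,
    map_correlation,
    peak_distribution_kl,
    smooth_map,
    spatial_information,
    specificity,
)


def _record(ids, times, duration=2.0, x_start=0.0, x_end=1.0, n_e=10):
    return SpikeRecord(
        ids=np.asarray(ids, dtype=np.int32),
        times=np.asarray(times, dtype=float),
        duration=duration,
        n_neurons=n_e,
        n_excit=n_e,
        meta={"x_start": x_start, "x_end": x_end},
    )


class TestRateMap:
    def test_occupancy_normalization_single_trial(self):
        # 3 spikes in one bin of a 2 s lap: occupancy 2/50 s -> 75 Hz raw
        times = [0.5004, 0.5008, 0.5012]  # x ~ 0.25 -> bin 12
        rec = _record([0, 0, 0], times)
        fields = compute_rate_map([rec])
        assert fields.raw_rates[0].sum() == pytest.approx(75.0)
        assert fields.raw_rates[0, 12] == pytest.approx(75.0)

    def test_homogeneous_cell_yields_flat_map(self, rng):
        recs = []
        for _ in range(40):
            times = np.sort(rng.uniform(0, 2.0, rng.poisson(10)))
            recs.append(_record(np.zeros(len(times)), times))
        fields = compute_rate_map(recs)
        assert fields.rates[0].mean() == pytest.approx(5.0, rel=0.15)
        assert fields.rates[0].std() < 2.0

    def test_single_bin_smooths_to_gaussian_bump(self):
        raw = np.zeros((1, 50))
        raw[0, 25] = 1.0
        sm = smooth_map(raw, 2.0)[0]
        assert sm.argmax() == 25
        # interior mass is conserved by the renormalized kernel
        assert sm.sum() == pytest.approx(1.0, abs=1e-6)
        assert sm[25] / sm[27] == pytest.approx(np.exp(0.5), rel=0.05)

    def test_smoothing_preserves_constant_map(self):
        sm = smooth_map(np.full((1, 50), 3.3), 2.0)
        assert np.allclose(sm, 3.3)

    def test_leftward_trajectory_maps_time_to_reversed_position(self):
        rec = _record([0], [0.1], x_start=1.0, x_end=0.0)  # early spike, x ~ 0.95
        fields = compute_rate_map([rec])
        assert fields.raw_rates[0].argmax() == 47


class TestSpecificity:
    def test_fraction_above_quarter_max(self):
        rates = np.zeros(50)
        rates[:10] = 10.0  # 10 of 50 bins exceed 25% of max
        assert specificity(rates) == pytest.approx(0.8)

    def test_uniform_map_scores_zero(self):
        assert specificity(np.full(50, 4.2)) == 0.0

    def test_single_bin_scores_near_one(self):
        rates = np.zeros(50)
        rates[7] = 1.0
        assert specificity(rates) == pytest.approx(1 - 1 / 50)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            specificity(np.zeros(50))

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_rate_scaling(self, scale):
        rng = np.random.default_rng(0)
        rates = rng.gamma(2.0, 1.0, 50)
        assert specificity(rates * scale) == pytest.approx(specificity(rates))


class TestSpatialInformation:
    def test_half_track_firing_is_one_bit(self):
        rates = np.zeros(50)
        rates[:25] = 7.0
        assert spatial_information(rates) == pytest.approx(1.0)

    def test_single_bin_is_log2_nbins(self):
        rates = np.zeros(50)
        rates[3] = 2.0
        assert spatial_information(rates) == pytest.approx(np.log2(50))

    def test_uniform_firing_is_zero(self):
        assert spatial_information(np.full(50, 3.0)) == pytest.approx(0.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_bounded_by_zero_and_log2_nbins(self, seed):
        rates = np.random.default_rng(seed).gamma(0.5, 2.0, 50)
        if rates.sum() == 0:
            return
        si = spatial_information(rates)
        assert -1e-9 <= si <= np.log2(50) + 1e-9


class TestPeakDistribution:
    def test_uniform_over_half_the_bins_is_one_bit(self):
        peaks = np.repeat(np.arange(25), 4)  # equal counts in 25 of 50 bins
        assert peak_distribution_kl(peaks) == pytest.approx(1.0)

    def test_perfectly_uniform_is_zero(self):
        peaks = np.repeat(np.arange(50), 3)
        assert peak_distribution_kl(peaks) == pytest.approx(0.0)

    def test_single_bin_is_log2_nbins(self):
        assert peak_distribution_kl(np.full(30, 17)) == pytest.approx(np.log2(50))

    def test_central_third_examples(self):
        assert central_third_fraction(np.arange(50)) == pytest.approx(17 / 50)
        assert central_third_fraction(np.array([0, 0, 49])) == 0.0
        # bins 25,25,25,2 (1-based) -> 0-based 24,24,24,1 -> 3 of 4 central
        assert central_third_fraction(np.array([24, 24, 24, 1])) == pytest.approx(0.75)


class TestMapCorrelation:
    def test_identical_maps_correlate_perfectly(self, rng):
        m = rng.gamma(2.0, 2.0, (40, 50))
        assert map_correlation(m, m) == pytest.approx(1.0)

    def test_independent_maps_correlate_near_zero(self, rng):
        a = rng.gamma(2.0, 2.0, (500, 50))
        b = rng.gamma(2.0, 2.0, (500, 50))
        assert abs(map_correlation(a, b)) < 0.1

    def test_invariant_to_consistent_cell_relabeling(self, rng):
        a = rng.gamma(2.0, 2.0, (40, 50))
        b = rng.gamma(2.0, 2.0, (40, 50))
        perm = rng.permutation(40)
        assert map_correlation(a[perm], b[perm]) == pytest.approx(map_correlation(a, b))

    def test_symmetry(self, rng):
        a = rng.gamma(2.0, 2.0, (40, 50))
        b = rng.gamma(2.0, 2.0, (40, 50))
        assert map_correlation(a, b) == pytest.approx(map_correlation(b, a))


class TestTimeFields:
    def test_position_locked_cell_has_more_place_than_time_information(self):
        # spikes at fixed position x=0.25 across speeds 1x and 2x
        trials = []
        for speed, dur in ((1.0, 2.0), (2.0, 1.0)):
            t_spike = 0.25 * dur  # time of crossing x = 0.25
            for _ in range(5):
                trials.append(
                    _record([0] * 4, [t_spike + d for d in (0, 1e-3, 2e-3, 3e-3)],
                            duration=dur)
                )
        place = compute_rate_map(trials)
        time_f = compute_time_fields(trials)
        si_place = spatial_information(place.rates[0])
        si_time = spatial_information(time_f.rates[0])
        assert si_place > si_time

    def test_latency_locked_cell_has_sharper_time_field(self):
        trials = []
        for speed, dur in ((1.0, 2.0), (2.0, 1.0)):
            for _ in range(5):
                trials.append(_record([0] * 3, [0.5, 0.501, 0.502], duration=dur))
        place = compute_rate_map(trials)
        time_f = compute_time_fields(trials)
        assert spatial_information(time_f.rates[0]) > spatial_information(place.rates[0])

    def test_constant_rate_cell_has_no_information(self, rng):
        trials = []
        for _ in range(50):
            times = np.sort(rng.uniform(0, 2.0, 30))
            trials.append(_record(np.zeros(30), times))
        place = compute_rate_map(trials)
        time_f = compute_time_fields(trials)
        assert spatial_information(place.rates[0]) < 0.05
        assert spatial_information(time_f.rates[0]) < 0.05


def test_center_of_mass_track_fraction():
    rates = np.zeros(50)
    rates[25] = 1.0
    assert field_center_of_mass(rates) == pytest.approx(25.5 / 50)
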