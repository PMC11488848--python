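import numpy as np
import pytest

from clusterplay._rng import substream
from clusterplay.clusterdyn import (
    ActiveClusterSequence,
    ClusterRateCurves,
    active_cluster_count_correlation,
    active_clusters,
    cluster_rate_curves,
    mean_relative_rank,
    sequence_match_test,
    shuffle_identities,
)
from clusterplay.config import NetworkParams
from clusterplay.events import PBE
from clusterplay.lifsim import SpikeRecord
from clusterplay.netgen import EnvironmentSpec, assign_clusters
from clusterplay.placefield import PlaceFieldMap


def _curves(rates, dt=1e-3):
    return ClusterRateCurves(rates=np.asarray(rates, dtype=float), dt=dt, start=0.0)


def _members(n_clusters=3, participation=1.0, n=500):
    params = NetworkParams(
        n=n, excit_fraction=0.75, n_clusters=n_clusters,
        cluster_participation=participation,
    )
    return assign_clusters(params, substream(0, "m"))


class TestActiveClusters:
    def test_single_dominant_cluster(self):
        r = np.zeros((3, 50))
        r[2, :] = 1.0
        seq = active_clusters(_curves(r))
        assert seq.clusters == [2]
        assert seq.durations[0] == pytest.approx(0.05)

    def test_sequential_dominance_with_durations(self):
        # A dominant for 30 ms, then B for 50 ms, each >2x the others
        r = np.full((3, 80), 0.1)
        r[0, :30] = 1.0
        r[1, 30:] = 1.0
        seq = active_clusters(_curves(r))
        assert seq.clusters == [0, 1]
        assert seq.durations == pytest.approx([0.03, 0.05])

    def test_identical_curves_yield_empty_sequence(self):
        r = np.ones((2, 40))
        seq = active_clusters(_curves(r))
        assert seq.clusters == []

    def test_dominance_requires_double_rate(self):
        r = np.ones((2, 40))
        r[0] *= 1.8  # above the rest but below the 2x criterion
        assert active_clusters(_curves(r)).clusters == []
        r[0] = 2.5
        assert active_clusters(_curves(r)).clusters == [0]

    def test_rate_curves_from_spikes(self):
        members = _members()
        c0 = np.flatnonzero(members.membership[:, 0])[:5]
        ids = np.repeat(c0, 3)
        times = np.sort(np.random.default_rng(0).uniform(1.0, 1.05, ids.size))
        rec = SpikeRecord(ids=ids.astype(np.int32), times=times, duration=2.0,
                          n_neurons=500, n_excit=375)
        ev = PBE(start=1.0, end=1.05, n_cells=5, peak_rate=1.0, decodable=True)
        curves = cluster_rate_curves(rec, ev, members)
        assert curves.rates.shape[0] == 3
        assert curves.rates[0].max() > 2 * curves.rates[1].max()
        seq = active_clusters(curves)
        assert seq.clusters == [0]


class TestSequenceMatch:
    def test_null_probability_is_one_third(self, rng):
        env = EnvironmentSpec.draw(0, 15, rng)
        seqs = [rng.choice(15, 3, replace=False) for _ in range(2000)]
        frac, p = sequence_match_test(seqs, env, rng, n_boot=200)
        assert frac == pytest.approx(1 / 3, abs=0.04)
        assert p > 0.01  # random sequences are not significant

    def test_all_monotone_sequences_significant(self, rng):
        env = EnvironmentSpec.draw(0, 15, rng)
        order = np.argsort(env.cluster_rank_bias)
        seqs = [order[[1, 5, 9]] for _ in range(60)]
        frac, p = sequence_match_test(seqs, env, rng, n_boot=500)
        assert frac == 1.0
        assert p < 0.01

    def test_requires_three_cluster_events(self, rng):
        env = EnvironmentSpec.draw(0, 15, rng)
        with pytest.raises(ValueError):
            sequence_match_test([[1, 2]], env, rng)


class TestCountCorrelation:
    def test_strictly_decreasing_z_gives_minus_one(self, rng):
        counts = np.repeat([1, 2, 3, 4], 30)
        # per-count shuffle pools identical; |r| decreasing with count
        abs_r = 1.0 - counts * 0.2 + rng.normal(0, 1e-3, counts.size)
        shuffle = np.tile(rng.uniform(0, 0.1, (counts.size, 50)), 1)
        rho, p = active_cluster_count_correlation(counts, abs_r, shuffle)
        assert rho == pytest.approx(-1.0, abs=0.05)
        assert p < 1e-10

    def test_shuffled_pairing_near_zero(self, rng):
        counts = rng.integers(1, 5, 200)
        abs_r = rng.uniform(0, 1, 200)
        shuffle = rng.uniform(0, 1, (200, 50))
        rho, p = active_cluster_count_correlation(counts, abs_r, shuffle)
        assert abs(rho) < 0.15

    def test_constant_count_undefined(self, rng):
        with pytest.raises(ValueError):
            active_cluster_count_correlation(
                np.ones(10, dtype=int), rng.uniform(0, 1, 10), rng.uniform(0, 1, (10, 5))
            )


class TestIdentityShuffles:
    def test_across_is_a_permutation(self, rng):
        members = _members(5, 1.4)
        perm = shuffle_identities(members, "across", rng)
        assert sorted(perm.tolist()) == list(range(members.n_excit))

    def test_within_single_cluster_fixes_multicluster_cells(self, rng):
        members = _members(5, 1.6)
        perm = shuffle_identities(members, "within_single_cluster", rng)
        multi = np.flatnonzero(members.participation > 1)
        assert np.all(perm[multi] == multi)
        moved = np.flatnonzero(perm != np.arange(members.n_excit))
        assert len(moved) > 0

    def test_within_single_cluster_preserves_cluster_spike_counts(self, rng):
        members = _members(5, 1.6)
        perm = shuffle_identities(members, "within_single_cluster", rng)
        spikes = rng.poisson(2.0, members.n_excit)
        for c in range(5):
            cells = members.membership[:, c]
            assert spikes[perm][cells].sum() == spikes[cells].sum()

    def test_within_cluster_moves_only_through_shared_membership(self, rng):
        members = _members(5, 1.6)
        perm = shuffle_identities(members, "within_cluster", rng)
        assert sorted(perm.tolist()) == list(range(members.n_excit))
        # single-cluster cells can only assume identities from their own
        # cluster's shared-membership neighborhood closure; verify at least
        # that every moved single-cluster cell maps to a cell sharing a
        # cluster with *some* cell of its own cluster set (chain property)
        shared = members.shares_cluster()
        moved = np.flatnonzero(perm != np.arange(members.n_excit))
        assert len(moved) > 0

    def test_identity_permutation_relabel_is_noop(self, rng):
        rec = SpikeRecord(
            ids=np.array([0, 3, 5], dtype=np.int32),
            times=np.array([0.1, 0.2, 0.3]),
            duration=1.0, n_neurons=500, n_excit=375,
        )
        out = rec.relabel(np.arange(375))
        assert np.array_equal(out.ids, rec.ids)


class TestMeanRelativeRank:
    def _fields(self, n_cells=3):
        rates = np.zeros((n_cells, 50))
        for i in range(n_cells):
            rates[i, 10 + 15 * i] = 10.0
        return PlaceFieldMap(rates=rates, raw_rates=rates.copy())

    def test_toy_enumeration(self):
        # two events over 3 cells with hand-computed rank order
        ids = np.array([0, 1, 2, 2, 1, 0], dtype=np.int32)
        times = np.array([0.10, 0.11, 0.12, 0.50, 0.51, 0.52])
        rec = SpikeRecord(ids=ids, times=times, duration=1.0, n_neurons=3, n_excit=3)
        events = [
            PBE(start=0.09, end=0.13, n_cells=3, peak_rate=1, decodable=True),
            PBE(start=0.49, end=0.53, n_cells=3, peak_rate=1, decodable=True),
        ]
        res = mean_relative_rank(
            rec, events, slopes=[1.0, 1.0], fields=self._fields(),
            direction_correct=False,
        )
        # event 1 ranks: 0,0.5,1 ; event 2 ranks: 1,0.5,0 -> means 0.5 each
        assert np.allclose(res.mean_rank, 0.5)

    def test_direction_correction_inverts_negative_slope_events(self):
        ids = np.array([0, 1, 2, 2, 1, 0], dtype=np.int32)
        times = np.array([0.10, 0.11, 0.12, 0.50, 0.51, 0.52])
        rec = SpikeRecord(ids=ids, times=times, duration=1.0, n_neurons=3, n_excit=3)
        events = [
            PBE(start=0.09, end=0.13, n_cells=3, peak_rate=1, decodable=True),
            PBE(start=0.49, end=0.53, n_cells=3, peak_rate=1, decodable=True),
        ]
        res = mean_relative_rank(
            rec, events, slopes=[1.0, -1.0], fields=self._fields(),
            direction_correct=True,
        )
        # second event inverted: both events rank cells 0,1,2 as 0,0.5,1
        assert res.mean_rank == pytest.approx([0.0, 0.5, 1.0])
        assert res.slope > 0

    def test_always_first_cell_has_zero_rank(self):
        ids = np.array([0, 1, 0, 2], dtype=np.int32)
        times = np.array([0.1, 0.11, 0.5, 0.51])
        rec = SpikeRecord(ids=ids, times=times, duration=1.0, n_neurons=3, n_excit=3)
        events = [
            PBE(start=0.09, end=0.12, n_cells=2, peak_rate=1, decodable=True),
            PBE(start=0.49, end=0.52, n_cells=2, peak_rate=1, decodable=True),
        ]
        res = mean_relative_rank(
            rec, events, slopes=[1.0, 1.0], fields=self._fields(),
            direction_correct=True,
        )
        assert res.mean_rank[res.cell_ids.tolist().index(0)] == 0.0
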