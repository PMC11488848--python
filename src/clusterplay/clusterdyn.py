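"""Cluster-level event dynamics, identity-shuffle controls, and spike ranks.

During a population burst, typically one cluster dominates at a time; a
cluster is *active* if at some instant its population rate exceeds twice
that of every other cluster.  The analyses here quantify that structure
(active-cluster sequences and durations, their relation to decoded
sequence quality), provide the three cell-identity shuffle controls used
to show that cluster identity is sufficient for preplay, and relate each
cell's within-event spike rank to its place-field position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisParams
from .events import PBE
from .lifsim import SpikeRecord
from .netgen import ClusterMembership, EnvironmentSpec
from .placefield import PlaceFieldMap, field_center_of_mass

__all__ = [
    "ClusterRateCurves",
    "ActiveClusterSequence",
    "cluster_rate_curves",
    "active_clusters",
    "sequence_match_test",
    "active_cluster_count_correlation",
    "shuffle_identities",
    "RankAnalysis",
    "mean_relative_rank",
]


@dataclass
class ClusterRateCurves:
    """Per-cluster smoothed mean member firing rate over an event window."""

    rates: np.ndarray  # (n_clusters, n_steps) Hz per member cell
    dt: float
    start: float

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.rates.shape[1]) * self.dt


@dataclass
class ActiveClusterSequence:
    """Ordered active clusters of one event with most-active durations."""

    clusters: list[int]
    durations: list[float]


def cluster_rate_curves(
    spikes: SpikeRecord,
    event: PBE,
    members: ClusterMembership,
    analysis: AnalysisParams | None = None,
    grid_dt: float = 1e-3,
) -> ClusterRateCurves:
    """Smoothed mean firing rate of each cluster's members in the window.

    Cells belonging to several clusters contribute to each of their
    clusters' curves.  Rates are per member cell, smoothed with the same
    15 ms SD kernel used for PBE detection.
    """
    if analysis is None:
        analysis = AnalysisParams()
    n_steps = max(1, int(round((event.end - event.start) / grid_dt)))
    n_c = members.n_clusters
    sizes = members.cluster_sizes
    sel = (
        (spikes.times >= event.start)
        & (spikes.times <= event.end)
        & (spikes.ids < members.n_excit)
    )
    ids = spikes.ids[sel]
    bins = np.minimum(
        ((spikes.times[sel] - event.start) / grid_dt).astype(np.int64), n_steps - 1
    )
    rates = np.zeros((n_c, n_steps))
    for c in range(n_c):
        in_c = members.membership[ids, c]
        counts = np.bincount(bins[in_c], minlength=n_steps).astype(float)
        rates[c] = counts / (sizes[c] * grid_dt)
    sd = analysis.cluster_rate_smooth_sd / grid_dt
    rates = gaussian_filter1d(rates, sd, axis=1, truncate=4.0)
    return ClusterRateCurves(rates=rates, dt=grid_dt, start=event.start)


def active_clusters(
    curves: ClusterRateCurves, ratio: float = 2.0
) -> ActiveClusterSequence:
    """Active clusters of one event, in order of first dominance.

    A cluster is active if at some instant its rate exceeds ``ratio``
    times the rate of every other cluster.  Durations are the total time
    each active cluster spends as the (strictly) most active one; the
    sequence is ordered by the first time that happens.  Ties leave both
    clusters inactive at that instant, so identical curves yield an empty
    sequence.
    """
    r = curves.rates
    n_c, n_steps = r.shape
    if n_c < 2:
        active = [0] if n_c == 1 and r[0].any() else []
        return ActiveClusterSequence(
            clusters=active, durations=[n_steps * curves.dt] if active else []
        )
    order = np.argsort(r, axis=0)
    top = order[-1]
    second = r[order[-2], np.arange(n_steps)]
    top_rate = r[top, np.arange(n_steps)]
    is_active_now = top_rate > ratio * second
    active_set = set(np.unique(top[is_active_now]).tolist())

    clusters: list[int] = []
    durations: dict[int, float] = {}
    most_active_valid = top_rate > second  # strictly most active
    for i in range(n_steps):
        c = int(top[i])
        if c not in active_set or not most_active_valid[i]:
            continue
        if c not in durations:
            durations[c] = 0.0
            clusters.append(c)
        durations[c] += curves.dt
    return ActiveClusterSequence(
        clusters=clusters, durations=[durations[c] for c in clusters]
    )


def sequence_match_test(
    sequences: Sequence[Sequence[int]],
    env: EnvironmentSpec,
    rng: np.random.Generator,
    n_boot: int = 10000,
) -> tuple[float, float]:
    """Do 3-cluster activation sequences follow the track's bias order?

    For events with exactly three active clusters, a sequence *matches*
    when its clusters' rank biases are monotone (in either direction).
    Under the null of sampling three distinct clusters uniformly without
    replacement the match probability is 2/3! = 1/3; the bootstrap draws
    ``n_boot`` datasets of the same size and returns (actual fraction,
    fraction of null datasets with a match fraction >= actual).
    """
    triples = [s for s in sequences if len(s) == 3]
    if not triples:
        raise ValueError("no events with exactly three active clusters")
    bias = env.cluster_rank_bias

    def is_monotone(seq) -> bool:
        b = bias[list(seq)]
        return bool(np.all(np.diff(b) > 0) or np.all(np.diff(b) < 0))

    actual = float(np.mean([is_monotone(s) for s in triples]))
    n_c = len(bias)
    null_fracs = np.empty(n_boot)
    for i in range(n_boot):
        hits = 0
        for _ in triples:
            seq = rng.choice(n_c, size=3, replace=False)
            hits += is_monotone(seq)
        null_fracs[i] = hits / len(triples)
    p = float(np.mean(null_fracs >= actual))
    return actual, p


def active_cluster_count_correlation(
    counts: np.ndarray, abs_r: np.ndarray, shuffle_abs_r: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of active-cluster count with normalized |r|.

    Each event's |r| is z-scored against the pooled shuffle |r| of all
    events with the same active-cluster count, so that the correlation is
    not driven by count-dependent shuffle baselines (longer events have
    more active clusters *and* different shuffle statistics).
    """
    counts = np.asarray(counts)
    abs_r = np.asarray(abs_r, dtype=float)
    z = np.full(len(counts), np.nan)
    for c in np.unique(counts):
        sel = counts == c
        pool = np.asarray(shuffle_abs_r)[sel].ravel()
        sd = pool.std()
        if sd == 0:
            continue
        z[sel] = (abs_r[sel] - pool.mean()) / sd
    ok = ~np.isnan(z)
    if np.unique(counts[ok]).size < 2:
        raise ValueError("active-cluster count is constant; correlation undefined")
    rho, p = sps.spearmanr(counts[ok], z[ok])
    return float(rho), float(p)


def shuffle_identities(
    members: ClusterMembership,
    mode: str,
    rng: np.random.Generator,
    n_swaps_factor: int = 10,
) -> np.ndarray:
    """Permutation of E-cell identities under one of three constraints.

    ``across``: uniform permutation of all E cells.
    ``within_cluster``: composed from random transpositions restricted to
    pairs sharing at least one cluster (``n_swaps_factor * nE`` swaps).
    ``within_single_cluster``: as ``within_cluster`` but cells belonging
    to more than one cluster are fixed points.

    Returns ``perm`` with ``perm[i]`` = the cell whose identity cell ``i``
    assumes.
    """
    n_e = members.n_excit
    if mode == "across":
        return rng.permutation(n_e)
    if mode not in ("within_cluster", "within_single_cluster"):
        raise ValueError(f"unknown shuffle mode '{mode}'")
    shared = members.shares_cluster()
    eligible = np.ones(n_e, dtype=bool)
    if mode == "within_single_cluster":
        eligible = members.participation == 1
    perm = np.arange(n_e)
    candidates = np.flatnonzero(eligible)
    for _ in range(n_swaps_factor * n_e):
        i = candidates[rng.integers(len(candidates))]
        partners = np.flatnonzero(shared[i] & eligible)
        if len(partners) == 0:
            continue
        j = partners[rng.integers(len(partners))]
        perm[i], perm[j] = perm[j], perm[i]
    return perm


@dataclass
class RankAnalysis:
    """Per-cell mean relative spike rank vs place-field position."""

    cell_ids: np.ndarray
    mean_rank: np.ndarray
    field_location: np.ndarray  # center of mass, track fraction
    slope: float
    intercept: float
    pearson_r: float
    meta: dict[str, Any] = field(default_factory=dict)


def _event_ranks(
    spikes: SpikeRecord, event: PBE, n_excit: int, key: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    sel = (spikes.times >= event.start) & (spikes.times <= event.end) & (
        spikes.ids < n_excit
    )
    ids = spikes.ids[sel]
    times = spikes.times[sel]
    cells = np.unique(ids)
    if len(cells) == 0:
        return cells, np.empty(0)
    stat = np.empty(len(cells))
    for k, c in enumerate(cells):
        t = times[ids == c]
        stat[k] = np.mean(t) if key == "mean" else np.median(t)
    order = np.argsort(stat, kind="stable")
    ranks = np.empty(len(cells))
    ranks[order] = np.arange(len(cells))
    if len(cells) > 1:
        ranks /= len(cells) - 1
    else:
        ranks[:] = 0.5
    return cells, ranks


def mean_relative_rank(
    spikes: SpikeRecord,
    events: Sequence[PBE],
    slopes: Sequence[float],
    fields: PlaceFieldMap,
    members: ClusterMembership | None = None,
    scope: str = "network",
    direction_correct: bool = True,
    rank_key: str = "mean",
    min_peak_rate: float = 3.0,
) -> RankAnalysis:
    """Mean relative within-event spike rank of each place cell.

    Cells participating in an event are ranked by their mean (or median)
    spike time, normalized to [0, 1].  With ``direction_correct`` the
    ranks are inverted in events whose decoded trajectory slope (the sign
    of the weighted correlation) is negative, so forward and reverse
    sequences reinforce instead of cancel.  ``scope='cluster'`` ranks each
    cell only against co-participants sharing a cluster with it.  The
    regression is of mean rank against place-field center of mass.
    """
    n_e = fields.rates.shape[0]
    sums = np.zeros(n_e)
    counts = np.zeros(n_e)
    shared = members.shares_cluster() if scope == "cluster" else None
    if scope == "cluster" and members is None:
        raise ValueError("cluster scope requires membership")
    for event, slope in zip(events, slopes):
        cells, ranks = _event_ranks(spikes, event, n_e, rank_key)
        if len(cells) < 2:
            continue
        if direction_correct and slope < 0:
            ranks = 1.0 - ranks
        if scope == "network":
            sums[cells] += ranks
            counts[cells] += 1
        else:
            order = np.argsort(ranks, kind="stable")
            for idx, c in enumerate(cells):
                peers = np.flatnonzero(shared[c][cells])
                if len(peers) == 0:
                    continue
                group = np.append(peers, idx)
                r_in_group = float(np.sum(ranks[group] < ranks[idx]))
                denom = max(len(group) - 1, 1)
                sums[c] += r_in_group / denom
                counts[c] += 1

    mask = (counts > 0) & fields.place_cell_mask(min_peak_rate)
    cells = np.flatnonzero(mask)
    mean_rank = sums[cells] / counts[cells]
    loc = np.array([field_center_of_mass(fields.rates[c]) for c in cells])
    fit = sps.linregress(loc, mean_rank)
    return RankAnalysis(
        cell_ids=cells,
        mean_rank=mean_rank,
        field_location=loc,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        meta={"scope": scope, "direction_correct": direction_correct},
    )
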