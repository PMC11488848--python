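"""Experiment orchestration: fiducial ensembles, parameter grids, remapping.

The canonical protocol simulates, per network: five 2 s constant-speed
laps of each of the two linear-track trajectories per environment, and one
sleep session.  Place fields come from the run trials; population burst
events detected during sleep are Bayesian-decoded with the place fields of
a designated headline trajectory (environment 0, leftward travel), and
their sequence quality is tested against time-bin shuffles, pooling events
over all networks of an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from ._rng import substream
from .config import ConfigError, RunConfig, with_overrides
from .events import PBEList, detect_pbes, population_rate
from .graphmetrics import GraphSummary, summarize_graph
from .lifsim import SpikeRecord, simulate_run_trials, simulate_sleep
from .netgen import NetworkRealization, build_network, feasible
from .placefield import PlaceFieldMap, compute_rate_map, map_correlation
from .preplay import (
    DecodedEvent,
    PreplaySignificance,
    decode_ensemble,
    evaluate_preplay,
    median_shift,
)

__all__ = [
    "HEADLINE_TRAJECTORY",
    "NetworkBundle",
    "EnsembleResult",
    "simulate_network_bundle",
    "run_fiducial",
    "pooled_significance",
    "GridPointSummary",
    "run_grid",
    "scale_w_ee_with_pc",
    "MultiEnvResult",
    "run_multi_environment",
]

#: trajectory whose place fields are used for headline decoding
HEADLINE_TRAJECTORY = (0, "left")


@dataclass
class NetworkBundle:
    """Everything computed for one network realization."""

    network: NetworkRealization
    sleep: SpikeRecord
    pbes: PBEList
    fields: dict[tuple[int, str], PlaceFieldMap]
    decoded: dict[tuple[int, str], list[DecodedEvent]]
    graph: GraphSummary | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def headline_events(self) -> list[DecodedEvent]:
        return self.decoded[HEADLINE_TRAJECTORY]

    def median_shift(self, trajectory: tuple[int, str] = HEADLINE_TRAJECTORY) -> float:
        dec = self.decoded[trajectory]
        if not dec:
            return float("nan")
        abs_r = np.array([d.stats.abs_r for d in dec])
        sh = np.concatenate([d.shuffle_abs_r for d in dec])
        return median_shift(abs_r, sh)


def simulate_network_bundle(
    config: RunConfig,
    seed: int,
    environments: Sequence[int] = (0,),
    directions: Sequence[str] = ("left", "right"),
    decode_trajectories: Sequence[tuple[int, str]] | None = None,
    compute_graph: bool = True,
) -> NetworkBundle:
    """Build, simulate, and analyze one network.

    ``decode_trajectories`` selects which place-field maps decode the
    sleep events (default: the headline trajectory only).  All requested
    (environment, direction) rate maps are always computed.
    """
    if decode_trajectories is None:
        decode_trajectories = [HEADLINE_TRAJECTORY]
    net = build_network(config, seed=seed)
    fields: dict[tuple[int, str], PlaceFieldMap] = {}
    for env in environments:
        for direction in directions:
            trials = simulate_run_trials(net, env, direction)
            fields[(env, direction)] = compute_rate_map(
                trials, config.analysis, label=f"env{env}-{direction}"
            )
    sleep = simulate_sleep(net)
    trace = population_rate(sleep, config.analysis)
    pbes = detect_pbes(trace, sleep, config.analysis)
    decoded = {
        traj: decode_ensemble(
            sleep,
            pbes,
            fields[traj],
            config.analysis,
            shuffle_seed=int(substream(seed, "shuffles", *traj).integers(2**31)),
        )
        for traj in decode_trajectories
    }
    graph = summarize_graph(net.conn.ee) if compute_graph else None
    return NetworkBundle(
        network=net,
        sleep=sleep,
        pbes=pbes,
        fields=fields,
        decoded=decoded,
        graph=graph,
        meta={"seed": seed},
    )


@dataclass
class EnsembleResult:
    """A set of networks simulated under one configuration."""

    config: RunConfig
    bundles: list[NetworkBundle]
    significance: PreplaySignificance

    @property
    def events(self) -> list[DecodedEvent]:
        return [d for b in self.bundles for d in b.headline_events]

    def per_network_shifts(self) -> np.ndarray:
        return np.array([b.median_shift() for b in self.bundles])

    def per_network_swi(self) -> np.ndarray:
        return np.array([b.graph.swi for b in self.bundles])


def pooled_significance(
    bundles: Sequence[NetworkBundle], trajectory: tuple[int, str] = HEADLINE_TRAJECTORY
) -> PreplaySignificance:
    """Significance of all networks' events pooled (as for Fig-style CDFs)."""
    events = [d for b in bundles for d in b.decoded[trajectory]]
    return evaluate_preplay(events)


def run_fiducial(
    config: RunConfig | None = None,
    n_networks: int = 10,
    base_seed: int | None = None,
    environments: Sequence[int] = (0,),
    directions: Sequence[str] = ("left", "right"),
    decode_trajectories: Sequence[tuple[int, str]] | None = None,
    compute_graph: bool = True,
) -> EnsembleResult:
    """Simulate an ensemble of networks at one parameter point.

    Seeds are drawn deterministically from the config seed (or
    ``base_seed``), one per network.
    """
    if config is None:
        config = RunConfig()
    config.validate()
    seed = config.seed if base_seed is None else base_seed
    net_seeds = substream(seed, "ensemble").integers(2**31, size=n_networks)
    bundles = [
        simulate_network_bundle(
            config,
            int(s),
            environments=environments,
            directions=directions,
            decode_trajectories=decode_trajectories,
            compute_graph=compute_graph,
        )
        for s in net_seeds
    ]
    return EnsembleResult(
        config=config, bundles=bundles, significance=pooled_significance(bundles)
    )


def identity_shuffle_analysis(
    bundles: Sequence[NetworkBundle],
    mode: str,
    n_replicates: int = 5,
    seed: int = 0,
    trajectory: tuple[int, str] = HEADLINE_TRAJECTORY,
) -> list[PreplaySignificance]:
    """Re-decode sleep events after shuffling cell identities.

    For each replicate, every network's E-cell identities are permuted
    (mode ``across``, ``within_cluster`` or ``within_single_cluster``, see
    :func:`clusterplay.clusterdyn.shuffle_identities`), the already
    detected PBEs are re-decoded with the unshuffled place fields, and the
    pooled ensemble significance is evaluated.  PBE detection itself is
    permutation-invariant, so events are not re-detected.
    """
    from .clusterdyn import shuffle_identities

    out = []
    for rep in range(n_replicates):
        events: list[DecodedEvent] = []
        for b in bundles:
            rng = substream(seed, "identity-shuffle", mode, rep, b.meta["seed"])
            perm = shuffle_identities(b.network.members, mode, rng)
            shuffled_sleep = b.sleep.relabel(perm)
            events.extend(
                decode_ensemble(
                    shuffled_sleep,
                    b.pbes,
                    b.fields[trajectory],
                    b.network.config.analysis,
                    shuffle_seed=int(rng.integers(2**31)),
                )
            )
        out.append(evaluate_preplay(events))
    return out


def scale_w_ee_with_pc(config: RunConfig, p_ee: float) -> RunConfig:
    """Change ``p_ee`` while rescaling ``w_ee`` to keep total E-E input fixed.

    Halving the connection probability doubles the connection strength and
    vice versa (reference density 0.08).
    """
    base = RunConfig().network
    factor = base.p_ee / p_ee
    return with_overrides(config, network={"p_ee": p_ee, "w_ee": base.w_ee * factor})


@dataclass
class GridPointSummary:
    n_clusters: int
    participation: float
    p_ee: float
    feasible: bool
    n_events: int = 0
    ks_statistic: float = float("nan")
    ks_pvalue: float = float("nan")
    median_shift: float = float("nan")
    mean_swi: float = float("nan")
    network_shifts: np.ndarray | None = None
    network_swi: np.ndarray | None = None


def run_grid(
    config: RunConfig | None = None,
    n_clusters_values: Sequence[int] = (8, 15, 30),
    participation_values: Sequence[float] = (1.0, 1.25, 2.5),
    p_ee_values: Sequence[float] = (0.08,),
    n_networks: int = 5,
    sleep_duration: float | None = None,
) -> list[GridPointSummary]:
    """Sweep the (n_clusters, participation, p_ee) grid.

    Infeasible points (within-cluster probability > 1 or participation >
    n_clusters) are returned flagged and skipped.  ``w_ee`` is rescaled
    inversely with ``p_ee``.
    """
    if config is None:
        config = RunConfig()
    out: list[GridPointSummary] = []
    for p_ee in p_ee_values:
        scaled = scale_w_ee_with_pc(config, p_ee)
        for nc in n_clusters_values:
            for mu in participation_values:
                try:
                    point = with_overrides(
                        scaled,
                        network={"n_clusters": nc, "cluster_participation": mu},
                    )
                except ConfigError:
                    out.append(GridPointSummary(nc, mu, p_ee, feasible=False))
                    continue
                if not feasible(point.network):
                    out.append(GridPointSummary(nc, mu, p_ee, feasible=False))
                    continue
                if sleep_duration is not None:
                    point = with_overrides(
                        point, session={"sleep_duration": sleep_duration}
                    )
                res = run_fiducial(point, n_networks=n_networks)
                shifts = res.per_network_shifts()
                out.append(
                    GridPointSummary(
                        nc,
                        mu,
                        p_ee,
                        feasible=True,
                        n_events=res.significance.n_events,
                        ks_statistic=res.significance.ks_statistic,
                        ks_pvalue=res.significance.ks_pvalue,
                        median_shift=res.significance.median_shift,
                        mean_swi=float(res.per_network_swi().mean()),
                        network_shifts=shifts,
                        network_swi=res.per_network_swi(),
                    )
                )
    return out


@dataclass
class MultiEnvResult:
    """Cross-environment remapping and cross-decoding of one ensemble."""

    ensemble: EnsembleResult
    within_env_correlations: list[float]
    cross_env_correlations: list[float]
    significance_by_trajectory: dict[tuple[int, str], PreplaySignificance]


def run_multi_environment(
    config: RunConfig | None = None,
    n_networks: int = 5,
    n_environments: int = 2,
    base_seed: int | None = None,
) -> MultiEnvResult:
    """Simulate several environments and decode each PBE with every map.

    Environments share the network and the raw location-cue weight draws;
    they differ only in the cluster-rank bias permutation and the context
    weights.  Reports population-vector map correlations for
    within-environment (left vs right, same environment) and
    cross-environment trajectory pairs, plus the pooled preplay
    significance under each of the trajectory decodings.
    """
    if config is None:
        config = RunConfig()
    envs = tuple(range(n_environments))
    trajectories = [(e, d) for e in envs for d in ("left", "right")]
    ensemble = run_fiducial(
        config,
        n_networks=n_networks,
        base_seed=base_seed,
        environments=envs,
        decode_trajectories=trajectories,
        compute_graph=False,
    )
    within, cross = [], []
    for b in ensemble.bundles:
        for i, ta in enumerate(trajectories):
            for tb in trajectories[i + 1 :]:
                c = map_correlation(b.fields[ta].rates, b.fields[tb].rates)
                (within if ta[0] == tb[0] else cross).append(c)
    sig = {t: pooled_significance(ensemble.bundles, t) for t in trajectories}
    return MultiEnvResult(
        ensemble=ensemble,
        within_env_correlations=within,
        cross_env_correlations=cross,
        significance_by_trajectory=sig,
    )
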