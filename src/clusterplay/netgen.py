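"""Construction of randomly clustered networks and their input weights.

Excitatory cells are assigned to ``n_clusters`` equally sized, randomly
overlapping clusters.  Recurrent E-to-E connections exist only between
cells that share at least one cluster; the within-cluster connection
probability is raised above the global target ``p_ee`` so that the total
number of connections approaches ``p_ee * nE * (nE - 1)``.  Each
environment is defined purely by a random permutation of cluster rank
biases applied to the two location-cue input weights plus a fresh draw of
context-cue weights: nothing else about the network changes between
environments, which is what makes preplay of arbitrary environments
possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .config import ConfigError, InputParams, NetworkParams, RunConfig

__all__ = [
    "ClusterMembership",
    "Connectivity",
    "EnvironmentSpec",
    "InputWeightSet",
    "NetworkRealization",
    "assign_clusters",
    "within_cluster_probability",
    "build_connectivity",
    "lognormal_weights",
    "generate_input_weights",
    "build_network",
]


@dataclass(frozen=True)
class ClusterMembership:
    """Binary membership of each excitatory cell in each cluster."""

    membership: np.ndarray  # (n_excit, n_clusters) bool

    @property
    def n_excit(self) -> int:
        return self.membership.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.membership.shape[1]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.membership.sum(axis=0)

    @property
    def participation(self) -> np.ndarray:
        """Number of clusters each cell belongs to."""
        return self.membership.sum(axis=1)

    @property
    def mean_participation(self) -> float:
        return float(self.participation.mean())

    def shares_cluster(self) -> np.ndarray:
        """Boolean matrix: do cells i and j share at least one cluster?"""
        m = self.membership.astype(np.int32)
        shared = (m @ m.T) > 0
        np.fill_diagonal(shared, False)
        return shared


@dataclass(frozen=True)
class Connectivity:
    """Directed boolean adjacency blocks. There is no I-to-I block."""

    ee: np.ndarray  # (nE, nE): ee[i, j] is a connection i -> j
    ei: np.ndarray  # (nE, nI)
    ie: np.ndarray  # (nI, nE)


@dataclass(frozen=True)
class EnvironmentSpec:
    """One environment = a permutation of cluster rank biases.

    ``cluster_rank_bias[c]`` is the normalized bias of cluster ``c``,
    evenly spaced in [-1, +1] over a random ordering of the clusters: the
    first cluster in the ordering gets -1 (rightward cue preference), the
    last +1 (leftward preference).
    """

    env_id: int
    cluster_rank_bias: np.ndarray  # (n_clusters,)

    @classmethod
    def draw(cls, env_id: int, n_clusters: int, rng: np.random.Generator) -> "EnvironmentSpec":
        order = rng.permutation(n_clusters)
        bias = np.empty(n_clusters)
        levels = np.linspace(-1.0, 1.0, n_clusters) if n_clusters > 1 else np.zeros(1)
        bias[order] = levels
        return cls(env_id=env_id, cluster_rank_bias=bias)


@dataclass(frozen=True)
class InputWeightSet:
    """Per-neuron feed-forward conductance weights (siemens), full network.

    Location-cue weights are zero for inhibitory cells (they receive only
    the context cue).  ``context`` holds the raw context draw; session-kind
    scaling factors are applied at simulation time.
    """

    w_left: np.ndarray  # (n,)
    w_right: np.ndarray  # (n,)
    w_context: np.ndarray  # (n,)
    bias: np.ndarray  # (n_excit,) per-E-cell bias in [-bias_scale, bias_scale]
    env_id: int | str = 0


def assign_clusters(
    params: NetworkParams, rng: np.random.Generator
) -> ClusterMembership:
    """Randomly assign excitatory cells to equally sized clusters.

    Every cell is first placed in exactly one cluster (round-robin over a
    random ordering of the cells, so base sizes are equal whenever
    ``n_clusters`` divides ``n_excit``).  Each cluster is then topped up
    with ``round(nE * (mu_c - 1) / n_clusters)`` further cells drawn
    without replacement from the cells not already in it, bringing every
    cluster to the same size ``nE * mu_c / n_clusters`` (rounded) and the
    realized mean participation within one rounding step of ``mu_c``.
    """
    params.validate()
    n_e, n_c = params.n_excit, params.n_clusters
    mu = params.cluster_participation
    extra = round(n_e * (mu - 1.0) / n_c)
    base = n_e // n_c
    if base + extra > n_e:
        raise ConfigError("required cluster size exceeds the number of E cells")

    membership = np.zeros((n_e, n_c), dtype=bool)
    order = rng.permutation(n_e)
    for pos, cell in enumerate(order):
        membership[cell, pos % n_c] = True

    for c in range(n_c):
        if extra == 0:
            break
        candidates = np.flatnonzero(~membership[:, c])
        picked = rng.choice(candidates, size=extra, replace=False)
        membership[picked, c] = True
    return ClusterMembership(membership=membership)


def within_cluster_probability(params: NetworkParams) -> float:
    """Within-cluster connection probability calibrated to global ``p_ee``.

    With ``C_tot = nE (nE - 1)`` possible ordered E pairs and
    ``C_clust = n_clust (n_clust - 1) n_c`` possible within-cluster pairs
    (real-valued cluster size ``n_clust = nE mu_c / n_c``), the
    within-cluster probability is ``p_ee * C_tot / C_clust``.

    Raises
    ------
    ConfigError
        If the result exceeds 1, i.e. the requested global density cannot
        be reached through within-cluster connections alone.
    """
    params.validate()
    n_e = params.n_excit
    n_clust = n_e * params.cluster_participation / params.n_clusters
    c_tot = n_e * (n_e - 1)
    c_clust = n_clust * (n_clust - 1) * params.n_clusters
    if c_clust <= 0:
        raise ConfigError("cluster size too small for any within-cluster pair")
    p = params.p_ee * c_tot / c_clust
    if p > 1.0:
        raise ConfigError(
            f"infeasible geometry: within-cluster probability {p:.3f} > 1 "
            f"(n_clusters={params.n_clusters}, "
            f"participation={params.cluster_participation})"
        )
    return p


def feasible(params: NetworkParams) -> bool:
    """Whether the (n_clusters, participation, p_ee) point is realizable."""
    try:
        within_cluster_probability(params)
        return True
    except ConfigError:
        return False


def build_connectivity(
    members: ClusterMembership, params: NetworkParams, rng: np.random.Generator
) -> Connectivity:
    """Sample the directed connectivity.

    Each ordered pair of E cells sharing at least one cluster receives a
    single Bernoulli trial at the within-cluster probability (no self
    connections); E-to-I and I-to-E pairs connect independently with
    probability ``p_ei_ie``; there are no I-to-I connections.
    """
    p_within = within_cluster_probability(params)
    eligible = members.shares_cluster()
    n_e, n_i = params.n_excit, params.n_inhib
    ee = eligible & (rng.random((n_e, n_e)) < p_within)
    ei = rng.random((n_e, n_i)) < params.p_ei_ie
    ie = rng.random((n_i, n_e)) < params.p_ei_ie
    return Connectivity(ee=ee, ei=ei, ie=ie)


def lognormal_weights(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal draws parameterized by their arithmetic mean and SD."""
    if sd == 0:
        return np.full(size, mean)
    mu = math.log(mean**2 / math.sqrt(sd**2 + mean**2))
    sigma = math.sqrt(math.log(1.0 + sd**2 / mean**2))
    return rng.lognormal(mu, sigma, size)


def cell_biases(members: ClusterMembership, env: EnvironmentSpec, bias_scale: float) -> np.ndarray:
    """Per-E-cell location bias: ``bias_scale`` times the mean normalized
    rank of the cell's clusters."""
    m = members.membership
    mean_rank = (m @ env.cluster_rank_bias) / m.sum(axis=1)
    return bias_scale * mean_rank


def generate_input_weights(
    members: ClusterMembership,
    env: EnvironmentSpec,
    net: NetworkParams,
    inputs: InputParams,
    rng_location: np.random.Generator,
    rng_context: np.random.Generator,
) -> InputWeightSet:
    """Draw feed-forward weights for one environment (or sleep session).

    Raw location-cue weights (one independent draw per cue per E cell) are
    drawn from ``rng_location``; each environment redraws them, so
    remapping combines the cluster-rank bias permutation with fresh
    per-cell draws and cross-environment map correlations are near zero
    while cells sharing clusters still remap coherently.  The left cue
    weight is scaled by ``1 + bias`` and the right by ``1 - bias``.
    """
    n, n_e = net.n, net.n_excit
    raw_left = lognormal_weights(inputs.w_in_mean, inputs.w_in_sd, n_e, rng_location)
    raw_right = lognormal_weights(inputs.w_in_mean, inputs.w_in_sd, n_e, rng_location)
    bias = cell_biases(members, env, inputs.bias_scale)

    w_left = np.zeros(n)
    w_right = np.zeros(n)
    w_left[:n_e] = raw_left * (1.0 + bias)
    w_right[:n_e] = raw_right * (1.0 - bias)
    w_context = lognormal_weights(inputs.w_in_mean, inputs.w_context_sd, n, rng_context)
    return InputWeightSet(
        w_left=w_left, w_right=w_right, w_context=w_context, bias=bias, env_id=env.env_id
    )


@dataclass
class NetworkRealization:
    """One random network instance plus its per-environment input weights.

    Excitatory cells are indices ``0 .. n_excit-1``; inhibitory cells are
    ``n_excit .. n-1`` throughout the package.
    """

    config: RunConfig
    members: ClusterMembership
    conn: Connectivity
    seed: int
    _weights_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_excit(self) -> int:
        return self.config.network.n_excit

    def environment(self, env_id: int) -> EnvironmentSpec:
        rng = substream(self.seed, "environment", env_id)
        return EnvironmentSpec.draw(env_id, self.config.network.n_clusters, rng)

    def input_weights(self, session: int | str) -> InputWeightSet:
        """Weights for environment ``env_id`` (int) or the ``"sleep"`` session.

        The sleep session has no location bias (bias enters only through
        the location cues, which are silent during sleep) but its own
        unique context-weight draw.
        """
        if session in self._weights_cache:
            return self._weights_cache[session]
        net, inputs = self.config.network, self.config.inputs
        rng_ctx = substream(self.seed, "weights", "context", session)
        if session == "sleep":
            n = net.n
            w = InputWeightSet(
                w_left=np.zeros(n),
                w_right=np.zeros(n),
                w_context=lognormal_weights(
                    inputs.w_in_mean, inputs.w_context_sd, n, rng_ctx
                ),
                bias=np.zeros(net.n_excit),
                env_id="sleep",
            )
        else:
            rng_loc = substream(self.seed, "weights", "location", session)
            w = generate_input_weights(
                self.members, self.environment(session), net, inputs, rng_loc, rng_ctx
            )
        self._weights_cache[session] = w
        return w


def build_network(config: RunConfig, seed: int | None = None) -> NetworkRealization:
    """Build one network realization (clusters + connectivity) from a seed."""
    config.validate()
    seed = config.seed if seed is None else seed
    members = assign_clusters(config.network, substream(seed, "clusters"))
    conn = build_connectivity(members, config.network, substream(seed, "connectivity"))
    return NetworkRealization(config=config, members=members, conn=conn, seed=seed)
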