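"""Conductance-based LIF network simulation of run and sleep sessions.

A *run* session is one constant-speed traversal of the 1 m linear track
(2 s per lap at 1x speed).  During run, each excitatory cell receives two
linearly ramping location cues whose Poisson rates always sum to the peak
rate, plus a position-independent context cue whose weight is scaled down
for E cells (``f_e_awake``).  A *sleep* session has the location cues
silent; only the context cue drives the network (E weight unscaled,
I weight scaled by ``f_i_sleep``), and activity is fluctuation-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from ._kernels import _lif_session, adjacency_to_csr
from ._rng import kernel_seed, substream
from .config import CellParams
from .netgen import InputWeightSet, NetworkRealization

__all__ = [
    "StimulusProtocol",
    "NeuronState",
    "SpikeRecord",
    "location_cue_rates",
    "initialize_state",
    "simulate_session",
    "simulate_run_trials",
    "simulate_sleep",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus schedule for one session.

    ``x_start``/``x_end`` give the track-fraction trajectory endpoints of
    a run session (traversed at constant speed); they are ignored during
    sleep, when the location-cue rate is identically zero.
    """

    kind: str  # "run" | "sleep"
    duration: float
    x_start: float = 0.0
    x_end: float = 1.0
    speed: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("run", "sleep"):
            raise ValueError("kind must be 'run' or 'sleep'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def position(self, t: np.ndarray | float) -> np.ndarray | float:
        """Track fraction at time ``t`` (run sessions are constant-speed)."""
        return self.x_start + (self.x_end - self.x_start) * np.asarray(t) / self.duration

    @classmethod
    def run_lap(cls, direction: str, lap_duration: float = 2.0, speed: float = 1.0) -> "StimulusProtocol":
        """One lap; ``direction`` 'right' runs x: 0 -> 1, 'left' x: 1 -> 0."""
        if direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        x0, x1 = (0.0, 1.0) if direction == "right" else (1.0, 0.0)
        return cls(
            kind="run",
            duration=lap_duration / speed,
            x_start=x0,
            x_end=x1,
            speed=speed,
            label=direction,
        )

    @classmethod
    def sleep(cls, duration: float) -> "StimulusProtocol":
        return cls(kind="sleep", duration=duration, label="sleep")


def location_cue_rates(x: float, rate_peak: float = 5000.0) -> tuple[float, float]:
    """Poisson rates (Hz) of the two location cues at track fraction ``x``.

    The left cue peaks at ``x = 0`` and falls linearly to zero at ``x = 1``;
    the right cue is its mirror, so the two rates always sum to
    ``rate_peak``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("track fraction must lie in [0, 1]")
    return rate_peak * (1.0 - x), rate_peak * x


@dataclass
class NeuronState:
    """Full dynamical state of the network at one instant."""

    v: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    g_sra: np.ndarray
    g_ext: np.ndarray


@dataclass
class SpikeRecord:
    """Timestamped spikes of all neurons for one session.

    ``ids``/``times`` are sorted by time; excitatory cells are ids
    ``< n_excit``.
    """

    ids: np.ndarray
    times: np.ndarray
    duration: float
    n_neurons: int
    n_excit: int
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.ids)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def excitatory(self) -> "SpikeRecord":
        keep = self.ids < self.n_excit
        return replace(self, ids=self.ids[keep], times=self.times[keep])

    def window(self, start: float, end: float) -> "SpikeRecord":
        keep = (self.times >= start) & (self.times <= end)
        return replace(self, ids=self.ids[keep], times=self.times[keep])

    def relabel(self, permutation: np.ndarray) -> "SpikeRecord":
        """Map E-cell spike ids through ``permutation`` (identity for I)."""
        full = np.arange(self.n_neurons)
        full[: self.n_excit] = permutation
        return replace(self, ids=full[self.ids].astype(self.ids.dtype))

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rate (Hz) over the session."""
        return np.bincount(self.ids, minlength=self.n_neurons) / self.duration


def _context_scale(kind: str, inputs) -> tuple[float, float]:
    if kind == "run":
        return inputs.f_e_awake, inputs.f_i_awake
    return inputs.f_e_sleep, inputs.f_i_sleep


def _effective_context(network: NetworkRealization, weights: InputWeightSet, kind: str) -> np.ndarray:
    f_e, f_i = _context_scale(kind, network.config.inputs)
    n_e = network.n_excit
    w = weights.w_context.copy()
    w[:n_e] *= f_e
    w[n_e:] *= f_i
    return w


def initialize_state(
    network: NetworkRealization,
    weights: InputWeightSet,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
) -> NeuronState:
    """Initial conditions approximating feed-forward steady state.

    The membrane starts at the leak reversal; recurrent and SRA
    conductances start at zero.  The feed-forward conductance of each cue
    is drawn from a Gaussian at its steady-state mean ``w * rate * tau_e``
    with the shot-noise standard deviation ``w * sqrt(rate * tau_e / 2)``
    (truncated at zero), evaluated at the session's starting position.
    """
    cells = network.config.cells
    inputs = network.config.inputs
    n = network.config.network.n
    v = np.full(n, cells.e_leak)

    if protocol.kind == "run":
        r_left, r_right = location_cue_rates(protocol.x_start, inputs.rate_peak)
    else:
        r_left = r_right = 0.0
    r_ctx = inputs.rate_peak
    w_ctx = _effective_context(network, weights, protocol.kind)

    g_ext = np.zeros(n)
    for w, rate in (
        (weights.w_left, r_left),
        (weights.w_right, r_right),
        (w_ctx, r_ctx),
    ):
        if rate <= 0:
            continue
        mean = w * rate * cells.tau_e
        sd = w * np.sqrt(rate * cells.tau_e / 2.0)
        g_ext += np.maximum(0.0, rng.normal(mean, sd))

    zeros = np.zeros(n)
    return NeuronState(v=v, g_e=zeros.copy(), g_i=zeros.copy(), g_sra=zeros.copy(), g_ext=g_ext)


def _csr(network: NetworkRealization):
    cache = getattr(network, "_csr_cache", None)
    if cache is None:
        n_e = network.n_excit
        cache = (
            *adjacency_to_csr(network.conn.ee),
            *adjacency_to_csr(network.conn.ei, offset=n_e),
            *adjacency_to_csr(network.conn.ie),
        )
        network._csr_cache = cache
    return cache


def simulate_session(
    network: NetworkRealization,
    weights: InputWeightSet,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    state: NeuronState | None = None,
    record_v: int | None = None,
    mean_rate_capacity: float = 50.0,
) -> SpikeRecord:
    """Integrate one session and return its spikes.

    Parameters
    ----------
    rng
        Source for the initial state and the session's Poisson input
        stream.
    state
        Optional explicit initial state (defaults to
        :func:`initialize_state`).
    record_v
        If given, the membrane trace of that neuron is stored in
        ``record.meta['v_trace']``.
    mean_rate_capacity
        Spike-buffer headroom in Hz per neuron; the simulation aborts with
        a diagnostic if exceeded (runaway excitation).
    """
    config = network.config
    cells: CellParams = config.cells
    net = config.network
    inputs = config.inputs
    n, n_e = net.n, net.n_excit

    if state is None:
        state = initialize_state(network, weights, protocol, rng)
    n_steps = int(round(protocol.duration / cells.dt))
    rate_loc = inputs.rate_peak if protocol.kind == "run" else 0.0
    w_ctx = _effective_context(network, weights, protocol.kind)

    ee_indptr, ee_idx, ei_indptr, ei_idx, ie_indptr, ie_idx = _csr(network)
    max_spikes = int(mean_rate_capacity * n * protocol.duration) + 1000

    out = _lif_session(
        n_steps,
        cells.dt,
        n,
        n_e,
        cells.v_thresh,
        cells.v_reset,
        cells.e_leak,
        cells.e_inh,
        cells.e_sra,
        cells.c_m,
        cells.g_leak,
        cells.delta_sra,
        np.exp(-cells.dt / cells.tau_e),
        np.exp(-cells.dt / cells.tau_i),
        np.exp(-cells.dt / cells.tau_sra),
        np.exp(-cells.dt / cells.tau_e),  # g_ext decays with tau_e
        ee_indptr,
        ee_idx,
        ei_indptr,
        ei_idx,
        ie_indptr,
        ie_idx,
        net.w_ee,
        net.w_ei,
        net.w_ie,
        weights.w_left,
        weights.w_right,
        w_ctx,
        rate_loc,
        inputs.rate_peak,
        protocol.x_start,
        protocol.x_end,
        state.v,
        state.g_e,
        state.g_i,
        state.g_sra,
        state.g_ext,
        kernel_seed(rng),
        -1 if record_v is None else int(record_v),
        max_spikes,
    )
    spike_ids, spike_times, n_spikes, v, g_e, g_i, g_sra, g_ext, v_trace = out
    if n_spikes == -1:
        raise RuntimeError(
            f"spike buffer exceeded ({mean_rate_capacity} Hz/neuron) in "
            f"session '{protocol.label}': runaway excitation"
        )
    if n_spikes == -2:
        raise FloatingPointError(
            f"membrane potential diverged in session '{protocol.label}'"
        )

    meta: dict[str, Any] = {
        "kind": protocol.kind,
        "label": protocol.label,
        "env": weights.env_id,
        "x_start": protocol.x_start,
        "x_end": protocol.x_end,
        "final_state": NeuronState(v=v, g_e=g_e, g_i=g_i, g_sra=g_sra, g_ext=g_ext),
    }
    if record_v is not None:
        meta["v_trace"] = v_trace
    return SpikeRecord(
        ids=spike_ids[:n_spikes].copy(),
        times=spike_times[:n_spikes].copy(),
        duration=protocol.duration,
        n_neurons=n,
        n_excit=n_e,
        meta=meta,
    )


def simulate_run_trials(
    network: NetworkRealization,
    env_id: int,
    direction: str,
    n_laps: int | None = None,
    speed: float = 1.0,
) -> list[SpikeRecord]:
    """Simulate ``n_laps`` independent constant-speed laps of a trajectory."""
    plan = network.config.session
    if n_laps is None:
        n_laps = plan.laps_per_trajectory
    weights = network.input_weights(env_id)
    records = []
    for lap in range(n_laps):
        protocol = StimulusProtocol.run_lap(direction, plan.lap_duration, speed)
        rng = substream(network.seed, "session", "run", env_id, direction, speed, lap)
        rec = simulate_session(network, weights, protocol, rng)
        rec.meta.update(trial=lap, env=env_id, direction=direction, speed=speed)
        records.append(rec)
    return records


def simulate_sleep(
    network: NetworkRealization, duration: float | None = None
) -> SpikeRecord:
    """Simulate the sleep session (context cue only, no location input)."""
    if duration is None:
        duration = network.config.session.sleep_duration
    if duration == 0:
        n = network.config.network.n
        return SpikeRecord(
            ids=np.empty(0, dtype=np.int32),
            times=np.empty(0),
            duration=0.0,
            n_neurons=n,
            n_excit=network.n_excit,
            meta={"kind": "sleep", "label": "sleep", "env": "sleep"},
        )
    weights = network.input_weights("sleep")
    protocol = StimulusProtocol.sleep(duration)
    rng = substream(network.seed, "session", "sleep")
    return simulate_session(network, weights, protocol, rng)
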