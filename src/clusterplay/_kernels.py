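"""Numba forward-Euler kernel for the conductance-based LIF network.

The integrator advances all neurons on a fixed grid ``dt``:

1. feed-forward Poisson input counts are drawn per neuron per cue
   (exact Poisson inversion sampling with mean ``rate * dt``, so the
   input statistics are independent of the step size) and immediately
   step ``g_ext`` by that neuron's cue weight per input spike;
2. the membrane is updated with the current conductances,
   ``C_m dV/dt = -g_L(V-E_L) - g_E(V-E_E) - g_I(V-E_I)
   - g_SRA(V-E_SRA) - g_ext V``  (the external reversal equals ``E_E = 0``);
3. all conductances decay by their per-step exponential factors;
4. neurons at or above threshold spike: the spike is recorded at the end
   of the step, the membrane is reset, ``g_SRA`` steps by ``delta_sra``,
   and recurrent conductance steps are delivered to postsynaptic targets
   (taking effect from the next step).

Poisson draws use an inline xorshift64* stream, one state per session,
which keeps the hot loop cheap and the whole session reproducible from a
single 64-bit seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.types import float64, uint64

_MULT = np.uint64(0x2545F4914F6CDD1D)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=False)
def _lif_session(
    n_steps: int,
    dt: float,
    n: int,
    n_excit: int,
    # cell parameters
    v_thresh: float,
    v_reset: float,
    e_leak: float,
    e_inh: float,
    e_sra: float,
    c_m: float,
    g_leak: float,
    delta_sra: float,
    decay_e: float,
    decay_i: float,
    decay_sra: float,
    decay_ext: float,
    # recurrent connectivity (CSR target lists)
    ee_indptr,
    ee_idx,
    ei_indptr,
    ei_idx,
    ie_indptr,
    ie_idx,
    w_ee: float,
    w_ei: float,
    w_ie: float,
    # feed-forward input
    w_left,
    w_right,
    w_ctx,
    rate_loc: float,
    rate_ctx: float,
    x_start: float,
    x_end: float,
    # initial state
    v0,
    g_e0,
    g_i0,
    g_sra0,
    g_ext0,
    rng_state: int,
    v_trace_id: int,
    max_spikes: int,
):
    v = v0.copy()
    g_e = g_e0.copy()
    g_i = g_i0.copy()
    g_sra = g_sra0.copy()
    g_ext = g_ext0.copy()

    spike_ids = np.empty(max_spikes, dtype=np.int32)
    spike_times = np.empty(max_spikes, dtype=np.float64)
    n_spikes = 0
    v_trace = np.empty(n_steps if v_trace_id >= 0 else 0, dtype=np.float64)

    s = uint64(rng_state)
    lam_ctx = rate_ctx * dt
    exp_ctx = np.exp(-lam_ctx)
    have_ctx = rate_ctx > 0.0
    have_loc = rate_loc > 0.0
    dx = (x_end - x_start) / n_steps if n_steps > 0 else 0.0
    inv_cm = dt / c_m

    for t in range(n_steps):
        x = x_start + dx * t
        lam_left = rate_loc * (1.0 - x) * dt
        lam_right = rate_loc * x * dt
        exp_left = np.exp(-lam_left)
        exp_right = np.exp(-lam_right)
        for i in range(n):
            # feed-forward Poisson counts per step (inversion sampling);
            # location cues reach E cells only
            if have_loc and i < n_excit:
                s ^= s << uint64(13)
                s ^= s >> uint64(7)
                s ^= s << uint64(17)
                u = float64((s * _MULT) >> uint64(11)) * _INV53
                if u > exp_left:
                    k = 0
                    term = exp_left
                    cum = exp_left
                    while u > cum:
                        k += 1
                        term *= lam_left / k
                        cum += term
                    g_ext[i] += k * w_left[i]
                s ^= s << uint64(13)
                s ^= s >> uint64(7)
                s ^= s << uint64(17)
                u = float64((s * _MULT) >> uint64(11)) * _INV53
                if u > exp_right:
                    k = 0
                    term = exp_right
                    cum = exp_right
                    while u > cum:
                        k += 1
                        term *= lam_right / k
                        cum += term
                    g_ext[i] += k * w_right[i]
            if have_ctx:
                s ^= s << uint64(13)
                s ^= s >> uint64(7)
                s ^= s << uint64(17)
                u = float64((s * _MULT) >> uint64(11)) * _INV53
                if u > exp_ctx:
                    k = 0
                    term = exp_ctx
                    cum = exp_ctx
                    while u > cum:
                        k += 1
                        term *= lam_ctx / k
                        cum += term
                    g_ext[i] += k * w_ctx[i]

            # membrane update (E_E = E_ext = 0 mV)
            vi = v[i]
            v[i] = vi + inv_cm * (
                -g_leak * (vi - e_leak)
                - g_e[i] * vi
                - g_i[i] * (vi - e_inh)
                - g_sra[i] * (vi - e_sra)
                - g_ext[i] * vi
            )
            g_e[i] *= decay_e
            g_i[i] *= decay_i
            g_sra[i] *= decay_sra
            g_ext[i] *= decay_ext

        if v_trace_id >= 0:
            v_trace[t] = v[v_trace_id]

        for i in range(n):
            if v[i] >= v_thresh:
                if n_spikes >= max_spikes:
                    return spike_ids, spike_times, -1, v, g_e, g_i, g_sra, g_ext, v_trace
                spike_ids[n_spikes] = i
                spike_times[n_spikes] = (t + 1) * dt
                n_spikes += 1
                v[i] = v_reset
                g_sra[i] += delta_sra
                if i < n_excit:
                    for k in range(ee_indptr[i], ee_indptr[i + 1]):
                        g_e[ee_idx[k]] += w_ee
                    for k in range(ei_indptr[i], ei_indptr[i + 1]):
                        g_e[ei_idx[k]] += w_ei
                else:
                    j = i - n_excit
                    for k in range(ie_indptr[j], ie_indptr[j + 1]):
                        g_i[ie_idx[k]] += w_ie

        if t % 1000 == 999:  # guard against numerical blow-up
            for i in range(n):
                if np.abs(v[i]) > 1.0:  # |V| beyond any physical value
                    return spike_ids, spike_times, -2, v, g_e, g_i, g_sra, g_ext, v_trace

    return spike_ids, spike_times, n_spikes, v, g_e, g_i, g_sra, g_ext, v_trace


def adjacency_to_csr(block: np.ndarray, offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Convert a boolean adjacency block to CSR (indptr, target indices)."""
    counts = block.sum(axis=1)
    indptr = np.zeros(block.shape[0] + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    idx = (np.nonzero(block)[1] + offset).astype(np.int64)
    return indptr, idx
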