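"""Memoryless Bayesian decoding of population burst events.

Spikes of place cells (field peak > 3 Hz) are binned at 10 ms from event
start; per time bin, the posterior over the 50 spatial bins is

    P(x | s)  ∝  prod_i r_i(x)^{s_i} * exp(-tau * sum_i r_i(x)),

the independent-Poisson likelihood with a uniform position prior.  Each
event yields a signed weighted space-time correlation r (posterior
probabilities as weights; |r| measures sequence linearity, the sign its
direction), the maximum jump distance of the posterior peak between
adjacent bins, and the mean per-bin entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import AnalysisParams
from .events import PBE
from .lifsim import SpikeRecord
from .placefield import PlaceFieldMap

__all__ = [
    "PosteriorMatrix",
    "EventDecodeStats",
    "bin_event_spikes",
    "decode_counts",
    "decode_event",
    "weighted_correlation",
    "max_jump",
    "event_entropy",
    "decode_stats",
]


@dataclass
class PosteriorMatrix:
    """Decoded position probability, (n_spatial_bins, n_time_bins)."""

    p: np.ndarray
    bin_width: float
    event: PBE | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_time_bins(self) -> int:
        return self.p.shape[1]


@dataclass(frozen=True)
class EventDecodeStats:
    """Per-event trajectory statistics."""

    r: float  # signed weighted correlation
    abs_r: float
    max_jump: float  # fraction of track length
    entropy: float  # bits, mean over time bins


def bin_event_spikes(
    spikes: SpikeRecord,
    event: PBE,
    cell_ids: np.ndarray,
    bin_width: float = 10e-3,
) -> np.ndarray:
    """Spike-count matrix (len(cell_ids), n_bins) tiled from event start.

    A final partial bin shorter than ``bin_width`` is dropped so that the
    Poisson window ``tau`` is constant across columns.
    """
    n_bins = int((event.end - event.start) / bin_width + 1e-9)
    counts = np.zeros((len(cell_ids), n_bins), dtype=np.int64)
    if n_bins == 0:
        return counts
    lookup = -np.ones(spikes.n_neurons, dtype=np.int64)
    lookup[cell_ids] = np.arange(len(cell_ids))
    sel = (spikes.times >= event.start) & (spikes.times < event.start + n_bins * bin_width)
    rows = lookup[spikes.ids[sel]]
    cols = ((spikes.times[sel] - event.start) / bin_width).astype(np.int64)
    keep = rows >= 0
    np.add.at(counts, (rows[keep], cols[keep]), 1)
    return counts


def decode_counts(
    counts: np.ndarray,
    rates: np.ndarray,
    tau: float = 10e-3,
    rate_floor: float = 0.01,
) -> np.ndarray:
    """Posterior matrix from binned spike counts and place-field rates.

    ``rates`` is (n_cells, n_spatial_bins) in Hz; rates are clamped below
    at ``rate_floor`` Hz so that a spike from a cell silent at some
    position does not zero the whole likelihood.  Columns are normalized
    in log space for numerical stability.  Zero-spike columns follow the
    same formula (likelihood ``exp(-tau * sum_i r_i(x))``).
    """
    r = np.maximum(np.asarray(rates, dtype=float), rate_floor)
    log_r = np.log(r)
    # (n_spatial, n_time): sum_i s_i log r_i(x) - tau * sum_i r_i(x)
    log_l = log_r.T @ counts - tau * r.sum(axis=0)[:, None]
    log_l -= log_l.max(axis=0, keepdims=True)
    p = np.exp(log_l)
    return p / p.sum(axis=0, keepdims=True)


def decode_event(
    spikes: SpikeRecord,
    event: PBE,
    fields: PlaceFieldMap,
    analysis: AnalysisParams | None = None,
    place_cell_mask: np.ndarray | None = None,
) -> PosteriorMatrix:
    """Decode one PBE with the place fields of one trajectory."""
    if analysis is None:
        analysis = AnalysisParams()
    if place_cell_mask is None:
        place_cell_mask = fields.place_cell_mask(analysis.place_peak_min_rate)
    cell_ids = np.flatnonzero(place_cell_mask)
    counts = bin_event_spikes(spikes, event, cell_ids, analysis.decode_bin)
    p = decode_counts(
        counts,
        fields.rates[cell_ids],
        tau=analysis.decode_bin,
        rate_floor=analysis.decode_rate_floor,
    )
    return PosteriorMatrix(
        p=p, bin_width=analysis.decode_bin, event=event, meta={"fields": fields.label}
    )


def weighted_correlation(p: np.ndarray) -> float:
    """Signed weighted Pearson correlation of position vs time.

    Every space-time cell contributes the point (time-bin center,
    position-bin center) with weight equal to its decoded probability.
    Returns NaN when the weighted variance of either coordinate vanishes
    (e.g. a single time bin, or a time-independent point-mass posterior).
    """
    p = np.asarray(p, dtype=float)
    n_x, n_t = p.shape
    if n_t < 2:
        return float("nan")
    w = p / p.sum()
    x = (np.arange(n_x) + 0.5) / n_x
    t = np.arange(n_t) + 0.5
    mx = float((w.sum(axis=1) * x).sum())
    mt = float((w.sum(axis=0) * t).sum())
    dx = x - mx
    dt_ = t - mt
    cov = float(dx @ w @ dt_)
    var_x = float((w.sum(axis=1) * dx**2).sum())
    var_t = float((w.sum(axis=0) * dt_**2).sum())
    if var_x <= 0 or var_t <= 0:
        return float("nan")
    return cov / np.sqrt(var_x * var_t)


def max_jump(p: np.ndarray) -> float:
    """Maximum jump of the posterior peak between adjacent time bins.

    Expressed as a fraction of the track length; argmax ties break toward
    the lowest bin index.
    """
    p = np.asarray(p)
    peaks = p.argmax(axis=0)
    if len(peaks) < 2:
        return 0.0
    return float(np.abs(np.diff(peaks)).max() / p.shape[0])


def event_entropy(p: np.ndarray) -> float:
    """Mean over time bins of the position-probability entropy (bits)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return float(-terms.sum(axis=0).mean())


def decode_stats(p: np.ndarray) -> EventDecodeStats:
    r = weighted_correlation(p)
    return EventDecodeStats(
        r=r, abs_r=abs(r), max_jump=max_jump(p), entropy=event_entropy(p)
    )
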