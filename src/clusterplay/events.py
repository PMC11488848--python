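"""Population-burst-event (PBE) detection in sleep spike data.

The excitatory population rate (mean instantaneous rate per E cell,
Gaussian-smoothed with a 15 ms SD kernel on the simulation grid) is
thresholded at mean + 1 SD of the whole session.  Excursions must last at
least 30 ms and peak above 0.5 Hz; events separated by less than 10 ms
are merged.  Events with at least 5 participating E cells and at least
50 ms duration are flagged decodable and become preplay candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import AnalysisParams
from .lifsim import SpikeRecord

__all__ = ["PopulationRateTrace", "PBE", "PBEList", "population_rate", "detect_pbes"]


@dataclass
class PopulationRateTrace:
    """Smoothed mean E-cell firing rate on a uniform time grid."""

    rate: np.ndarray  # Hz per cell
    dt: float
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        self.mean = float(self.rate.mean()) if len(self.rate) else 0.0
        self.sd = float(self.rate.std()) if len(self.rate) else 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.rate)) * self.dt


@dataclass
class PBE:
    """One population burst event."""

    start: float
    end: float
    n_cells: int
    peak_rate: float
    decodable: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PBEList:
    events: list[PBE] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def decodable(self) -> list[PBE]:
        return [e for e in self.events if e.decodable]


def population_rate(
    spikes: SpikeRecord, analysis: AnalysisParams | None = None, grid_dt: float | None = None
) -> PopulationRateTrace:
    """Smoothed mean firing rate of the excitatory population.

    Spike counts are binned on ``grid_dt`` (defaults to the simulation
    step), converted to Hz per E cell, and smoothed with a Gaussian kernel
    of SD ``pbe_smooth_sd`` truncated at 4 SD.
    """
    if analysis is None:
        analysis = AnalysisParams()
    if grid_dt is None:
        grid_dt = spikes.meta.get("dt", 1e-4)
    n_steps = int(round(spikes.duration / grid_dt))
    if n_steps == 0:
        return PopulationRateTrace(rate=np.zeros(0), dt=grid_dt)
    keep = spikes.ids < spikes.n_excit
    bins = np.minimum((spikes.times[keep] / grid_dt).astype(np.int64), n_steps - 1)
    counts = np.bincount(bins, minlength=n_steps).astype(float)
    rate = counts / (spikes.n_excit * grid_dt)
    smoothed = gaussian_filter1d(rate, analysis.pbe_smooth_sd / grid_dt, truncate=4.0)
    return PopulationRateTrace(rate=smoothed, dt=grid_dt)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open index intervals."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_pbes(
    trace: PopulationRateTrace,
    spikes: SpikeRecord,
    analysis: AnalysisParams | None = None,
) -> PBEList:
    """Detect PBEs from a population-rate trace.

    Threshold = session mean + ``pbe_threshold_sd`` SDs (statistics over
    the whole session, events included).  Candidate excursions are gated
    on duration (>= 30 ms) and peak rate (>= 0.5 Hz), then merged when the
    gap between consecutive events is shorter than 10 ms.  Event
    boundaries are the threshold crossings of the smoothed trace.
    """
    if analysis is None:
        analysis = AnalysisParams()
    thresh = trace.mean + analysis.pbe_threshold_sd * trace.sd
    dt = trace.dt
    candidates = []
    for i0, i1 in _runs_above(trace.rate > thresh):
        duration = (i1 - i0) * dt
        peak = trace.rate[i0:i1].max()
        if duration >= analysis.pbe_min_duration and peak >= analysis.pbe_min_peak_rate:
            candidates.append([i0 * dt, i1 * dt, peak])

    merged: list[list[float]] = []
    for start, end, peak in candidates:
        if merged and start - merged[-1][1] < analysis.pbe_merge_gap:
            merged[-1][1] = end
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([start, end, peak])

    events = []
    e_ids = spikes.ids[spikes.ids < spikes.n_excit]
    e_times = spikes.times[spikes.ids < spikes.n_excit]
    for start, end, peak in merged:
        in_win = (e_times >= start) & (e_times <= end)
        n_cells = len(np.unique(e_ids[in_win]))
        decodable = (
            n_cells >= analysis.decode_min_cells
            and (end - start) >= analysis.decode_min_duration
        )
        events.append(
            PBE(start=start, end=end, n_cells=n_cells, peak_rate=float(peak), decodable=decodable)
        )
    return PBEList(events=events, meta={"threshold": thresh, "mean": trace.mean, "sd": trace.sd})
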