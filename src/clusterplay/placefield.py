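"""Place-field (and time-field) rate maps and their summary statistics.

Rate maps are trial-averaged, occupancy-discounted firing rates in fifty
2 cm bins of the 1 m track, smoothed with a 4 cm (2-bin) Gaussian kernel.
Under the constant-speed protocol the occupancy is uniform, so the
discounting is a constant factor.  Cells whose smoothed map peaks above
3 Hz are treated as place cells for statistics and decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .config import AnalysisParams
from .lifsim import SpikeRecord

__all__ = [
    "PlaceFieldMap",
    "smooth_map",
    "compute_rate_map",
    "compute_time_fields",
    "specificity",
    "spatial_information",
    "peak_distribution_kl",
    "central_third_fraction",
    "map_correlation",
    "field_center_of_mass",
]


def _smoothing_matrix(n_bins: int, sd_bins: float) -> np.ndarray:
    """Truncated-renormalized Gaussian smoothing as a (n_bins, n_bins) matrix.

    Each output bin is a Gaussian-weighted average of the input bins with
    the kernel renormalized over the bins that fall inside the track, so a
    constant map stays exactly constant and no rate mass leaks off-track.
    """
    centers = np.arange(n_bins)
    k = np.exp(-0.5 * ((centers[:, None] - centers[None, :]) / sd_bins) ** 2)
    return k / k.sum(axis=1, keepdims=True)


def smooth_map(rates: np.ndarray, sd_bins: float) -> np.ndarray:
    """Smooth rows of ``rates`` with the truncated-renormalized kernel."""
    m = _smoothing_matrix(rates.shape[-1], sd_bins)
    return rates @ m.T


@dataclass
class PlaceFieldMap:
    """Binned, smoothed firing-rate map of all E cells for one trajectory."""

    rates: np.ndarray  # (n_cells, n_bins) Hz, smoothed
    raw_rates: np.ndarray  # pre-smoothing
    label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def peak_rates(self) -> np.ndarray:
        return self.rates.max(axis=1)

    @property
    def peak_bins(self) -> np.ndarray:
        """Peak bin per cell; ties broken toward the lowest bin index."""
        return self.rates.argmax(axis=1)

    def place_cell_mask(self, min_peak_rate: float = 3.0) -> np.ndarray:
        return self.peak_rates > min_peak_rate

    def reflected(self) -> "PlaceFieldMap":
        return PlaceFieldMap(
            rates=self.rates[:, ::-1].copy(),
            raw_rates=self.raw_rates[:, ::-1].copy(),
            label=self.label + "-reflected",
            meta=dict(self.meta),
        )


def compute_rate_map(
    trials: Sequence[SpikeRecord],
    analysis: AnalysisParams | None = None,
    label: str = "",
) -> PlaceFieldMap:
    """Compute the trial-averaged place-field map of all excitatory cells.

    Each trial must be a constant-speed traversal carrying its trajectory
    endpoints in ``meta['x_start']/['x_end']``; spike times are mapped to
    track fractions through the trial's linear trajectory, binned, divided
    by per-bin occupancy time, averaged over trials, then smoothed.
    """
    if analysis is None:
        analysis = AnalysisParams()
    if not trials:
        raise ValueError("need at least one trial")
    n_bins = analysis.n_spatial_bins
    n_e = trials[0].n_excit
    acc = np.zeros((n_e, n_bins))
    for rec in trials:
        x0 = rec.meta.get("x_start", 0.0)
        x1 = rec.meta.get("x_end", 1.0)
        occupancy = rec.duration / n_bins
        keep = rec.ids < n_e
        ids = rec.ids[keep]
        x = x0 + (x1 - x0) * rec.times[keep] / rec.duration
        bins = np.minimum((x * n_bins).astype(np.int64), n_bins - 1)
        counts = np.zeros((n_e, n_bins))
        np.add.at(counts, (ids, bins), 1.0)
        acc += counts / occupancy
    raw = acc / len(trials)
    sd_bins = analysis.field_smooth_sd / (analysis.track_length / n_bins)
    return PlaceFieldMap(
        rates=smooth_map(raw, sd_bins),
        raw_rates=raw,
        label=label,
        meta={"n_trials": len(trials)},
    )


def compute_time_fields(
    trials: Sequence[SpikeRecord],
    analysis: AnalysisParams | None = None,
    window: float = 2.0,
    label: str = "time",
) -> PlaceFieldMap:
    """Rate map binned in *time* (fifty 40 ms bins over the first 2 s).

    Combining trials run at different speeds dissociates place from time
    coding: a location-locked cell keeps its spatial bin but shifts its
    time bin when the speed changes.
    """
    if analysis is None:
        analysis = AnalysisParams()
    n_bins = analysis.n_spatial_bins
    bin_width = window / n_bins
    n_e = trials[0].n_excit
    acc = np.zeros((n_e, n_bins))
    for rec in trials:
        keep = (rec.ids < n_e) & (rec.times < window)
        ids = rec.ids[keep]
        bins = np.minimum((rec.times[keep] / bin_width).astype(np.int64), n_bins - 1)
        counts = np.zeros((n_e, n_bins))
        np.add.at(counts, (ids, bins), 1.0)
        acc += counts / bin_width
    raw = acc / len(trials)
    sd_bins = analysis.field_smooth_sd / (analysis.track_length / n_bins)
    return PlaceFieldMap(rates=smooth_map(raw, sd_bins), raw_rates=raw, label=label)


def specificity(rates: np.ndarray) -> float:
    """1 minus the fraction of bins whose rate exceeds 25% of the peak.

    A cell firing uniformly scores 0; a cell firing in a single bin scores
    ``1 - 1/n_bins``.  Undefined (ValueError) for an all-zero map.
    """
    rates = np.asarray(rates, dtype=float)
    peak = rates.max()
    if peak <= 0:
        raise ValueError("specificity undefined for an all-zero field")
    return 1.0 - np.mean(rates > 0.25 * peak)


def spatial_information(rates: np.ndarray, occupancy: np.ndarray | None = None) -> float:
    """Spatial information in bits/spike: ``sum_i p_i (r_i/rbar) log2(r_i/rbar)``.

    ``occupancy`` defaults to uniform.  Zero-rate bins contribute zero (the
    ``x log x -> 0`` limit); the result lies in ``[0, log2 n_bins]``.
    """
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    p = np.full(n, 1.0 / n) if occupancy is None else np.asarray(occupancy, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1")
    rbar = float(p @ rates)
    if rbar <= 0:
        raise ValueError("spatial information undefined for an all-zero field")
    rel = rates / rbar
    terms = np.zeros(n)
    pos = rel > 0
    terms[pos] = p[pos] * rel[pos] * np.log2(rel[pos])
    return float(terms.sum())


def peak_distribution_kl(peak_bins: np.ndarray, n_bins: int = 50) -> float:
    """KL divergence (bits) of the peak-bin distribution from uniform.

    ``D_KL = sum_i p_i^data log2(p_i^data / p_i^uniform)``; 0 for a
    perfectly uniform peak distribution, ``log2 n_bins`` if all peaks share
    one bin.  Empty bins contribute 0.
    """
    peak_bins = np.asarray(peak_bins)
    if peak_bins.size == 0:
        raise ValueError("need at least one place cell")
    p_data = np.bincount(peak_bins, minlength=n_bins) / peak_bins.size
    p_unif = 1.0 / n_bins
    pos = p_data > 0
    return float(np.sum(p_data[pos] * np.log2(p_data[pos] / p_unif)))


def central_third_fraction(peak_bins: np.ndarray, n_bins: int = 50) -> float:
    """Fraction of place-cell peaks in the central third of the track.

    For 50 bins the central third is bins 17-33 (1-based), the middle 17.
    """
    peak_bins = np.asarray(peak_bins)
    if peak_bins.size == 0:
        raise ValueError("no place cells")
    width = round(n_bins / 3.0)  # 17 bins for the 50-bin track
    lo = (n_bins - width) // 2  # 0-based first central bin (16 -> 1-based 17)
    hi = lo + width  # one past the last central bin (1-based 33)
    return float(np.mean((peak_bins >= lo) & (peak_bins < hi)))


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Mean over spatial bins of the population-vector Pearson correlation.

    For each bin, the rate vector over cells of map A is correlated with
    that of map B; bins where either population vector has zero variance
    are skipped.  Symmetric in its arguments and invariant to consistent
    relabeling of cells.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have identical (cells, bins) shape")
    corrs = []
    for j in range(a.shape[1]):
        va, vb = a[:, j], b[:, j]
        if va.std() == 0 or vb.std() == 0:
            continue
        corrs.append(np.corrcoef(va, vb)[0, 1])
    if not corrs:
        raise ValueError("all bins had zero-variance population vectors")
    return float(np.mean(corrs))


def field_center_of_mass(rates: np.ndarray) -> float:
    """Center of mass of a smoothed field, as a track fraction."""
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    if total <= 0:
        raise ValueError("undefined for an all-zero field")
    centers = (np.arange(len(rates)) + 0.5) / len(rates)
    return float((rates * centers).sum() / total)
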