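"""Ensemble significance of decoded events against time-bin-shuffle nulls.

The null model permutes the order of an event's 10 ms time bins, which
destroys sequential structure while preserving the per-bin content.
Because the decoder is memoryless, permuting the posterior's columns is
exactly equivalent to permuting the binned spike vectors before decoding.
Three significance summaries are computed over an ensemble of events:

* a two-sample KS test of actual vs pooled shuffled |r| distributions
  (with the median shift of |r| as the effect size),
* a bootstrap p-value grid over (minimum |r|, maximum jump distance)
  quality thresholds, and
* per-event p-values against each event's own shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats as sps

from ._rng import substream
from .config import AnalysisParams
from .decode import EventDecodeStats, PosteriorMatrix, decode_event, decode_stats, max_jump, weighted_correlation
from .events import PBEList
from .lifsim import SpikeRecord
from .placefield import PlaceFieldMap

__all__ = [
    "DecodedEvent",
    "PreplaySignificance",
    "shuffle_event",
    "decode_ensemble",
    "ks_preplay_test",
    "median_shift",
    "threshold_grid_bootstrap",
    "per_event_pvalue",
    "evaluate_preplay",
    "DEFAULT_R_THRESHOLDS",
    "DEFAULT_JD_THRESHOLDS",
]

DEFAULT_R_THRESHOLDS = np.round(np.arange(0.0, 0.81, 0.1), 10)
DEFAULT_JD_THRESHOLDS = np.round(np.arange(0.1, 1.01, 0.1), 10)


@dataclass
class DecodedEvent:
    """One decodable PBE with its posterior, statistics, and shuffle stats."""

    posterior: PosteriorMatrix
    stats: EventDecodeStats
    shuffle_abs_r: np.ndarray
    shuffle_jd: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)


def shuffle_event(
    p: np.ndarray, n_shuffles: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """|r| and jump distance of ``n_shuffles`` column permutations of ``p``."""
    abs_r = np.empty(n_shuffles)
    jd = np.empty(n_shuffles)
    n_t = p.shape[1]
    for k in range(n_shuffles):
        perm = rng.permutation(n_t)
        q = p[:, perm]
        abs_r[k] = abs(weighted_correlation(q))
        jd[k] = max_jump(q)
    return abs_r, jd


def decode_ensemble(
    spikes: SpikeRecord,
    pbes: PBEList,
    fields: PlaceFieldMap,
    analysis: AnalysisParams | None = None,
    shuffle_seed: int = 0,
) -> list[DecodedEvent]:
    """Decode all decodable PBEs of one session and attach shuffle nulls.

    Events whose weighted correlation is undefined (zero weighted variance
    of position or time, e.g. fewer than two complete time bins) are
    excluded; the count of exclusions is recorded on each event's meta.
    Shuffle streams are keyed by (seed, event index) so individual events
    are reproducible in isolation.
    """
    if analysis is None:
        analysis = AnalysisParams()
    mask = fields.place_cell_mask(analysis.place_peak_min_rate)
    decoded: list[DecodedEvent] = []
    n_excluded = 0
    for idx, event in enumerate(pbes.decodable()):
        post = decode_event(spikes, event, fields, analysis, place_cell_mask=mask)
        if post.n_time_bins < 2:
            n_excluded += 1
            continue
        st = decode_stats(post.p)
        if np.isnan(st.r):
            n_excluded += 1
            continue
        rng = substream(shuffle_seed, "time-bin-shuffle", idx)
        sh_r, sh_jd = shuffle_event(post.p, analysis.n_shuffles, rng)
        decoded.append(
            DecodedEvent(
                posterior=post,
                stats=st,
                shuffle_abs_r=sh_r,
                shuffle_jd=sh_jd,
                meta={"event_index": idx, "n_excluded_so_far": n_excluded},
            )
        )
    return decoded


def ks_preplay_test(
    actual_abs_r: np.ndarray, shuffle_abs_r: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS statistic and p for actual vs shuffled |r|."""
    stat = sps.ks_2samp(actual_abs_r, shuffle_abs_r)
    return float(stat.statistic), float(stat.pvalue)


def median_shift(actual_abs_r: np.ndarray, shuffle_abs_r: np.ndarray) -> float:
    """Median |r| of actual events minus median |r| of pooled shuffles."""
    return float(np.median(actual_abs_r) - np.median(shuffle_abs_r))


def threshold_grid_bootstrap(
    abs_r: np.ndarray,
    jd: np.ndarray,
    shuffle_abs_r: np.ndarray,
    shuffle_jd: np.ndarray,
    r_thresholds: np.ndarray = DEFAULT_R_THRESHOLDS,
    jd_thresholds: np.ndarray = DEFAULT_JD_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap p-value grid over quality thresholds.

    Parameters
    ----------
    abs_r, jd
        Per-event statistics, shape (n_events,).
    shuffle_abs_r, shuffle_jd
        Per-event shuffle statistics, shape (n_events, n_shuffles); shuffle
        dataset ``k`` is column ``k`` across all events.

    Returns
    -------
    p_grid : (len(r_thresholds), len(jd_thresholds)) array
        Fraction of shuffle datasets whose passing fraction equals or
        exceeds the actual passing fraction.  Ties count toward p, so the
        all-pass corner (every event passes in every dataset) is p = 1,
        never significant; p = 0 is reportable as < 1/n_datasets.
    empty : boolean array of the same shape
        Cells where no event — actual or shuffled — passed both gates.
    """
    abs_r = np.asarray(abs_r)
    jd = np.asarray(jd)
    n_events, n_datasets = np.asarray(shuffle_abs_r).shape
    p_grid = np.empty((len(r_thresholds), len(jd_thresholds)))
    empty = np.zeros_like(p_grid, dtype=bool)
    for i, r_min in enumerate(r_thresholds):
        pass_r = abs_r >= r_min
        sh_pass_r = shuffle_abs_r >= r_min
        for j, jd_max in enumerate(jd_thresholds):
            actual_frac = np.mean(pass_r & (jd <= jd_max))
            sh_frac = np.mean(sh_pass_r & (shuffle_jd <= jd_max), axis=0)
            p_grid[i, j] = np.mean(sh_frac >= actual_frac)
            empty[i, j] = actual_frac == 0 and not sh_frac.any()
    return p_grid, empty


def per_event_pvalue(abs_r: float, shuffle_abs_r: np.ndarray) -> float:
    """Fraction of the event's own shuffles with higher |r|."""
    return float(np.mean(np.asarray(shuffle_abs_r) > abs_r))


@dataclass
class PreplaySignificance:
    """Ensemble shuffle-test report."""

    n_events: int
    ks_statistic: float
    ks_pvalue: float
    median_shift: float
    p_grid: np.ndarray
    empty_cells: np.ndarray
    r_thresholds: np.ndarray
    jd_thresholds: np.ndarray
    event_pvalues: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def fraction_events_significant(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.event_pvalues < alpha))

    def grid_significant(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_grid < alpha) & ~self.empty_cells


def evaluate_preplay(
    decoded: Sequence[DecodedEvent],
    r_thresholds: np.ndarray = DEFAULT_R_THRESHOLDS,
    jd_thresholds: np.ndarray = DEFAULT_JD_THRESHOLDS,
) -> PreplaySignificance:
    """Full significance report for an ensemble of decoded events.

    Events may be pooled across networks before calling (shuffle |r|
    distributions are pooled the same way for the KS test).
    """
    if not decoded:
        raise ValueError("no decoded events")
    abs_r = np.array([d.stats.abs_r for d in decoded])
    jd = np.array([d.stats.max_jump for d in decoded])
    sh_r = np.stack([d.shuffle_abs_r for d in decoded])
    sh_jd = np.stack([d.shuffle_jd for d in decoded])
    ks_stat, ks_p = ks_preplay_test(abs_r, sh_r.ravel())
    p_grid, empty = threshold_grid_bootstrap(abs_r, jd, sh_r, sh_jd, r_thresholds, jd_thresholds)
    ev_p = np.array([per_event_pvalue(r, s) for r, s in zip(abs_r, sh_r)])
    return PreplaySignificance(
        n_events=len(decoded),
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        median_shift=median_shift(abs_r, sh_r.ravel()),
        p_grid=p_grid,
        empty_cells=empty,
        r_thresholds=np.asarray(r_thresholds),
        jd_thresholds=np.asarray(jd_thresholds),
        event_pvalues=ev_p,
        meta={"mean_entropy": float(np.mean([d.stats.entropy for d in decoded]))},
    )
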