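"""Plain-text serialization: spike tables, rate-map matrices, reports.

Spikes travel as columnar TSV (``session_id  neuron_id  t_seconds``,
sorted by time), rate maps and p-value grids as delimited matrices with a
header row, and significance reports as flat key-value text with a
machine-readable JSON twin.  Every writer embeds a configuration hash so
outputs can be traced to the parameters that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import RunConfig
from .lifsim import SpikeRecord
from .placefield import PlaceFieldMap
from .preplay import PreplaySignificance

__all__ = [
    "config_hash",
    "write_spike_table",
    "read_spike_table",
    "write_rate_map",
    "read_rate_map",
    "write_events",
    "write_significance_report",
]


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full parameter tree."""
    tree = dataclasses.asdict(config)
    blob = json.dumps(tree, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_spike_table(path: str | Path, record: SpikeRecord, session_id: str = "s0") -> None:
    df = pd.DataFrame(
        {
            "session_id": session_id,
            "neuron_id": record.ids.astype(int),
            "t_seconds": np.round(record.times, 6),
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# duration={record.duration} n_neurons={record.n_neurons} "
            f"n_excit={record.n_excit}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_spike_table(path: str | Path) -> SpikeRecord:
    """Read a columnar spike table (microsecond-precision round trip).

    Rejects unsorted or negative spike times with the offending line
    number.
    """
    meta: dict[str, Any] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for part in first[1:].split():
                k, v = part.split("=")
                meta[k] = float(v)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    required = {"session_id", "neuron_id", "t_seconds"}
    if not required.issubset(df.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}")
    times = df["t_seconds"].to_numpy(dtype=float)
    ids = df["neuron_id"].to_numpy(dtype=np.int32)
    if (times < 0).any():
        line = int(np.flatnonzero(times < 0)[0]) + 3  # header + column row
        raise ValueError(f"negative spike time at line {line}")
    if (np.diff(times) < 0).any():
        line = int(np.flatnonzero(np.diff(times) < 0)[0]) + 4
        raise ValueError(f"spike times not sorted at line {line}")
    n_neurons = int(meta.get("n_neurons", ids.max() + 1 if len(ids) else 1))
    return SpikeRecord(
        ids=ids,
        times=times,
        duration=float(meta.get("duration", times.max() if len(times) else 0.0)),
        n_neurons=n_neurons,
        n_excit=int(meta.get("n_excit", n_neurons)),
        meta={"source": str(path)},
    )


def write_rate_map(path: str | Path, fields: PlaceFieldMap, track_length: float = 1.0) -> None:
    """Delimited matrix, one row per cell, header of bin centers in cm."""
    n_bins = fields.n_bins
    centers_cm = (np.arange(n_bins) + 0.5) * track_length / n_bins * 100.0
    df = pd.DataFrame(fields.rates, columns=[f"{c:.1f}" for c in centers_cm])
    df.insert(0, "cell", np.arange(fields.rates.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_rate_map(path: str | Path) -> PlaceFieldMap:
    df = pd.read_csv(path, sep="\t")
    rates = df.drop(columns=["cell"]).to_numpy(dtype=float)
    return PlaceFieldMap(rates=rates, raw_rates=rates.copy(), label=str(path))


def write_events(path: str | Path, pbes, config: RunConfig | None = None) -> None:
    rows = [
        {
            "start": e.start,
            "end": e.end,
            "duration": e.duration,
            "n_cells": e.n_cells,
            "peak_rate": e.peak_rate,
            "decodable": int(e.decodable),
        }
        for e in pbes
    ]
    df = pd.DataFrame(rows, columns=["start", "end", "duration", "n_cells", "peak_rate", "decodable"])
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_significance_report(
    path: str | Path, sig: PreplaySignificance, config: RunConfig | None = None
) -> None:
    """Key-value text report plus a JSON twin next to it."""
    path = Path(path)
    lines = {
        "n_events": sig.n_events,
        "ks_statistic": round(sig.ks_statistic, 6),
        "ks_pvalue": sig.ks_pvalue,
        "median_shift": round(sig.median_shift, 6),
        "fraction_events_significant": round(sig.fraction_events_significant(), 6),
    }
    if config is not None:
        lines["config_hash"] = config_hash(config)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in lines.items():
            fh.write(f"{k}: {v}\n")
        fh.write("p_grid (rows: min |r| thresholds; cols: max jump thresholds):\n")
        header = "\t".join(f"jd<={j:g}" for j in sig.jd_thresholds)
        fh.write(f"r>=\t{header}\n")
        for r, row in zip(sig.r_thresholds, sig.p_grid):
            fh.write(f"{r:g}\t" + "\t".join(f"{p:.2f}" for p in row) + "\n")
    twin = dict(lines)
    twin["p_grid"] = sig.p_grid.tolist()
    twin["r_thresholds"] = sig.r_thresholds.tolist()
    twin["jd_thresholds"] = sig.jd_thresholds.tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(twin, indent=1))
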