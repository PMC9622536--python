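"""Quantification of response-locked ERP components.

The error(-related) negativity Ne/c is measured at FCz as the mean of the
five samples centred on the negative peak within 0-150 ms after the
response; the error positivity Pe/c at Cz as the same peak-anchored mean
around the positive peak in 150-300 ms, and additionally as the plain
mean activity over 150-300 ms.  All measures are taken on per-cell
averaged waveforms (per participant), window endpoints inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet, align

#: (channel, window, polarity) of the standard component measures
COMPONENT_DEFS = {
    "Ne_c": ("FCz", (0.0, 150.0), "negative"),
    "Pe_c_peak": ("Cz", (150.0, 300.0), "positive"),
    "Pe_c_mean": ("Cz", (150.0, 300.0), "none"),
}


@dataclass(frozen=True)
class ComponentMeasure:
    component: str
    channel: str
    window_ms: tuple[float, float]
    polarity: str
    cell: str
    value: float
    peak_latency_ms: float | None
    n_trials: int


def average_by_cell(
    epochs: EpochSet, table: pd.DataFrame, cell_column: str = "response_type",
    exclude: tuple[str, ...] = ("unlabeled",),
) -> dict[str, tuple[np.ndarray, int]]:
    """Per-cell mean waveform (channels x samples) and trial count.

    ``cell_column`` names a column of the aligned trial table; trials with
    a cell label in ``exclude`` are skipped.  Empty cells are omitted with
    a warning.
    """
    tab = align(epochs, table)
    cells = tab[cell_column].astype(str)
    out: dict[str, tuple[np.ndarray, int]] = {}
    for cell in pd.unique(cells):
        if cell in exclude or cell in ("nan", "none"):
            continue
        m = (cells == cell).to_numpy()
        if not m.any():
            warnings.warn(f"empty cell {cell!r}; omitted")
            continue
        out[str(cell)] = (epochs.data[m].mean(axis=0).astype(float), int(m.sum()))
    return out


def peak_mean_amplitude(
    waveform: np.ndarray,
    times: np.ndarray,
    window_ms: tuple[float, float],
    polarity: str,
    halfwidth_samples: int = 2,
) -> tuple[float, float]:
    """Mean of the ``2*halfwidth+1`` samples centred on the in-window peak.

    Returns ``(amplitude, peak_latency_ms)``.  The peak is the extremum of
    the requested polarity among samples inside the inclusive window; ties
    resolve to the earliest latency (logged).  The averaging neighbourhood
    may extend beyond the window but must stay inside the epoch.
    """
    waveform = np.asarray(waveform, float)
    times = np.asarray(times, float)
    t0, t1 = window_ms
    m = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if not m.any():
        raise ValueError(f"window {window_ms} outside waveform")
    idx = np.flatnonzero(m)
    seg = waveform[idx]
    if polarity == "negative":
        k = int(np.argmin(seg))
        ties = np.isclose(seg, seg[k]).sum()
    elif polarity == "positive":
        k = int(np.argmax(seg))
        ties = np.isclose(seg, seg[k]).sum()
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if ties > 1:
        warnings.warn(f"{ties} tied extrema in window; using earliest")
    peak = idx[k]
    lo, hi = peak - halfwidth_samples, peak + halfwidth_samples + 1
    if lo < 0 or hi > len(waveform):
        raise ValueError("peak neighbourhood extends beyond the epoch")
    return float(waveform[lo:hi].mean()), float(times[peak])


def window_mean_activity(
    waveform: np.ndarray, times: np.ndarray, window_ms: tuple[float, float]
) -> float:
    """Arithmetic mean over all samples in the inclusive window."""
    times = np.asarray(times, float)
    m = (times >= window_ms[0] - 1e-9) & (times <= window_ms[1] + 1e-9)
    if not m.any():
        raise ValueError(f"window {window_ms} outside waveform")
    return float(np.asarray(waveform, float)[m].mean())


def measure_components(
    epochs: EpochSet,
    table: pd.DataFrame,
    cell_column: str = "response_type",
    components: dict | None = None,
) -> pd.DataFrame:
    """Tidy table of component measures, one row per cell x component."""
    defs = components or COMPONENT_DEFS
    cells = average_by_cell(epochs, table, cell_column)
    rows = []
    for comp, (channel, window, polarity) in defs.items():
        ci = epochs.channel_index(channel)
        for cell, (wave, n) in cells.items():
            if polarity == "none":
                val, lat = window_mean_activity(wave[ci], epochs.times, window), None
            else:
                val, lat = peak_mean_amplitude(wave[ci], epochs.times, window, polarity)
            rows.append(ComponentMeasure(comp, channel, window, polarity,
                                         cell, val, lat, n))
    return pd.DataFrame([r.__dict__ for r in rows])


def trial_matched_subsample(
    epochs_by_cell: dict[str, EpochSet], seed: int = 0
) -> dict[str, EpochSet]:
    """Randomly subsample every cell (without replacement) to the minimum
    cell count, so averages across cells rest on equal trial numbers."""
    if not epochs_by_cell:
        return {}
    n_min = min(e.n_trials for e in epochs_by_cell.values())
    rng = np.random.default_rng(seed)
    out = {}
    for cell in sorted(epochs_by_cell):
        ep = epochs_by_cell[cell]
        pick = np.sort(rng.choice(ep.n_trials, size=n_min, replace=False))
        sub = ep.copy(data=ep.data[pick])
        sub.trial_ids = ep.trial_ids[pick]
        sub.log(f"trial-matched to {n_min} trials")
        out[cell] = sub
    return out
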