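"""Dwell-time and transition-event statistics of idealized two-state traces.

A two-state (low/high ΔHeight) idealization partitions each molecule's
record into dwells; transitions between them are 'up' (low→high) and 'down'
(high→low) events.  The module provides the standard single-channel
summaries: censored-aware dwell extraction, fixed-window event counting,
sliding dwell-time averages along the experiment, the population fraction
of high-state molecules over time, and the equilibrium free-energy
difference implied by the mean dwell ratio,

    ΔG = −ln(τ_low / τ_high)  [k_BT]

(negative when the low state is favored).  No missed-event correction for
the finite frame time is applied; one-frame dwells are kept but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stasi import StateModel

__all__ = [
    "DwellRecord",
    "EventSeries",
    "extract_dwells",
    "events_from_dwells",
    "bin_transitions",
    "sliding_dwell_average",
    "fraction_open_vs_time",
    "energy_difference",
]


@dataclass
class DwellRecord:
    molecule_id: int
    state: int  # 0 = low, 1 = high
    entry_time: float  # s
    duration: float  # s
    censored: bool  # first or last dwell of the record
    single_frame: bool = False  # one-frame blip, kept but flagged


@dataclass
class EventSeries:
    """Transition events of one or more molecules, time-sorted."""

    times: np.ndarray  # s
    directions: np.ndarray  # +1 = up (low→high), −1 = down


def extract_dwells(
    model: StateModel, times: np.ndarray, molecule_id: int = 0
) -> list[DwellRecord]:
    """Maximal constant-state runs of a two-state idealization.

    Dwell boundaries sit at the entry times of the runs; the last dwell
    extends one sampling interval past its final frame so the durations sum
    to the trace span.  First and last dwells are censored (their true
    length is unobserved).
    """
    if model.k > 2:
        raise ValueError("dwell extraction expects a two-state idealization")
    t = np.asarray(times, dtype=float)
    labels = model.labels
    if t.size != labels.size:
        raise ValueError("times and labels must align")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    edges = np.concatenate([[0], np.flatnonzero(np.diff(labels) != 0) + 1, [labels.size]])
    dwells = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        t_end = t[b] if b < t.size else t[-1] + dt
        dwells.append(
            DwellRecord(
                molecule_id=molecule_id,
                state=int(labels[a]),
                entry_time=float(t[a]),
                duration=float(t_end - t[a]),
                censored=(i == 0) or (b == labels.size),
                single_frame=(b - a) == 1,
            )
        )
    return dwells


def events_from_dwells(dwells: list[DwellRecord]) -> EventSeries:
    """Up/down transition events at the entry times of non-initial dwells."""
    times, dirs = [], []
    by_mol: dict[int, list[DwellRecord]] = {}
    for d in dwells:
        by_mol.setdefault(d.molecule_id, []).append(d)
    for recs in by_mol.values():
        recs = sorted(recs, key=lambda d: d.entry_time)
        for prev, cur in zip(recs[:-1], recs[1:]):
            times.append(cur.entry_time)
            dirs.append(+1 if cur.state > prev.state else -1)
    order = np.argsort(times)
    return EventSeries(
        times=np.asarray(times, dtype=float)[order],
        directions=np.asarray(dirs, dtype=int)[order],
    )


def bin_transitions(
    events: EventSeries, t0: float, t1: float, bin_width: float = 30.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin up and down event counts over half-open bins [t0+i·w, t0+(i+1)·w).

    Returns (bin_left_edges, up_counts, down_counts); total counts inside
    [t0, t1) are conserved.
    """
    if t0 >= t1:
        raise ValueError("t0 must be < t1")
    edges = np.arange(t0, t1 + bin_width, bin_width)
    if edges[-1] < t1:
        edges = np.append(edges, edges[-1] + bin_width)
    up = np.histogram(events.times[events.directions > 0], bins=edges)[0]
    down = np.histogram(events.times[events.directions < 0], bins=edges)[0]
    return edges[:-1], up, down


def sliding_dwell_average(
    dwells: list[DwellRecord], window_events: int = 20, state: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean dwell duration over a sliding window of ``window_events`` events.

    Dwells (censored excluded) are ordered by entry time; each window's mean
    duration is reported at the window's mean entry time.  With fewer events
    than the window, the single global mean is returned (flagged by the
    output having length 1).
    """
    use = sorted((d for d in dwells if not d.censored), key=lambda d: d.entry_time)
    if state is not None:
        use = [d for d in use if d.state == state]
    if not use:
        return np.array([]), np.array([])
    t = np.array([d.entry_time for d in use])
    dur = np.array([d.duration for d in use])
    if len(use) < window_events:
        return np.array([t.mean()]), np.array([dur.mean()])
    n = len(use) - window_events + 1
    times = np.array([t[i : i + window_events].mean() for i in range(n)])
    means = np.array([dur[i : i + window_events].mean() for i in range(n)])
    return times, means


def fraction_open_vs_time(models: list[StateModel]) -> np.ndarray:
    """Percentage of molecules in the high state per frame.

    All models must share the frame grid; frames where a molecule has no
    label (shorter trace) are excluded from that frame's denominator.
    """
    if not models:
        raise ValueError("need at least one molecule")
    n = max(m.labels.size for m in models)
    high = np.zeros(n)
    tot = np.zeros(n)
    for m in models:
        high_state = m.k - 1  # top level is 'high'; a 1-state model is all low
        ln = m.labels.size
        tot[:ln] += 1
        if m.k >= 2:
            high[:ln] += m.labels == high_state
    with np.errstate(invalid="ignore"):
        return 100.0 * high / tot


def energy_difference(mean_dwell_low: float, mean_dwell_high: float) -> float:
    """Free-energy difference ΔG = −ln(τ_low/τ_high) in k_BT.

    Negative values favor the low(-height) state; antisymmetric under
    swapping the arguments.
    """
    if mean_dwell_low <= 0 or mean_dwell_high <= 0:
        raise ValueError("mean dwell times must be > 0")
    return float(-np.log(mean_dwell_low / mean_dwell_high))
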