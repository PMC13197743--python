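"""Desaturation-event detection, delineation, ODI and hypoxic burden.

The event delineation follows a rainwater-trapping scheme on the 1 Hz signal:
each nadir's window extends bidirectionally to the nearest samples recovering
at least 75% of the preceding peak-to-nadir amplitude, overlong windows are
clipped to twice the first-pass mean duration, the per-event baseline is the
maximum saturation in the 100 s preceding the window, and the event area is
the baseline-deficit integral over the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from oxiscreen.errors import ContractError
from oxiscreen.spo2_io import Spo2Signal

#: Seconds of signal preceding the window start searched for the baseline.
BASELINE_LOOKBACK_S = 100

#: Fraction of peak-to-nadir amplitude that must be recovered at the window edge.
RECOVERY_FRACTION = 0.75

#: First-pass-mean multiplier capping window durations in the refinement pass.
DURATION_CAP_FACTOR = 2.0


@dataclass
class DesatEvent:
    """A delineated desaturation episode; window is half-open [win_start, win_finish)."""

    nadir_idx: int
    win_start: int
    win_finish: int
    preceding_peak_idx: int
    baseline: float
    depth: float
    area: float

    @property
    def duration_s(self) -> int:
        return self.win_finish - self.win_start

    def __post_init__(self) -> None:
        if not self.win_start <= self.nadir_idx < self.win_finish:
            raise ContractError("event window must contain its nadir")


@dataclass
class EventSet:
    events: list[DesatEvent] = field(default_factory=list)

    @property
    def mean_duration_s(self) -> float:
        if not self.events:
            return 0.0
        return float(np.mean([e.duration_s for e in self.events]))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def _valid_runs(mask: np.ndarray):
    """Yield (start, stop) of maximal runs of valid samples (half-open)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def _run_extrema(values: np.ndarray, start: int, stop: int):
    """Interior local extrema of values[start:stop], plateaus collapsed to
    their first index. Returns (indices, kinds) with kind +1 = max, -1 = min."""
    seg = values[start:stop]
    keep = np.concatenate([[True], np.diff(seg) != 0])  # compress plateaus
    comp_idx = np.flatnonzero(keep)
    comp = seg[comp_idx]
    if comp.size < 3:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.int8)
    d = np.sign(np.diff(comp))
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    which = np.flatnonzero(is_min | is_max) + 1
    kinds = np.where(is_min[which - 1], -1, 1).astype(np.int8)
    return comp_idx[which] + start, kinds


def local_extrema(signal: Spo2Signal):
    """All interior local extrema of a 1 Hz signal, per valid run.

    Returns (indices, kinds): sample indices in increasing order and a
    parallel array of kinds (+1 local maximum, -1 local minimum). Plateau
    runs of equal values collapse to the run's first index; invalid samples
    break extremal runs.
    """
    all_idx: list[np.ndarray] = []
    all_kind: list[np.ndarray] = []
    for start, stop in _valid_runs(signal.valid_mask):
        idx, kinds = _run_extrema(signal.values, start, stop)
        all_idx.append(idx)
        all_kind.append(kinds)
    if not all_idx:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.int8)
    return np.concatenate(all_idx), np.concatenate(all_kind)


def _preceding_peak(values: np.ndarray, valid: np.ndarray, lo: int, nadir: int) -> int:
    """Index of the preceding peak: the highest valid sample between the
    previous nadir (or run start) and this nadir. Noise-robust stand-in for
    'the peak preceding the event'; falls back to the nadir itself when the
    range is empty (zero-amplitude degenerate event)."""
    if lo >= nadir:
        return int(nadir)
    seg = np.where(valid[lo:nadir], values[lo:nadir], -np.inf)
    best = int(np.argmax(seg))
    if not np.isfinite(seg[best]):
        return int(nadir)
    return lo + best


def detect_valleys(signal: Spo2Signal, min_depth: float = 2.0) -> list[int]:
    """Indices of desaturation nadirs: local minima of topographic prominence
    ≥ min_depth.

    Prominence is two-sided (the smaller of the climbs to enclosing higher
    ground), so noise wiggles riding a steep desaturation flank are not
    promoted to independent events; plateau runs of equal minima collapse to
    the run's first index, and invalid samples break extremal runs.
    """
    if signal.rate_hz != 1.0:
        raise ContractError("detect_valleys expects a 1 Hz signal")
    nadirs: list[int] = []
    values = signal.values
    for start, stop in _valid_runs(signal.valid_mask):
        seg = values[start:stop]
        if seg.size < 3:
            continue
        idx, _props = find_peaks(-seg, prominence=min_depth)
        for i in idx:
            j = int(i)
            while j > 0 and seg[j - 1] == seg[j]:  # plateau → first index
                j -= 1
            nadirs.append(start + j)
    return sorted(set(nadirs))


def _scan_window(values: np.ndarray, valid: np.ndarray, nadir: int,
                 recovery: float, low: int, high: int) -> tuple[int, int]:
    """Bidirectional recovery scan within [low, high). Returns half-open
    (win_start, win_finish); win_start is the nearest sample at or before the
    nadir with value ≥ recovery, win_finish the nearest strictly after."""
    i = nadir
    while i > low:
        if valid[i] and values[i] >= recovery:
            break
        i -= 1
    j = nadir + 1
    while j < high:
        if valid[j] and values[j] >= recovery:
            break
        j += 1
    return i, j


def delineate_events(signal: Spo2Signal, nadirs: list[int]) -> EventSet:
    """Delineate windows, baselines, depths and areas for the given nadirs.

    Adjacent windows are truncated at the midpoint between their nadirs so no
    sample's deficit is counted twice. After the first pass, windows longer
    than ``DURATION_CAP_FACTOR`` times the pass-one mean duration are
    symmetrically clipped about their nadir.
    """
    if signal.rate_hz != 1.0:
        raise ContractError("delineate_events expects a 1 Hz signal")
    n = len(signal.values)
    values, valid = signal.values, signal.valid_mask
    nadirs = sorted(int(i) for i in nadirs)
    for i in nadirs:
        if not 0 <= i < n:
            raise ContractError(f"nadir index {i} out of range")
    if not nadirs:
        return EventSet([])

    # Preceding peak per nadir: highest point since the previous nadir,
    # clamped to the nadir's own valid run.
    runs = list(_valid_runs(valid))
    peaks: dict[int, int] = {}
    for k, nad in enumerate(nadirs):
        run_start = next((s for s, e in runs if s <= nad < e), 0)
        lo = run_start if k == 0 else max(run_start, nadirs[k - 1] + 1)
        peaks[nad] = _preceding_peak(values, valid, lo, nad)

    # Pass one: recovery scan, bounded by recording edges and nadir midpoints.
    windows: list[tuple[int, int]] = []
    for k, nad in enumerate(nadirs):
        low = 0 if k == 0 else (nadirs[k - 1] + nad + 1) // 2
        high = n if k == len(nadirs) - 1 else (nad + nadirs[k + 1] + 1) // 2
        peak = peaks.get(nad, nad)
        amplitude = values[peak] - values[nad]
        recovery = values[nad] + RECOVERY_FRACTION * amplitude
        windows.append(_scan_window(values, valid, nad, recovery, low, high))

    # Refinement: cap overlong windows at twice the pass-one mean duration.
    durations = [wf - ws for ws, wf in windows]
    cap = DURATION_CAP_FACTOR * float(np.mean(durations))
    allowed = max(1, int(np.floor(cap)))
    refined: list[tuple[int, int]] = []
    for (ws, wf), nad in zip(windows, nadirs):
        if wf - ws > cap:
            left = allowed // 2
            right = max(1, allowed - left)
            ws = max(ws, nad - left)
            wf = min(wf, nad + right)
        refined.append((ws, wf))

    events: list[DesatEvent] = []
    for (ws, wf), nad in zip(refined, nadirs):
        lb = max(0, ws - BASELINE_LOOKBACK_S)
        prefix = values[lb:ws][valid[lb:ws]]
        baseline = float(np.max(prefix)) if prefix.size else float(values[peaks.get(nad, nad)])
        depth = max(0.0, baseline - float(values[nad]))
        events.append(DesatEvent(
            nadir_idx=nad,
            win_start=ws,
            win_finish=wf,
            preceding_peak_idx=peaks.get(nad, nad),
            baseline=baseline,
            depth=depth,
            area=_deficit_area(values, valid, ws, wf, baseline),
        ))
    return EventSet(events)


def _deficit_area(values: np.ndarray, valid: np.ndarray, win_start: int,
                  win_finish: int, baseline: float) -> float:
    """Trapezoidal integral of max(0, baseline - value) over the window (%·s).

    Integrates over the closed sample range [win_start, min(win_finish, n-1)];
    invalid samples contribute zero deficit.
    """
    end = min(win_finish, len(values) - 1)
    if end <= win_start:
        return 0.0
    seg = values[win_start:end + 1]
    deficit = np.where(valid[win_start:end + 1], np.maximum(0.0, baseline - seg), 0.0)
    total = 0.0
    for t in range(len(deficit) - 1):
        total += 0.5 * (deficit[t] + deficit[t + 1])
    return float(total)


def hypoxic_burden(events: EventSet, trt_hours: float) -> float:
    """Total desaturation area normalized by recording time (%·min/h)."""
    if not trt_hours > 0:
        raise ContractError("trt_hours must be positive")
    total_area_pct_s = sum(e.area for e in events)
    return (total_area_pct_s / 60.0) / trt_hours


def odi(events: EventSet, tst_hours: float, drop_threshold: float = 4.0) -> float:
    """Desaturation events with depth ≥ drop_threshold per hour of sleep."""
    if not tst_hours > 0:
        raise ContractError("tst_hours must be positive")
    qualifying = sum(1 for e in events if e.depth >= drop_threshold)
    return qualifying / tst_hours


def events_table(events: EventSet, subject_id: str = "") -> pd.DataFrame:
    """Event-level export in the canonical delimited layout."""
    rows = [
        {
            "subject_id": subject_id,
            "nadir_idx": e.nadir_idx,
            "win_start": e.win_start,
            "win_finish": e.win_finish,
            "baseline": e.baseline,
            "depth": e.depth,
            "duration_s": e.duration_s,
            "area": e.area,
        }
        for e in events
    ]
    columns = ["subject_id", "nadir_idx", "win_start", "win_finish",
               "baseline", "depth", "duration_s", "area"]
    return pd.DataFrame(rows, columns=columns)
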