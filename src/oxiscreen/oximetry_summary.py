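"""Summary oximetry parameters and assembly of the 8-feature vector.

Feature order is fixed package-wide: MeanSpO2, MinSpO2, ODI, T90, ST90, HB,
AttnEn, TotalPower.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from oxiscreen.desat_events import EventSet, hypoxic_burden, local_extrema, odi
from oxiscreen.errors import ContractError, DegenerateInputError
from oxiscreen.spo2_io import Spo2Signal

FEATURE_NAMES = ("MeanSpO2", "MinSpO2", "ODI", "T90", "ST90", "HB", "AttnEn", "TotalPower")

#: Ultradian band (Hz) whose integrated periodogram power defines TotalPower.
ULTRADIAN_BAND = (0.014, 0.035)

#: Floor added to band power before the dB transform (constant signal → -120 dB).
POWER_FLOOR = 1e-12

#: Minimum valid duration (s) for a spectral estimate.
MIN_SPECTRUM_SECONDS = 600


@dataclass
class OximetryFeatures:
    mean_spo2: float
    min_spo2: float
    odi: float
    t90: float
    st90: float
    hb: float
    attn_en: float
    total_power: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_spo2, self.min_spo2, self.odi, self.t90,
                         self.st90, self.hb, self.attn_en, self.total_power])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.as_array()))


def basic_stats(signal: Spo2Signal) -> tuple[float, float]:
    """(mean, minimum) saturation over valid samples only."""
    valid = signal.valid_values()
    if valid.size == 0:
        raise DegenerateInputError("no valid samples")
    return float(np.mean(valid)), float(np.min(valid))


def time_below_threshold(signal: Spo2Signal, tst_minutes: float,
                         threshold: float = 90.0) -> tuple[float, float]:
    """Minutes, and percentage of sleep time, strictly below the threshold."""
    if not tst_minutes > 0:
        raise ContractError("tst_minutes must be positive")
    if signal.rate_hz != 1.0:
        raise ContractError("time_below_threshold expects a 1 Hz signal")
    below = np.count_nonzero(signal.valid_mask & (signal.values < threshold))
    t = below / 60.0
    return t, 100.0 * t / tst_minutes


def interval_entropy(intervals) -> float:
    """Shannon entropy (nats) of the empirical distribution of integer intervals."""
    intervals = list(intervals)
    if len(intervals) == 0:
        return 0.0
    counts = np.array(list(Counter(intervals).values()), dtype=np.float64)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def extrema_interval_streams(signal: Spo2Signal) -> dict[str, list[int]]:
    """The four key-pattern interval streams between adjacent local extrema.

    Streams: max→max and min→min (gaps between successive same-kind extrema)
    and max→min / min→max (gaps between successive opposite-kind extrema in
    the merged, time-ordered extrema sequence).
    """
    idx, kinds = local_extrema(signal)
    maxima = idx[kinds > 0]
    minima = idx[kinds < 0]
    streams: dict[str, list[int]] = {
        "max_max": np.diff(maxima).astype(int).tolist(),
        "min_min": np.diff(minima).astype(int).tolist(),
        "max_min": [],
        "min_max": [],
    }
    for k in range(len(idx) - 1):
        gap = int(idx[k + 1] - idx[k])
        if kinds[k] > 0 and kinds[k + 1] < 0:
            streams["max_min"].append(gap)
        elif kinds[k] < 0 and kinds[k + 1] > 0:
            streams["min_max"].append(gap)
    return streams


def attention_entropy(signal: Spo2Signal) -> float:
    """Mean Shannon entropy (nats) of the four extrema-interval streams.

    An exactly periodic signal (all intervals identical within every stream)
    scores 0; irregular extrema spacing raises the score.
    """
    streams = extrema_interval_streams(signal)
    return float(np.mean([interval_entropy(v) for v in streams.values()]))


def lomb_scargle_power(signal: Spo2Signal, freqs_hz: np.ndarray) -> np.ndarray:
    """Lomb–Scargle periodogram of the mean-removed valid samples.

    Mask-aware: invalid samples are simply absent from the irregular sample
    set, so gaps need no imputation.
    """
    t = np.flatnonzero(signal.valid_mask).astype(np.float64) / signal.rate_hz
    y = signal.values[signal.valid_mask].astype(np.float64)
    if t.size < 2:
        raise DegenerateInputError("too few valid samples for a periodogram")
    y = y - y.mean()
    if np.all(y == 0):
        return np.zeros_like(freqs_hz, dtype=np.float64)
    return lombscargle(t, y, 2.0 * np.pi * np.asarray(freqs_hz, dtype=np.float64))


def band_power(signal: Spo2Signal, band: tuple[float, float], n_grid: int = 256) -> float:
    """Numerically integrated periodogram power over a frequency band."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ContractError(f"invalid band {band}")
    freqs = np.linspace(lo, hi, max(int(n_grid), 200))
    power = lomb_scargle_power(signal, freqs)
    return float(np.trapezoid(power, freqs))


def total_power(signal: Spo2Signal, band: tuple[float, float] = ULTRADIAN_BAND,
                n_grid: int = 256) -> float:
    """Integrated ultradian-band periodogram power, in dB."""
    if np.count_nonzero(signal.valid_mask) / signal.rate_hz < MIN_SPECTRUM_SECONDS:
        raise DegenerateInputError(
            f"need at least {MIN_SPECTRUM_SECONDS} s of valid signal for total_power")
    return float(10.0 * np.log10(band_power(signal, band, n_grid) + POWER_FLOOR))


def feature_vector(signal: Spo2Signal, events: EventSet, tst_hours: float,
                   trt_hours: float | None = None) -> OximetryFeatures:
    """Assemble the canonical 8-parameter vector for one subject."""
    if trt_hours is None:
        trt_hours = signal.trt_hours
    mean_spo2, min_spo2 = basic_stats(signal)
    t90, st90 = time_below_threshold(signal, tst_minutes=tst_hours * 60.0)
    return OximetryFeatures(
        mean_spo2=mean_spo2,
        min_spo2=min_spo2,
        odi=odi(events, tst_hours),
        t90=t90,
        st90=st90,
        hb=hypoxic_burden(events, trt_hours),
        attn_en=attention_entropy(signal),
        total_power=total_power(signal),
    )
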