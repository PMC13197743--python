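"""Ingestion of nocturnal SpO2 recordings into the canonical 1 Hz representation.

All downstream analysis operates on :class:`Spo2Signal`: a fixed-rate
saturation series with a per-sample validity mask. Time is sample-indexed,
0-based, with half-open windows ``[start, end)`` in seconds at 1 Hz.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from oxiscreen.errors import ContractError, DegenerateInputError, FormatError

#: Saturation below this is treated as oximeter artifact and masked invalid.
PLAUSIBLE_MIN = 40.0
PLAUSIBLE_MAX = 100.0

#: Channel labels tried, in order, when no hint is given for EDF input.
DEFAULT_SPO2_CHANNELS = ("SpO2", "SaO2", "SPO2", "OSAT", "Oxygen saturation")


@dataclass
class Spo2Signal:
    """A saturation time series at a fixed sampling rate.

    Parameters
    ----------
    values
        Saturation percentages. Out-of-range values may be retained here but
        must be flagged in ``valid_mask``.
    rate_hz
        Sampling rate in Hz (> 0).
    valid_mask
        Per-sample analyzability flag; defaults to all-valid.
    subject_id
        Opaque identifier carried through exports.
    """

    values: np.ndarray
    rate_hz: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ContractError("values must be one-dimensional")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ContractError("valid_mask and values must have equal length")
        if not self.rate_hz > 0:
            raise ContractError(f"rate_hz must be positive, got {self.rate_hz}")
        valid = self.values[self.valid_mask]
        if valid.size and (np.any(valid < 0) or np.any(valid > 100) or not np.all(np.isfinite(valid))):
            raise ContractError("valid samples must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def trt_seconds(self) -> float:
        """Total recording time in seconds."""
        return len(self.values) / self.rate_hz

    @property
    def trt_hours(self) -> float:
        return self.trt_seconds / 3600.0

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class ValidityReport:
    analyzable_seconds: float
    required_seconds: float
    is_valid: bool
    invalid_fraction: float


def _mask_raw(values: np.ndarray) -> np.ndarray:
    """Validity mask for raw parsed values: finite, in [0,100], plausible."""
    with np.errstate(invalid="ignore"):
        return (
            np.isfinite(values)
            & (values >= PLAUSIBLE_MIN)
            & (values <= PLAUSIBLE_MAX)
        )


def _read_delimited(path: Path) -> tuple[np.ndarray, float]:
    """Parse a two-column (time_s, spo2) text file; returns (values, rate_hz).

    Dialect: optional header line, comma or tab separated (auto-detected).
    Non-numeric saturation entries become NaN (masked downstream).
    """
    text = path.read_text()
    if not text.strip():
        raise DegenerateInputError(f"{path}: empty recording")
    sample = text[:4096]
    delim = "\t" if sample.count("\t") >= sample.count(",") else ","

    times: list[float] = []
    sats: list[float] = []
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    for row_idx, row in enumerate(reader):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise FormatError(f"{path}: line {row_idx + 1} has fewer than 2 columns")
        t_txt, v_txt = row[0].strip(), row[1].strip()
        try:
            t = float(t_txt)
        except ValueError:
            if row_idx == 0:  # header line
                continue
            raise FormatError(f"{path}: non-numeric time at line {row_idx + 1}: {t_txt!r}")
        try:
            v = float(v_txt)
        except ValueError:
            v = math.nan
        times.append(t)
        sats.append(v)

    if not times:
        raise DegenerateInputError(f"{path}: no data rows")
    t_arr = np.asarray(times)
    v_arr = np.asarray(sats)
    if len(t_arr) > 1:
        steps = np.diff(t_arr)
        step = float(np.median(steps))
        if step <= 0:
            raise FormatError(f"{path}: time column is not strictly increasing")
        rate = 1.0 / step
    else:
        rate = 1.0
    return v_arr, rate


def _read_edf_spo2(path: Path, channel_hint: str | None) -> tuple[np.ndarray, float]:
    from oxiscreen import _edf

    channels = _edf.read_edf(path)
    wanted = [channel_hint] if channel_hint else list(DEFAULT_SPO2_CHANNELS)
    by_label = {c.label.lower(): c for c in channels}
    for name in wanted:
        ch = by_label.get(name.lower())
        if ch is not None:
            if ch.values.size == 0:
                raise DegenerateInputError(f"{path}: channel {ch.label!r} is empty")
            return ch.values, ch.rate_hz
    available = ", ".join(c.label for c in channels)
    raise FormatError(
        f"{path}: no saturation channel found (looked for {wanted}; available: {available})"
    )


def read_signal(path, format: str = "delimited-text", channel_hint: str | None = None,
                subject_id: str | None = None) -> Spo2Signal:
    """Read a recording at its native rate.

    Out-of-range (<0, >100) or physiologically implausible (<40%) samples are
    retained as values but flagged invalid in the mask; non-numeric entries
    are stored as NaN and flagged invalid.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "delimited-text":
        values, rate = _read_delimited(path)
    elif format.upper() == "EDF":
        values, rate = _read_edf_spo2(path, channel_hint)
    else:
        raise FormatError(f"unknown format {format!r}")
    if values.size == 0:
        raise DegenerateInputError(f"{path}: empty record")
    return Spo2Signal(
        values=values,
        rate_hz=rate,
        valid_mask=_mask_raw(values),
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_signal(path, signal: Spo2Signal) -> None:
    """Write a signal in the canonical delimited-text exchange format."""
    step = 1.0 / signal.rate_hz
    with open(path, "w", newline="") as fh:
        fh.write("time_s,spo2\n")
        for k, (v, ok) in enumerate(zip(signal.values, signal.valid_mask)):
            txt = f"{v:.10g}" if ok and np.isfinite(v) else "NA"
            fh.write(f"{k * step:.10g},{txt}\n")


def resample_to_1hz(signal: Spo2Signal) -> Spo2Signal:
    """Reduce a signal to 1 Hz by per-second means of valid native samples.

    Output sample ``k`` is the mean of valid native samples with timestamps in
    the half-open window ``[k, k+1)`` seconds; windows with no valid samples
    are masked invalid. A 1 Hz input is returned unchanged.
    """
    if signal.rate_hz == 1.0:
        return signal
    if signal.rate_hz < 1.0:
        raise ContractError("cannot resample a sub-1 Hz recording to 1 Hz")

    n_native = len(signal.values)
    times = np.arange(n_native) / signal.rate_hz
    bins = np.floor(times).astype(np.intp)
    n_out = int(bins[-1]) + 1 if n_native else 0

    ok = signal.valid_mask & np.isfinite(signal.values)
    counts = np.bincount(bins[ok], minlength=n_out)
    sums = np.bincount(bins[ok], weights=signal.values[ok], minlength=n_out)

    out = np.full(n_out, np.nan)
    mask = counts > 0
    out[mask] = sums[mask] / counts[mask]
    return Spo2Signal(values=out, rate_hz=1.0, valid_mask=mask, subject_id=signal.subject_id)


def validate_recording(signal: Spo2Signal, required_hours: float = 4.0) -> ValidityReport:
    """Apply the minimum-analyzable-duration rule (default: more than 4 h)."""
    if signal.rate_hz != 1.0:
        raise ContractError("validate_recording expects a 1 Hz signal")
    analyzable = float(np.count_nonzero(signal.valid_mask))
    required = required_hours * 3600.0
    n = len(signal.values)
    return ValidityReport(
        analyzable_seconds=analyzable,
        required_seconds=required,
        is_valid=analyzable > required,
        invalid_fraction=1.0 - analyzable / n if n else 1.0,
    )


def with_values(signal: Spo2Signal, values: np.ndarray) -> Spo2Signal:
    """Copy of ``signal`` with substituted values (same mask/rate/id)."""
    return replace(signal, values=np.asarray(values, dtype=np.float64))
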