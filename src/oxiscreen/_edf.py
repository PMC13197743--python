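"""Minimal EDF (European Data Format) reader/writer.

Supports plain EDF with a fixed-rate numeric channel: the 256-byte main
header, per-signal headers, and little-endian int16 data records with linear
physical scaling. EDF+ annotation channels are ignored. This is deliberately
small; it exists to pull a saturation channel out of a recording, not to be a
general EDF library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from oxiscreen.errors import FormatError

_HEADER_BYTES = 256
_SIGNAL_HEADER_BYTES = 256


@dataclass
class EdfChannel:
    label: str
    physical_dim: str
    rate_hz: float
    values: np.ndarray  # physical units, float64


def _ascii(raw: bytes) -> str:
    return raw.decode("ascii", errors="replace").strip()


def _float(raw: bytes, what: str) -> float:
    try:
        return float(_ascii(raw))
    except ValueError as exc:
        raise FormatError(f"unparseable EDF header field {what!r}: {raw!r}") from exc


def read_edf(path) -> list[EdfChannel]:
    """Read all ordinary signals of an EDF file into physical units."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER_BYTES)
        if len(head) < _HEADER_BYTES:
            raise FormatError(f"{path}: truncated EDF header")
        n_records = int(_float(head[236:244], "n_records"))
        record_duration = _float(head[244:252], "record_duration")
        n_signals = int(_float(head[252:256], "n_signals"))
        if n_signals <= 0:
            raise FormatError(f"{path}: no signals in EDF header")

        sig_head = fh.read(n_signals * _SIGNAL_HEADER_BYTES)
        if len(sig_head) < n_signals * _SIGNAL_HEADER_BYTES:
            raise FormatError(f"{path}: truncated EDF signal headers")

        # Signal headers are stored field-major: all labels, all transducers, ...
        base = 0

        def take(width: int):
            nonlocal base
            out = [sig_head[base + i * width: base + (i + 1) * width] for i in range(n_signals)]
            base += width * n_signals
            return out

        labels = [_ascii(b) for b in take(16)]
        take(80)  # transducer type
        dims = [_ascii(b) for b in take(8)]
        phys_min = [_float(b, "phys_min") for b in take(8)]
        phys_max = [_float(b, "phys_max") for b in take(8)]
        dig_min = [_float(b, "dig_min") for b in take(8)]
        dig_max = [_float(b, "dig_max") for b in take(8)]
        take(80)  # prefiltering
        nsamp = [int(_float(b, "samples_per_record")) for b in take(8)]

        samples_per_record = sum(nsamp)
        raw = np.frombuffer(fh.read(), dtype="<i2")

    if n_records < 0:  # -1 means "unknown"; infer from payload size
        n_records = raw.size // samples_per_record
    raw = raw[: n_records * samples_per_record].reshape(n_records, samples_per_record)

    channels: list[EdfChannel] = []
    col = 0
    for i in range(n_signals):
        digital = raw[:, col: col + nsamp[i]].reshape(-1).astype(np.float64)
        col += nsamp[i]
        dig_span = dig_max[i] - dig_min[i]
        if dig_span == 0:
            gain, offset = 1.0, 0.0
        else:
            gain = (phys_max[i] - phys_min[i]) / dig_span
            offset = phys_min[i] - gain * dig_min[i]
        rate = nsamp[i] / record_duration if record_duration > 0 else float(nsamp[i])
        channels.append(EdfChannel(labels[i], dims[i], rate, digital * gain + offset))
    return channels


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, channels: list[tuple[str, float, np.ndarray]],
              record_duration: float = 1.0) -> None:
    """Write channels as plain EDF. Each channel is (label, rate_hz, values).

    Values are stored with physical range [0, 100] mapped onto the full int16
    digital range, which is ample precision for saturation percentages. All
    channel lengths must cover an integer number of records.
    """
    n_signals = len(channels)
    nsamp = [int(round(rate * record_duration)) for _, rate, _ in channels]
    lengths = {len(v) / n for (_, _, v), n in zip(channels, nsamp)}
    if len(lengths) != 1:
        raise ValueError("channels imply differing record counts")
    n_records = int(lengths.pop())

    header_bytes = _HEADER_BYTES + n_signals * _SIGNAL_HEADER_BYTES
    head = b"".join([
        _pad("0", 8), _pad("X", 80), _pad("X", 80),
        _pad("01.01.24", 8), _pad("00.00.00", 8),
        _pad(str(header_bytes), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad(f"{record_duration:g}", 8), _pad(str(n_signals), 4),
    ])

    phys_min, phys_max, dig_min, dig_max = 0.0, 100.0, -32768, 32767
    sig_head = b"".join(
        [b"".join(_pad(lbl, 16) for lbl, _, _ in channels)]
        + [b"".join(_pad("", 80) for _ in channels)]
        + [b"".join(_pad("%", 8) for _ in channels)]
        + [b"".join(_pad(f"{phys_min:g}", 8) for _ in channels)]
        + [b"".join(_pad(f"{phys_max:g}", 8) for _ in channels)]
        + [b"".join(_pad(str(dig_min), 8) for _ in channels)]
        + [b"".join(_pad(str(dig_max), 8) for _ in channels)]
        + [b"".join(_pad("", 80) for _ in channels)]
        + [b"".join(_pad(str(n), 8) for n in nsamp)]
        + [b"".join(_pad("", 32) for _ in channels)]
    )

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = [
        np.clip(np.round((np.asarray(v, dtype=np.float64) - phys_min) / gain + dig_min),
                dig_min, dig_max).astype("<i2")
        for _, _, v in channels
    ]
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        for r in range(n_records):
            for d, n in zip(digital, nsamp):
                fh.write(d[r * n:(r + 1) * n].tobytes())
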