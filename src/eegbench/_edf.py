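"""Minimal EDF (European Data Format, 16-bit) writer.

Only writing is implemented here (reading goes through ``mne``): the format
is a fixed-width ASCII header followed by little-endian int16 data records,
with a per-channel linear mapping between digital and physical values.
Quantization error is therefore bounded by half a digital step of the stored
physical range.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

_DIG_MIN, _DIG_MAX = -32767, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    s = f"{value:.{max(width - 2, 0)}g}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    channels: Sequence[np.ndarray],
    fs: float,
    labels: Sequence[str],
) -> None:
    """Write equal-length channels sampled at ``fs`` to an EDF file."""
    channels = [np.asarray(c, dtype=float) for c in channels]
    n = channels[0].size
    if any(c.size != n for c in channels):
        raise ValueError("all channels must have equal length")
    ns = len(channels)

    # one-second records when the layout allows, else a single record
    if float(fs).is_integer() and n % int(fs) == 0:
        samples_per_record = int(fs)
        n_records = n // samples_per_record
        record_duration = 1.0
    else:
        samples_per_record = n
        n_records = 1
        record_duration = n / fs

    # round the physical range through its 8-char ASCII header representation
    # first, so the digital mapping matches what a reader will reconstruct
    phys_max = [
        float(_num(max(float(np.max(np.abs(c))), 1e-12), 8).decode())
        for c in channels
    ]
    scale = [(2 * p) / (_DIG_MAX - _DIG_MIN) for p in phys_max]
    digital = [
        np.clip(np.round(c / s), _DIG_MIN, _DIG_MAX).astype("<i2")
        for c, s in zip(channels, scale)
    ]

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X eegbench", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _num(record_duration, 8),
            _field(str(ns), 4),
        ]
    )
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in range(ns))  # transducer
    header += b"".join(_field("V", 8) for _ in range(ns))  # physical dimension
    header += b"".join(_num(-p, 8) for p in phys_max)
    header += b"".join(_num(p, 8) for p in phys_max)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_field(str(samples_per_record), 8) for _ in range(ns))
    header += b"".join(_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * samples_per_record, (r + 1) * samples_per_record)
            for d in digital:
                fh.write(d[sl].tobytes())


def quantization_step(peak_abs: float) -> float:
    """Physical size of one digital step for a channel with the given peak."""
    return 2 * max(peak_abs, 1e-12) / (_DIG_MAX - _DIG_MIN)
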