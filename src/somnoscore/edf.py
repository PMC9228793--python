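"""Minimal European Data Format (EDF) reader and writer.

EDF stores multichannel signals as fixed-width ASCII headers followed by
interleaved 16-bit little-endian integer data records; each channel carries
its own samples-per-record, so mixed sampling rates are preserved exactly.
This module implements the subset needed for polysomnography round-trips:
uniform continuous signals, one-second data records, physical units in µV.
Amplitudes are quantized to the 16-bit grid spanned by each channel's
physical range (the writer's only lossy step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignal", "read_edf_file", "write_edf_file"]

# symmetric digital range so 0 µV is exactly representable on the ±V grid
_DIG_MIN, _DIG_MAX = -32767, 32767


@dataclass
class EdfSignal:
    """One signal as stored in an EDF file."""

    label: str
    samples: np.ndarray
    fs: float
    physical_dim: str = "uV"

    @property
    def quant_step(self) -> float:
        """Amplitude of one digital unit for the physical range the writer picks."""
        lo, hi = _physical_range(self.samples)
        return (hi - lo) / (_DIG_MAX - _DIG_MIN)


def _physical_range(x: np.ndarray) -> tuple[float, float]:
    """Symmetric physical range covering the signal; ±500 µV unless it clips."""
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    half = max(500.0, peak * 1.01, 1e-6)
    return -half, half


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf_file(path, signals: list[EdfSignal], *, start_date="01.01.00", start_time="00.00.00") -> str:
    """Write signals to an EDF file with one-second data records.

    Every channel's sampling rate must be an integer (samples per one-second
    record must be whole); durations are truncated to the shortest whole
    number of records shared by all channels.
    """
    if not signals:
        raise ValueError("no signals to write")
    spr = []  # samples per record
    for sig in signals:
        n = sig.fs * 1.0
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(f"channel {sig.label!r}: fs={sig.fs} not integer samples/second")
        spr.append(int(round(n)))
    n_records = min(int(sig.samples.size // n) for sig, n in zip(signals, spr))
    if n_records < 1:
        raise ValueError("signals shorter than one 1-s data record")

    ns = len(signals)
    header_bytes = 256 * (ns + 1)
    header = b"".join(
        [
            _field("0", 8),  # version
            _field("X X X X", 80),  # patient id (anonymised)
            _field("Startdate X", 80),  # recording id
            _field(start_date, 8),
            _field(start_time, 8),
            _field(header_bytes, 8),
            _field("", 44),  # reserved
            _field(n_records, 8),
            _field(1, 8),  # record duration, seconds
            _field(ns, 4),
        ]
    )

    phys = [_physical_range(s.samples) for s in signals]
    per_sig = b"".join(
        [
            b"".join(_field(s.label, 16) for s in signals),
            b"".join(_field("", 80) for _ in signals),  # transducer
            b"".join(_field(s.physical_dim, 8) for s in signals),
            b"".join(_field(f"{lo:.1f}", 8) for lo, _ in phys),
            b"".join(_field(f"{hi:.1f}", 8) for _, hi in phys),
            b"".join(_field(_DIG_MIN, 8) for _ in signals),
            b"".join(_field(_DIG_MAX, 8) for _ in signals),
            b"".join(_field("", 80) for _ in signals),  # prefiltering
            b"".join(_field(n, 8) for n in spr),
            b"".join(_field("", 32) for _ in signals),  # reserved
        ]
    )

    digital = []
    for sig, (lo, hi), n in zip(signals, phys, spr):
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        d = np.rint((sig.samples[: n_records * n] - lo) * gain + _DIG_MIN)
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2").reshape(n_records, n))

    with open(path, "wb") as f:
        f.write(header)
        f.write(per_sig)
        for r in range(n_records):
            for d in digital:
                f.write(d[r].tobytes())
    return str(path)


def _ascii(b: bytes) -> str:
    return b.decode("ascii", errors="replace").strip()


def read_edf_file(path) -> list[EdfSignal]:
    """Read an EDF/EDF+ file; returns one EdfSignal per stored channel."""
    try:
        with open(path, "rb") as f:
            head = f.read(256)
            if len(head) < 256:
                raise IOError(f"{path}: truncated EDF header")
            try:
                header_bytes = int(_ascii(head[184:192]))
                n_records = int(_ascii(head[236:244]))
                record_dur = float(_ascii(head[244:252]))
                ns = int(_ascii(head[252:256]))
            except ValueError:
                raise IOError(f"{path}: malformed EDF header fields") from None
            sig_head = f.read(256 * ns)
            if len(sig_head) < 256 * ns:
                raise IOError(f"{path}: truncated EDF signal headers")

            def col(offset: int, width: int, i: int) -> str:
                base = offset * ns + width * i
                return _ascii(sig_head[base : base + width])

            labels = [col(0, 16, i) for i in range(ns)]
            phys_lo = [float(col(96 + 8, 8, i) or 0) for i in range(ns)]  # offset 104
            phys_hi = [float(col(96 + 16, 8, i) or 0) for i in range(ns)]
            dig_lo = [int(col(96 + 24, 8, i) or 0) for i in range(ns)]
            dig_hi = [int(col(96 + 32, 8, i) or 0) for i in range(ns)]
            dims = [col(96, 8, i) for i in range(ns)]
            spr = [int(col(96 + 40 + 80, 8, i)) for i in range(ns)]

            if n_records < 0:
                # EDF allows -1 for "unknown"; infer from file size
                import os

                payload = os.path.getsize(path) - header_bytes
                n_records = payload // (2 * sum(spr))

            data = np.frombuffer(f.read(2 * sum(spr) * n_records), dtype="<i2")
    except OSError as e:
        raise IOError(f"cannot read EDF file {path}: {e}") from e

    if data.size < sum(spr) * n_records:
        raise IOError(f"{path}: EDF payload shorter than header declares")

    signals = []
    rec_len = sum(spr)
    offsets = np.cumsum([0] + spr)
    records = data[: rec_len * n_records].reshape(n_records, rec_len)
    for i in range(ns):
        raw = records[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        denom = dig_hi[i] - dig_lo[i]
        gain = (phys_hi[i] - phys_lo[i]) / denom if denom else 1.0
        samples = (raw - dig_lo[i]) * gain + phys_lo[i]
        fs = spr[i] / record_dur
        signals.append(EdfSignal(labels[i], samples, fs, physical_dim=dims[i]))
    return signals
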