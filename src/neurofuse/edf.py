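"""Minimal EDF (European Data Format) writer and reader.

Plain EDF, not EDF+: fixed-length data records of one second each, 16-bit
little-endian samples, physical units in microvolts.  Each signal's physical
range is chosen from its own data and re-parsed from the 8-character ASCII
header fields before digitization, so a write/read round trip is exact to
within one quantization step of the stored range.

The header's start date/time are fixed constants: output bytes are fully
determined by the samples and labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} characters")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float) -> str:
    """Format a float into at most 8 ASCII characters."""
    for fmt in ("%g", "%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % x
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot represent {x} in 8 characters")


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              labels: tuple[str, ...], physical_dim: str = "uV") -> None:
    """Write channels x samples ``data`` (microvolts) as a plain EDF file.

    The sampling rate must be an integer (one data record per second) and the
    signal length an integer number of seconds; trailing partial seconds are
    rejected rather than silently padded.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise ValueError("data must be channels x samples matching labels")
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1-s record
    n_sig, n_samp = data.shape
    if n_samp % spr != 0:
        raise ValueError(
            f"signal length {n_samp} is not a whole number of 1-s records at fs={fs}")
    n_rec = n_samp // spr

    # per-signal physical range, re-parsed from header strings for exactness
    phys_min, phys_max, digital = [], [], []
    for x in data:
        amp = float(np.max(np.abs(x)))
        amp = amp * 1.001 if amp > 0 else 1.0
        lo = float(_fmt_float(-amp))
        hi = float(_fmt_float(amp))
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        d = np.rint((x - lo) * gain + _DIG_MIN)
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    header_bytes = 256 * (1 + n_sig)
    head = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(header_bytes, 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(n_sig, 4),
    ])
    fields = [
        [(lab, 16) for lab in labels],
        [("", 80)] * n_sig,                       # transducer
        [(physical_dim, 8)] * n_sig,
        [(_fmt_float(v), 8) for v in phys_min],
        [(_fmt_float(v), 8) for v in phys_max],
        [(_DIG_MIN, 8)] * n_sig,
        [(_DIG_MAX, 8)] * n_sig,
        [("", 80)] * n_sig,                       # prefiltering
        [(spr, 8)] * n_sig,
        [("", 32)] * n_sig,
    ]
    sig_head = b"".join(_ascii(v, w) for group in fields for v, w in group)

    records = np.stack(digital)  # n_sig x n_samp
    body = records.reshape(n_sig, n_rec, spr).transpose(1, 0, 2).tobytes()
    try:
        with open(path, "wb") as fh:
            fh.write(head + sig_head + body)
    except OSError as exc:
        raise OSError(f"failed to write EDF file {path}: {exc}") from exc


def read_edf(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read a plain EDF file; returns (channels x samples in physical units,
    sampling rate, channel labels)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: too short to be an EDF file")
    n_rec = int(raw[236:244])
    rec_dur = float(raw[244:252])
    n_sig = int(raw[252:256])
    off = 256

    def field(width: int, conv=str) -> list:
        nonlocal off
        out = [conv(raw[off + i * width: off + (i + 1) * width].decode("ascii").strip())
               for i in range(n_sig)]
        off += width * n_sig
        return out

    labels = field(16)
    field(80)  # transducer
    field(8)   # physical dimension
    pmin = field(8, float)
    pmax = field(8, float)
    dmin = field(8, int)
    dmax = field(8, int)
    field(80)  # prefiltering
    spr = field(8, int)
    field(32)  # reserved

    body = np.frombuffer(raw, dtype="<i2", offset=256 * (1 + n_sig))
    per_rec = sum(spr)
    if body.size != n_rec * per_rec:
        raise ValueError(f"{path}: data section size mismatch")
    body = body.reshape(n_rec, per_rec)
    data = np.empty((n_sig, n_rec * max(spr)), dtype=float)
    pos = 0
    for i in range(n_sig):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        sig = body[:, pos:pos + spr[i]].reshape(-1).astype(float)
        data[i, : n_rec * spr[i]] = (sig - dmin[i]) * gain + pmin[i]
        pos += spr[i]
    fs = spr[0] / rec_dur
    return data, fs, tuple(labels)


def quantization_step(data: np.ndarray) -> float:
    """Worst-case physical quantization step for ``data`` written by write_edf."""
    amp = float(np.max(np.abs(data)))
    amp = amp * 1.001 if amp > 0 else 1.0
    hi = float(_fmt_float(amp))
    return 2 * hi / (_DIG_MAX - _DIG_MIN)
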