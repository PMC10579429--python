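"""Minimal FCS 3.0/3.1 reader and writer for list-mode floating-point data.

Covers the subset of the Flow Cytometry Standard this package needs: the
58-byte ASCII header with segment offsets, a delimited TEXT segment (doubled
delimiters inside values are unescaped), and a DATA segment in list mode
($MODE/L) with $DATATYPE F (float32) or D (float64) and byte order given by
$BYTEORD.  Integer data, analysis segments and multi-dataset files are out of
scope.  The writer emits just enough (FCS3.0, float32, little-endian) to
round-trip the reader and to serve as a fixture generator.
"""
from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_fcs", "write_fcs", "is_fcs"]


def is_fcs(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(6) in (b"FCS3.0", b"FCS3.1")


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # a doubled delimiter inside a value is an escaped literal delimiter
    sentinel = b"\x00\x01\x02"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2:
        parts = parts[:-1]
    return {
        parts[i].decode("ascii", "replace").strip().upper():
        parts[i + 1].decode("ascii", "replace").strip()
        for i in range(0, len(parts), 2)
    }


def read_fcs(path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS 3.0/3.1 file; returns (N x d float array, channel names)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    version = blob[0:6]
    if version not in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(
            f"not an FCS 3.0/3.1 file (magic {version!r} at offset 0)"
        )

    def _offset(segment: slice) -> int:
        text = blob[segment].decode("ascii", "replace").strip()
        return int(text) if text else 0

    text_begin = _offset(slice(10, 18))
    text_end = _offset(slice(18, 26))
    data_begin = _offset(slice(26, 34))
    data_end = _offset(slice(34, 42))
    if text_end <= text_begin:
        raise ValueError(f"malformed FCS header: TEXT segment {text_begin}-{text_end}")
    keys = _parse_text(blob[text_begin:text_end + 1])
    if data_begin == 0 or data_end == 0:
        data_begin = int(keys.get("$BEGINDATA", 0))
        data_end = int(keys.get("$ENDDATA", 0))
    if data_end <= data_begin:
        raise ValueError(f"malformed FCS file: DATA segment {data_begin}-{data_end}")
    mode = keys.get("$MODE", "L").upper()
    if mode != "L":
        raise ValueError(f"unsupported FCS mode {mode!r} (only list mode)")
    datatype = keys.get("$DATATYPE", "F").upper()
    if datatype not in ("F", "D"):
        raise ValueError(
            f"unsupported $DATATYPE {datatype!r} (only floating point)"
        )
    n_par = int(keys["$PAR"])
    n_tot = int(keys["$TOT"])
    byteord = keys.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    dtype = np.dtype(("<" if little else ">") + ("f4" if datatype == "F" else "f8"))
    names = []
    for i in range(1, n_par + 1):
        names.append(keys.get(f"$P{i}N", keys.get(f"$P{i}S", f"P{i}")))
    raw = blob[data_begin:data_begin + n_tot * n_par * dtype.itemsize]
    values = np.frombuffer(raw, dtype=dtype).astype(float).reshape(n_tot, n_par)
    return values, names


def write_fcs(path, values: np.ndarray, channel_names: list[str]) -> None:
    """Write list-mode float32 FCS 3.0 (little-endian)."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float32))
    n_tot, n_par = values.shape
    if len(channel_names) != n_par:
        raise ValueError("one channel name per column required")
    delim = "/"
    pairs = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        pairs[f"$P{i}N"] = str(name).replace(delim, delim + delim)
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(max(np.max(np.abs(values)), 1.0)) * 2)
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim
    text_bytes = text.encode("ascii")
    header_len = 58
    text_begin = header_len
    text_end = text_begin + len(text_bytes) - 1
    data_begin = text_end + 1
    data_end = data_begin + n_tot * n_par * 4 - 1
    header = (
        b"FCS3.0    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_begin:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(values.astype("<f4").tobytes())
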