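"""Readers, writers and value transforms for event tables.

Event tables arrive either as FCS 3.0/3.1 files or as delimited text (comma
or tab separated, header row of channel names, no index column).  Transforms
are explicit and never applied silently; the samplers operate on raw channel
values unless the caller opts in.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import fcs
from .events import EventTable

__all__ = [
    "read_events",
    "write_events",
    "asinh_transform",
    "asinh_inverse",
    "log10_transform",
]


def asinh_transform(values: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """asinh(x / cofactor): monotone, linear near zero, log-like for large x."""
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def asinh_inverse(values: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    return np.sinh(np.asarray(values, dtype=float)) * cofactor


def log10_transform(values: np.ndarray, floor: float = 1.0) -> np.ndarray:
    """log10 of values floored at ``floor`` (cytometry data can reach zero)."""
    return np.log10(np.maximum(np.asarray(values, dtype=float), floor))


_TRANSFORMS = {
    None: lambda v, **kw: v,
    "none": lambda v, **kw: v,
    "asinh": lambda v, cofactor=150.0, **kw: asinh_transform(v, cofactor),
    "log10": lambda v, floor=1.0, **kw: log10_transform(v, floor),
}


def read_events(
    path,
    channels: list[str] = None,
    transform: str = None,
    cofactor: float = 150.0,
    log_floor: float = 1.0,
) -> EventTable:
    """Read an event table from FCS or delimited text.

    The format is detected from the file magic (FCS) with a delimited-text
    fallback; ``channels`` restricts and orders the columns, and ``transform``
    ("asinh" with ``cofactor`` or "log10" with ``log_floor``) is applied to
    the values after selection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fcs.is_fcs(path):
        values, names = fcs.read_fcs(path)
        table = EventTable(values, names)
    else:
        sep = None
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        frame = pd.read_csv(path, sep=sep)
        table = EventTable(frame.to_numpy(dtype=float), list(frame.columns))
    if channels is not None:
        table = table.select(channels)
    if transform not in _TRANSFORMS:
        raise ValueError(
            f"unknown transform {transform!r}; valid: none, asinh, log10"
        )
    values = _TRANSFORMS[transform](
        table.values, cofactor=cofactor, floor=log_floor
    )
    return EventTable(values, table.channel_names)


def write_events(path, table: EventTable) -> None:
    """Write an event table as CSV (or FCS if the suffix is .fcs)."""
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        fcs.write_fcs(path, table.values, table.channel_names)
    else:
        pd.DataFrame(table.values, columns=table.channel_names).to_csv(
            path, index=False
        )
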