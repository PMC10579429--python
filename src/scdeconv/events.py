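"""Per-cell event tables: rows are cells, columns are cytometer channels."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventTable"]


@dataclass
class EventTable:
    """N x d matrix of fluorescence intensities with channel labels.

    Values are arbitrary cytometer units; no missing values are allowed and at
    least one event must be present.
    """

    values: np.ndarray
    channel_names: list[str] = field(default=None)

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (cells x channels) array")
        if values.shape[0] < 1:
            raise ValueError("event table must contain at least one event")
        if not np.all(np.isfinite(values)):
            raise ValueError("event table contains missing or non-finite values")
        self.values = values
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(values.shape[1])]
        else:
            self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != values.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{values.shape[1]} columns"
            )

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def select(self, channels: list[str]) -> "EventTable":
        """Restrict to the named channels (order follows the request)."""
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise KeyError(
                f"channels {missing} not present; available: {self.channel_names}"
            )
        idx = [self.channel_names.index(c) for c in channels]
        return EventTable(self.values[:, idx], list(channels))

    def __len__(self) -> int:
        return self.n_events
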