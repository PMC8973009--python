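"""Core in-memory containers shared across the pipeline.

A :class:`Recording` is a continuous multichannel signal; an
:class:`EpochSet` is the event-locked trials x channels x samples array
that every analysis stage consumes; a :class:`DirectedNetwork` holds
directed edges with integer-sample lags, used both for generator ground
truth and for inference output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("onset_sample", "onset_s", "type", "valence", "learned", "phase")
LABEL_COLUMNS = ("valence", "learned", "phase")


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


@dataclass
class Recording:
    """Continuous multichannel signal in physical units (µV).

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Unique channel labels; the leading character encodes hemisphere
        ("L" or "R") for bilateral montages.
    filter_history : list of str
        Human-readable record of filters already applied.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    filter_history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite samples")
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        self.channels = list(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def validate_events(events: pd.DataFrame, n_samples: int | None = None) -> pd.DataFrame:
    """Check the event-table schema and ordering invariants.

    Onsets must be non-negative integers and strictly increasing; if
    ``n_samples`` is given, onsets must lie within the recording.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) and onsets.min() < 0:
        raise ValueError("event onsets must be >= 0")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    if n_samples is not None and len(onsets) and onsets.max() >= n_samples:
        raise ValueError("event onset beyond end of recording")
    return events


@dataclass
class EpochSet:
    """Event-locked trials, one fixed-length window per trial.

    ``data`` has shape (n_trials, n_channels, n_samples) and ``times`` is
    the common time axis in seconds with 0 at the event.  ``rejected`` is
    a per-(trial, channel) boolean mask; the data itself is never deleted
    by artifact screening.  After :func:`dirflow.preprocess.normalize`,
    ``norm_mu``/``norm_sd`` record the per-trial-channel statistics that
    were removed so the transform is auditable.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    channels: list[str]
    labels: pd.DataFrame
    rejected: np.ndarray | None = None
    norm_mu: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (trials x channels x samples)")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("time axis length must match the sample axis")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[:2], dtype=bool)
        self.labels = self.labels.reset_index(drop=True)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label row per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            rejected=None if self.rejected is None else self.rejected.copy(),
            labels=self.labels.copy(),
            norm_mu=None if self.norm_mu is None else self.norm_mu.copy(),
            norm_sd=None if self.norm_sd is None else self.norm_sd.copy(),
        )

    def side_indices(self, side: str) -> np.ndarray:
        """Indices of channels on hemisphere ``side`` ("L" or "R")."""
        idx = [i for i, c in enumerate(self.channels) if c.startswith(side)]
        if not idx:
            raise ValueError(f"no channels on side {side!r}")
        return np.asarray(idx)

    def side_mean(self, side: str) -> np.ndarray:
        """Across-channel mean signal of one hemisphere, (trials x samples)."""
        return self.data[:, self.side_indices(side), :].mean(axis=1)

    def window_slice(self, window_ms: Sequence[float]) -> slice:
        """Sample slice (inclusive endpoints) for a window in ms."""
        lo, hi = float(window_ms[0]) / 1e3, float(window_ms[1]) / 1e3
        if hi <= lo:
            raise ValueError("window start must precede window end")
        i0 = int(np.searchsorted(self.times, lo - 0.5 / self.fs))
        i1 = int(np.searchsorted(self.times, hi - 0.5 / self.fs))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError("window outside the epoch time axis")
        return slice(i0, i1 + 1)


@dataclass
class NetworkEdge:
    """Directed edge: information flows ``source`` -> ``target``."""

    source: str | int
    target: str | int
    lag_samples: int
    strength: float = 0.0
    p: float | None = None


@dataclass
class DirectedNetwork:
    """Directed graph over channels or sources with per-edge lags."""

    nodes: list
    edges: list[NetworkEdge]
    hemispheres: dict = field(default_factory=dict)

    def edge_set(self) -> set[tuple]:
        return {(e.source, e.target) for e in self.edges}

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source == e.target:
                raise ValueError("self-edges are not allowed")
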