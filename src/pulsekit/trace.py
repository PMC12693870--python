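"""Uniformly sampled signal containers.

A :class:`SignalTrace` is the universal currency between the simulator, the
detectors and the reconstruction code: an ordered array of demodulated
impedance-magnitude samples (volts) with a sampling rate and a start time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class TimeGrid:
    """A uniform sample grid without data: length, rate and origin."""

    n_samples: int
    fs_Sa_s: float
    t_start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("a time grid needs at least 2 samples")
        if not self.fs_Sa_s > 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.fs_Sa_s

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + (self.n_samples - 1) / self.fs_Sa_s

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.fs_Sa_s


@dataclass
class SignalTrace:
    """Uniformly sampled impedance-magnitude series s[i] (volts).

    Sample indices are the authoritative event coordinates; times are derived
    as ``t_start_s + i / fs_Sa_s``.
    """

    samples: np.ndarray
    fs_Sa_s: float
    t_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ConfigError("a trace must be a 1-D array with >= 2 samples")
        if not self.fs_Sa_s > 0:
            raise ConfigError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("trace samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_Sa_s

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.samples.size, self.fs_Sa_s, self.t_start_s)

    def times(self) -> np.ndarray:
        return self.grid.times()

    def index_to_time(self, idx) -> np.ndarray | float:
        return self.t_start_s + np.asarray(idx) / self.fs_Sa_s

    def time_to_index(self, t) -> np.ndarray | int:
        idx = np.rint((np.asarray(t) - self.t_start_s) * self.fs_Sa_s).astype(int)
        return idx

    def copy(self) -> "SignalTrace":
        return SignalTrace(self.samples.copy(), self.fs_Sa_s, self.t_start_s)
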