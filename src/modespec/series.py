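"""Core time-series container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BOLDSeries"]


@dataclass(frozen=True)
class BOLDSeries:
    """A single regularly sampled BOLD time series (one voxel or ROI).

    Parameters
    ----------
    values
        Signal samples in arbitrary units.
    dt
        Sampling interval in seconds (the fMRI repetition time for raw
        voxel data).
    t0
        Acquisition time of the first retained sample, seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite samples")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 0.5 / self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    def with_values(self, values: np.ndarray) -> "BOLDSeries":
        """Return a copy carrying new samples on the same time grid."""
        return BOLDSeries(values=np.asarray(values, dtype=float),
                          dt=self.dt, t0=self.t0)
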