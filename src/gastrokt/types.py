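"""Core in-memory containers shared across the toolkit.

Axis convention: image arrays are ``(x, y, slice, time)``; k-space arrays are
``(kx, ky, slice, time)`` with the DC sample at ``(nx//2, ny//2)``.  Indices
are 0-based; physical coordinates are in millimetres measured from the grid
corner (voxel centres sit at ``(i + 0.5) * dx``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageSeries", "KSpaceSeries", "RespirationTrace"]


@dataclass
class ImageSeries:
    """Real-valued dynamic image stack.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, n_slices, n_frames)
        Magnitude intensities (non-negative).
    voxel_size : tuple of float
        ``(dx, dy, dz)`` in mm.
    frame_times : ndarray, shape (n_frames,)
        Acquisition time of each frame in seconds, strictly increasing.
    provenance : str
        Free-form label recording how the series was produced.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_times: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"ImageSeries expects a 4D (x, y, slice, time) array, got ndim={self.values.ndim}"
            )
        if self.frame_times.shape != (self.values.shape[3],):
            raise ValueError("frame_times length must equal the time dimension")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def copy(self) -> "ImageSeries":
        return ImageSeries(
            self.values.copy(), tuple(self.voxel_size), self.frame_times.copy(), self.provenance
        )


@dataclass
class KSpaceSeries:
    """Complex k-space samples plus the phase-encode sampling mask.

    ``values`` has shape ``(nkx, nky, n_slices, n_frames)``; ``mask`` has shape
    ``(nky, n_slices, n_frames)`` and is True where the ky line was acquired.
    Unacquired lines hold zeros.
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_times: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("KSpaceSeries expects a 4D (kx, ky, slice, time) array")
        expected = (self.values.shape[1], self.values.shape[2], self.values.shape[3])
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != expected:
            raise ValueError(f"mask shape {self.mask.shape} != expected {expected}")
        if self.frame_times.shape != (self.values.shape[3],):
            raise ValueError("frame_times length must equal the time dimension")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    @property
    def n_pe(self) -> int:
        """Number of phase-encode (ky) lines."""
        return self.values.shape[1]

    def is_fully_sampled(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "KSpaceSeries":
        return KSpaceSeries(
            self.values.copy(),
            self.mask.copy(),
            tuple(self.voxel_size),
            self.frame_times.copy(),
            dict(self.attrs),
        )


@dataclass
class RespirationTrace:
    """Uniformly sampled respiratory pressure signal.

    One short pressure burst per breath (inhalation) followed by a quiescent
    interval (slow exhalation), as recorded by a pressure pillow.
    """

    sample_times: np.ndarray
    pressure: np.ndarray
    rate_nominal: float  # cycles per minute

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.sample_times.shape != self.pressure.shape:
            raise ValueError("sample_times and pressure must have the same shape")

    @property
    def sampling_rate(self) -> float:
        if self.sample_times.size < 2:
            raise ValueError("trace too short to infer a sampling rate")
        return 1.0 / float(self.sample_times[1] - self.sample_times[0])
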