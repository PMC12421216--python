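"""Time-interleaved Cartesian undersampling and respiratory-gated scheduling.

The acquisition model: phase-encode (ky) lines are skipped with a reduction
factor R at the k-space periphery while a centred block of auto-calibration
(ACS) lines is always acquired; the skipped-line pattern shifts by one line
each frame so the union of R consecutive frames covers every line.  Volumes
(all slices) are triggered off the respiratory trace and acquired during the
quiescent slow-exhalation phase, which sets the effective temporal resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .types import KSpaceSeries, RespirationTrace

__all__ = [
    "SamplingPattern",
    "AcquisitionParams",
    "AcquisitionSchedule",
    "build_mask",
    "apply_mask",
    "volume_acquisition_time",
    "detect_triggers",
    "schedule_volumes",
]


@dataclass
class SamplingPattern:
    """Parametric description of the time-interleaved undersampling.

    ``n_acs`` central lines are always sampled; peripheral line ``j`` is
    sampled at frame ``t`` iff ``j % reduction == phase_rule(t)``.  The ACS
    block is placed so the DC line (index ``n_pe // 2``) is the upper-middle
    ACS line when ``n_acs`` is even.
    """

    n_pe: int
    n_acs: int = 12
    reduction: int = 3
    phase_rule: Callable[[int], int] | None = None  # default: t % reduction

    def __post_init__(self) -> None:
        if self.n_pe <= 0:
            raise ValueError("n_pe must be positive")
        if not 0 <= self.n_acs <= self.n_pe:
            raise ValueError(f"need 0 <= n_acs <= n_pe, got n_acs={self.n_acs}, n_pe={self.n_pe}")
        if self.reduction < 1:
            raise ValueError("reduction factor must be >= 1")

    @property
    def dc_line(self) -> int:
        return self.n_pe // 2

    @property
    def acs_lines(self) -> np.ndarray:
        start = self.dc_line - self.n_acs // 2
        return np.arange(start, start + self.n_acs)

    def phase(self, frame_index: int) -> int:
        if self.phase_rule is not None:
            return int(self.phase_rule(frame_index)) % self.reduction
        return frame_index % self.reduction


@dataclass
class AcquisitionParams:
    """Sequence parameters of the multi-slice gradient-echo protocol.

    Defaults are the accelerated rat protocol: TR 10.6 ms, TE 1.6 ms, FA 25
    degrees, FOV 64 x 42 mm, matrix 128 x 84, 24 slices of 1.5 mm in 6 packets
    of 4, 24 phase-encode lines acquired per slice per frame (12 ACS + 12
    peripheral lines at R = 3 under one reading; see the pattern config for
    the alternative reading with 24 peripheral lines).
    """

    tr: float = 10.6  # ms
    te: float = 1.6  # ms
    fa: float = 25.0  # degrees
    n_slices: int = 24
    slices_per_packet: int = 4
    n_packets: int = 6
    lines_per_slice_per_frame: int = 24
    fov: tuple[float, float] = (64.0, 42.0)  # mm
    matrix: tuple[int, int] = (128, 84)
    slice_thickness: float = 1.5  # mm

    def __post_init__(self) -> None:
        if self.n_slices != self.slices_per_packet * self.n_packets:
            raise ValueError("n_slices must equal slices_per_packet * n_packets")
        if self.lines_per_slice_per_frame > self.matrix[1]:
            raise ValueError("cannot acquire more lines per frame than phase-encode lines")


@dataclass
class AcquisitionSchedule:
    """Gated acquisition timing: when each volume (and packet) was acquired."""

    trigger_times: np.ndarray  # all respiration triggers seen, s
    volume_starts: np.ndarray  # s
    volume_ends: np.ndarray  # s
    packet_starts: np.ndarray = field(default=None)  # (n_volumes, n_packets), s
    truncated: bool = False

    @property
    def n_volumes(self) -> int:
        return len(self.volume_starts)

    @property
    def effective_resolution(self) -> np.ndarray:
        """Start-to-start interval between successive volumes, s."""
        return np.diff(self.volume_starts)

    @property
    def frame_times(self) -> np.ndarray:
        return np.asarray(self.volume_starts, dtype=float)


def build_mask(pattern: SamplingPattern, frame_index: int) -> np.ndarray:
    """Boolean ky-line mask for one frame: ACS always on, interleaved periphery."""
    if frame_index < 0:
        raise ValueError("frame index must be non-negative")
    mask = np.zeros(pattern.n_pe, dtype=bool)
    mask[pattern.acs_lines] = True
    lines = np.arange(pattern.n_pe)
    mask |= (lines % pattern.reduction) == pattern.phase(frame_index)
    return mask


def apply_mask(kspace: KSpaceSeries, pattern: SamplingPattern) -> KSpaceSeries:
    """Retrospectively undersample fully sampled k-space.

    Unsampled lines are zeroed and flagged false in the mask; sampled lines
    are copied bit-identically.
    """
    if pattern.n_pe != kspace.n_pe:
        raise ValueError(
            f"pattern n_pe={pattern.n_pe} does not match k-space ky dimension {kspace.n_pe}"
        )
    if not kspace.is_fully_sampled():
        raise ValueError("apply_mask expects fully sampled input k-space")
    out = kspace.copy()
    n_frames = out.shape[3]
    for t in range(n_frames):
        line_mask = build_mask(pattern, t)
        out.values[:, ~line_mask, :, t] = 0.0
        out.mask[~line_mask, :, t] = False
    out.attrs.update(
        {"reduction": pattern.reduction, "n_acs": pattern.n_acs}
    )
    return out


def volume_acquisition_time(params: AcquisitionParams) -> float:
    """Seconds to acquire one volume (all slices).

    Slices within a packet are excited within one TR period (slice loop inside
    the PE loop inside the packet loop), so the volume time is
    ``n_packets * lines_per_slice_per_frame * TR``.
    """
    return params.n_packets * params.lines_per_slice_per_frame * params.tr * 1e-3


def detect_triggers(trace: RespirationTrace, threshold: float | None = None) -> np.ndarray:
    """Gating triggers: the falling edge of each respiratory burst.

    The trigger marks the onset of the quiescent slow-exhalation phase, when
    acquisition can start without respiratory motion corruption.  ``threshold``
    defaults to halfway between the trace minimum and maximum; a flat trace
    (or a threshold above the maximum) yields an empty result.
    """
    p = trace.pressure
    if p.size == 0:
        raise ValueError("empty respiration trace")
    if threshold is None:
        lo, hi = float(p.min()), float(p.max())
        if hi - lo <= 0:
            return np.array([])
        threshold = lo + 0.5 * (hi - lo)
    above = p > threshold
    falling = np.flatnonzero(above[:-1] & ~above[1:])
    return trace.sample_times[falling + 1]


def schedule_volumes(
    triggers: Sequence[float],
    volume_time: float,
    n_packets: int = 1,
    n_volumes: int | None = None,
) -> AcquisitionSchedule:
    """Assign volume acquisitions to respiration triggers.

    A volume starts at the first trigger at-or-after the previous volume ends
    (triggers arriving during an ongoing volume are ignored — no
    re-triggering) and runs uninterrupted for ``volume_time`` seconds,
    spanning multiple respiratory cycles when the cycle is shorter than the
    volume time.  With periodic triggers of cycle c the start-to-start
    interval is ``ceil(volume_time / c) * c``.
    """
    triggers = np.asarray(triggers, dtype=float)
    if triggers.size and np.any(np.diff(triggers) <= 0):
        raise ValueError("triggers must be strictly increasing")
    if volume_time <= 0:
        raise ValueError("volume_time must be positive")
    starts, ends = [], []
    next_free = -np.inf
    for t in triggers:
        if t >= next_free:
            starts.append(t)
            ends.append(t + volume_time)
            next_free = t + volume_time
            if n_volumes is not None and len(starts) >= n_volumes:
                break
    truncated = n_volumes is not None and len(starts) < n_volumes
    if truncated:
        warnings.warn(
            f"only {len(starts)} of {n_volumes} requested volumes could be scheduled "
            "from the available triggers",
            stacklevel=2,
        )
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    packet_time = volume_time / n_packets
    packets = starts[:, None] + packet_time * np.arange(n_packets)[None, :]
    return AcquisitionSchedule(triggers, starts, ends, packets, truncated)
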