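"""Single-coil k-t kernel interpolation reconstruction.

Missing phase-encode lines of a time-interleaved undersampled acquisition are
estimated as shift-invariant linear combinations of acquired neighbours in
(kx, ky, t) — a k-t GRAPPA-style convolutional interpolation adapted to a
single receive coil.  Two image properties justify linear predictability
here: a piecewise-homogeneous bright lumen acts as an effective spatial
sensitivity profile (a convolution kernel in k-space), and the quasi-periodic
narrow-band contraction dynamics justify time-invariant kernels.

Kernel weights are calibrated on the fully sampled auto-calibration (ACS)
block by unregularized linear least squares and then applied to fill every
skipped line; acquired samples are never modified (data consistency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import SamplingPattern, apply_mask
from .types import ImageSeries, KSpaceSeries

__all__ = [
    "KTKernelSet",
    "CalibrationReport",
    "enumerate_kernel_geometry",
    "calibrate",
    "interpolate",
    "reconstruct_images",
    "kt_reconstruct",
    "reconstruct_undersampled",
]

# A kernel "shape" is keyed by (target phase, tuple of usable frame offsets);
# interior frames use the full centred window, sequence edges get dedicated
# clamped-window variants.
ShapeKey = tuple[int, tuple[int, ...]]


def _source_offsets(
    reduction: int,
    phase: int,
    t_offsets: tuple[int, ...],
    max_dky: int | None,
) -> list[tuple[int, int]]:
    """Sampled-lattice (dky, dt) source offsets for one target phase.

    For a target line of phase p (ky ≡ phase(t) + p mod R), the sampled lines
    at frame offset dt sit at dky ≡ dt - p (mod R); the nearest one above and
    below the target are used, optionally pruned to |dky| <= max_dky so the
    full stencil can fit inside the ACS block.
    """
    sources: list[tuple[int, int]] = []
    for dt in t_offsets:
        a = (dt - phase) % reduction
        if a == 0:
            cands = [0]
        else:
            cands = [a, a - reduction]
        for dky in cands:
            if max_dky is not None and abs(dky) > max_dky:
                continue
            if dky == 0 and dt == 0:
                continue  # the target itself
            sources.append((dky, dt))
    return sources


@dataclass
class KTKernelSet:
    """Calibrated k-t interpolation kernels.

    ``shapes`` maps a :data:`ShapeKey` to its (dky, dt) source offsets;
    ``weights`` (after calibration) maps the same key to a complex array of
    shape ``(n_sources, n_kx_taps)``; kx taps run ``-kx_halfwidth ..
    +kx_halfwidth``.
    """

    reduction: int
    kx_halfwidth: int = 2
    t_offsets: tuple[int, ...] = ()
    max_dky: int | None = None
    shapes: dict[ShapeKey, list[tuple[int, int]]] = field(default_factory=dict)
    weights: dict[ShapeKey, np.ndarray] = field(default_factory=dict)

    @property
    def n_kx_taps(self) -> int:
        return 2 * self.kx_halfwidth + 1

    @property
    def kx_taps(self) -> np.ndarray:
        return np.arange(-self.kx_halfwidth, self.kx_halfwidth + 1)

    def shape_for(self, phase: int, t: int, n_frames: int) -> ShapeKey:
        """Shape key for a target at frame ``t``.

        At sequence edges the temporal window is shifted (keeping its length)
        to stay inside the record; if the record is shorter than the window it
        is truncated as well.  Edge variants get dedicated calibrated kernels.
        """
        lo, hi = min(self.t_offsets), max(self.t_offsets)
        shift = 0
        if t + lo < 0:
            shift = -(t + lo)
        elif t + hi > n_frames - 1:
            shift = (n_frames - 1) - (t + hi)
        offs = tuple(o + shift for o in self.t_offsets if 0 <= t + o + shift < n_frames)
        if not offs:
            raise ValueError("frame count smaller than the temporal kernel window")
        key = (phase, offs)
        if key not in self.shapes:
            srcs = _source_offsets(self.reduction, phase, offs, self.max_dky)
            self._validate_sources(srcs, key)
            self.shapes[key] = srcs
        return key

    def _validate_sources(self, sources, key) -> None:
        if len(sources) < 2:
            raise ValueError(f"kernel {key}: window too small, only {len(sources)} sources")
        n_frames = len({dt for _, dt in sources})
        if n_frames < 2:
            raise ValueError(
                f"kernel {key}: needs sources from >= 2 temporal frames, got {n_frames}"
            )

    @property
    def is_calibrated(self) -> bool:
        return bool(self.weights)


def enumerate_kernel_geometry(
    reduction: int,
    kx_halfwidth: int = 2,
    t_halfwidth: int | None = None,
    max_dky: int | None = None,
) -> KTKernelSet:
    """Lay out (uncalibrated) kernel geometry for a reduction factor R.

    One kernel shape per missing phase p in 1..R-1 (so R=3 yields the classic
    two distinct shapes).  The temporal window spans R frames centred on the
    target by default (``t_halfwidth`` overrides the half-width); ``max_dky``
    prunes ky sources so the stencil fits inside a narrow ACS block.
    """
    if reduction < 2:
        raise ValueError("kernel interpolation requires reduction >= 2")
    if t_halfwidth is None:
        lo, hi = -((reduction - 1) // 2), reduction // 2
    else:
        lo, hi = -t_halfwidth, t_halfwidth
    t_offsets = tuple(range(lo, hi + 1))
    kset = KTKernelSet(
        reduction=reduction, kx_halfwidth=kx_halfwidth, t_offsets=t_offsets, max_dky=max_dky
    )
    for phase in range(1, reduction):
        key = (phase, t_offsets)
        srcs = _source_offsets(reduction, phase, t_offsets, max_dky)
        kset._validate_sources(srcs, key)
        kset.shapes[key] = srcs
    return kset


@dataclass
class CalibrationReport:
    """Least-squares fit diagnostics per kernel shape."""

    residuals: dict[ShapeKey, float] = field(default_factory=dict)
    n_equations: dict[ShapeKey, int] = field(default_factory=dict)
    condition: dict[ShapeKey, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def keystr(key: ShapeKey) -> str:
            phase, offs = key
            return f"phase={phase},window={','.join(map(str, offs))}"

        return {
            "residuals": {keystr(k): v for k, v in self.residuals.items()},
            "n_equations": {keystr(k): v for k, v in self.n_equations.items()},
            "condition": {keystr(k): v for k, v in self.condition.items()},
            "warnings": list(self.warnings),
        }


def _acs_rows(kspace: KSpaceSeries) -> np.ndarray:
    """Rows sampled in every frame and slice (the ACS block)."""
    always = kspace.mask.all(axis=(1, 2))
    rows = np.flatnonzero(always)
    if rows.size == 0:
        raise ValueError("no ACS lines: no ky row is sampled in every frame")
    return rows


def calibrate(
    kspace: KSpaceSeries,
    geometry: KTKernelSet,
    frames: np.ndarray | None = None,
) -> tuple[KTKernelSet, CalibrationReport]:
    """Fit kernel weights on the ACS block by unregularized least squares.

    For every kernel shape, equations are assembled from all ACS positions
    (sliding over kx, ky, frames, and slices) where the full source stencil
    lies inside the ACS rows; the pooled system ``A w = b`` is solved with no
    regularization.  ``frames`` restricts calibration to a frame subset
    (default: all frames jointly, per the time-invariant-kernel premise).
    Underdetermined systems raise; rank-deficiency falls back to the
    minimum-norm solution with a report warning.
    """
    data = kspace.values
    nkx, _, n_slices, n_frames = data.shape
    acs = _acs_rows(kspace)
    w = geometry.kx_halfwidth
    kx_lo, kx_hi = w, nkx - w
    if kx_hi <= kx_lo:
        raise ValueError("kx dimension smaller than the kernel kx support")
    frame_pool = np.arange(n_frames) if frames is None else np.asarray(frames, int)

    # group calibration frames by their clamped-window shape key per phase
    report = CalibrationReport()
    kset = KTKernelSet(
        reduction=geometry.reduction,
        kx_halfwidth=geometry.kx_halfwidth,
        t_offsets=geometry.t_offsets,
        max_dky=geometry.max_dky,
        shapes=dict(geometry.shapes),
    )
    jobs: dict[ShapeKey, list[int]] = {}
    for phase in range(1, geometry.reduction):
        for t in frame_pool:
            key = kset.shape_for(phase, int(t), n_frames)
            jobs.setdefault(key, []).append(int(t))

    kx_idx = np.arange(kx_lo, kx_hi)
    taps = kset.kx_taps
    acs_set = set(int(r) for r in acs)
    for key, t_list in jobs.items():
        sources = kset.shapes[key]
        ky_targets = np.array(
            [ky for ky in acs if all((ky + dky) in acs_set for dky, _ in sources)], int
        )
        if ky_targets.size == 0:
            raise ValueError(
                f"kernel {key}: stencil does not fit inside the {acs.size}-line ACS block; "
                "reduce the ky span (max_dky) or acquire more ACS lines"
            )
        t_arr = np.asarray(sorted(set(t_list)), int)
        cols = []
        for dky, dt in sources:
            for dkx in taps:
                shifted = data[np.ix_(kx_idx + dkx, ky_targets + dky,
                                      np.arange(n_slices), t_arr + dt)]
                cols.append(shifted.reshape(-1))
        A = np.stack(cols, axis=1)
        b = data[np.ix_(kx_idx, ky_targets, np.arange(n_slices), t_arr)].reshape(-1)
        n_eq, n_w = A.shape
        if n_eq < n_w:
            raise ValueError(
                f"kernel {key}: underdetermined calibration ({n_eq} equations, {n_w} weights)"
            )
        sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
        if rank < n_w:
            report.warnings.append(
                f"kernel {key}: rank-deficient calibration (rank {rank} < {n_w}); "
                "minimum-norm solution used"
            )
        bnorm = float(np.linalg.norm(b))
        resid = float(np.linalg.norm(A @ sol - b)) / bnorm if bnorm > 0 else 0.0
        report.residuals[key] = resid
        report.n_equations[key] = int(n_eq)
        report.condition[key] = float(sv[0] / sv[-1]) if sv.size and sv[-1] > 0 else np.inf
        kset.weights[key] = sol.reshape(len(sources), kset.n_kx_taps)
    return kset, report


def _frame_phase_offsets(kspace: KSpaceSeries, reduction: int, acs: np.ndarray) -> np.ndarray:
    """Per-frame peripheral phase offset implied by the mask."""
    n_pe = kspace.n_pe
    offsets = np.empty(kspace.shape[3], dtype=int)
    peripheral = np.setdiff1d(np.arange(n_pe), acs)
    for t in range(kspace.shape[3]):
        line_mask = kspace.mask[:, 0, t]
        if not np.all(kspace.mask[:, :, t] == line_mask[:, None]):
            raise ValueError("mask differs across slices within a frame")
        sampled = peripheral[line_mask[peripheral]]
        residues = np.unique(sampled % reduction)
        if residues.size != 1:
            raise ValueError(
                f"frame {t}: sampled peripheral lines are not a single interleave "
                f"(residues {residues}); mask inconsistent with the kernel reduction"
            )
        offsets[t] = int(residues[0])
    return offsets


def interpolate(undersampled: KSpaceSeries, kernels: KTKernelSet) -> KSpaceSeries:
    """Fill every skipped line with its calibrated kernel prediction.

    Acquired lines pass through bit-exactly; ky source indices wrap modulo
    the grid (the discrete Fourier transform of a sampled image is periodic
    in k); the output mask is all-true.
    """
    if not kernels.is_calibrated:
        raise ValueError("kernels are not calibrated")
    R = kernels.reduction
    data = undersampled.values
    nkx, n_pe, n_slices, n_frames = data.shape
    if n_frames < 2:
        raise ValueError("frame count smaller than the temporal kernel window")
    out = undersampled.copy()
    if undersampled.is_fully_sampled():
        return out
    acs = _acs_rows(undersampled)
    offsets = _frame_phase_offsets(undersampled, R, acs)
    w = kernels.kx_halfwidth
    taps = kernels.kx_taps
    for t in range(n_frames):
        missing = np.flatnonzero(~undersampled.mask[:, 0, t])
        for ky in missing:
            phase = (int(ky) - offsets[t]) % R
            if phase == 0:
                raise ValueError(
                    f"line ky={ky} frame {t} is on the sampled interleave but masked out; "
                    "mask inconsistent with kernels"
                )
            key = kernels.shape_for(phase, t, n_frames)
            if key not in kernels.weights:
                raise ValueError(f"no calibrated weights for kernel {key}")
            sources = kernels.shapes[key]
            wts = kernels.weights[key]
            acc = np.zeros((nkx, n_slices), dtype=complex)
            for j, (dky, dt) in enumerate(sources):
                src_ky = (ky + dky) % n_pe
                line = data[:, src_ky, :, t + dt]
                padded = np.pad(line, ((w, w), (0, 0)))
                for m, dkx in enumerate(taps):
                    acc += wts[j, m] * padded[w + dkx : w + dkx + nkx, :]
            out.values[:, ky, :, t] = acc
    out.mask[:] = True
    out.attrs["kt_interpolated"] = True
    return out


def reconstruct_images(kspace: KSpaceSeries) -> ImageSeries:
    """Magnitude images from complete k-space: centred inverse 2D DFT per slice/frame."""
    if not kspace.mask.all():
        raise ValueError("k-space has unfilled lines; interpolate before reconstructing")
    img = np.fft.ifft2(np.fft.ifftshift(kspace.values, axes=(0, 1)), axes=(0, 1))
    return ImageSeries(
        np.abs(img),
        tuple(kspace.voxel_size),
        kspace.frame_times.copy(),
        provenance="kt-recon" if kspace.attrs.get("kt_interpolated") else "ifft",
    )


def _default_max_dky(n_acs: int) -> int:
    """Widest symmetric ky span whose stencil still fits in the ACS block."""
    return max(1, n_acs // 2 - 1)


def _split_temporal_mean(kspace: KSpaceSeries) -> tuple[KSpaceSeries, np.ndarray]:
    """Static/dynamic decomposition of undersampled k-space.

    Every ky line is revisited every R frames by the interleaved pattern, so
    each line's temporal mean over its acquired frames estimates the static
    component of the scene for the full grid.  Returning the mean-removed
    residual (zero where unacquired) lets the k-t kernels model only the
    dynamic content; the static part is restored exactly after interpolation.
    """
    v = kspace.values
    m = kspace.mask  # (ky, slice, time)
    cnt = m.sum(axis=2)
    safe = np.maximum(cnt, 1)
    mean = (v * m[None]).sum(axis=3) / safe[None]
    mean[:, cnt == 0] = 0.0
    resid = (v - mean[..., None]) * m[None]
    out = KSpaceSeries(
        resid, kspace.mask.copy(), tuple(kspace.voxel_size),
        kspace.frame_times.copy(), dict(kspace.attrs),
    )
    return out, mean


def kt_reconstruct(
    undersampled: KSpaceSeries,
    reduction: int | None = None,
    n_acs: int | None = None,
    kx_halfwidth: int = 2,
    t_halfwidth: int | None = None,
    per_slice: bool = False,
    subtract_temporal_mean: bool = True,
) -> tuple[ImageSeries, CalibrationReport]:
    """Calibrate, fill, and reconstruct an undersampled k-space series.

    ``reduction`` defaults to the value recorded in the k-space attributes.
    The kernel ky span is capped so calibration on the available ACS block is
    well posed.  By default the static component (each line's temporal mean
    over its acquired frames) is split off before calibration and restored
    after interpolation, so the kernels model only the dynamic residual;
    acquired samples are unaffected by the decomposition.  ``per_slice=True``
    calibrates a separate kernel set for each slice instead of sharing one
    set across slices.
    """
    if reduction is None:
        reduction = undersampled.attrs.get("reduction")
        if reduction is None:
            raise ValueError("reduction not given and not recorded in k-space attrs")
    reduction = int(reduction)
    if reduction == 1 or undersampled.is_fully_sampled():
        return reconstruct_images(undersampled), CalibrationReport()
    if n_acs is None:
        n_acs = int(_acs_rows(undersampled).size)
    geometry = enumerate_kernel_geometry(
        reduction, kx_halfwidth, t_halfwidth, max_dky=_default_max_dky(n_acs)
    )
    work = undersampled
    mean = None
    if subtract_temporal_mean:
        work, mean = _split_temporal_mean(undersampled)
    if not per_slice:
        kernels, report = calibrate(work, geometry)
        filled = interpolate(work, kernels)
    else:
        report = CalibrationReport()
        parts = []
        for s in range(work.shape[2]):
            sub = KSpaceSeries(
                work.values[:, :, s : s + 1, :],
                work.mask[:, s : s + 1, :],
                tuple(work.voxel_size),
                work.frame_times.copy(),
                dict(work.attrs),
            )
            kernels, rep = calibrate(sub, geometry)
            for key in rep.residuals:
                skey = (key[0] * 1000 + s, key[1])  # disambiguate per-slice entries
                report.residuals[skey] = rep.residuals[key]
                report.n_equations[skey] = rep.n_equations[key]
                report.condition[skey] = rep.condition[key]
            report.warnings.extend(rep.warnings)
            parts.append(interpolate(sub, kernels).values)
        filled = work.copy()
        filled.values = np.concatenate(parts, axis=2)
        filled.mask[:] = True
        filled.attrs["kt_interpolated"] = True
    if mean is not None:
        filled = KSpaceSeries(
            filled.values + mean[..., None], filled.mask, tuple(filled.voxel_size),
            filled.frame_times, dict(filled.attrs),
        )
    return reconstruct_images(filled), report


def reconstruct_undersampled(
    full_kspace: KSpaceSeries,
    pattern: SamplingPattern,
    **kwargs,
) -> tuple[ImageSeries, CalibrationReport]:
    """Retrospective pipeline: undersample fully sampled k-space, then reconstruct."""
    under = apply_mask(full_kspace, pattern)
    return kt_reconstruct(under, reduction=pattern.reduction, n_acs=pattern.n_acs, **kwargs)
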