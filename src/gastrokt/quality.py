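"""Image-quality metrics for reconstruction validation.

Reconstructions are compared against the fully sampled reference with the
relative error (RE, L2 of the difference over L2 of the reference), SSIM, and
PSNR, after normalizing both series to [0, 1] with one global scaling so the
temporal intensity dynamics are preserved.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .types import ImageSeries

__all__ = [
    "QualityMetrics",
    "normalize01",
    "relative_error",
    "psnr",
    "ssim",
    "mip",
    "pearson_r",
    "evaluate",
]

from dataclasses import dataclass


@dataclass
class QualityMetrics:
    re: float
    ssim: float
    psnr: float

    def to_dict(self) -> dict:
        return {"re": self.re, "ssim": self.ssim, "psnr": self.psnr}


def _values(images) -> np.ndarray:
    return images.values if isinstance(images, ImageSeries) else np.asarray(images, float)


def normalize01(images: ImageSeries) -> ImageSeries:
    """Rescale the whole series to [0, 1] with one global min/max scaling."""
    v = images.values
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        raise ValueError("constant series: [0, 1] normalization undefined")
    return ImageSeries(
        (v - lo) / (hi - lo), tuple(images.voxel_size), images.frame_times.copy(),
        images.provenance,
    )


def _check_shapes(test: np.ndarray, ref: np.ndarray) -> None:
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")


def relative_error(test, ref) -> float:
    """L2 norm of the vectorized difference divided by the L2 norm of the reference."""
    t, r = _values(test), _values(ref)
    _check_shapes(t, r)
    rnorm = float(np.linalg.norm(r))
    if rnorm == 0:
        raise ValueError("zero-norm reference")
    return float(np.linalg.norm(t - r)) / rnorm


def psnr(test, ref, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB (inf if identical)."""
    t, r = _values(test), _values(ref)
    _check_shapes(t, r)
    mse = float(np.mean((t - r) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(test, ref, win_size: int = 7, data_range: float = 1.0) -> float:
    """Mean structural similarity, computed per 2D slice/frame and averaged.

    Standard Wang et al. formulation (uniform window, K1=0.01, K2=0.03)
    via scikit-image.
    """
    t, r = _values(test), _values(ref)
    _check_shapes(t, r)
    if t.ndim == 2:
        t = t[:, :, None, None]
        r = r[:, :, None, None]
    if win_size > min(t.shape[0], t.shape[1]):
        raise ValueError("SSIM window larger than the in-plane image dimensions")
    vals = [
        structural_similarity(
            t[:, :, s, k], r[:, :, s, k], win_size=win_size, data_range=data_range,
            gaussian_weights=False,
        )
        for s in range(t.shape[2])
        for k in range(t.shape[3])
    ]
    return float(np.mean(vals))


def mip(images: ImageSeries, axis: int = 2) -> np.ndarray:
    """Maximum intensity projection along one spatial axis, per frame."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be a spatial axis index (0, 1, or 2)")
    return images.values.max(axis=axis)


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length value lists."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def evaluate(test: ImageSeries, ref: ImageSeries, normalize: bool = True) -> QualityMetrics:
    """RE / SSIM / PSNR of a reconstruction against its reference.

    With ``normalize=True`` both series are first globally normalized to
    [0, 1], matching the evaluation convention of the protocol.
    """
    if normalize:
        test = normalize01(test)
        ref = normalize01(ref)
    return QualityMetrics(
        re=relative_error(test, ref),
        ssim=ssim(test, ref),
        psnr=psnr(test, ref),
    )
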