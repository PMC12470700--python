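"""Image-quality metrics.

Contrast here is the span-to-mean ratio ``(I_max - I_min) / I_mean``.  It
is sometimes loosely called Michelson contrast in the radiography
enhancement literature, but note the classical Michelson definition is
``(I_max - I_min) / (I_max + I_min)``; this module implements the
span-to-mean form used by the enhancement pipeline's evaluation.

Entropy is Shannon entropy in bits over a fixed-width histogram spanning
the image's *nominal* dynamic range (0..255 for 8-bit data), not the
empirical min-max.  Anchoring the bins to the bit depth keeps entropies
comparable across filter settings: an image that occupies a narrow slice
of the range scores low however the slice is stretched.

PSNR/SNR follow the usual decibel definitions; SSIM delegates to the
standard Gaussian-weighted implementation (11x11 window, sigma 1.5,
K1=0.01, K2=0.03).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .errors import InvalidInputError, UndefinedMetricError
from .grid import ImageGrid


def _values(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, ImageGrid) else np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite values")
    return arr


def contrast(image) -> float:
    """Span-to-mean contrast ``(max - min) / mean`` over the whole grid.

    Raises :class:`UndefinedMetricError` when the mean is zero (e.g. an
    all-zero residual); that case is reported as undefined, never as 0.
    """
    arr = _values(image)
    mean = float(arr.mean())
    if mean == 0.0:
        raise UndefinedMetricError("contrast undefined: image mean is zero")
    return float((arr.max() - arr.min()) / mean)


def shannon_entropy(image, nbins: int = 256, value_range: tuple[float, float] | None = None) -> float:
    """Shannon entropy (bits) of the grey-level histogram.

    The histogram has ``nbins`` equal bins over ``value_range``; when the
    range is omitted it is taken from the image's nominal bit depth
    (``[0, 2**bit_depth)``, so each integer level of an exactly-occupied
    8-bit image falls in its own bin), or ``[0, 256)`` for a bare array.
    Zero-probability bins contribute nothing.  The result lies in
    ``[0, log2(nbins)]``.
    """
    if nbins < 2:
        raise InvalidInputError(f"nbins must be >= 2, got {nbins}")
    arr = _values(image)
    if value_range is None:
        top = image.nominal_max + 1 if isinstance(image, ImageGrid) else 256.0
        value_range = (0.0, float(top))
    counts, _ = np.histogram(arr, bins=nbins, range=value_range)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() + 0.0)


def mse(image, reference) -> float:
    """Mean squared pixel difference."""
    a, b = _values(image), _values(reference)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(image, reference, l_max: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(l_max**2 / MSE)`` in dB.

    Identical images have zero MSE; the infinite PSNR is signalled by
    returning ``math.inf`` rather than raising.
    """
    err = mse(image, reference)
    if err == 0.0:
        return math.inf
    return float(10.0 * np.log10(l_max * l_max / err))


def snr(signal_mean: float, noise_variance: float) -> float:
    """Signal-to-noise ratio ``10 log10(mean**2 / variance)`` in dB."""
    if not (signal_mean > 0):
        raise InvalidInputError(f"signal mean must be positive, got {signal_mean}")
    if noise_variance < 0:
        raise InvalidInputError(f"noise variance must be >= 0, got {noise_variance}")
    if noise_variance == 0:
        return math.inf
    return float(10.0 * np.log10(signal_mean**2 / noise_variance))


def estimate_noise_variance(image, reference=None, mask=None) -> float:
    """Noise variance for :func:`snr`.

    With a reference, the variance of the difference image; with a boolean
    mask, the variance of the masked (nominally flat) region; one of the
    two must be given — the pipeline has no blind noise estimator.
    """
    arr = _values(image)
    if reference is not None:
        ref = _values(reference)
        if ref.shape != arr.shape:
            raise InvalidInputError("reference shape mismatch")
        return float(np.var(arr - ref))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise InvalidInputError("mask shape mismatch")
        if not mask.any():
            raise InvalidInputError("mask selects no pixels")
        return float(np.var(arr[mask]))
    raise InvalidInputError("need a reference image or a flat-region mask")


def ssim(image, reference, data_range: float | None = None) -> float:
    """Mean structural similarity index.

    Gaussian-weighted 11x11 window (sigma 1.5), K1=0.01, K2=0.03; the
    dynamic range defaults to the image's nominal bit-depth range.
    """
    a, b = _values(image), _values(reference)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise InvalidInputError("image smaller than the 11x11 SSIM window")
    if data_range is None:
        data_range = image.nominal_max if isinstance(image, ImageGrid) else 255.0
    return float(
        structural_similarity(
            a, b, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03, data_range=data_range,
        )
    )


@dataclass(frozen=True)
class QualityReport:
    """Bundle of the metrics for one image (reference metrics optional).

    ``psnr_db`` and ``snr_db`` may be ``math.inf`` (identical images /
    zero noise); ``contrast`` is ``None`` when undefined (zero-mean
    image).
    """

    contrast: float | None
    entropy_bits: float
    mse: float | None = None
    psnr_db: float | None = None
    snr_db: float | None = None
    ssim: float | None = None


def quality_report(image, reference=None, l_max: float | None = None) -> QualityReport:
    """Compute all applicable metrics for an image.

    Reference-based metrics (MSE/PSNR/SSIM/SNR) are included only when a
    reference is given.  An undefined contrast is recorded as ``None``.
    """
    try:
        c = contrast(image)
    except UndefinedMetricError:
        c = None
    ent = shannon_entropy(image)
    if reference is None:
        return QualityReport(contrast=c, entropy_bits=ent)
    if l_max is None:
        l_max = image.nominal_max if isinstance(image, ImageGrid) else 255.0
    err = mse(image, reference)
    ref_arr = _values(reference)
    noise_var = estimate_noise_variance(image, reference=reference)
    mean_signal = float(ref_arr.mean())
    return QualityReport(
        contrast=c,
        entropy_bits=ent,
        mse=err,
        psnr_db=psnr(image, reference, l_max=l_max),
        snr_db=snr(mean_signal, noise_var) if mean_signal > 0 and noise_var >= 0 else None,
        ssim=ssim(image, reference, data_range=l_max),
    )
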