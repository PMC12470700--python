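"""Comparator enhancement methods and the comparison harness.

Two widely used baselines at their conventional settings:

* **CLAHE** — contrast-limited adaptive histogram equalisation, clip
  limit 0.01 on an 8x8 tile grid (delegated to scikit-image);
* **Gaussian unsharp masking** — ``I + amount * (I - G(I))`` with a
  5-tap Gaussian blur and amount 1.5, clipped to the nominal range.

``compare_methods`` runs any subset of {original, cream, bosso, clahe,
unsharp} on one image and tabulates the quality metrics, optionally
against a reference image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.exposure import equalize_adapthist

from .enhance import EnhancementConfig, enhance_image
from .errors import CreamBossoError, InvalidInputError, ParameterError
from .grid import ImageGrid
from .metrics import quality_report


@dataclass(frozen=True)
class BaselineConfig:
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    unsharp_kernel: int = 5
    unsharp_amount: float = 1.5
    unsharp_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0:
            raise ParameterError("clahe_clip must be > 0")
        if min(self.clahe_tiles) < 1:
            raise ParameterError("clahe_tiles must be >= 1")
        if self.unsharp_kernel < 3 or self.unsharp_kernel % 2 == 0:
            raise ParameterError("unsharp_kernel must be an odd integer >= 3")
        if self.unsharp_amount < 0:
            raise ParameterError("unsharp_amount must be >= 0")
        if self.unsharp_sigma <= 0:
            raise ParameterError("unsharp_sigma must be > 0")


def clahe(image: ImageGrid, config: BaselineConfig | None = None) -> ImageGrid:
    """Contrast-limited adaptive histogram equalisation.

    The tile grid divides the image into ``clahe_tiles`` regions; output
    is rescaled back to the image's nominal range.  A constant image has
    no contrast to redistribute and is returned unchanged.
    """
    config = config or BaselineConfig()
    px = image.pixels
    ty, tx = config.clahe_tiles
    if px.shape[0] < ty or px.shape[1] < tx:
        raise InvalidInputError(
            f"image {px.shape} smaller than the CLAHE tile grid {config.clahe_tiles}"
        )
    if px.max() == px.min():
        return image.with_pixels(px.copy(), source="clahe")
    kernel_size = (max(1, px.shape[0] // ty), max(1, px.shape[1] // tx))
    normalised = px / image.nominal_max
    out = equalize_adapthist(normalised, kernel_size=kernel_size,
                             clip_limit=config.clahe_clip)
    return image.with_pixels(out * image.nominal_max, source="clahe")


def gaussian_blur_5tap(values: np.ndarray, sigma: float, kernel: int) -> np.ndarray:
    """Gaussian blur truncated to a ``kernel x kernel`` support."""
    radius = (kernel - 1) // 2
    return gaussian_filter(values, sigma=sigma, truncate=radius / sigma, mode="nearest")


def unsharp_mask(image: ImageGrid, config: BaselineConfig | None = None) -> ImageGrid:
    """Gaussian unsharp masking ``clip(I + amount * (I - G(I)))``."""
    config = config or BaselineConfig()
    px = image.pixels
    blurred = gaussian_blur_5tap(px, config.unsharp_sigma, config.unsharp_kernel)
    out = px + config.unsharp_amount * (px - blurred)
    return image.with_pixels(np.clip(out, 0.0, image.nominal_max), source="unsharp")


METHODS = ("original", "cream", "bosso", "clahe", "unsharp")


def apply_method(image: ImageGrid, method: str,
                 enh_config: EnhancementConfig | None = None,
                 base_config: BaselineConfig | None = None) -> ImageGrid:
    """Dispatch one enhancement method by name."""
    enh_config = enh_config or EnhancementConfig()
    if method == "original":
        return image
    if method in ("cream", "bosso"):
        return enhance_image(image, replace(enh_config, filter_kind=method))
    if method == "clahe":
        return clahe(image, base_config)
    if method == "unsharp":
        return unsharp_mask(image, base_config)
    raise InvalidInputError(f"unknown method {method!r}; choose from {METHODS}")


def compare_methods(image: ImageGrid, methods,
                    reference: ImageGrid | None = None,
                    enh_config: EnhancementConfig | None = None,
                    base_config: BaselineConfig | None = None) -> pd.DataFrame:
    """Quality-metric table, one row per method.

    A method that fails on this image (e.g. undefined contrast) gets NaN
    cells rather than aborting the whole comparison.
    """
    methods = list(methods)
    if not methods:
        raise InvalidInputError("need at least one method to compare")
    rows = []
    for method in methods:
        row: dict[str, object] = {"method": method}
        try:
            out = apply_method(image, method, enh_config, base_config)
            report = quality_report(out, reference=reference)
            row["contrast"] = report.contrast if report.contrast is not None else float("nan")
            row["entropy_bits"] = report.entropy_bits
            if reference is not None:
                row["psnr_db"] = report.psnr_db
                row["snr_db"] = report.snr_db
                row["ssim"] = report.ssim
        except CreamBossoError:
            row.setdefault("contrast", float("nan"))
            row.setdefault("entropy_bits", float("nan"))
            if reference is not None:
                for key in ("psnr_db", "snr_db", "ssim"):
                    row.setdefault(key, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
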