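"""Cream and Bosso filter kernels and their per-pixel parameter estimator.

The two kernels model the point-spread of scattered radiation around a
pixel.  With ``r = sqrt(i**2 + j**2 + d**2)`` the radial (dimensionless)
distance from the window centre:

* the **Cream** kernel is exponential, ``F1(i, j) ∝ exp(-mu * r)``,
  matching the empirical short-range decay of scattered photons;
* the **Bosso** kernel is Gaussian, ``F2(i, j) ∝ exp(-s * r**2)``,
  matching diffuse low-frequency scatter and system blur.

Both are normalised to unit sum over their ``(2h+1) x (2h+1)`` support, so
convolution with either is a convex combination of neighbourhood
intensities.  The shape parameter (attenuation ``mu`` for Cream, spread
``s`` for Bosso) is estimated per pixel by inverting the Beer-Lambert
attenuation law: ``param = -(1/d) * ln(I / I0)``, clamped for numerical
stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ParameterError

DEFAULT_HALF_WIDTH = 3  # 7x7 window
DEFAULT_EPSILON = 1e-6

_KINDS = ("cream", "bosso")


@dataclass(frozen=True)
class ParameterPlan:
    """Inputs of the per-pixel parameter estimator.

    d is the effective propagation distance (dimensionless), i0 the
    reference incident intensity (typically the image maximum), and
    epsilon the floor applied to the intensity ratio before the log so the
    estimate stays finite at zero-intensity pixels.
    """

    d: float
    i0: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and self.d > 0):
            raise ParameterError(f"d must be a positive real, got {self.d}")
        if not (np.isfinite(self.i0) and self.i0 > 0):
            raise ParameterError(f"i0 must be a positive real, got {self.i0}")
        if not (0 < self.epsilon < 1):
            raise ParameterError(f"epsilon must lie in (0, 1), got {self.epsilon}")


@dataclass(frozen=True)
class FilterKernel:
    """A normalised spatial kernel on the square index set {-h..h}^2.

    ``weights[h + i, h + j]`` is the weight at offset ``(i, j)``.
    """

    kind: str
    half_width: int
    d: float
    param: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def size(self) -> int:
        return 2 * self.half_width + 1


def offset_grids(half_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Index offset grids i, j over {-h..h} x {-h..h}."""
    if half_width < 1:
        raise ParameterError(f"half_width must be >= 1, got {half_width}")
    rng = np.arange(-half_width, half_width + 1)
    return np.meshgrid(rng, rng, indexing="ij")


def kernel_cost(kind: str, d: float, half_width: int) -> np.ndarray:
    """The exponent multiplier grid: r for cream, r**2 for bosso.

    The per-pixel kernel is ``exp(-param * cost)`` (normalised), so this
    grid is the only place the two kernel families differ.
    """
    if not (np.isfinite(d) and d > 0):
        raise ParameterError(f"d must be a positive real, got {d}")
    ii, jj = offset_grids(half_width)
    r2 = ii.astype(np.float64) ** 2 + jj.astype(np.float64) ** 2 + d * d
    if kind == "cream":
        return np.sqrt(r2)
    if kind == "bosso":
        return r2
    raise ParameterError(f"unknown kernel kind {kind!r}")


def estimate_local_parameter(intensity, plan: ParameterPlan):
    """Per-pixel attenuation/spread estimate by inverse attenuation.

    Returns ``-(1/d) * ln(clamp(intensity / i0, epsilon, 1))``.  Accepts a
    scalar or an array; the result is non-negative, zero wherever
    ``intensity >= i0`` and bounded above by ``-ln(epsilon)/d``.  The same
    estimator serves both the Cream attenuation ``mu`` and the Bosso
    spread ``s``.
    """
    arr = np.asarray(intensity, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("intensity must be finite")
    ratio = np.clip(arr / plan.i0, plan.epsilon, 1.0)
    out = -np.log(ratio) / plan.d
    if np.isscalar(intensity) or arr.ndim == 0:
        return float(out)
    return out


def _build(kind: str, d: float, param: float, half_width: int) -> FilterKernel:
    if not (np.isfinite(param) and param >= 0):
        raise ParameterError(f"kernel parameter must be >= 0, got {param}")
    cost = kernel_cost(kind, d, half_width)
    w = np.exp(-param * cost)
    w /= w.sum()
    return FilterKernel(kind=kind, half_width=half_width, d=d, param=param, weights=w)


def cream_kernel(d: float, mu: float, half_width: int = DEFAULT_HALF_WIDTH) -> FilterKernel:
    """Exponential scatter kernel ``exp(-mu * sqrt(i^2 + j^2 + d^2))``, unit sum."""
    return _build("cream", d, mu, half_width)


def bosso_kernel(d: float, s: float, half_width: int = DEFAULT_HALF_WIDTH) -> FilterKernel:
    """Gaussian scatter kernel ``exp(-s * (i^2 + j^2 + d^2))``, unit sum.

    The constant factor ``exp(-s * d**2)`` cancels under normalisation, so
    the normalised weights depend on ``d`` only through nothing at all —
    two Bosso kernels with equal ``s`` are identical whatever their ``d``.
    """
    return _build("bosso", d, s, half_width)


def make_kernel(kind: str, d: float, param: float,
                half_width: int = DEFAULT_HALF_WIDTH) -> FilterKernel:
    """Dispatch on kernel kind."""
    return _build(kind, d, param, half_width)
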