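"""Shared fixtures and the independent brute-force reference pipeline."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from creambosso import PhantomSpec, generate
from creambosso.io import bundled_ratings, bundled_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def reference_smooth(pixels: np.ndarray, kind: str, d: float, h: int = 3,
                     epsilon: float = 1e-6) -> np.ndarray:
    """Nested-loop reimplementation of the adaptive smoothing stage.

    Recomputes, pixel by pixel: the inverse-attenuation parameter
    estimate, the kernel over the full window, its normalisation, and the
    convolution sum ``I_s(x, y) = sum_{i,j} I(x-i, y-j) F(i, j)`` on the
    symmetric-reflection padded image.  Deliberately slow and independent
    of the vectorised implementation.
    """
    px = np.asarray(pixels, dtype=np.float64)
    i0 = px.max()
    padded = np.pad(px, h, mode="symmetric")
    out = np.empty_like(px)
    for x in range(px.shape[0]):
        for y in range(px.shape[1]):
            ratio = min(max(px[x, y] / i0, epsilon), 1.0)
            param = -math.log(ratio) / d
            num = 0.0
            den = 0.0
            for i in range(-h, h + 1):
                for j in range(-h, h + 1):
                    r2 = i * i + j * j + d * d
                    cost = math.sqrt(r2) if kind == "cream" else r2
                    w = math.exp(-param * cost)
                    num += w * padded[x - i + h, y - j + h]
                    den += w
            out[x, y] = num / den
    return out


def reference_enhance(pixels: np.ndarray, kind: str, d: float, h: int = 3,
                      epsilon: float = 1e-6) -> np.ndarray:
    """reference_smooth followed by the positive-residual threshold."""
    px = np.asarray(pixels, dtype=np.float64)
    smoothed = reference_smooth(px, kind, d, h, epsilon)
    return np.where(px > smoothed, px - smoothed, 0.0)


@pytest.fixture(scope="session")
def default_phantom():
    """The default knee phantom pair (seed 42, k=0.3, sigma=12, Poisson)."""
    spec = PhantomSpec()
    primary, degraded = generate(spec)
    return spec, primary, degraded


@pytest.fixture(scope="session")
def small_phantom():
    """A 64x64 noise-free knee phantom for fast pipeline tests."""
    spec = PhantomSpec(size=(64, 64), noise="none", scatter_sigma=4.0, seed=7)
    primary, degraded = generate(spec)
    return spec, primary, degraded


@pytest.fixture(scope="session")
def knee_table():
    return bundled_table("knee")


@pytest.fixture(scope="session")
def wrist_table():
    return bundled_table("wrist")


@pytest.fixture(scope="session")
def breast_table():
    return bundled_table("breast")


@pytest.fixture(scope="session")
def expert_records():
    return bundled_ratings()
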