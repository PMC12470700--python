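"""Seeded synthetic radiograph phantoms.

Clinical radiographs are not redistributable, so every stage of the
pipeline is exercised on synthetic phantoms that reproduce the three
degradations the filters are designed against:

1. **Primary image** — Beer-Lambert attenuation of a uniform incident
   beam through a 2-D thickness map built from overlapping ellipses:
   ``I_p = i0 * exp(-T)``, where T is the summed attenuation-thickness
   product of the structures covering each pixel.
2. **Scatter** — an additive low-frequency background, modelled as a
   Gaussian-blurred copy of the primary scaled by the scatter fraction k
   (a crude but standard stand-in for the Compton scatter PSF).
3. **Quantum noise** — Poisson noise on the detected signal, then
   rounding to the nominal bit depth.

Presets sketch the qualitative geometry of the anatomies the method
targets — knee (two long bones and a joint gap), wrist (many small
bones), breast (low-contrast blobs with point microcalcifications) — with
no claim of anatomical fidelity.  The ``flat`` preset (no structures) is
the degenerate control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError, ParameterError
from .grid import ImageGrid

PRESETS = ("knee", "wrist", "breast", "flat")


@dataclass(frozen=True)
class Ellipse:
    """One structure: centre/axes in pixels, attenuation-thickness product t."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]    # (semi-axis rows, semi-axis cols)
    thickness: float             # dimensionless mu*t product
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ParameterError("ellipse axes must be positive")
        if self.thickness < 0:
            raise ParameterError("ellipse thickness must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom realisation (fully deterministic given seed)."""

    size: tuple[int, int] = (256, 256)
    preset: str = "knee"
    structures: tuple[Ellipse, ...] | None = None  # None -> preset layout
    scatter_fraction: float = 0.3
    scatter_sigma: float = 12.0
    noise: str = "poisson"
    seed: int = 42
    i0: float = 255.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ParameterError(f"preset must be one of {PRESETS}")
        if not (0.0 <= self.scatter_fraction <= 1.0):
            raise ParameterError("scatter_fraction must lie in [0, 1]")
        if self.scatter_sigma <= 0:
            raise ParameterError("scatter_sigma must be positive")
        if self.noise not in ("none", "poisson"):
            raise ParameterError("noise must be 'none' or 'poisson'")
        if self.i0 <= 0:
            raise ParameterError("i0 must be positive")
        if min(self.size) < 8:
            raise ParameterError("phantom must be at least 8x8")


def preset_structures(preset: str, size: tuple[int, int]) -> tuple[Ellipse, ...]:
    """Ellipse layout for a named preset, scaled to the grid size."""
    h, w = size
    r, c = h / 256.0, w / 256.0  # layouts are designed on a 256x256 canvas

    def e(cy, cx, ay, ax, t, angle=0.0):
        return Ellipse((cy * r, cx * c), (ay * r, ax * c), t, angle)

    if preset == "flat":
        return ()
    if preset == "knee":
        return (
            e(128, 128, 126, 70, 0.30),          # soft-tissue envelope
            e(60, 124, 58, 26, 1.20),            # femur shaft
            e(196, 132, 56, 24, 1.20),           # tibia shaft
            e(112, 104, 16, 18, 0.50),           # medial condyle
            e(112, 148, 16, 18, 0.50),           # lateral condyle
            e(144, 126, 12, 30, 0.45),           # tibial plateau
            e(104, 70, 18, 9, 0.90),             # patella (offset)
        )
    if preset == "wrist":
        carpals = tuple(
            e(cy, cx, 9, 8, 1.0)
            for cy, cx in ((118, 96), (116, 122), (120, 148), (134, 86),
                           (138, 112), (136, 140), (140, 164), (122, 172))
        )
        metacarpals = tuple(
            e(64, cx, 36, 6, 0.85, angle)
            for cx, angle in ((84, -8.0), (112, -3.0), (140, 3.0), (168, 9.0))
        )
        return (
            e(128, 128, 126, 84, 0.25),          # soft tissue
            e(204, 112, 46, 12, 1.10),           # radius
            e(206, 148, 44, 10, 1.05),           # ulna
        ) + carpals + metacarpals
    if preset == "breast":
        blobs = tuple(
            e(cy, cx, ay, ax, 0.15)
            for cy, cx, ay, ax in ((96, 96, 34, 28), (150, 120, 28, 36),
                                   (110, 160, 24, 20), (170, 80, 20, 24))
        )
        calcs = tuple(
            e(cy, cx, 1.6, 1.6, 2.0)
            for cy, cx in ((88, 132), (142, 96), (160, 150), (104, 76), (126, 140))
        )
        return (e(128, 120, 118, 102, 0.40),) + blobs + calcs
    raise ParameterError(f"unknown preset {preset!r}")


def _thickness_map(structures, size: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : size[0], 0 : size[1]].astype(np.float64)
    t = np.zeros(size, dtype=np.float64)
    for s in structures:
        cy, cx = s.center
        ay, ax = s.axes
        th = np.deg2rad(s.angle_deg)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        inside = (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
        t[inside] += s.thickness
    return t


def generate_primary(spec: PhantomSpec) -> ImageGrid:
    """Scatter- and noise-free Beer-Lambert projection ``i0 * exp(-T)``."""
    structures = spec.structures
    if structures is None:
        structures = preset_structures(spec.preset, spec.size)
    if not structures and spec.preset != "flat":
        raise InvalidInputError(
            f"preset {spec.preset!r} requires at least one structure"
        )
    t = _thickness_map(structures, spec.size)
    primary = spec.i0 * np.exp(-t)
    return ImageGrid(primary, bit_depth=spec.bit_depth, source=f"phantom:{spec.preset}:primary")


def degrade(primary: ImageGrid, spec: PhantomSpec) -> ImageGrid:
    """Add scatter background and quantum noise to a primary image.

    ``I = clip(I_p + k * (I_p (*) Gaussian(sigma)))`` with the blur kernel
    normalised to unit sum, followed by seeded Poisson noise on the
    detected signal and rounding to the nominal bit depth.  With k = 0 and
    noise off, the primary passes through untouched.
    """
    px = primary.pixels
    out = px.copy()
    if spec.scatter_fraction > 0:
        scatter = gaussian_filter(px, sigma=spec.scatter_sigma, mode="nearest")
        out = px + spec.scatter_fraction * scatter
    out = np.clip(out, 0.0, primary.nominal_max)
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        out = rng.poisson(out).astype(np.float64)
        out = np.clip(np.rint(out), 0.0, primary.nominal_max)
    return primary.with_pixels(out, source=f"phantom:{spec.preset}:degraded")


def generate(spec: PhantomSpec) -> tuple[ImageGrid, ImageGrid]:
    """(primary, degraded) pair for one spec."""
    primary = generate_primary(spec)
    return primary, degrade(primary, spec)
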