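"""d-parameter sweeps and curve analytics.

A sweep enhances one image with both filters over a grid of ``d`` values
and records span-to-mean contrast and Shannon entropy of each residual.
The resulting table (a DataFrame with columns ``d, contrast_cream,
contrast_bosso, entropy_cream, entropy_bosso``) is the object the curve
analytics operate on: crossover detection (where the Cream curve finally
overtakes the Bosso curve), elbow detection (largest curvature of a
contrast curve), and optimal-d selection (maximum contrast subject to
entropy stability).

The analytics are pure functions of the table, so they apply equally to
tables computed here and to externally measured sweep tables loaded from
CSV.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .enhance import EnhancementConfig, enhance_image
from .errors import InfeasibleError, InvalidInputError, UndefinedMetricError
from .grid import ImageGrid
from .metrics import contrast, shannon_entropy

SWEEP_COLUMNS = (
    "d",
    "contrast_cream",
    "contrast_bosso",
    "entropy_cream",
    "entropy_bosso",
)

_FILTERS = ("cream", "bosso")


def _check_filter(filter_kind: str) -> None:
    if filter_kind not in _FILTERS:
        raise InvalidInputError(f"filter_kind must be one of {_FILTERS}")


def run_sweep(image: ImageGrid, d_grid, config: EnhancementConfig | None = None) -> pd.DataFrame:
    """Enhance ``image`` at every d in ``d_grid`` with both filters.

    ``d_grid`` must be non-empty and strictly increasing.  An undefined
    contrast (all-zero residual) is recorded as NaN, not silently as 0.
    """
    d_grid = [float(d) for d in d_grid]
    if not d_grid:
        raise InvalidInputError("d_grid is empty")
    if any(d <= 0 for d in d_grid):
        raise InvalidInputError("d values must be positive")
    if any(b <= a for a, b in zip(d_grid, d_grid[1:])):
        raise InvalidInputError("d_grid must be strictly increasing")
    if config is None:
        config = EnhancementConfig()

    rows = []
    for d in d_grid:
        row: dict[str, float] = {"d": d}
        for kind in _FILTERS:
            enhanced = enhance_image(image, replace(config, filter_kind=kind, d=d))
            try:
                row[f"contrast_{kind}"] = contrast(enhanced)
            except UndefinedMetricError:
                row[f"contrast_{kind}"] = float("nan")
            row[f"entropy_{kind}"] = shannon_entropy(enhanced)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def _columns(table: pd.DataFrame, metric: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = [c for c in SWEEP_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"sweep table missing columns {missing}")
    d = table["d"].to_numpy(dtype=float)
    return (
        d,
        table[f"{metric}_cream"].to_numpy(dtype=float),
        table[f"{metric}_bosso"].to_numpy(dtype=float),
    )


def find_crossover(table: pd.DataFrame, metric: str = "contrast") -> float | None:
    """The d from which the Cream curve finally dominates the Bosso curve.

    Returns the smallest grid d such that Cream strictly exceeds Bosso at
    that point *and every later point* (the final sign change: transient
    early crossings that are later undone do not count), or ``None`` when
    Cream does not dominate through the end of the grid.
    """
    if metric not in ("contrast", "entropy"):
        raise InvalidInputError(f"metric must be 'contrast' or 'entropy', got {metric!r}")
    d, cream, bosso = _columns(table, metric)
    if len(d) < 2:
        raise InvalidInputError("need at least two sweep rows")
    dominates = cream > bosso
    # scan from the end for the longest all-True suffix
    if not dominates[-1]:
        return None
    k = len(d) - 1
    while k > 0 and dominates[k - 1]:
        k -= 1
    return float(d[k])


def select_optimal_d(table: pd.DataFrame, filter_kind: str, entropy_tol: float = 0.02) -> float:
    """Maximum-contrast d subject to entropy stability.

    A grid point is admissible when its relative entropy step from the
    previous point, ``|H_k - H_{k-1}| / H_{k-1}``, is at most
    ``entropy_tol``; among admissible points the one with the largest
    contrast wins, ties broken toward smaller d (less aggressive
    filtering).  Raises :class:`InfeasibleError` when no point qualifies.
    """
    _check_filter(filter_kind)
    d, *_ = _columns(table, "contrast")
    if len(d) < 2:
        raise InvalidInputError("need at least two sweep rows")
    c = table[f"contrast_{filter_kind}"].to_numpy(dtype=float)
    h = table[f"entropy_{filter_kind}"].to_numpy(dtype=float)
    prev = h[:-1]
    step = np.abs(np.diff(h))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(prev > 0, step / prev, np.where(step == 0, 0.0, np.inf))
    admissible = np.flatnonzero(rel <= entropy_tol) + 1
    if admissible.size == 0:
        raise InfeasibleError(
            f"no grid point satisfies the {entropy_tol:.0%} entropy-stability constraint"
        )
    best = admissible[np.argmax(c[admissible])]  # argmax takes the first max -> smaller d
    return float(d[best])


def detect_elbow(table: pd.DataFrame, filter_kind: str) -> float:
    """The d of largest curvature of the contrast curve.

    Curvature is measured by the absolute discrete second difference
    ``|c[k+1] - 2 c[k] + c[k-1]|`` at the interior grid points; ties break
    toward smaller d.  This is a generic knee detector for sweep curves —
    a clinically chosen operating point typically also weighs reader
    preference, which no curve statistic captures.
    """
    _check_filter(filter_kind)
    d, *_ = _columns(table, "contrast")
    if len(d) < 3:
        raise InvalidInputError("need at least three sweep rows for an elbow")
    c = table[f"contrast_{filter_kind}"].to_numpy(dtype=float)
    second = np.abs(c[2:] - 2.0 * c[1:-1] + c[:-2])
    return float(d[1 + int(np.argmax(second))])
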