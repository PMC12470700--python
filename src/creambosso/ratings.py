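"""Expert-rating analytics.

Readers score enhanced images on a 1-5 Likert scale (1 unsatisfactory,
5 excellent) per filter and per d value.  This module aggregates such
scores: a d-weighted mean rating per filter, Cohen's kappa for
inter-rater agreement, and per-filter summaries (histograms, per-d means,
dominance fractions above a d threshold).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError

LIKERT_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class RatingRecord:
    """One scored image/d combination; a missing score is None."""

    image_id: str
    d: float
    cream: int | None = None
    bosso: int | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and self.d > 0):
            raise InvalidInputError(f"d must be positive, got {self.d}")
        for name, value in (("cream", self.cream), ("bosso", self.bosso)):
            if value is not None and value not in LIKERT_LEVELS:
                raise InvalidInputError(
                    f"{name} rating must be in {LIKERT_LEVELS} or missing, got {value}"
                )

    def rating(self, filter_kind: str) -> int | None:
        if filter_kind == "cream":
            return self.cream
        if filter_kind == "bosso":
            return self.bosso
        raise InvalidInputError(f"unknown filter {filter_kind!r}")


def weighted_average_d(records, filter_kind: str, mode: str = "d-weighted") -> float:
    """Aggregate ratings c_i over d values d_i.

    ``mode='d-weighted'`` computes ``sum(c_i * d_i) / sum(d_i)`` — note
    this is a d-weighted mean *rating* (constant ratings c return c), on
    the 1-5 scale, despite its name.  ``mode='rating-weighted'`` computes
    the alternative ``sum(c_i * d_i) / sum(c_i)``, a rating-weighted mean
    d value.  Records missing the requested filter's score are skipped.
    """
    pairs = [(r.d, r.rating(filter_kind)) for r in records]
    pairs = [(d, c) for d, c in pairs if c is not None]
    if not pairs:
        raise InvalidInputError(f"no records carry a {filter_kind} rating")
    d = np.array([p[0] for p in pairs], dtype=float)
    c = np.array([p[1] for p in pairs], dtype=float)
    if mode == "d-weighted":
        return float((c * d).sum() / d.sum())
    if mode == "rating-weighted":
        return float((c * d).sum() / c.sum())
    raise InvalidInputError(f"mode must be 'd-weighted' or 'rating-weighted', got {mode!r}")


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_o`` is the observed fraction of agreeing pairs; ``p_e`` the
    agreement expected from the two raters' marginal category frequencies.
    Raises :class:`UndefinedMetricError` when ``p_e = 1`` (both raters
    constant and identical), where kappa is undefined.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b) or not a:
        raise InvalidInputError("rating vectors must be equal-length and non-empty")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    count_a, count_b = Counter(a), Counter(b)
    categories = set(count_a) | set(count_b)
    p_e = sum(count_a[c] * count_b[c] for c in categories) / (n * n)
    if p_e == 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class RatingSummary:
    """Aggregates of a rating table (see :func:`rating_summary`)."""

    histogram_cream: dict[int, int]
    histogram_bosso: dict[int, int]
    mean_by_d_cream: dict[float, float]
    mean_by_d_bosso: dict[float, float]
    d_threshold: float
    n_above_threshold: int
    cream_dominance: float
    bosso_dominance: float
    tie_fraction: float


def _histogram(values) -> dict[int, int]:
    counts = Counter(v for v in values if v is not None)
    return {level: counts.get(level, 0) for level in LIKERT_LEVELS}


def _mean_by_d(records, filter_kind: str) -> dict[float, float]:
    by_d: dict[float, list[int]] = {}
    for r in records:
        c = r.rating(filter_kind)
        if c is not None:
            by_d.setdefault(r.d, []).append(c)
    return {d: float(np.mean(v)) for d, v in sorted(by_d.items())}


def rating_summary(records, d_threshold: float = 2.9) -> RatingSummary:
    """Histograms, per-d means, and high-d dominance fractions.

    Dominance: among records with ``d > d_threshold`` and both scores
    present, the fraction where one filter strictly out-rates the other;
    ties are reported separately.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("no rating records")
    above = [r for r in records if r.d > d_threshold
             and r.cream is not None and r.bosso is not None]
    n = len(above)
    cream_wins = sum(r.cream > r.bosso for r in above)
    bosso_wins = sum(r.bosso > r.cream for r in above)
    ties = n - cream_wins - bosso_wins
    return RatingSummary(
        histogram_cream=_histogram(r.cream for r in records),
        histogram_bosso=_histogram(r.bosso for r in records),
        mean_by_d_cream=_mean_by_d(records, "cream"),
        mean_by_d_bosso=_mean_by_d(records, "bosso"),
        d_threshold=d_threshold,
        n_above_threshold=n,
        cream_dominance=cream_wins / n if n else 0.0,
        bosso_dominance=bosso_wins / n if n else 0.0,
        tie_fraction=ties / n if n else 0.0,
    )
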