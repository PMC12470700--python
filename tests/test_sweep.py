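"""Sweep execution and curve analytics (crossover, optimal d, elbow)."""

import numpy as np
import pandas as pd
import pytest

from creambosso import (
    EnhancementConfig,
    contrast,
    detect_elbow,
    enhance_image,
    find_crossover,
    run_sweep,
    select_optimal_d,
    shannon_entropy,
)
from creambosso.errors import InfeasibleError, InvalidInputError


def make_table(d, cream_c, bosso_c, cream_h=None, bosso_h=None):
    n = len(d)
    return pd.DataFrame(
        {
            "d": d,
            "contrast_cream": cream_c,
            "contrast_bosso": bosso_c,
            "entropy_cream": cream_h if cream_h is not None else [0.4] * n,
            "entropy_bosso": bosso_h if bosso_h is not None else [0.4] * n,
        }
    )


class TestRunSweep:
    def test_single_value_grid_gives_one_row(self, small_phantom):
        _, _, degraded = small_phantom
        table = run_sweep(degraded, [1.4])
        assert len(table) == 1 and table.loc[0, "d"] == 1.4

    def test_cells_match_standalone_computation(self, small_phantom):
        """Each sweep cell reproduces the standalone enhance+metric call."""
        _, _, degraded = small_phantom
        table = run_sweep(degraded, [0.6, 1.4])
        for _, row in table.iterrows():
            for kind in ("cream", "bosso"):
                enhanced = enhance_image(
                    degraded, EnhancementConfig(filter_kind=kind, d=row["d"])
                )
                assert row[f"contrast_{kind}"] == contrast(enhanced)
                assert row[f"entropy_{kind}"] == shannon_entropy(enhanced)

    def test_full_default_grid_is_finite(self, small_phantom):
        _, _, degraded = small_phantom
        grid = [round(0.2 * k, 10) for k in range(1, 16)]
        table = run_sweep(degraded, grid)
        assert len(table) == 15
        assert np.isfinite(table.drop(columns="d").to_numpy()).all()

    def test_all_zero_residual_flagged_not_zero(self):
        from creambosso import ImageGrid

        img = ImageGrid(np.full((16, 16), 120.0))  # constant -> zero residual
        table = run_sweep(img, [1.0])
        assert np.isnan(table.loc[0, "contrast_cream"])
        assert np.isnan(table.loc[0, "contrast_bosso"])

    @pytest.mark.parametrize("grid", [[], [1.0, 1.0], [2.0, 1.0], [-1.0, 1.0]])
    def test_bad_grids_rejected(self, grid, small_phantom):
        _, _, degraded = small_phantom
        with pytest.raises(InvalidInputError):
            run_sweep(degraded, grid)


class TestCrossover:
    def test_cream_dominant_everywhere_returns_first_d(self):
        t = make_table([1, 2, 3], [2.0, 2.1, 2.2], [1.0, 1.1, 1.2])
        assert find_crossover(t) == 1.0

    def test_bosso_dominant_everywhere_returns_none(self):
        t = make_table([1, 2, 3], [1.0, 1.1, 1.2], [2.0, 2.1, 2.2])
        assert find_crossover(t) is None

    def test_transient_crossing_is_ignored(self):
        """An early crossing later undone does not count; only the final
        dominance onset does."""
        t = make_table(
            [1, 2, 3, 4, 5],
            [2.0, 3.0, 1.0, 3.0, 3.0],
            [2.5, 2.5, 2.5, 2.5, 2.5],
        )
        assert find_crossover(t) == 4.0

    def test_knee_fixture_crossover(self, knee_table):
        assert find_crossover(knee_table, "contrast") == pytest.approx(2.6)

    def test_wrist_fixture_crossover(self, wrist_table):
        # cream overtakes bosso from d = 1.8 onward in the wrist series
        assert find_crossover(wrist_table, "contrast") == pytest.approx(1.8)

    def test_breast_fixture_never_crosses(self, breast_table):
        assert find_crossover(breast_table, "contrast") is None

    def test_requires_two_rows(self, knee_table):
        with pytest.raises(InvalidInputError):
            find_crossover(knee_table.iloc[:1])


class TestOptimalD:
    def test_monotone_contrast_stable_entropy_gives_last_d(self):
        t = make_table([1, 2, 3], [1.0, 2.0, 3.0], [1.0] * 3,
                       cream_h=[0.400, 0.401, 0.402])
        assert select_optimal_d(t, "cream") == 3.0

    def test_knee_fixture_cream_optimum(self, knee_table):
        assert select_optimal_d(knee_table, "cream", entropy_tol=0.02) == pytest.approx(3.0)

    def test_zero_tolerance_with_entropy_drift_is_infeasible(self):
        t = make_table([1, 2, 3], [1.0, 2.0, 3.0], [1.0] * 3,
                       cream_h=[0.40, 0.41, 0.42])
        with pytest.raises(InfeasibleError):
            select_optimal_d(t, "cream", entropy_tol=0.0)

    def test_tie_breaks_toward_smaller_d(self):
        t = make_table([1, 2, 3], [1.0, 5.0, 5.0], [1.0] * 3)
        assert select_optimal_d(t, "cream") == 2.0

    def test_unstable_points_excluded(self):
        # the largest contrast sits behind an entropy jump > tol
        t = make_table([1, 2, 3], [1.0, 2.0, 9.0], [1.0] * 3,
                       cream_h=[0.40, 0.401, 0.48])
        assert select_optimal_d(t, "cream") == 2.0


class TestElbow:
    def test_linear_curve_ties_to_smallest_interior_d(self):
        t = make_table([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0], [0.0] * 4)
        assert detect_elbow(t, "cream") == 2.0

    def test_single_slope_break_is_found(self):
        d = [1, 2, 3, 4, 5]
        c = [1.0, 2.0, 3.0, 3.1, 3.2]  # slope breaks at d = 3
        t = make_table(d, c, [0.0] * 5)
        assert detect_elbow(t, "cream") == 3.0

    def test_knee_fixture_cream_elbow(self, knee_table):
        """Largest |second difference| of the measured cream contrast
        column sits at d = 0.4 (verified by direct differencing)."""
        c = knee_table["contrast_cream"].to_numpy()
        second = np.abs(np.diff(c, 2))
        d_oracle = knee_table["d"].to_numpy()[1 + int(np.argmax(second))]
        assert detect_elbow(knee_table, "cream") == pytest.approx(d_oracle)
        assert detect_elbow(knee_table, "cream") == pytest.approx(0.4)

    def test_requires_three_rows(self, knee_table):
        with pytest.raises(InvalidInputError):
            detect_elbow(knee_table.iloc[:2], "cream")
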