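"""Deposition grids, d_max ratio scans, and daily deposition series."""

import numpy as np
import pandas as pd
import pytest

from carcassdrift.catchment import (
    daily_deposition,
    deposition_grid,
    dmax_ratio_scan,
    ratio_crossing,
)
from carcassdrift.drift_sim import DriftConfig, Island, simulate_releases
from carcassdrift.float_model import FloatParams, calibrate, float_prob
from shapely.geometry import Polygon

P7 = calibrate(7)
#: nearly-degenerate float function: p(f) ~ 1 for small f
P_ONE = FloatParams(eta1=1.0, eta2=0.1, eta3=300.0)


def f_for_p(p: float, params: FloatParams = P7) -> float:
    """Float duration at which the float function equals p (oracle inverse)."""
    return params.eta3 - np.log(p / (params.eta1 - p)) / params.eta2


def make_particles(rows):
    """Particle table from (release_day, x0, y0, d0, fate, island, half,
    float_hours, beach_day) tuples."""
    cols = ["release_day", "x0", "y0", "d0", "fate", "island", "half",
            "float_hours", "beach_day"]
    df = pd.DataFrame(rows, columns=cols)
    df["x_land"] = np.nan
    df["y_land"] = np.nan
    return df


class TestDepositionGrid:
    def test_two_particles_one_cell(self):
        f08, f05 = f_for_p(0.8), f_for_p(0.5)
        parts = make_particles([
            (0, 12.0, 12.0, 17.0, "beached", "A", "north", f08, 4),
            (0, 13.0, 13.0, 18.4, "beached", "A", "north", f05, 4),
            (0, 80.0, 80.0, 113.0, "at_sea", None, None, 336.0, -1),
        ])
        grid = deposition_grid(parts, P7, window=(3, 6))
        assert grid.total("A") == pytest.approx(1.3, abs=1e-9)
        # both starts fall in the same 5-km cell [10, 15) x [10, 15)
        df = grid.to_dataframe()
        assert len(df) == 1
        assert df.iloc[0]["weight"] == pytest.approx(1.3, abs=1e-9)

    def test_all_at_sea_gives_zero_grid(self):
        parts = make_particles(
            [(0, 5.0, 5.0, 7.0, "at_sea", None, None, 336.0, -1)] * 3
        )
        grid = deposition_grid(parts, P7, window=(3, 6))
        assert grid.total("A") == 0.0
        assert grid.to_dataframe().empty

    def test_requires_lead_in_releases(self):
        parts = make_particles(
            [(5, 5.0, 5.0, 7.0, "at_sea", None, None, 336.0, -1)]
        )
        with pytest.raises(ValueError, match="3 days"):
            deposition_grid(parts, P7, window=(6, 8))

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            deposition_grid(make_particles([]), P7, window=(3, 6))

    def test_northerly_wind_confines_origins_north(self, constant_wind, island):
        g = constant_wind(0.0, -8.0)  # from the north
        parts = simulate_releases(
            g, [island], [0, 1, 2, 3], DriftConfig(n_particles=300, seed=4),
            d_max=40.0,
        )
        grid = deposition_grid(parts, P7, window=(3, 5))
        df = grid.to_dataframe()
        assert len(df) > 0
        assert (df["cell_y_km"] > 0).all()


class TestDmaxRatioScan:
    def test_wind_away_from_b_gives_zero_ratio(self, constant_wind):
        # island B sits 80 km south of A; a steady southerly wind carries
        # every particle released within 50 km of A northward, away from B
        a = Island("A", Polygon([(-5, -5), (5, -5), (5, 5), (-5, 5)]))
        b = Island("B", Polygon([(-5, -85), (5, -85), (5, -75), (-5, -75)]))
        g = constant_wind(0.0, 10.0)
        parts = simulate_releases(
            g, [a, b], [0, 1, 2, 3], DriftConfig(n_particles=400, seed=5),
            d_max=50.0, center_island=a,
        )
        scan = dmax_ratio_scan(parts, P7, [10, 20, 40, 50], (0, 10), "A", "B")
        defined = scan[scan["defined"]]
        assert len(defined) > 0
        assert (defined["ratio"] == 0.0).all()

    def test_symmetric_weights_give_unit_ratio(self):
        f05 = f_for_p(0.5)
        parts = make_particles([
            (0, 0.0, 10.0, 10.0, "beached", "A", "north", f05, 1),
            (0, 0.0, -10.0, 10.0, "beached", "B", "north", f05, 1),
        ])
        scan = dmax_ratio_scan(parts, P7, [15, 20], (0, 5), "A", "B")
        np.testing.assert_allclose(scan["ratio"], 1.0)

    def test_b_exposure_monotone_in_dmax(self, constant_wind):
        # nested start subsets: windowed weight on the far island cannot
        # decrease as d_max grows; B (south of A, wind from the south) is
        # only reachable from starts beyond its near shore, d0 > 75 km
        a = Island("A", Polygon([(-5, -5), (5, -5), (5, 5), (-5, 5)]))
        b = Island("B", Polygon([(-5, -85), (5, -85), (5, -75), (-5, -75)]))
        g = constant_wind(0.0, 10.0)
        parts = simulate_releases(
            g, [a, b], [0, 1, 2], DriftConfig(n_particles=800, seed=6),
            d_max=100.0, center_island=a,
        )
        scan = dmax_ratio_scan(
            parts, P7, [10, 30, 50, 70, 85, 100], (0, 14), "A", "B"
        )
        assert (np.diff(scan["weight_b"].to_numpy()) >= -1e-12).all()
        assert scan.loc[scan["d_max"] <= 70, "weight_b"].max() == 0.0
        if (scan["weight_b"] > 0).any():
            assert ratio_crossing(scan, 1e-9) > 70.0

    def test_no_particles_within_smallest_dmax_is_error(self):
        parts = make_particles(
            [(0, 50.0, 0.0, 50.0, "at_sea", None, None, 336.0, -1)]
        )
        with pytest.raises(ValueError):
            dmax_ratio_scan(parts, P7, [2, 5], (0, 5), "A", "B")


class TestDailyDeposition:
    def test_single_cohort_single_day(self):
        parts = make_particles([
            (3, 0.0, 8.0, 8.0, "beached", "SPI", "north", 30.0, 4),
            (3, 0.0, 9.0, 9.0, "beached", "SPI", "north", 28.0, 4),
        ])
        series = daily_deposition(parts, P_ONE, d_max=10.0, split_y=0.0)
        p = series.table
        assert set(zip(p["release_day"], p["dep_day"])) == {(3, 4)}
        assert p["P"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_no_beachings_gives_empty_series(self):
        parts = make_particles(
            [(0, 0.0, 8.0, 8.0, "at_sea", None, None, 336.0, -1)]
        )
        series = daily_deposition(parts, P7, d_max=10.0)
        assert series.table.empty

    def test_normalised_by_released_not_beached(self):
        # 1 of 2 north-half releases beaches with p ~ 1: P = 1/2
        parts = make_particles([
            (0, 0.0, 8.0, 8.0, "beached", "SPI", "north", 20.0, 0),
            (0, 0.0, 9.0, 9.0, "at_sea", None, None, 336.0, -1),
        ])
        series = daily_deposition(parts, P_ONE, d_max=10.0, split_y=0.0)
        assert series.table["P"].iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_onshore_wind_beaches_within_three_days(self, constant_wind, island):
        # strong steady onshore drift: >= 70% of total deposition by day j+3
        g = constant_wind(0.0, -10.0)
        parts = simulate_releases(
            g, [island], [0], DriftConfig(n_particles=400, seed=8), d_max=30.0
        )
        series = daily_deposition(parts, P7, d_max=30.0, split_y=island.centroid[1])
        tot = series.table.groupby("dep_day")["P"].sum()
        assert tot.sum() > 0
        assert tot[tot.index <= 3].sum() / tot.sum() >= 0.70

    def test_normalisation_bound(self, constant_wind, island):
        # sum_i P_j(i) over all halves <= 1 for every release
        g = constant_wind(3.0, -9.0)
        parts = simulate_releases(
            g, [island], [0, 1], DriftConfig(n_particles=300, seed=9), d_max=25.0
        )
        series = daily_deposition(parts, P7, d_max=25.0, split_y=0.0)
        per_release = series.table.groupby(["release_day", "half"])["P"].sum()
        # per-half normalisation: each half's series alone is a probability
        assert (per_release <= 1.0 + 1e-12).all()

    def test_dmax_below_sampled_range_is_error(self):
        parts = make_particles(
            [(0, 0.0, 30.0, 30.0, "at_sea", None, None, 336.0, -1)]
        )
        with pytest.raises(ValueError):
            daily_deposition(parts, P7, d_max=10.0)

    def test_nesting_of_dmax_subsets(self, constant_wind, island):
        g = constant_wind(0.0, -10.0)
        parts = simulate_releases(
            g, [island], [0], DriftConfig(n_particles=300, seed=10), d_max=40.0
        )
        s_small = daily_deposition(parts, P7, d_max=15.0, split_y=0.0)
        s_large = daily_deposition(parts, P7, d_max=40.0, split_y=0.0)
        n_small = sum(v for (isl, h), v in s_small.n_released.items() if h == "north")
        n_large = sum(v for (isl, h), v in s_large.n_released.items() if h == "north")
        assert n_small <= n_large
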