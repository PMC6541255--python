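"""Catchment-area analysis: from trajectories to deposition summaries.

Given an ensemble of drift trajectories and a float function, this module
computes

* proportional-deposition grids — beaching weight p(f) summed into 5x5 km
  cells indexed by each particle's *start* location, mapping where beached
  carcasses plausibly originated;
* the between-island deposition-ratio scan over the assumed maximum
  offshore distance d_max, used to bound the at-sea distribution (carcasses
  on one island but none on its neighbour argue for small d_max);
* the daily proportional deposition series P_j(i): the probability that a
  carcass at sea on release day j beaches on day i, the quantity the
  mortality estimator inverts.

P_j(i) is normalised by the number of *released* particles (not beached
ones), so it is a per-carcass beaching probability.  For half-island
series the denominator is the released particles starting in that half's
half-plane: each half's series then refers to mortality occurring in that
half's waters, and the mortality estimator's sum over halves totals a
single uniform at-sea population without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drift_sim import Island
from .float_model import FloatParams, float_prob

__all__ = [
    "DepositionGrid",
    "DepositionSeries",
    "deposition_grid",
    "dmax_ratio_scan",
    "daily_deposition",
]


@dataclass
class DepositionGrid:
    """Beaching weight per start-location cell, per destination island."""

    cell_km: float
    extent_km: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    weights: dict[str, np.ndarray]  # island -> (ny, nx) summed p(f)
    window: tuple[int, int]

    def total(self, island: str) -> float:
        w = self.weights.get(island)
        return 0.0 if w is None else float(w.sum())

    def to_dataframe(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for isl, w in self.weights.items():
            yy, xx = np.nonzero(w)
            for iy, ix in zip(yy, xx):
                rows.append((xc[ix], yc[iy], isl, w[iy, ix]))
        return pd.DataFrame(rows, columns=["cell_x_km", "cell_y_km", "island", "weight"])


@dataclass
class DepositionSeries:
    """Daily proportional deposition P_j(i) in long form.

    ``table`` columns: release_day (j), dep_day (i), island, half (may be
    None for whole-island series), P.  ``n_released`` maps each series key
    (island, half) to its normalising released-particle count.
    """

    table: pd.DataFrame
    d_max: float
    n_released: dict[tuple[str, str | None], int] = field(default_factory=dict)

    def daily_totals(self, island: str, half: str | None = None) -> pd.Series:
        """Sum over releases: expected deposition per day, sum_j P_j(i)."""
        sel = self.table[self.table["island"] == island]
        sel = sel[sel["half"].isna()] if half is None else sel[sel["half"] == half]
        return sel.groupby("dep_day")["P"].sum()

    def release_total(self, island: str, half: str | None = None) -> pd.Series:
        """Per release day: total beaching probability sum_i P_j(i)."""
        sel = self.table[self.table["island"] == island]
        sel = sel[sel["half"].isna()] if half is None else sel[sel["half"] == half]
        return sel.groupby("release_day")["P"].sum()


def _weights(particles: pd.DataFrame, params: FloatParams) -> np.ndarray:
    w = np.zeros(len(particles))
    beached = (particles["fate"] == "beached").to_numpy()
    if beached.any():
        w[beached] = float_prob(
            particles.loc[beached, "float_hours"].to_numpy(), params
        )
    return w


def deposition_grid(
    particles: pd.DataFrame,
    params: FloatParams,
    window: tuple[int, int],
    cell_km: float = 5.0,
    extent_km: float = 100.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> DepositionGrid:
    """Sum beaching weights into start-location cells for one window.

    ``window`` is a closed (first, last) deposition-day interval; the
    trajectory set must include releases from at least 3 days before the
    window opens, since carcasses beaching early in the window may have
    been drifting for days.
    """
    if len(particles) == 0:
        raise ValueError("empty trajectory set")
    lo, hi = int(window[0]), int(window[1])
    if particles["release_day"].min() > lo - 3:
        raise ValueError(
            "trajectories must include releases from 3 days before the window"
        )
    half_n = int(np.ceil(extent_km / cell_km))
    edges = np.arange(-half_n, half_n + 1) * cell_km
    x_edges = center[0] + edges
    y_edges = center[1] + edges

    w = _weights(particles, params)
    in_win = (
        (particles["fate"] == "beached").to_numpy()
        & (particles["beach_day"].to_numpy() >= lo)
        & (particles["beach_day"].to_numpy() <= hi)
    )
    grids: dict[str, np.ndarray] = {}
    for isl in particles.loc[in_win, "island"].dropna().unique():
        m = in_win & (particles["island"] == isl).to_numpy()
        h, _, _ = np.histogram2d(
            particles.loc[m, "y0"], particles.loc[m, "x0"],
            bins=[y_edges, x_edges], weights=w[m],
        )
        grids[str(isl)] = h
    return DepositionGrid(cell_km, extent_km, x_edges, y_edges, grids, (lo, hi))


def dmax_ratio_scan(
    particles: pd.DataFrame,
    params: FloatParams,
    dmax_list,
    window: tuple[int, int],
    island_a: str,
    island_b: str,
) -> pd.DataFrame:
    """Windowed deposition on island B relative to island A versus d_max.

    For each d_max only particles with start distance d0 <= d_max
    contribute (nested subsets).  The ratio is B/A; it is 0 when A
    receives weight and B none, and NaN (flagged ``defined=False``) when
    both receive none.
    """
    dmax_arr = np.asarray(sorted(dmax_list), float)
    if len(particles) == 0 or (particles["d0"] <= dmax_arr[0]).sum() == 0:
        raise ValueError(f"no particle with d0 <= {dmax_arr[0]} km")
    w = _weights(particles, params)
    lo, hi = int(window[0]), int(window[1])
    in_win = (
        (particles["fate"] == "beached").to_numpy()
        & (particles["beach_day"].to_numpy() >= lo)
        & (particles["beach_day"].to_numpy() <= hi)
    )
    d0 = particles["d0"].to_numpy()
    on_a = in_win & (particles["island"] == island_a).to_numpy()
    on_b = in_win & (particles["island"] == island_b).to_numpy()
    rows = []
    for dm in dmax_arr:
        wa = float(w[on_a & (d0 <= dm)].sum())
        wb = float(w[on_b & (d0 <= dm)].sum())
        if wa > 0:
            ratio, defined = wb / wa, True
        elif wb > 0:
            ratio, defined = np.inf, True
        else:
            ratio, defined = np.nan, False
        rows.append((dm, wa, wb, ratio, defined))
    return pd.DataFrame(
        rows, columns=["d_max", "weight_a", "weight_b", "ratio", "defined"]
    )


def ratio_crossing(scan: pd.DataFrame, threshold: float) -> float:
    """Smallest d_max at which the B/A deposition ratio reaches a threshold.

    Linear interpolation between scan points; NaN if never reached.
    """
    s = scan[scan["defined"]].sort_values("d_max")
    r = s["ratio"].to_numpy()
    d = s["d_max"].to_numpy()
    above = np.nonzero(r >= threshold)[0]
    if above.size == 0:
        return float("nan")
    k = above[0]
    if k == 0 or r[k] == r[k - 1]:
        return float(d[k])
    t = (threshold - r[k - 1]) / (r[k] - r[k - 1])
    return float(d[k - 1] + t * (d[k] - d[k - 1]))


def daily_deposition(
    particles: pd.DataFrame,
    params: FloatParams,
    d_max: float,
    by_half: bool = True,
    split_y: float | Island = 0.0,
) -> DepositionSeries:
    """Proportional daily deposition P_j(i) for starts within d_max.

    ``split_y`` (a y-coordinate, or an Island whose centroid supplies it)
    separates the northern from the southern half-plane used for the
    per-half normalising denominators when ``by_half``.
    """
    if len(particles) == 0:
        raise ValueError("empty trajectory set")
    if particles["d0"].min() > d_max:
        raise ValueError(f"d_max={d_max} km below all sampled start distances")
    sy = split_y.centroid[1] if isinstance(split_y, Island) else float(split_y)

    sub = particles[particles["d0"] <= d_max].copy()
    sub["w"] = _weights(sub, params)
    rows = []
    n_released: dict[tuple[str, str | None], int] = {}
    # denominators are per release day: each cohort is its own release
    if by_half:
        sub["start_half"] = np.where(sub["y0"].to_numpy() >= sy, "north", "south")
        for j, day in sub.groupby("release_day"):
            denom = day.groupby("start_half").size().to_dict()
            beached = day[day["fate"] == "beached"]
            for (isl, half, i), grp in beached.groupby(
                ["island", "half", "beach_day"]
            ):
                n = int(denom.get(str(half), 0))
                if n == 0:
                    continue
                rows.append((int(j), int(i), str(isl), str(half),
                             float(grp["w"].sum()) / n))
            for isl in particles["island"].dropna().unique():
                for h in ("north", "south"):
                    key = (str(isl), h)
                    n_released[key] = n_released.get(key, 0) + int(denom.get(h, 0))
    else:
        for j, day in sub.groupby("release_day"):
            n_all = len(day)
            beached = day[day["fate"] == "beached"]
            for (isl, i), grp in beached.groupby(["island", "beach_day"]):
                rows.append((int(j), int(i), str(isl), None,
                             float(grp["w"].sum()) / n_all))
            for isl in particles["island"].dropna().unique():
                key = (str(isl), None)
                n_released[key] = n_released.get(key, 0) + n_all
    table = pd.DataFrame(
        rows, columns=["release_day", "dep_day", "island", "half", "P"]
    )
    return DepositionSeries(table=table, d_max=float(d_max), n_released=n_released)
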