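"""Gridded surface-wind time series on a planar-km frame.

The drift model runs in a local tangent plane (km) centred on the primary
island, so the wind container is a regular (time, y, x) grid of u/v
components in m/s with a uniform 3-hourly time axis.  Interpolation is
bilinear in space and linear in time, matching how reanalysis winds are
commonly sampled onto Lagrangian particles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["WindGrid", "OutOfDomainError"]


class OutOfDomainError(ValueError):
    """Requested location lies outside the wind grid's spatial hull."""


@dataclass
class WindGrid:
    """Regular wind grid: ``u``/``v`` of shape (n_times, n_y, n_x) in m/s.

    ``times_h`` are hours since ``origin`` (a timestamp), strictly
    ascending with a uniform step (3 h for reanalysis-style input).
    ``x_km``/``y_km`` are ascending node coordinates in the planar frame.
    """

    times_h: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    u: np.ndarray
    v: np.ndarray
    origin: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2000-01-01"))

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != (self.times_h.size, self.y_km.size, self.x_km.size):
            raise ValueError(f"u has shape {self.u.shape}, expected "
                             f"{(self.times_h.size, self.y_km.size, self.x_km.size)}")
        if self.v.shape != self.u.shape:
            raise ValueError("u and v shapes differ")
        if self.times_h.size > 1:
            steps = np.diff(self.times_h)
            if not np.allclose(steps, steps[0]):
                raise ValueError("time axis must be uniformly spaced")
            if steps[0] <= 0:
                raise ValueError("time axis must be ascending")
        if not (np.all(np.diff(self.x_km) > 0) and np.all(np.diff(self.y_km) > 0)):
            raise ValueError("spatial axes must be strictly ascending")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("wind components must be finite")
        self._warned_time_clamp = False

    # ------------------------------------------------------------------ #

    @property
    def step_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0]) if self.times_h.size > 1 else 3.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask: points inside the grid's rectangular hull."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.x_km[0]) & (x <= self.x_km[-1])
            & (y >= self.y_km[0]) & (y <= self.y_km[-1])
        )

    def _fields_at(self, t_h: float) -> tuple[np.ndarray, np.ndarray]:
        """Time-interpolated (u, v) fields, clamped beyond the series."""
        t = float(t_h)
        if t <= self.times_h[0] or t >= self.times_h[-1]:
            if (t < self.times_h[0] - 1e-9 or t > self.times_h[-1] + 1e-9) and (
                not self._warned_time_clamp
            ):
                log.warning("time %.1f h outside wind series; clamped to edge", t)
                self._warned_time_clamp = True
            k = 0 if t <= self.times_h[0] else -1
            return self.u[k], self.v[k]
        i1 = int(np.searchsorted(self.times_h, t, side="right"))
        i0 = i1 - 1
        w = (t - self.times_h[i0]) / (self.times_h[i1] - self.times_h[i0])
        return (
            (1.0 - w) * self.u[i0] + w * self.u[i1],
            (1.0 - w) * self.v[i0] + w * self.v[i1],
        )

    def _bilinear(self, fu: np.ndarray, fv: np.ndarray,
                  x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # positions clamped to the hull: used by the advection loop, where
        # leaving the domain is handled by the caller
        xc = np.clip(x, self.x_km[0], self.x_km[-1])
        yc = np.clip(y, self.y_km[0], self.y_km[-1])
        ix = np.clip(np.searchsorted(self.x_km, xc, side="right") - 1, 0,
                     max(self.x_km.size - 2, 0))
        iy = np.clip(np.searchsorted(self.y_km, yc, side="right") - 1, 0,
                     max(self.y_km.size - 2, 0))
        if self.x_km.size == 1:
            wx = np.zeros_like(xc)
            ix1 = ix
        else:
            wx = (xc - self.x_km[ix]) / (self.x_km[ix + 1] - self.x_km[ix])
            ix1 = ix + 1
        if self.y_km.size == 1:
            wy = np.zeros_like(yc)
            iy1 = iy
        else:
            wy = (yc - self.y_km[iy]) / (self.y_km[iy + 1] - self.y_km[iy])
            iy1 = iy + 1
        out = []
        for f in (fu, fv):
            f00 = f[iy, ix]
            f01 = f[iy, ix1]
            f10 = f[iy1, ix]
            f11 = f[iy1, ix1]
            out.append(
                (1 - wy) * ((1 - wx) * f00 + wx * f01)
                + wy * ((1 - wx) * f10 + wx * f11)
            )
        return out[0], out[1]

    def interp(self, x: np.ndarray, y: np.ndarray, t_h: float
               ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (u, v) in m/s at planar positions and one instant.

        Positions outside the hull are sampled at the nearest edge (the
        advection loop treats such particles as lost); use
        :meth:`wind_at` for strict out-of-domain checking.
        """
        fu, fv = self._fields_at(t_h)
        return self._bilinear(fu, fv, np.asarray(x, float), np.asarray(y, float))

    def wind_at(self, x: float, y: float, t_h: float) -> tuple[float, float]:
        """(u, v) at one location/instant; raises outside the spatial hull."""
        if not bool(self.contains(x, y)):
            raise OutOfDomainError(f"({x}, {y}) km outside wind grid hull")
        u, v = self.interp(np.array([x]), np.array([y]), t_h)
        return float(u[0]), float(v[0])

    # ------------------------------ I/O ------------------------------- #

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns time_h, x_km, y_km, u, v."""
        tt, yy, xx = np.meshgrid(self.times_h, self.y_km, self.x_km, indexing="ij")
        return pd.DataFrame(
            {
                "time_h": tt.ravel(),
                "x_km": xx.ravel(),
                "y_km": yy.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       origin: pd.Timestamp | str = "2000-01-01") -> "WindGrid":
        times = np.sort(df["time_h"].unique())
        xs = np.sort(df["x_km"].unique())
        ys = np.sort(df["y_km"].unique())
        pivot = df.set_index(["time_h", "y_km", "x_km"]).sort_index()
        shape = (times.size, ys.size, xs.size)
        u = pivot["u"].to_numpy().reshape(shape)
        v = pivot["v"].to_numpy().reshape(shape)
        return cls(times, xs, ys, u, v, origin=pd.Timestamp(origin))

    @classmethod
    def read_csv(cls, path, origin: pd.Timestamp | str = "2000-01-01") -> "WindGrid":
        return cls.from_dataframe(pd.read_csv(path), origin=origin)

    @classmethod
    def from_xarray(cls, ds, u_var: str = "u10", v_var: str = "v10",
                    x_dim: str = "x", y_dim: str = "y") -> "WindGrid":
        """Build from a CF-style dataset with dims (time, y, x), coords in km."""
        times = pd.to_datetime(ds["time"].values)
        origin = pd.Timestamp(times[0])
        t_h = (times - origin) / pd.Timedelta(hours=1)
        return cls(
            np.asarray(t_h, float),
            np.asarray(ds[x_dim].values, float),
            np.asarray(ds[y_dim].values, float),
            np.asarray(ds[u_var].values, float),
            np.asarray(ds[v_var].values, float),
            origin=origin,
        )

    @classmethod
    def read_netcdf(cls, path, **kwargs) -> "WindGrid":
        import xarray as xr

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = xr.open_dataset(path)
        return cls.from_xarray(ds, **kwargs)
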