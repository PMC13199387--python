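"""Gridded monthly series: the carrier type for all fields in the pipeline.

Every field handled by the package — sea surface temperature (SST),
chlorophyll (CHL), photosynthetically available radiation (PAR), net primary
production (NPP) and all of their anomalies — travels as a
:class:`GriddedMonthlySeries`: a dense ``(time, lat, lon)`` array on a
regular monthly axis, with NaN marking missing cells and a units string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GriddedMonthlySeries", "monthly_period_index"]


def monthly_period_index(start_year: int, n_months: int, start_month: int = 1) -> pd.PeriodIndex:
    """Contiguous monthly :class:`pandas.PeriodIndex` of length ``n_months``."""
    start = pd.Period(year=start_year, month=start_month, freq="M")
    return pd.period_range(start=start, periods=n_months, freq="M")


@dataclass
class GriddedMonthlySeries:
    """A monthly ``(time, lat, lon)`` field with units and NaN-as-missing.

    Parameters
    ----------
    values
        Array of shape ``(n_time, n_lat, n_lon)``; NaN marks missing cells.
    time
        Strictly increasing, gap-free monthly :class:`pandas.PeriodIndex`.
    lat, lon
        Cell-centre coordinates in degrees; ``lat`` within [-90, 90].
    units
        Physical units of ``values`` (e.g. ``"degC"``, ``"mg m-3"``).
    """

    values: np.ndarray
    time: pd.PeriodIndex
    lat: np.ndarray
    lon: np.ndarray
    units: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not isinstance(self.time, pd.PeriodIndex):
            self.time = pd.PeriodIndex(self.time, freq="M")
        if self.values.ndim != 3:
            raise ValueError(f"values must be (time, lat, lon); got ndim={self.values.ndim}")
        nt, nlat, nlon = self.values.shape
        if len(self.time) != nt:
            raise ValueError(f"time axis length {len(self.time)} != values.shape[0] {nt}")
        if self.lat.shape != (nlat,) or self.lon.shape != (nlon,):
            raise ValueError("lat/lon lengths do not match the grid shape")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitudes must lie within [-90, 90] degrees")
        if nt >= 2:
            steps = np.diff(self.time.asi8)
            if np.any(steps <= 0):
                raise ValueError("time axis must be strictly increasing")
            gaps = np.flatnonzero(steps != 1)
            if gaps.size:
                i = gaps[0]
                raise ValueError(
                    f"time axis is not contiguous monthly: gap between "
                    f"{self.time[i]} and {self.time[i + 1]}"
                )
        if not self.units:
            raise ValueError("units must be a non-empty string")

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1..12) of every time step."""
        return np.asarray(self.time.month)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.time.year)

    @property
    def missing(self) -> np.ndarray:
        """Boolean missing-data mask, same shape as ``values``."""
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "GriddedMonthlySeries":
        """A copy on the same grid carrying new ``values`` (and optionally units)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)

    def same_grid(self, other: "GriddedMonthlySeries") -> bool:
        return (
            self.shape == other.shape
            and self.time.equals(other.time)
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
        )

    def require_same_grid(self, other: "GriddedMonthlySeries", what: str = "series") -> None:
        if not self.same_grid(other):
            raise ValueError(f"grid mismatch between {what}: time/lat/lon axes differ")

    # -- xarray bridge -------------------------------------------------------

    def to_dataarray(self, name: str = "field") -> "xr.DataArray":  # noqa: F821
        import xarray as xr

        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={
                "time": self.time.to_timestamp(),
                "lat": self.lat,
                "lon": self.lon,
            },
            name=name,
            attrs={"units": self.units},
        )
        da["lat"].attrs["units"] = "degrees_north"
        da["lon"].attrs["units"] = "degrees_east"
        return da

    @classmethod
    def from_dataarray(cls, da: "xr.DataArray") -> "GriddedMonthlySeries":  # noqa: F821
        da = da.transpose("time", "lat", "lon")
        time = pd.DatetimeIndex(da["time"].values).to_period("M")
        units = str(da.attrs.get("units", "") or "unknown")
        return cls(
            values=np.asarray(da.values, dtype=float),
            time=pd.PeriodIndex(time, freq="M"),
            lat=np.asarray(da["lat"].values, dtype=float),
            lon=np.asarray(da["lon"].values, dtype=float),
            units=units,
        )
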