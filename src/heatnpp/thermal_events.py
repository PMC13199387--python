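"""Fixed-baseline monthly climatologies and warm-condition labelling.

A marine heatwave (MHW) month is one whose SST exceeds the seasonally
varying 90th-percentile threshold of a fixed baseline climatology; a month
with a positive SST anomaly that stays at or below that threshold is a
moderate-warming month (``SSTA_PLUS``). Labels are computed per cell-month;
no minimum-duration rule is applied at monthly resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .series import GriddedMonthlySeries

__all__ = [
    "LABEL_MISSING",
    "LABEL_OTHER",
    "LABEL_SSTA_PLUS",
    "LABEL_MHW",
    "LABEL_CODES",
    "MonthlyClimatology",
    "ConditionLabelGrid",
    "monthly_climatology",
    "anomalies",
    "label_conditions",
]

logger = logging.getLogger(__name__)

LABEL_MISSING = -1
LABEL_OTHER = 0
LABEL_SSTA_PLUS = 1
LABEL_MHW = 2
LABEL_CODES = {
    "MISSING": LABEL_MISSING,
    "OTHER": LABEL_OTHER,
    "SSTA_PLUS": LABEL_SSTA_PLUS,
    "MHW": LABEL_MHW,
}


@dataclass
class MonthlyClimatology:
    """Per-calendar-month mean and q-quantile fields over a fixed baseline."""

    mean_clim: np.ndarray   # (12, lat, lon)
    q_clim: np.ndarray      # (12, lat, lon)
    baseline: tuple[int, int]
    q: float = 0.90
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        self.mean_clim = np.asarray(self.mean_clim, dtype=float)
        self.q_clim = np.asarray(self.q_clim, dtype=float)
        if self.mean_clim.shape != self.q_clim.shape or self.mean_clim.shape[0] != 12:
            raise ValueError("climatology fields must both be (12, lat, lon)")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mean_clim.shape[1:]  # type: ignore[return-value]


@dataclass
class ConditionLabelGrid:
    """Integer-coded per cell-month condition labels (see ``LABEL_CODES``)."""

    labels: np.ndarray  # (time, lat, lon) int8
    time: "pd.PeriodIndex"  # noqa: F821
    lat: np.ndarray
    lon: np.ndarray
    codes: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.codes is None:
            self.codes = dict(LABEL_CODES)

    def condition_mask(self, condition: str | int) -> np.ndarray:
        """Boolean (time, lat, lon) mask of cell-months carrying ``condition``."""
        code = self.codes[condition] if isinstance(condition, str) else int(condition)
        return self.labels == code


def _baseline_selector(series: GriddedMonthlySeries, baseline: tuple[int, int]) -> np.ndarray:
    y0, y1 = int(baseline[0]), int(baseline[1])
    years = series.years
    if y0 > y1:
        raise ValueError("baseline must be (first_year, last_year) with first <= last")
    if y0 < years.min() or y1 > years.max():
        raise ValueError(
            f"baseline {y0}-{y1} lies outside the series span "
            f"{years.min()}-{years.max()}"
        )
    return (years >= y0) & (years <= y1)


def monthly_climatology(
    sst: GriddedMonthlySeries,
    baseline: tuple[int, int],
    q: float = 0.90,
    *,
    min_samples: int = 2,
    quantile_method: str = "linear",
) -> MonthlyClimatology:
    """Per-calendar-month baseline mean and q-quantile of a gridded series.

    For each calendar month and cell the mean and the q-quantile are taken
    over the baseline years, excluding missing values; cells with fewer than
    ``min_samples`` valid baseline values for some month are masked (NaN)
    there. The quantile uses the declared interpolation convention
    (default: linear interpolation between order statistics).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    in_base = _baseline_selector(sst, baseline)
    months = sst.months
    nlat, nlon = sst.shape[1:]
    mean_clim = np.full((12, nlat, nlon), np.nan)
    q_clim = np.full((12, nlat, nlon), np.nan)
    n_starved = 0
    for m in range(1, 13):
        sel = in_base & (months == m)
        if not sel.any():
            continue
        sample = sst.values[sel]  # (n_years_m, lat, lon)
        n_valid = np.sum(~np.isnan(sample), axis=0)
        enough = n_valid >= min_samples
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(sample, axis=0)
            qq = np.nanquantile(sample, q, axis=0, method=quantile_method)
        mean_clim[m - 1] = np.where(enough, mu, np.nan)
        q_clim[m - 1] = np.where(enough, qq, np.nan)
        n_starved += int(np.sum(~enough & (n_valid > 0)))
    if n_starved:
        logger.warning(
            "monthly_climatology: %d (month, cell) samples below min_samples=%d were masked",
            n_starved, min_samples,
        )
    return MonthlyClimatology(mean_clim, q_clim, (int(baseline[0]), int(baseline[1])),
                              q=q, quantile_method=quantile_method)


def anomalies(series: GriddedMonthlySeries, clim: MonthlyClimatology) -> GriddedMonthlySeries:
    """Series minus its monthly climatological mean, units preserved."""
    if clim.grid_shape != series.shape[1:]:
        raise ValueError("grid mismatch between series and climatology")
    anom = series.values - clim.mean_clim[series.months - 1]
    return series.with_values(anom)


def label_conditions(
    sst: GriddedMonthlySeries, clim: MonthlyClimatology
) -> ConditionLabelGrid:
    """Label every cell-month as MHW, SSTA_PLUS, OTHER or MISSING.

    MHW: SST strictly exceeds the seasonally varying q-quantile threshold.
    SSTA_PLUS: SST strictly exceeds the monthly mean but stays at or below
    the threshold. OTHER: SST at or below the monthly mean. Cells missing in
    either the input or the climatology are MISSING. The climatology may come
    from a baseline window different from the labelled span.
    """
    if clim.grid_shape != sst.shape[1:]:
        raise ValueError("grid mismatch between SST and climatology")
    mi = sst.months - 1
    mean = clim.mean_clim[mi]
    thr = clim.q_clim[mi]
    v = sst.values
    invalid = np.isnan(v) | np.isnan(mean) | np.isnan(thr)
    labels = np.full(v.shape, LABEL_OTHER, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        labels[v > mean] = LABEL_SSTA_PLUS
        labels[v > thr] = LABEL_MHW
    labels[invalid] = LABEL_MISSING
    return ConditionLabelGrid(labels, sst.time, sst.lat, sst.lon)
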