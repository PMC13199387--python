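"""Region masks, condition composites and area-weighted summary statistics.

Conventions: cells are weighted by the cosine of their centre latitude
wherever an area weight is needed. Box-plot statistics (quartiles, whiskers)
are computed over the unweighted cell values within a region, while the
single "mean" marker is area-weighted — matching the usual presentation of
regional NPP budgets. The internal NPP unit is mg C m-2 day-1;
:func:`to_annual_gc` converts reported values to gC m-2 year-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classification import RESPONSE_CODES, ResponseClassMap
from .series import GriddedMonthlySeries
from .thermal_events import ConditionLabelGrid, MonthlyClimatology

__all__ = [
    "RegionMask",
    "RegionalSummary",
    "change_ratio",
    "regional_summary",
    "band_summary",
    "class_conditioned_summary",
    "cos_lat_weights",
    "to_annual_gc",
]

logger = logging.getLogger(__name__)


def cos_lat_weights(lat: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Cos-latitude area weights broadcast to a (lat, lon) grid."""
    w = np.cos(np.deg2rad(np.asarray(lat, dtype=float)))
    return np.broadcast_to(w[:, None], grid_shape).copy()


def to_annual_gc(mg_per_day: np.ndarray | float) -> np.ndarray | float:
    """Convert mg C m-2 day-1 to gC m-2 year-1."""
    return np.asarray(mg_per_day) * 365.0 / 1000.0


@dataclass
class RegionMask:
    """A named boolean region on the data grid with cos-latitude weights."""

    name: str
    mask: np.ndarray            # (lat, lon) bool
    lat: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.lat.size:
            raise ValueError("mask must be (lat, lon) and match the latitude vector")
        if not self.mask.any():
            raise ValueError(f"region {self.name!r} has no cells")

    @property
    def weights(self) -> np.ndarray:
        return cos_lat_weights(self.lat, self.mask.shape)


@dataclass
class RegionalSummary:
    """Box-plot-style summary of per-cell values inside one region."""

    region: str
    condition: str
    n_cells: int
    weighted_mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def change_ratio(
    series: GriddedMonthlySeries,
    labels: ConditionLabelGrid,
    condition: str,
    clim: MonthlyClimatology | None = None,
    *,
    min_condition_months: int = 3,
    mean_floor: float = 1e-6,
) -> np.ndarray:
    """Percent change of a field's condition-month mean against its local mean.

    Per cell: ``100 * (mean over condition months - long-term mean) /
    long-term mean``, the long-term mean being the cell's time mean over the
    full span of ``series`` (equivalently, the mean of its monthly
    climatology when one is supplied on the same grid). Cells with fewer
    than ``min_condition_months`` condition months or a long-term mean whose
    magnitude is below ``mean_floor`` are masked.
    """
    if series.shape != labels.labels.shape:
        raise ValueError("series and labels are on different grids")
    sel = labels.condition_mask(condition) & ~np.isnan(series.values)
    counts = sel.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond_mean = np.where(sel, series.values, 0.0).sum(axis=0) / counts
    if clim is not None:
        if clim.grid_shape != series.shape[1:]:
            raise ValueError("climatology grid does not match the series")
        local_mean = np.nanmean(clim.mean_clim, axis=0)
    else:
        local_mean = np.nanmean(series.values, axis=0)
    small = np.abs(local_mean) < mean_floor
    n_small = int(np.sum(small & (counts >= min_condition_months)))
    if n_small:
        logger.warning("change_ratio: %d cells masked for near-zero local mean", n_small)
    ok = (counts >= min_condition_months) & ~small & ~np.isnan(local_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = 100.0 * (cond_mean - local_mean) / local_mean
    return np.where(ok, ratio, np.nan)


def regional_summary(
    field: np.ndarray,
    mask: RegionMask,
    *,
    condition: str = "",
    quantile_method: str = "linear",
) -> RegionalSummary:
    """Area-weighted mean plus unweighted box statistics of a field in a region.

    NaN cells are excluded. Whiskers sit at Q1 - 1.5*IQR and Q3 + 1.5*IQR,
    clipped to the observed range.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != mask.mask.shape:
        raise ValueError("field and mask are on different grids")
    sel = mask.mask & ~np.isnan(field)
    if not sel.any():
        raise ValueError(f"region {mask.name!r} is empty after masking")
    vals = field[sel]
    w = mask.weights[sel]
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo = max(float(vals.min()), float(q1 - 1.5 * iqr))
    hi = min(float(vals.max()), float(q3 + 1.5 * iqr))
    return RegionalSummary(
        region=mask.name, condition=condition, n_cells=int(sel.sum()),
        weighted_mean=float((vals * w).sum() / w.sum()),
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=lo, whisker_high=hi,
    )


def band_summary(
    field: np.ndarray,
    lat: np.ndarray,
    edges: "list[float] | np.ndarray",
) -> dict:
    """Cos-latitude-weighted mean of a (lat, lon) field per latitude band.

    ``edges`` are strictly increasing band boundaries in degrees; a cell
    belongs to the band whose lower edge it reaches (lower-edge-inclusive),
    with the final band also including its upper edge so a covering set of
    edges partitions every cell exactly once. Empty bands yield NaN.
    """
    field = np.asarray(field, dtype=float)
    lat = np.asarray(lat, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with at least two values")
    weights = cos_lat_weights(lat, field.shape)
    out: dict = {}
    for k in range(edges.size - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == edges.size - 2:
            in_band = (lat >= lo) & (lat <= hi)
        else:
            in_band = (lat >= lo) & (lat < hi)
        sel = np.broadcast_to(in_band[:, None], field.shape) & ~np.isnan(field)
        key = (float(lo), float(hi))
        if not sel.any():
            out[key] = np.nan
            continue
        out[key] = float((field[sel] * weights[sel]).sum() / weights[sel].sum())
    return out


def class_conditioned_summary(
    baseline_field: np.ndarray,
    anomaly_field: np.ndarray,
    classes: ResponseClassMap,
    *,
    which: tuple = ("ENHANCED", "INHIBITED"),
    quantile_method: str = "linear",
) -> dict:
    """Summaries of a baseline field and an anomaly composite per response class.

    For each requested class, returns :class:`RegionalSummary` statistics of
    the baseline field and of the (already condition-composited) anomaly
    field over that class's cells. Raises if a requested class is empty.
    """
    out: dict = {}
    for name in which:
        code = classes.codes[name] if name in classes.codes else RESPONSE_CODES[name]
        cells = classes.classes == code
        if not cells.any():
            raise ValueError(f"response class {name!r} has no cells")
        mask = RegionMask(name=name, mask=cells, lat=classes.lat)
        out[name] = {
            "baseline": regional_summary(baseline_field, mask, condition="baseline",
                                         quantile_method=quantile_method),
            "anomaly": regional_summary(anomaly_field, mask, condition="anomaly",
                                        quantile_method=quantile_method),
        }
    return out
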