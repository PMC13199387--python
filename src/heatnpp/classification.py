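"""Driver-dominance and warming-response classification of grid cells.

Two complementary per-cell classifications:

* **dominance** — under a given warm condition, is the composited NPP
  anomaly carried mainly by the SST-dependent or the SST-independent group
  of the regression budget? Decided by comparing the absolute composite
  means; an exact tie goes to SST-independent (the conservative choice) and
  is flagged.
* **warming response** — the sign of the Pearson correlation between the
  NPP anomaly and the SST anomaly, kept only where significant at the
  chosen confidence level (default 90%). Significantly positive cells are
  "MHW-enhanced", significantly negative cells "MHW-inhibited".

Area fractions weight cells by the cosine of latitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decomposition import CompositeComponents
from .series import GriddedMonthlySeries
from .thermal_events import ConditionLabelGrid

__all__ = [
    "DOM_UNDEFINED",
    "DOM_SST_DEPENDENT",
    "DOM_SST_INDEPENDENT",
    "RESP_UNDEFINED",
    "RESP_NEUTRAL",
    "RESP_ENHANCED",
    "RESP_INHIBITED",
    "DominanceMap",
    "ResponseClassMap",
    "dominance_map",
    "response_class_map",
    "area_fraction",
]

DOM_UNDEFINED = -1
DOM_SST_DEPENDENT = 1
DOM_SST_INDEPENDENT = 2
DOMINANCE_CODES = {
    "UNDEFINED": DOM_UNDEFINED,
    "SST_DEPENDENT": DOM_SST_DEPENDENT,
    "SST_INDEPENDENT": DOM_SST_INDEPENDENT,
}

RESP_UNDEFINED = -1
RESP_NEUTRAL = 0
RESP_ENHANCED = 1
RESP_INHIBITED = 2
RESPONSE_CODES = {
    "UNDEFINED": RESP_UNDEFINED,
    "NEUTRAL": RESP_NEUTRAL,
    "ENHANCED": RESP_ENHANCED,
    "INHIBITED": RESP_INHIBITED,
}


@dataclass
class DominanceMap:
    """Per-cell dominant budget group under one condition."""

    condition: str
    classes: np.ndarray          # (lat, lon) int codes, see DOMINANCE_CODES
    dep_magnitude: np.ndarray    # |composite mean| of the SST-dependent group
    indep_magnitude: np.ndarray
    tie: np.ndarray              # (lat, lon) bool, exact-tie cells
    lat: np.ndarray
    lon: np.ndarray
    codes: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = dict(DOMINANCE_CODES)


@dataclass
class ResponseClassMap:
    """Per-cell NPPA-SSTA correlation, significance and response class."""

    r: np.ndarray                # (lat, lon)
    p: np.ndarray
    classes: np.ndarray          # int codes, see RESPONSE_CODES
    n: np.ndarray                # per-cell sample sizes
    alpha_sig: float
    lat: np.ndarray
    lon: np.ndarray
    codes: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = dict(RESPONSE_CODES)


def dominance_map(composite: CompositeComponents) -> DominanceMap:
    """Classify each cell by the larger of the two composited group magnitudes.

    Strict inequality decides; SST-dependent wins only when its absolute
    composite mean strictly exceeds the SST-independent one. Cells whose
    composite is masked are UNDEFINED.
    """
    dep = np.abs(composite.sst_dependent)
    indep = np.abs(composite.sst_independent)
    classes = np.full(dep.shape, DOM_UNDEFINED, dtype=np.int8)
    defined = ~(np.isnan(dep) | np.isnan(indep))
    with np.errstate(invalid="ignore"):
        classes[defined & (dep > indep)] = DOM_SST_DEPENDENT
        classes[defined & (dep <= indep)] = DOM_SST_INDEPENDENT
    tie = defined & (dep == indep)
    return DominanceMap(
        condition=composite.condition, classes=classes,
        dep_magnitude=dep, indep_magnitude=indep, tie=tie,
        lat=composite.lat, lon=composite.lon,
    )


def response_class_map(
    nppa: GriddedMonthlySeries,
    ssta: GriddedMonthlySeries,
    *,
    alpha_sig: float = 0.10,
    labels: ConditionLabelGrid | None = None,
    condition: str | None = None,
    min_months: int = 8,
) -> ResponseClassMap:
    """Classify cells by the sign of the significant NPPA-SSTA correlation.

    Pearson r per cell over all complete months (or over one condition's
    months when ``labels``/``condition`` restrict the sample); the two-sided
    p-value comes from the t transform ``t = r * sqrt(df / (1 - r^2))`` with
    ``df = n - 2``. ENHANCED means r > 0 with p < ``alpha_sig``, INHIBITED
    r < 0 with p < ``alpha_sig``; other defined cells are NEUTRAL and cells
    with fewer than ``min_months`` months or zero variance are UNDEFINED.
    """
    nppa.require_same_grid(ssta, "nppa/ssta")
    if not 0.0 < alpha_sig <= 1.0:
        raise ValueError("alpha_sig must lie in (0, 1]")
    y = nppa.values.copy()
    x = ssta.values.copy()
    if condition is not None:
        if labels is None:
            raise ValueError("a condition subset requires labels")
        keep = labels.condition_mask(condition)
        y = np.where(keep, y, np.nan)
        x = np.where(keep, x, np.nan)

    ok = ~(np.isnan(x) | np.isnan(y))
    n = ok.sum(axis=0)
    xz = np.where(ok, x, 0.0)
    yz = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = xz.sum(axis=0) / n
        ym = yz.sum(axis=0) / n
        xc = np.where(ok, x - xm, 0.0)
        yc = np.where(ok, y - ym, 0.0)
        sxx = (xc**2).sum(axis=0)
        syy = (yc**2).sum(axis=0)
        sxy = (xc * yc).sum(axis=0)
        r = sxy / np.sqrt(sxx * syy)
    r = np.clip(r, -1.0, 1.0)

    defined = (n >= min_months) & (sxx > 0) & (syy > 0)
    df = np.maximum(n - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 0.0)

    classes = np.full(r.shape, RESP_UNDEFINED, dtype=np.int8)
    classes[defined] = RESP_NEUTRAL
    sig = defined & (p < alpha_sig)
    classes[sig & (r > 0)] = RESP_ENHANCED
    classes[sig & (r < 0)] = RESP_INHIBITED
    r = np.where(defined, r, np.nan)
    p = np.where(defined, p, np.nan)
    return ResponseClassMap(r=r, p=p, classes=classes, n=n,
                            alpha_sig=alpha_sig, lat=nppa.lat, lon=nppa.lon)


def area_fraction(
    classes: np.ndarray,
    target_class: int | str,
    lat: np.ndarray,
    *,
    codes: dict | None = None,
    undefined_code: int = -1,
) -> float:
    """Cos-latitude-weighted area fraction of one class among defined cells.

    UNDEFINED cells are excluded from numerator and denominator; raises if no
    cell is defined.
    """
    classes = np.asarray(classes)
    if isinstance(target_class, str):
        if codes is None:
            raise ValueError("string target_class requires a code table")
        target = codes[target_class]
    else:
        target = int(target_class)
    lat = np.asarray(lat, dtype=float)
    w = np.cos(np.deg2rad(lat))
    weights = np.broadcast_to(w[:, None], classes.shape)
    defined = classes != undefined_code
    total = float(weights[defined].sum())
    if total <= 0.0:
        raise ValueError("no defined cells: area fraction is undefined")
    return float(weights[defined & (classes == target)].sum()) / total
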