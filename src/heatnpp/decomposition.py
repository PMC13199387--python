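"""Two-stage per-cell regression partition of NPP anomalies.

Stage 1 splits the chlorophyll and light anomalies into an SST-projected
part and a residual,

    CHLA = alpha * SSTA + CHLA_res,     PARA = beta * SSTA + PARA_res,

with ``alpha``/``beta`` ordinary-least-squares slopes (no intercept: the
inputs are anomalies with near-zero baseline mean). Stage 2 regresses the
NPP anomaly jointly on the five series,

    NPPA = a*SSTA + b*CHLA_sst + c*PARA_sst + d*CHLA_res + e*PARA_res + NPPA_res,

and groups the first three terms as "SST-dependent NPPA" and the last three
(including the residual) as "SST-independent NPPA". The partition is exact
by construction at every fitted month.

Identifiability
---------------
``CHLA_sst = alpha*SSTA`` and ``PARA_sst = beta*SSTA`` are exactly
proportional to SSTA, so the stage-2 design always has (at most) rank 3 and
the split of the SSTA-direction slope among ``a``, ``b`` and ``c`` is not
determined by the data; any choice with the same combination
``g = a + b*alpha + c*beta`` yields identical fitted series. The solver
returns the minimum-norm representative (via SVD least squares) and also
reports ``g`` itself, which — together with ``alpha``, ``beta``, ``d`` and
``e`` — is the identifiable parameter set. All grouped series, composites
and downstream classifications depend only on the identifiable quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .series import GriddedMonthlySeries
from .thermal_events import ConditionLabelGrid, LABEL_CODES

__all__ = [
    "TERM_NAMES",
    "CellDecomposition",
    "GridDecomposition",
    "CompositeComponents",
    "decompose_cell",
    "decompose_grid",
    "composite_components",
]

logger = logging.getLogger(__name__)

#: the six budget terms of the stage-2 partition, in display order
TERM_NAMES = ("a_ssta", "b_chla_sst", "c_para_sst", "d_chla_res", "e_para_res", "nppa_res")

_REGRESSOR_NAMES = ("ssta", "chla_sst", "para_sst", "chla_res", "para_res")


@dataclass
class CellDecomposition:
    """Coefficients, component series and diagnostics for one cell.

    Series are full input length with NaN outside the fitted sample.
    """

    alpha: float
    beta: float
    a: float
    b: float
    c: float
    d: float
    e: float
    g: float                       # identifiable SSTA-direction slope a + b*alpha + c*beta
    chla_sst: np.ndarray
    chla_res: np.ndarray
    para_sst: np.ndarray
    para_res: np.ndarray
    terms: dict                    # the six named budget series
    sst_dependent: np.ndarray
    sst_independent: np.ndarray
    n: int
    r2: float
    rank: int
    degenerate: bool
    zero_variance: tuple
    valid: np.ndarray              # boolean fit-sample mask on the input time axis

    @property
    def coefficients(self) -> dict:
        return {k: getattr(self, k) for k in ("alpha", "beta", "a", "b", "c", "d", "e", "g")}


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def decompose_cell(
    ssta,
    chla,
    para,
    nppa,
    *,
    min_months: int = 24,
    intercept: bool = False,
) -> CellDecomposition:
    """Fit the two-stage decomposition for one cell's aligned anomaly series.

    Missing months are dropped listwise across all four series so every
    fitted quantity shares one sample; fewer than ``min_months`` complete
    months raises. A zero-variance SSTA makes the thermal pathway undefined:
    the cell is flagged degenerate, ``alpha``/``beta``/``a``/``b``/``c`` are
    set to 0 by convention, and the residual pathways carry all variance.
    With ``intercept=True`` an intercept is carried in both stages and its
    stage-2 estimate is folded into ``NPPA_res`` so the six-term budget still
    sums exactly to NPPA.
    """
    s = _as_1d(ssta, "ssta")
    ch = _as_1d(chla, "chla")
    pa = _as_1d(para, "para")
    npr = _as_1d(nppa, "nppa")
    if not (s.shape == ch.shape == pa.shape == npr.shape):
        raise ValueError("anomaly series must share one length")
    nt = s.size
    valid = ~(np.isnan(s) | np.isnan(ch) | np.isnan(pa) | np.isnan(npr))
    n = int(valid.sum())
    if n < min_months:
        raise ValueError(f"only {n} complete months; need at least {min_months}")

    sv, cv, pv, yv = s[valid], ch[valid], pa[valid], npr[valid]
    if intercept:
        s_mu, c_mu, p_mu, y_mu = sv.mean(), cv.mean(), pv.mean(), yv.mean()
    else:
        s_mu = c_mu = p_mu = y_mu = 0.0

    # no-intercept fits only need a non-null SSTA vector; with an intercept the
    # slope needs genuine variance
    degenerate = float(np.std(sv)) == 0.0 if intercept else not np.any(sv != 0.0)

    if degenerate:
        alpha = beta = 0.0
    else:
        sc = sv - s_mu
        ss = float(sc @ sc)
        alpha = float(sc @ (cv - c_mu) / ss)
        beta = float(sc @ (pv - p_mu) / ss)

    chla_sst = np.full(nt, np.nan)
    para_sst = np.full(nt, np.nan)
    chla_res = np.full(nt, np.nan)
    para_res = np.full(nt, np.nan)
    chla_sst[valid] = alpha * sv
    para_sst[valid] = beta * sv
    stage1_icpt_c = c_mu - alpha * s_mu if intercept else 0.0
    stage1_icpt_p = p_mu - beta * s_mu if intercept else 0.0
    chla_res[valid] = cv - alpha * sv - stage1_icpt_c
    para_res[valid] = pv - beta * sv - stage1_icpt_p

    # stage 2: joint OLS on the five series (minimum-norm under collinearity)
    X = np.column_stack([sv, alpha * sv, beta * sv, chla_res[valid], para_res[valid]])
    zero_variance = tuple(
        name for j, name in enumerate(_REGRESSOR_NAMES) if not np.any(X[:, j] != 0.0)
    )
    if intercept:
        Xf = np.column_stack([X, np.ones(n)])
    else:
        Xf = X
    if degenerate:
        coef5 = np.zeros(5)
        icpt2 = y_mu if intercept else 0.0
        # residual pathways are still well defined against CHLA_res/PARA_res
        R = X[:, 3:5]
        if np.any(R != 0.0):
            sol, _, rnk, _ = np.linalg.lstsq(R, yv - icpt2, rcond=None)
            coef5[3:5] = sol
            rank = int(rnk)
        else:
            rank = 0
    else:
        sol, _, rnk, _ = np.linalg.lstsq(Xf, yv, rcond=None)
        coef5 = sol[:5]
        icpt2 = float(sol[5]) if intercept else 0.0
        rank = int(rnk)
    a, b, c, d, e = (float(v) for v in coef5)

    terms = {name: np.full(nt, np.nan) for name in TERM_NAMES}
    terms["a_ssta"][valid] = a * sv
    terms["b_chla_sst"][valid] = b * chla_sst[valid]
    terms["c_para_sst"][valid] = c * para_sst[valid]
    terms["d_chla_res"][valid] = d * chla_res[valid]
    terms["e_para_res"][valid] = e * para_res[valid]
    fitted5 = X @ coef5
    terms["nppa_res"][valid] = yv - fitted5  # any intercept is folded in here

    sst_dependent = terms["a_ssta"] + terms["b_chla_sst"] + terms["c_para_sst"]
    sst_independent = terms["d_chla_res"] + terms["e_para_res"] + terms["nppa_res"]

    sst_tot = float(yv @ yv)
    resid = terms["nppa_res"][valid]
    r2 = 1.0 - float(resid @ resid) / sst_tot if sst_tot > 0 else np.nan

    return CellDecomposition(
        alpha=alpha, beta=beta, a=a, b=b, c=c, d=d, e=e,
        g=a + b * alpha + c * beta,
        chla_sst=chla_sst, chla_res=chla_res, para_sst=para_sst, para_res=para_res,
        terms=terms, sst_dependent=sst_dependent, sst_independent=sst_independent,
        n=n, r2=r2, rank=rank, degenerate=bool(degenerate),
        zero_variance=zero_variance, valid=valid,
    )


_COEF_KEYS = ("alpha", "beta", "a", "b", "c", "d", "e", "g", "r2")


@dataclass
class GridDecomposition:
    """Per-cell decompositions over a grid, stored as coefficient maps and term stacks."""

    coef: dict                     # name -> (lat, lon) float map
    terms: dict                    # six (time, lat, lon) stacks
    sst_dependent: np.ndarray      # (time, lat, lon)
    sst_independent: np.ndarray
    n: np.ndarray                  # (lat, lon) fitted-sample sizes
    rank: np.ndarray
    degenerate: np.ndarray         # (lat, lon) bool
    masked: np.ndarray             # (lat, lon) bool: no fit (insufficient sample)
    time: "pd.PeriodIndex"  # noqa: F821
    lat: np.ndarray
    lon: np.ndarray

    @property
    def nppa_fitted_total(self) -> np.ndarray:
        """Reconstructed NPPA = SST-dependent + SST-independent at every cell-month."""
        return self.sst_dependent + self.sst_independent


def decompose_grid(
    ssta: GriddedMonthlySeries,
    chla: GriddedMonthlySeries,
    para: GriddedMonthlySeries,
    nppa: GriddedMonthlySeries,
    *,
    min_months: int = 24,
    intercept: bool = False,
    fit_mask: np.ndarray | None = None,
) -> GridDecomposition:
    """Apply :func:`decompose_cell` at every grid cell.

    Cells with fewer than ``min_months`` complete months (or entirely
    missing) are masked; results at the remaining cells are identical to
    calling :func:`decompose_cell` directly.

    ``fit_mask`` restricts the fitted sample to selected cell-months — a
    boolean array over time (or over the full grid), typically one
    condition's labels. This is the per-condition refit mode: by default the
    regression is fit once per cell over all available months and only the
    composites are condition-restricted, which is the stabler choice at
    monthly sample sizes, but refitting inside a condition captures coupling
    that holds only there (component series are then defined only on the
    selected months).
    """
    for other, what in ((chla, "ssta/chla"), (para, "ssta/para"), (nppa, "ssta/nppa")):
        ssta.require_same_grid(other, what)
    nt, nlat, nlon = ssta.shape
    if fit_mask is not None:
        fit_mask = np.asarray(fit_mask, dtype=bool)
        if fit_mask.shape == (nt,):
            fit_mask = np.broadcast_to(fit_mask[:, None, None], (nt, nlat, nlon))
        elif fit_mask.shape != (nt, nlat, nlon):
            raise ValueError("fit_mask must be (time,) or (time, lat, lon)")
        keep = lambda s: s.with_values(np.where(fit_mask, s.values, np.nan))
        ssta, chla, para, nppa = keep(ssta), keep(chla), keep(para), keep(nppa)
    if np.all(np.isnan(ssta.values)):
        raise ValueError("SSTA field is entirely missing")

    coef = {k: np.full((nlat, nlon), np.nan) for k in _COEF_KEYS}
    terms = {name: np.full((nt, nlat, nlon), np.nan) for name in TERM_NAMES}
    dep = np.full((nt, nlat, nlon), np.nan)
    indep = np.full((nt, nlat, nlon), np.nan)
    n_map = np.zeros((nlat, nlon), dtype=int)
    rank_map = np.zeros((nlat, nlon), dtype=int)
    degen = np.zeros((nlat, nlon), dtype=bool)
    masked = np.zeros((nlat, nlon), dtype=bool)

    for i in range(nlat):
        for j in range(nlon):
            try:
                cell = decompose_cell(
                    ssta.values[:, i, j], chla.values[:, i, j],
                    para.values[:, i, j], nppa.values[:, i, j],
                    min_months=min_months, intercept=intercept,
                )
            except ValueError:
                masked[i, j] = True
                continue
            for k in _COEF_KEYS:
                coef[k][i, j] = getattr(cell, k)
            for name in TERM_NAMES:
                terms[name][:, i, j] = cell.terms[name]
            dep[:, i, j] = cell.sst_dependent
            indep[:, i, j] = cell.sst_independent
            n_map[i, j] = cell.n
            rank_map[i, j] = cell.rank
            degen[i, j] = cell.degenerate

    n_deg, n_masked = int(degen.sum()), int(masked.sum())
    if n_deg or n_masked:
        logger.info("decompose_grid: %d degenerate, %d masked of %d cells",
                    n_deg, n_masked, nlat * nlon)
    return GridDecomposition(
        coef=coef, terms=terms, sst_dependent=dep, sst_independent=indep,
        n=n_map, rank=rank_map, degenerate=degen, masked=masked,
        time=ssta.time, lat=ssta.lat, lon=ssta.lon,
    )


@dataclass
class CompositeComponents:
    """Condition-mean NPPA and its grouped components, per cell."""

    condition: str
    nppa: np.ndarray             # (lat, lon)
    sst_dependent: np.ndarray
    sst_independent: np.ndarray
    n_months: np.ndarray         # (lat, lon) condition-month counts entering the mean
    lat: np.ndarray
    lon: np.ndarray


def composite_components(
    decomp: GridDecomposition,
    labels: ConditionLabelGrid,
    condition: str,
    *,
    min_condition_months: int = 3,
) -> CompositeComponents:
    """Time-mean of NPPA and the grouped components over one condition's months.

    Cells with fewer than ``min_condition_months`` labelled-and-fitted months
    are masked. The composite preserves the exact partition:
    mean(NPPA) = mean(SST-dependent) + mean(SST-independent).
    """
    if condition not in LABEL_CODES:
        raise ValueError(f"unknown condition {condition!r}; expected one of {sorted(LABEL_CODES)}")
    if decomp.sst_dependent.shape != labels.labels.shape:
        raise ValueError("decomposition and labels are on different grids")
    sel = labels.condition_mask(condition) & ~np.isnan(decomp.sst_dependent)
    counts = sel.sum(axis=0)
    enough = counts >= min_condition_months

    def _mean(stack: np.ndarray) -> np.ndarray:
        num = np.where(sel, stack, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / counts
        return np.where(enough, out, np.nan)

    dep = _mean(decomp.sst_dependent)
    indep = _mean(decomp.sst_independent)
    return CompositeComponents(
        condition=condition, nppa=dep + indep, sst_dependent=dep,
        sst_independent=indep, n_months=counts,
        lat=decomp.lat, lon=decomp.lon,
    )
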