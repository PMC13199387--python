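"""Synthetic monthly ocean scenes with known driver structure.

The generator produces SST, CHL, PAR and NPP on a monthly grid with exactly
the statistical structure the decomposition stage assumes:

* SST is a latitude-dependent seasonal cycle plus a stationary AR(1) anomaly
  (optionally with an inflated warm tail so marine heatwaves arise from the
  innovation distribution rather than being hand-placed);
* CHL and PAR anomalies are a linear-in-SSTA part plus independent noise;
* the NPP anomaly is a linear combination of the SSTA pathway, the
  SST-projected CHL/PAR parts, the residual CHL/PAR parts, and independent
  noise — or, optionally, NPP is produced by an Eppley-variant VGPM forward
  formula so the regression operates on a realistically nonlinear product.

Ground-truth coefficients are returned alongside the fields, which makes
every downstream stage testable without any external data product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import GriddedMonthlySeries, monthly_period_index

__all__ = [
    "SceneConfig",
    "VGPMParams",
    "Scene",
    "simulate_scene",
    "vgpm_eppley_forward",
]

_Z90 = 1.2815515655446004  # standard-normal 90th percentile


@dataclass
class VGPMParams:
    """Coefficients of the Eppley-variant VGPM forward formula.

    Depth-integrated NPP (mg C m-2 day-1) is modelled as

        NPP = scale * P_opt(SST) * PAR / (PAR + k) * Z_eu(CHL) * CHL * dayL

    with a chlorophyll-specific optimal rate that increases exponentially
    with temperature, ``P_opt = s * 10**(m*T + c)``, and a euphotic depth
    derived from integrated chlorophyll via the usual two-branch power laws.
    Every coefficient is configurable; the defaults follow the standard
    satellite-productivity implementation of the model.
    """

    pbopt_scale: float = 1.54
    pbopt_exp10_slope: float = 0.0275   # per degC
    pbopt_exp10_intercept: float = -0.07
    light_half_sat: float = 4.1         # mol photons m-2 day-1
    day_length_hours: float = 12.0
    npp_scale: float = 0.66125
    chl_tot_low: tuple[float, float] = (38.0, 0.425)   # CHL < 1 mg m-3
    chl_tot_high: tuple[float, float] = (40.2, 0.507)  # CHL >= 1 mg m-3
    zeu_deep: tuple[float, float] = (200.0, -0.293)
    zeu_shallow: tuple[float, float] = (568.2, -0.746)
    zeu_switch: float = 102.0           # metres

    def pbopt(self, sst: np.ndarray) -> np.ndarray:
        """Optimal chlorophyll-specific rate, mg C (mg CHL)-1 h-1."""
        return self.pbopt_scale * 10.0 ** (
            self.pbopt_exp10_slope * np.asarray(sst, dtype=float)
            + self.pbopt_exp10_intercept
        )


def vgpm_eppley_forward(
    chl: np.ndarray | float,
    sst: np.ndarray | float,
    par: np.ndarray | float,
    params: VGPMParams | None = None,
) -> np.ndarray:
    """Depth-integrated NPP (mg C m-2 day-1) from surface CHL, SST and PAR.

    CHL in mg m-3, SST in degC, PAR in mol photons m-2 day-1. Inputs
    broadcast; negative CHL or PAR is rejected. NPP is exactly zero wherever
    CHL is zero, and the exponential temperature dependence makes the ratio
    ``npp(T + dT) / npp(T)`` independent of T at fixed CHL and PAR.
    """
    p = params or VGPMParams()
    chl = np.asarray(chl, dtype=float)
    sst = np.asarray(sst, dtype=float)
    par = np.asarray(par, dtype=float)
    if np.any(chl < 0):
        raise ValueError("negative CHL is not physical")
    if np.any(par < 0):
        raise ValueError("negative PAR is not physical")

    chl_s, chl_e = np.where(chl < 1.0, p.chl_tot_low[0], p.chl_tot_high[0]), np.where(
        chl < 1.0, p.chl_tot_low[1], p.chl_tot_high[1]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        chl_tot = chl_s * chl ** chl_e
        z_eu = p.zeu_deep[0] * chl_tot ** p.zeu_deep[1]
        z_eu = np.where(
            z_eu <= p.zeu_switch,
            p.zeu_shallow[0] * chl_tot ** p.zeu_shallow[1],
            z_eu,
        )
        light = par / (par + p.light_half_sat)
        npp = p.npp_scale * p.pbopt(sst) * light * z_eu * chl * p.day_length_hours
    return np.where(chl > 0, npp, 0.0)


@dataclass
class SceneConfig:
    """Study conditions for one synthetic scene.

    Defaults emulate a 21-year monthly record (the length of the satellite
    productivity era analysed with these methods) on a coarse global-ocean
    grid spanning 60S-60N, with a warm-biased subtropical SST field, an AR(1)
    SST anomaly of ~0.8 degC stationary spread, a weak negative CHL response
    and a positive PAR response to warming, and NPP-anomaly coefficients
    sized so that direct thermal, chlorophyll and light pathways all
    contribute at realistic magnitudes (tens of mg C m-2 day-1).
    """

    n_years: int = 21
    n_lat: int = 10
    n_lon: int = 10
    start_year: int = 1998
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    sst_mean: float | np.ndarray | None = None          # degC, per latitude
    sst_seasonal_amp: float | np.ndarray | None = None  # degC, per latitude
    ar1_phi: float = 0.7
    sst_noise_sd: float = 0.6       # degC innovation SD
    alpha_true: float = -0.02       # mg m-3 per degC
    beta_true: float = 0.8          # mol photons m-2 day-1 per degC
    a_true: float = -12.0           # mg C m-2 day-1 per degC
    b_true: float = 150.0           # mg C m-2 day-1 per mg m-3
    c_true: float = 2.0             # mg C m-2 day-1 per mol photons m-2 day-1
    d_true: float = 250.0           # mg C m-2 day-1 per mg m-3
    e_true: float = 3.0             # mg C m-2 day-1 per mol photons m-2 day-1
    chl_res_sd: float = 0.05        # mg m-3
    par_res_sd: float = 2.0         # mol photons m-2 day-1
    npp_res_sd: float = 30.0        # mg C m-2 day-1
    mhw_boost: float = 0.0          # extra degC per unit of innovation tail excess
    mhw_npp_amp: float = 1.0        # amplification of the a-pathway in MHW months
    use_vgpm_forward: bool = False
    vgpm_params: VGPMParams = field(default_factory=VGPMParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not np.isfinite(self.ar1_phi) or abs(self.ar1_phi) >= 1.0:
            raise ValueError("ar1_phi must satisfy |phi| < 1")
        for name in ("sst_noise_sd", "chl_res_sd", "par_res_sd", "npp_res_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("alpha_true", "beta_true", "a_true", "b_true", "c_true",
                     "d_true", "e_true", "mhw_boost", "mhw_npp_amp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.lat is None:
            self.lat = np.linspace(-60.0, 60.0, self.n_lat)
        else:
            self.lat = np.asarray(self.lat, dtype=float)
            self.n_lat = self.lat.size
        if self.lon is None:
            self.lon = np.linspace(0.0, 360.0, self.n_lon, endpoint=False)
        else:
            self.lon = np.asarray(self.lon, dtype=float)
            self.n_lon = self.lon.size
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitudes must lie within [-90, 90]")
        if self.n_lat * self.n_lon < 2:
            raise ValueError("grid must have at least 2 cells")

    # per-latitude defaults ---------------------------------------------------

    def _lat_profile(self, value: float | np.ndarray | None, default: np.ndarray) -> np.ndarray:
        if value is None:
            return default
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_lat,))
        return np.array(arr)

    def sst_mean_profile(self) -> np.ndarray:
        latr = np.deg2rad(self.lat)
        return self._lat_profile(self.sst_mean, 28.0 * np.cos(latr))

    def sst_amp_profile(self) -> np.ndarray:
        latr = np.deg2rad(self.lat)
        return self._lat_profile(self.sst_seasonal_amp, 2.0 + 4.0 * np.sin(latr) ** 2)


@dataclass
class Scene:
    """One simulated scene: four fields, generator truth, raw anomalies."""

    sst: GriddedMonthlySeries
    chl: GriddedMonthlySeries
    par: GriddedMonthlySeries
    npp: GriddedMonthlySeries
    truth: dict
    anomalies: dict
    config: SceneConfig


def _seasonal_shape(months: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """(time, lat) seasonal factor in [-1, 1]; peak month 8 in the north, 2 in the south."""
    peak = np.where(lat >= 0.0, 8.0, 2.0)
    return np.cos(2.0 * np.pi * (months[:, None] - peak[None, :]) / 12.0)


def simulate_scene(cfg: SceneConfig) -> Scene:
    """Simulate one scene; identical config (including seed) gives identical arrays."""
    rng = np.random.default_rng(cfg.seed)
    nt = cfg.n_years * 12
    time = monthly_period_index(cfg.start_year, nt)
    months = np.asarray(time.month, dtype=float)
    nlat, nlon = cfg.n_lat, cfg.n_lon
    latr = np.deg2rad(cfg.lat)

    season = _seasonal_shape(months, cfg.lat)  # (time, lat)
    sst_base = (cfg.sst_mean_profile()[None, :] + cfg.sst_amp_profile()[None, :] * season)
    sst_base = np.broadcast_to(sst_base[:, :, None], (nt, nlat, nlon)).copy()

    # AR(1) SST anomaly, stationary initialisation; optional warm-tail inflation.
    z = rng.standard_normal((nt, nlat, nlon))
    innov = cfg.sst_noise_sd * z + cfg.mhw_boost * np.clip(z - _Z90, 0.0, None)
    ssta = np.empty((nt, nlat, nlon))
    sd_stat = cfg.sst_noise_sd / np.sqrt(1.0 - cfg.ar1_phi**2) if cfg.sst_noise_sd > 0 else 0.0
    ssta[0] = sd_stat * rng.standard_normal((nlat, nlon)) + innov[0]
    for t in range(1, nt):
        ssta[t] = cfg.ar1_phi * ssta[t - 1] + innov[t]

    eps_chl = cfg.chl_res_sd * rng.standard_normal((nt, nlat, nlon))
    eps_par = cfg.par_res_sd * rng.standard_normal((nt, nlat, nlon))
    eps_npp = cfg.npp_res_sd * rng.standard_normal((nt, nlat, nlon))

    chla = cfg.alpha_true * ssta + eps_chl
    para = cfg.beta_true * ssta + eps_par

    sst = sst_base + ssta

    # MHW-conditional amplification of the direct thermal pathway: the scene's
    # own per-(calendar month, cell) 90th percentile of SST marks its extremes,
    # matching what the labelling stage will recover from the emitted field.
    if cfg.mhw_npp_amp != 1.0:
        thr = np.empty((12, nlat, nlon))
        for m in range(1, 13):
            thr[m - 1] = np.quantile(sst[months == m], 0.90, axis=0)
        amp_mask = sst > thr[np.asarray(time.month) - 1]
        a_eff = cfg.a_true * (1.0 + (cfg.mhw_npp_amp - 1.0) * amp_mask)
    else:
        a_eff = cfg.a_true

    nppa = (
        a_eff * ssta
        + cfg.b_true * (cfg.alpha_true * ssta)
        + cfg.c_true * (cfg.beta_true * ssta)
        + cfg.d_true * eps_chl
        + cfg.e_true * eps_par
        + eps_npp
    )

    chl_base = (0.25 + 0.45 * np.sin(latr) ** 2)[None, :] * (1.0 + 0.2 * season)
    chl_base = np.broadcast_to(chl_base[:, :, None], (nt, nlat, nlon))
    par_base = np.maximum(8.0, (52.0 * np.cos(latr))[None, :] * (1.0 + 0.35 * season))
    par_base = np.broadcast_to(par_base[:, :, None], (nt, nlat, nlon))

    chl_raw = chl_base + chla
    par_raw = par_base + para
    chl = np.clip(chl_raw, 0.0, None)
    par = np.clip(par_raw, 0.0, None)

    if cfg.use_vgpm_forward:
        npp = vgpm_eppley_forward(chl, sst, par, cfg.vgpm_params)
        npp_raw = npp
    else:
        npp_base = (420.0 + 380.0 * np.sin(latr) ** 2)[None, :] * (1.0 + 0.25 * season)
        npp_base = np.broadcast_to(npp_base[:, :, None], (nt, nlat, nlon))
        npp_raw = npp_base + nppa
        npp = np.clip(npp_raw, 0.0, None)

    clip_fraction = {
        "chl": float(np.mean(chl_raw < 0.0)),
        "par": float(np.mean(par_raw < 0.0)),
        "npp": 0.0 if cfg.use_vgpm_forward else float(np.mean(npp_raw < 0.0)),
    }

    truth = {
        "alpha": cfg.alpha_true,
        "beta": cfg.beta_true,
        "a": cfg.a_true,
        "b": cfg.b_true,
        "c": cfg.c_true,
        "d": cfg.d_true,
        "e": cfg.e_true,
        # identifiable slope of the SSTA-direction pathway (see decomposition)
        "g": cfg.a_true + cfg.b_true * cfg.alpha_true + cfg.c_true * cfg.beta_true,
        "mhw_npp_amp": cfg.mhw_npp_amp,
        "clip_fraction": clip_fraction,
    }
    if cfg.use_vgpm_forward:
        # the linear NPPA coefficients do not describe a VGPM-generated field
        for k in ("a", "b", "c", "d", "e", "g"):
            truth[k] = None

    mk = lambda v, u: GriddedMonthlySeries(v, time, cfg.lat, cfg.lon, units=u)
    return Scene(
        sst=mk(sst, "degC"),
        chl=mk(chl, "mg m-3"),
        par=mk(par, "mol photons m-2 day-1"),
        npp=mk(npp, "mg C m-2 day-1"),
        truth=truth,
        anomalies={"ssta": ssta, "chla": chla, "para": para, "nppa": nppa,
                   "eps_chl": eps_chl, "eps_par": eps_par, "eps_npp": eps_npp},
        config=cfg,
    )
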