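import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from heatnpp import (
    GriddedMonthlySeries,
    SceneConfig,
    anomalies,
    monthly_climatology,
    monthly_period_index,
    simulate_scene,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_series(values, start_year=2000, lat=None, lon=None, units="degC"):
    """Wrap a (time, lat, lon) array as a GriddedMonthlySeries on a simple grid."""
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    if lat is None:
        lat = np.linspace(-60.0, 60.0, nlat) if nlat > 1 else np.array([0.0])
    if lon is None:
        lon = np.arange(nlon, dtype=float)
    return GriddedMonthlySeries(values, monthly_period_index(start_year, nt), lat, lon, units)


def pipeline_anomalies(scene, baseline=None):
    """Anomalies of all four scene fields against their own monthly climatology."""
    if baseline is None:
        yrs = scene.sst.years
        baseline = (int(yrs.min()), int(yrs.max()))
    out = {}
    for name in ("sst", "chl", "par", "npp"):
        series = getattr(scene, name)
        out[name] = anomalies(series, monthly_climatology(series, baseline))
    return out


def ols_normal_equations_oracle(ssta, chla, para, nppa):
    """Independent closed-form solve of both regression stages.

    Stage-1 slopes from the scalar projection formula; stage-2 coefficients
    from the explicit (pseudo-inverted) Gram matrix of the five regressors.
    """
    s, ch, pa, y = (np.asarray(v, dtype=float) for v in (ssta, chla, para, nppa))
    ss = s @ s
    alpha = s @ ch / ss
    beta = s @ pa / ss
    chl_res = ch - alpha * s
    par_res = pa - beta * s
    X = np.column_stack([s, alpha * s, beta * s, chl_res, par_res])
    G = X.T @ X
    coef = np.linalg.pinv(G) @ (X.T @ y)
    return {
        "alpha": alpha, "beta": beta,
        "a": coef[0], "b": coef[1], "c": coef[2], "d": coef[3], "e": coef[4],
        "g": coef[0] + coef[1] * alpha + coef[2] * beta,
    }


@pytest.fixture(scope="session")
def default_scene():
    """Small default-condition scene shared by read-only tests."""
    return simulate_scene(SceneConfig(n_lat=6, n_lon=6, seed=3))


@pytest.fixture(scope="session")
def default_anomalies(default_scene):
    return pipeline_anomalies(default_scene)
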