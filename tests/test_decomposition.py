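"""Two-stage regression: exactness, oracle equivalence, recovery, composites."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from heatnpp import (
    SceneConfig,
    composite_components,
    decompose_cell,
    decompose_grid,
    label_conditions,
    monthly_climatology,
    simulate_scene,
)
from heatnpp.decomposition import TERM_NAMES

from conftest import make_series, ols_normal_equations_oracle, pipeline_anomalies


def noisy_cell(seed=3, n=252, g_split=(3.0, 1.0, -2.0), alpha=2.0, beta=-1.0):
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, 1.0, n)
    e_c = rng.normal(0.0, 0.5, n)
    e_p = rng.normal(0.0, 0.8, n)
    e_n = rng.normal(0.0, 1.0, n)
    a, b, c = g_split
    ch = alpha * s + e_c
    pa = beta * s + e_p
    y = a * s + b * alpha * s + c * beta * s + 4.0 * e_c + 1.5 * e_p + e_n
    return s, ch, pa, y


class TestDecomposeCell:
    def test_zero_noise_cell_recovers_stage1_exactly_and_leaves_no_residual(self):
        n = 48
        s = np.sin(np.arange(n) / 3.0)
        ch, pa = 2.0 * s, -1.0 * s
        y = 3.0 * s + 1.0 * ch + (-2.0) * pa  # (a,b,c)=(3,1,-2), d=e=0
        cell = decompose_cell(s, ch, pa, y)
        assert cell.alpha == pytest.approx(2.0, abs=1e-12)
        assert cell.beta == pytest.approx(-1.0, abs=1e-12)
        # residual regressors are identically zero -> flagged, coefficients 0
        assert set(cell.zero_variance) == {"chla_res", "para_res"}
        assert cell.d == 0.0 and cell.e == 0.0
        np.testing.assert_allclose(cell.sst_dependent, y, atol=1e-10)
        np.testing.assert_allclose(cell.terms["nppa_res"], 0.0, atol=1e-10)
        # the SSTA-direction slope is identified even though (a,b,c) are not
        assert cell.g == pytest.approx(3.0 + 1.0 * 2.0 + (-2.0) * (-1.0), rel=1e-12)

    def test_conservation_is_exact_for_arbitrary_inputs(self):
        rng = np.random.default_rng(1)
        s, ch, pa, y = rng.normal(size=(4, 120))
        y *= 50.0
        cell = decompose_cell(s, ch, pa, y)
        total = sum(cell.terms[k] for k in TERM_NAMES)
        assert np.nanmax(np.abs(y - total)) < 1e-10 * np.max(np.abs(y))
        np.testing.assert_allclose(cell.sst_dependent + cell.sst_independent, total,
                                   atol=1e-12)

    def test_matches_normal_equations_oracle_on_seeded_cells(self):
        for seed in range(10):
            s, ch, pa, y = noisy_cell(seed=seed)
            cell = decompose_cell(s, ch, pa, y)
            oracle = ols_normal_equations_oracle(s, ch, pa, y)
            for key, want in oracle.items():
                got = getattr(cell, key)
                assert got == pytest.approx(want, rel=1e-8, abs=1e-10), key

    def test_residuals_are_orthogonal_to_their_regressors(self):
        s, ch, pa, y = noisy_cell(seed=8)
        cell = decompose_cell(s, ch, pa, y)
        scale = len(s) * np.std(s)
        assert abs(np.dot(cell.chla_res, s)) < 1e-8 * scale * np.std(ch)
        assert abs(np.dot(cell.para_res, s)) < 1e-8 * scale * np.std(pa)
        res = cell.terms["nppa_res"]
        for reg in (s, cell.chla_sst, cell.para_sst, cell.chla_res, cell.para_res):
            assert abs(np.dot(res, reg)) < 1e-7 * len(s) * np.std(y) * (np.std(reg) + 1e-30)

    @given(k=st.floats(0.1, 1000.0))
    def test_scaling_nppa_scales_all_stage2_coefficients_and_terms(self, k):
        s, ch, pa, y = noisy_cell(seed=2, n=120)
        base = decompose_cell(s, ch, pa, y)
        scaled = decompose_cell(s, ch, pa, k * y)
        for key in ("a", "b", "c", "d", "e", "g"):
            assert getattr(scaled, key) == pytest.approx(k * getattr(base, key), rel=1e-9)
        np.testing.assert_allclose(scaled.sst_dependent, k * base.sst_dependent, rtol=1e-9)
        np.testing.assert_allclose(scaled.sst_independent, k * base.sst_independent,
                                   rtol=1e-9, atol=1e-9 * k)

    def test_zero_variance_ssta_flags_degenerate_and_keeps_residual_pathways(self):
        rng = np.random.default_rng(4)
        n = 60
        s = np.zeros(n)
        ch = rng.normal(size=n)
        pa = rng.normal(size=n)
        y = 5.0 * ch - 2.0 * pa + rng.normal(scale=0.1, size=n)
        cell = decompose_cell(s, ch, pa, y)
        assert cell.degenerate
        assert (cell.alpha, cell.beta, cell.a, cell.b, cell.c) == (0, 0, 0, 0, 0)
        assert cell.d == pytest.approx(5.0, abs=0.1)
        assert cell.e == pytest.approx(-2.0, abs=0.1)
        total = sum(cell.terms[k] for k in TERM_NAMES)
        np.testing.assert_allclose(total, y, atol=1e-10)

    def test_listwise_missing_months_share_one_sample(self):
        s, ch, pa, y = noisy_cell(seed=5, n=60)
        s[3], ch[10], pa[20], y[30] = np.nan, np.nan, np.nan, np.nan
        cell = decompose_cell(s, ch, pa, y)
        assert cell.n == 56
        assert np.isnan(cell.sst_dependent[[3, 10, 20, 30]]).all()

    def test_too_few_months_rejected(self):
        s, ch, pa, y = noisy_cell(seed=6, n=20)
        with pytest.raises(ValueError, match="complete months"):
            decompose_cell(s, ch, pa, y, min_months=24)

    def test_intercept_option_estimates_near_zero_on_anomaly_input(self):
        s, ch, pa, y = noisy_cell(seed=7)
        plain = decompose_cell(s, ch, pa, y)
        with_icpt = decompose_cell(s, ch, pa, y, intercept=True)
        # the fitted intercept lands in the residual term; for anomaly input it
        # is statistically indistinguishable from zero
        icpt = np.nanmean(with_icpt.terms["nppa_res"])
        assert abs(icpt) < 3.0 * np.nanstd(y) / np.sqrt(len(y))
        assert with_icpt.g == pytest.approx(plain.g, rel=0.05)


class TestDecomposeGrid:
    def test_grid_replicating_one_cell_reproduces_the_cell_answer(self):
        s, ch, pa, y = noisy_cell(seed=3, n=120)
        tile = lambda v: make_series(np.tile(v[:, None, None], (1, 2, 2)))
        grid = decompose_grid(tile(s), tile(ch), tile(pa), tile(y))
        cell = decompose_cell(s, ch, pa, y)
        for key in ("alpha", "beta", "a", "b", "c", "d", "e", "g"):
            np.testing.assert_allclose(grid.coef[key], getattr(cell, key), rtol=1e-12)

    def test_fully_missing_cell_is_masked_without_contaminating_neighbours(self):
        s, ch, pa, y = noisy_cell(seed=3, n=120)
        stack = lambda v: np.tile(v[:, None, None], (1, 2, 2))
        arrs = [stack(v) for v in (s, ch, pa, y)]
        arrs[0][:, 0, 1] = np.nan
        grid = decompose_grid(*[make_series(a) for a in arrs])
        assert grid.masked[0, 1] and not grid.masked[0, 0]
        assert np.isnan(grid.coef["alpha"][0, 1])
        cell = decompose_cell(s, ch, pa, y)
        assert grid.coef["alpha"][0, 0] == pytest.approx(cell.alpha, rel=1e-12)

    def test_fit_mask_restricts_the_fitted_sample(self):
        s, ch, pa, y = noisy_cell(seed=9, n=120)
        tile = lambda v: make_series(np.tile(v[:, None, None], (1, 2, 2)))
        mask = np.zeros(120, dtype=bool)
        mask[:40] = True
        grid = decompose_grid(tile(s), tile(ch), tile(pa), tile(y),
                              fit_mask=mask, min_months=12)
        assert (grid.n == 40).all()
        assert np.isnan(grid.sst_dependent[40:]).all()
        cell = decompose_cell(s[:40], ch[:40], pa[:40], y[:40], min_months=12)
        np.testing.assert_allclose(grid.coef["g"], cell.g, rtol=1e-12)
        with pytest.raises(ValueError, match="fit_mask"):
            decompose_grid(tile(s), tile(ch), tile(pa), tile(y),
                           fit_mask=np.zeros((5, 2, 2), dtype=bool))

    def test_coefficient_recovery_is_unbiased_over_cells(self):
        cfg = SceneConfig(n_lat=8, n_lon=8, seed=12)
        scene = simulate_scene(cfg)
        a = pipeline_anomalies(scene)
        grid = decompose_grid(a["sst"], a["chl"], a["par"], a["npp"])
        for key, truth in (("alpha", cfg.alpha_true), ("beta", cfg.beta_true),
                           ("g", scene.truth["g"]), ("d", cfg.d_true), ("e", cfg.e_true)):
            est = grid.coef[key][~grid.masked]
            se = est.std(ddof=1) / np.sqrt(est.size)
            assert abs(est.mean() - truth) < 3.0 * se + 1e-12, key


@pytest.fixture(scope="module")
def labelled(default_scene, default_anomalies):
    a = default_anomalies
    clim = monthly_climatology(default_scene.sst, (1998, 2018))
    labels = label_conditions(default_scene.sst, clim)
    decomp = decompose_grid(a["sst"], a["chl"], a["par"], a["npp"])
    return decomp, labels


class TestCompositeComponents:

    def test_constant_components_composite_to_their_values(self, labelled):
        import dataclasses

        decomp, labels = labelled
        decomp = dataclasses.replace(
            decomp,
            sst_dependent=np.full_like(decomp.sst_dependent, 4.0),
            sst_independent=np.full_like(decomp.sst_independent, -1.0),
        )
        comp = composite_components(decomp, labels, "MHW")
        ok = ~np.isnan(comp.nppa)
        assert ok.any()
        np.testing.assert_allclose(comp.sst_dependent[ok], 4.0)
        np.testing.assert_allclose(comp.sst_independent[ok], -1.0)
        np.testing.assert_allclose(comp.nppa[ok], 3.0)

    def test_composite_additivity_is_exact(self, default_scene, default_anomalies):
        a = default_anomalies
        clim = monthly_climatology(default_scene.sst, (1998, 2018))
        labels = label_conditions(default_scene.sst, clim)
        decomp = decompose_grid(a["sst"], a["chl"], a["par"], a["npp"])
        for condition in ("SSTA_PLUS", "MHW"):
            comp = composite_components(decomp, labels, condition)
            err = np.nanmax(np.abs(comp.nppa - (comp.sst_dependent + comp.sst_independent)))
            assert err < 1e-10

    def test_cells_without_enough_condition_months_are_masked(self, labelled):
        decomp, labels = labelled
        comp = composite_components(decomp, labels, "MHW", min_condition_months=10**6)
        assert np.isnan(comp.nppa).all()

    def test_unknown_condition_rejected(self, labelled):
        decomp, labels = labelled
        with pytest.raises(ValueError, match="unknown condition"):
            composite_components(decomp, labels, "HEATWAVE")
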