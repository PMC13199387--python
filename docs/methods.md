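# Methods

## The problem

Marine heatwaves (MHWs) — months in which sea surface temperature (SST)
exceeds the seasonally varying 90th-percentile threshold of a fixed baseline
climatology — perturb ocean net primary production (NPP) through several
pathways at once: directly through temperature-dependent physiology, and
indirectly through chlorophyll (CHL) and light (PAR) changes that may or may
not themselves covary with the warming. `heatnpp` implements a pipeline that
separates these pathways per grid cell and asks, under moderate warming
versus MHW conditions, whether the NPP anomaly is carried mainly by
SST-coupled or SST-independent variability, and whether a cell's
productivity responds positively ("enhanced") or negatively ("inhibited")
to warm anomalies.

## Event labelling

For each calendar month `m` and cell, a fixed baseline window supplies a
mean `clim_m` and a quantile threshold `q90_m` (default probability 0.90,
linear interpolation between order statistics — the convention is recorded
on the climatology object and configurable, because at baseline sample
sizes around 20–25 years the labelled set is sensitive to it). A cell-month
is then labelled

* `MHW` if SST > `q90_m` (strict, matching "exceeds"),
* `SSTA_PLUS` if SST > `clim_m` and SST ≤ `q90_m` (moderate warming),
* `OTHER` if SST ≤ `clim_m`; missing inputs propagate as `MISSING`.

The three labels partition every non-missing cell-month, and the union of
`MHW` and `SSTA_PLUS` is exactly the set of positive-anomaly months. No
minimum-duration rule is applied at monthly resolution, no detrending is
applied before the climatology (the fixed-baseline convention), and no
multi-month smoothing is applied to the monthly climatology. A minimum of 2
valid baseline years per (month, cell) is required; leaner cells are masked
rather than extrapolated.

Out-of-baseline calibration: for stationary series the labelled MHW
frequency converges to `1 − q` as the baseline lengthens. At a 24-year
baseline the interpolated sample quantile carries a small positive
occupancy bias (order 1/n); the calibration checks therefore use long
baselines (hundreds of years per calendar month) where the residual bias is
well inside the binomial sampling band.

## Anomalies and the two-stage decomposition

Anomalies are deviations from the per-calendar-month baseline mean of each
field (SSTA, CHLA, PARA, NPPA), so baseline-window anomaly means vanish per
month and cell. Per cell, over the listwise-complete months of all four
series (default minimum 24 months), two ordinary-least-squares stages are
fit without intercepts (anomaly inputs have near-zero mean; an intercept
mode exists and its estimate is folded into the residual so the budget
stays exact):

Stage 1 splits CHLA and PARA into SST-projected and residual parts:

    CHLA = α·SSTA + CHLA_res        PARA = β·SSTA + PARA_res

Stage 2 regresses NPPA jointly on the five series:

    NPPA = a·SSTA + b·CHLA_sst + c·PARA_sst        (SST-dependent group)
         + d·CHLA_res + e·PARA_res + NPPA_res      (SST-independent group)

The six-term budget sums to NPPA exactly at every fitted month (the
residual is defined as the remainder), CHLA_res and PARA_res are exactly
sample-orthogonal to SSTA by construction, and NPPA_res is orthogonal to
all five regressors.

**Identifiability.** `CHLA_sst` and `PARA_sst` are exact scalar multiples
of SSTA, so the stage-2 design has rank 3 and only the combination
`g = a + b·α + c·β` (the SSTA-direction slope), together with `α, β, d, e`,
is determined by the data; any (a, b, c) with the same `g` generates
identical fields. The solver reports the minimum-norm representative (SVD
least squares) alongside `g` itself, and every grouped series, composite
and classification depends only on the identifiable quantities. Parameter-
recovery checks are therefore stated for (α, β, g, d, e). Columns that are
identically zero (e.g. zero-noise scenes) receive coefficient 0 and are
flagged; a zero-variance SSTA makes the thermal pathway undefined — the
cell is flagged degenerate, α, β, a, b, c are set to 0 by convention and
the residual pathways carry all variance.

**Composites and refits.** Condition composites are time means of NPPA and
the two grouped sums over one label's months (minimum 3), preserving the
exact partition. By default the regression is fit once per cell over all
months and only the composites are condition-restricted — the stabler
choice at monthly sample sizes. A per-condition refit mode (`fit_mask`)
restricts the fitted sample to one label's months. The distinction matters
when the SSTA–NPPA coupling itself changes under MHW conditions: an
MHW-conditional amplification of the thermal pathway is a nonlinearity in
SSTA, and a single all-months linear fit attributes only a fraction
`w = E[S²·1(S>s₉₀)]/E[S²] ≈ 0.33` of it to the fitted slope, pushing the
remaining ≈ 0.67 into the MHW-month residual — i.e. into the
SST-independent group. Conditional refits attribute the conditional
coupling to the thermal pathway, which is why the dominance-shift
demonstration uses them.

## Classification and aggregation

* **Dominance** (per condition): |composite mean of the SST-dependent
  group| vs |SST-independent group|; strict inequality decides, an exact
  tie goes to SST-independent (the conservative choice, flagged), masked
  composites are undefined. The comparison of composited means (rather
  than variance shares) matches the budget presentation; a variance-share
  mode would be a straightforward extension.
* **Warming response**: per-cell Pearson correlation of NPPA with SSTA over
  all complete months (a condition-restricted sample is available as an
  option), two-sided p-value from `t = r·sqrt((n−2)/(1−r²))`. Cells with
  `r > 0` and `p < α_sig` (default 0.10, i.e. 90% confidence) are
  MHW-enhanced, `r < 0` MHW-inhibited, the rest neutral; zero-variance or
  short samples (n < 8) are undefined. No autocorrelation correction and
  no multiple-testing adjustment across cells is applied; an
  effective-degrees-of-freedom option would be the natural refinement.
* **Aggregation**: area fractions and regional/band means weight cells by
  cos(latitude). Box statistics (quartiles, 1.5×IQR whiskers clipped to
  the observed range) are computed over unweighted cell values while the
  mean marker is area-weighted. Latitude bands are lower-edge-inclusive
  with the final band closing its upper edge, so a covering edge set
  partitions the grid and band means aggregate exactly to the global
  weighted mean. Change ratios compare one condition's composite mean to
  the cell's long-term mean in percent, masking cells whose long-term mean
  magnitude falls below a floor; note that a perturbation confined to
  condition months also lifts the long-term mean by its occupancy share,
  so an injected +10% on MHW months is recovered as
  `100·0.1·(1−f)/(1+0.1f)` with `f` the MHW occupancy (≈ 8.9% at f = 0.1).
  Internal NPP units are mg C m⁻² day⁻¹; `to_annual_gc` converts to
  gC m⁻² year⁻¹ (×365/1000) for reporting.

## The synthetic scene generator

The generator emits the exact forward model the decomposition assumes, on a
monthly grid with known coefficients:

* SST = latitude-dependent seasonal cycle (warmer and flatter in the
  subtropics, peak month 8 north / 2 south) + a stationary AR(1) anomaly
  (default φ = 0.7, innovation SD 0.6 °C ⇒ stationary spread ≈ 0.84 °C,
  initialised from the stationary distribution). An optional `mhw_boost`
  inflates the innovation's upper tail so warm extremes arise from the
  innovation distribution rather than being hand-placed, preserving the
  stationarity the climatology assumes.
* CHLA = α·SSTA + ε_chl, PARA = β·SSTA + ε_par, and
  NPPA = a·SSTA + b·(α·SSTA) + c·(β·SSTA) + d·ε_chl + e·ε_par + ε_npp,
  added to smooth positive base fields. Defaults (α = −0.02 mg m⁻³ °C⁻¹,
  β = +0.8 mol photons m⁻² day⁻¹ °C⁻¹, a = −12, b = 150, c = 2, d = 250,
  e = 3 in mg C m⁻² day⁻¹ per regressor unit, residual SDs 0.05 / 2 / 30)
  give all pathways realistic magnitudes of tens of mg C m⁻² day⁻¹ against
  base NPP of several hundred, a weak negative chlorophyll and positive
  light response to warming, and an overall warm-inhibited correlation
  r ≈ −0.3. The default record is 21 years (252 months), the length of the
  satellite-productivity era these methods target, on a coarse 60°S–60°N
  grid.
* Negative CHL/PAR/NPP from additive noise are clipped at zero and the
  clipped fraction reported (≈ 0 under defaults; the regression is
  unaffected when clipping is rare). Because generator anomalies are
  linear in the same monthly structure the pipeline estimates, subtracting
  the estimated monthly climatology reproduces the generator's anomaly
  relations exactly — zero-noise scenes round-trip to machine precision.
* `mhw_npp_amp` multiplies the direct thermal coefficient `a` in months
  where SST exceeds the scene's own per-(calendar month, cell) empirical
  90th percentile — the same threshold the labelling stage recovers — to
  emulate strengthened SST–NPP covariance under extreme warming.
* `use_vgpm_forward` replaces the linear NPPA construction with an
  Eppley-variant VGPM forward formula: NPP = 0.66125 · P_opt(SST) ·
  PAR/(PAR + 4.1) · Z_eu(CHL) · CHL · day length, with
  P_opt = 1.54·10^(0.0275·T − 0.07) (exponential in temperature) and the
  standard two-branch euphotic-depth power laws from integrated
  chlorophyll. Every coefficient is configurable; only the structural form
  matters for exercising the pipeline on a realistically nonlinear
  product. Linear ground-truth coefficients are not recorded for VGPM
  scenes (they do not describe the field).

What the generator does **not** emulate: spatial covariance between cells
(cells are independent), sea-ice or land masks, observational error
structure, trends, and the autocorrelation of CHL/PAR residuals. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under the assumed structure, not the magnitude of
any real-ocean response — headline area fractions and regional budgets
from real data require the multi-decade satellite and reanalysis products,
which are outside the package's scope.

## Numerical choices and problem sizes

Least squares uses SVD (`lstsq`) with machine-precision rank detection;
Gram-matrix pseudo-inverse solves serve as an independent oracle in tests.
Quantiles use linear interpolation unless configured otherwise. Missing
months are dropped listwise across all four series so every fitted
quantity shares one sample. Tests and the acceptance script run on scenes
of 100–800 cells × 60–252 months (10⁴ cells for calibration Monte-Carlo),
sizes at which every stage completes in seconds while leaving Monte-Carlo
bands tight enough to detect miscalibration; the pipeline itself is
vectorised over time and loops only over cells.

## Known limitations

* The (a, b, c) split is reported by minimum-norm convention only; consumers
  should use `g` and the grouped series (see Identifiability).
* Significance testing ignores serial correlation, so the effective type-I
  rate under strongly autocorrelated anomalies exceeds the nominal level.
* Dominance near |dep| ≈ |indep| is sampling-noise sensitive; the tie rule
  only fixes the measure-zero boundary.
* Region masks are consumed, not derived: large-marine-ecosystem or regime
  geometries must be supplied as raster masks.
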