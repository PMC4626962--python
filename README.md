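# pm25risk

Temporal–spatial simulation of urban PM2.5 concentration and mapping of
population-exposure risk, built around a back-propagation neural network
(BP-ANN) and simple GIS machinery.

The package is for air-quality and environmental-health analysts who have
per-station daily records — PM2.5, SO2, NO2 (μg/m³), mean temperature (°C),
precipitation (mm/day), wind speed (m/s), plus station-area GDP and
population density — and want to (1) screen which covariates move with
PM2.5, (2) fit and validate a nonlinear concentration model, (3) forecast
future concentrations from projected covariates, and (4) turn concentration
surfaces into population-exposure risk maps.

## The model

**Network.** A two-layer feed-forward network with logistic hidden units and
a linear output:

    H_j = f(Σ_i ω_ij x_i − α_j),   f(t) = 1/(1+e^−t)
    O_k = Σ_j H_j ω_jk − b_k

trained to minimize the sum of squared errors on min-max-normalized data.
Three optimizers are provided: the classic per-sample gradient-descent
update rules (`gd`), resilient backpropagation (`trainrp`, per-parameter
step sizes driven only by gradient *signs*), and Levenberg–Marquardt
(`trainlm`, damped Gauss–Newton steps `(JᵀJ + βI)d = −Jᵀe`).

**Forecasting** follows the fit-then-forecast (P–T–P′–T′) protocol: the
network is trained on historical covariate/concentration pairs, covariates
are extrapolated per station and calendar month (linear or compound-growth
trends, optionally with scenario factors), and the frozen network maps the
projected covariates P′ to future concentrations T′.

**Validation** uses four statistics per station: Pearson r, the index of
agreement IA = 1 − Σ(S−O)² / Σ(|S−Ō|+|O−Ō|)², mean bias error, and RMSE.

**Spatial stages.** Station values are interpolated onto a planar raster by
inverse-distance weighting (w_i = d_i^−p, exact at stations, convex in the
station values) and classified with exact Jenks natural breaks. Risk uses
the EPA-style inhalation chain: average daily dose ADD = C·IR·ED/(BW·AT),
slope factor SFI = UR·BW·IR, individual risk R_i = ADD·SFI (= C·IR²·UR when
ED = AT), and population risk POP_risk = R_i × population density, with
population-average defaults IR = 11.7 m³/day, UR = 0.008 per μg/m³,
BW = 57 kg.

**Synthetic data.** Monitoring data of this kind are rarely
redistributable, so `pm25risk.synthetic` generates station networks whose
pairwise correlations hit a published eight-variable screening table (e.g.
r(PM2.5, temperature) = −0.831, r(PM2.5, SO2) = +0.796) via a Gaussian
copula with quadrature-calibrated latent correlations, a genuine seasonal
cycle, and a *known* smooth response function — so model recovery can be
scored against ground truth. See `docs/methods.md` for details and limits.

## Worked example

```bash
python examples/02_train_and_validate.py
```

prints

```
trainlm: iterations 80, r=0.834 IA=0.902 MBE=-1.16 RMSE=24.94 ug/m3
trainrp: iterations 600, r=0.834 IA=0.902 MBE=-1.03 RMSE=24.95 ug/m3
```

Both optimizers reach held-out r ≈ 0.83 on two years of synthetic daily
records. That is essentially the noise ceiling: the generator's irreducible
residual SD is ≈ 25 μg/m³, which is exactly the RMSE the fits attain, and
the near-zero MBE says neither fit is biased. The other scripts in
`examples/` demonstrate the generator (01), screening (03), forecasting and
gridding (04) and risk zoning (05), each printing a few numbers and what
they mean.

The full pipeline is also available as a CLI:

```bash
pm25risk all --config config.yaml     # or: simulate/train/evaluate/forecast/grid/risk
```

which writes CSV reports, ESRI ASCII rasters and a deterministic
`manifest.json` (content hashes, seeds, parameters) to the configured
output directory.

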